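"""Gene-based analysis driver and result reporting.

Chains the I/O layer, the scoring mathematics and the set test over a
whole gene-model table: harmonize discovery summary statistics to the
test genotypes, apply the MAF filter and missing-call imputation once,
then per gene compute the LD-adjusted score and its regression p-value.
Also provides the threshold summary table (counts and proportions of
genes below a ladder of p-value thresholds) and the run manifest that
makes an analysis reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, core, genio, settest

logger = logging.getLogger("polaris")

__all__ = [
    "RunManifest",
    "GenewiseResult",
    "genewise_analysis",
    "summarize_thresholds",
]

TABLE_THRESHOLDS = (1.0, 0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte given the inputs."""

    command: str
    config: dict
    seed: int | None
    input_digests: dict[str, str]
    version: str
    timestamp: str

    @classmethod
    def create(cls, config: dict, seed: int | None = None,
               inputs: Sequence[str | Path] = ()) -> "RunManifest":
        digests = {}
        for p in inputs:
            p = Path(p)
            if p.exists():
                digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(command=" ".join(sys.argv), config=config, seed=seed,
                   input_digests=digests, version=__version__,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


@dataclass
class GenewiseResult:
    """Per-gene association results plus summary tables."""

    results: pd.DataFrame  # set_id, method, n_snps, statistic, df, p (sorted by p)
    threshold_summary: pd.DataFrame
    harmonization: genio.HarmonizationReport
    skipped: dict[str, str]  # gene -> reason
    n_annealed_loci: int
    scores: pd.DataFrame | None = None  # long per-person per-gene scores


def summarize_thresholds(pvalues: Sequence[float],
                         thresholds: Sequence[float] = TABLE_THRESHOLDS,
                         denominator: str = "total") -> pd.DataFrame:
    """Counts and proportions of p-values at or below each threshold.

    ``denominator="total"`` divides every count by the total number of
    sets analysed; ``denominator="previous"`` divides by the count at
    the next-looser threshold in the ladder.
    """
    if denominator not in ("total", "previous"):
        raise ValueError("denominator must be 'total' or 'previous'")
    p = np.asarray(list(pvalues), dtype=float)
    thresholds = sorted(thresholds, reverse=True)
    counts = [int((p <= t).sum()) for t in thresholds]
    rows = []
    for i, (t, k) in enumerate(zip(thresholds, counts)):
        if denominator == "total":
            denom = p.size
        else:
            denom = p.size if i == 0 else counts[i - 1]
        rows.append({"threshold": t, "n_genes": k,
                     "proportion": k / denom if denom else 0.0})
    return pd.DataFrame(rows)


def _format_df(df) -> str:
    return f"{df[0]},{df[1]}" if isinstance(df, tuple) else str(df)


def genewise_analysis(bed_prefix: str | Path,
                      summary_file: str | Path,
                      gene_model_file: str | Path | None = None,
                      set_file: str | Path | None = None,
                      *,
                      maf_threshold: float = 0.01,
                      ridge: float | str = "auto",
                      mode: str = "correlation",
                      gc_lambda: float | None = None,
                      covariates: np.ndarray | None = None,
                      method: str = "POLARIS",
                      anneal_alpha: float = 1e-6,
                      anneal_gap_bp: int = 250_000,
                      keep_scores: bool = False) -> GenewiseResult:
    """Gene-based association analysis over a whole PLINK dataset.

    For every gene (or explicit SNP set): restrict to harmonized,
    MAF-passing SNPs, compute the requested score on LD-adjusted dosages
    estimated from the test genotypes, and test it against the phenotype.
    ``method`` may also be ``"PCA_FTEST"`` to run the comparator instead.
    Genes whose SNPs are all filtered away are reported as skipped.
    Genes significant at ``anneal_alpha`` are merged into independent
    loci when separated by less than ``anneal_gap_bp``.
    """
    d = genio.read_plink(bed_prefix)
    summary = genio.read_summary_stats(summary_file)
    if gc_lambda is not None:
        summary = genio.genomic_control_adjust(summary, gc_lambda)
    summary, rep = genio.harmonize(summary, d.snps)

    usable = set(summary.ids)
    keep = [i for i, s in enumerate(d.snps) if s.id in usable]
    if not keep:
        raise ValueError("no SNPs survive harmonization")
    d = d.subset_snps(keep)
    d = genio.maf_filter(d, maf_threshold)
    d = genio.impute_missing(d)

    if (gene_model_file is None) == (set_file is None):
        raise ValueError("provide exactly one of gene_model_file / set_file")
    if gene_model_file is not None:
        genes = genio.read_gene_models(gene_model_file)
        sets = genio.assign_snps_to_sets(d.snps, genes)
        gene_pos = {str(g.gene_id): (str(g.chrom), int(g.start), int(g.end))
                    for g in genes.itertuples()}
    else:
        sets = genio.read_set_file(set_file)
        gene_pos = {}

    id_to_col = {s.id: i for i, s in enumerate(d.snps)}
    ridge_value = 1.0 / d.n if ridge == "auto" else float(ridge)

    rows, skipped = [], {}
    score_frames = []
    for sd in sets:
        cols = [id_to_col[s] for s in sd.snp_ids if s in id_to_col]
        if not cols:
            skipped[sd.set_id] = "all SNPs filtered"
            continue
        sub = d.subset_snps(cols)
        try:
            if method == "PCA_FTEST":
                res = settest.pca_ftest_set_test(sub.genotypes, sub.phenotype,
                                                 set_id=sd.set_id)
            else:
                beta = summary.beta_for(sub.snp_ids)
                c = core.correlation_matrix(sub.genotypes, mode=mode)
                spectrum = core.spectral_decompose(c)
                cfg = core.RidgeConfig(lambda0=ridge_value, mode=mode)
                if method == "POLARIS":
                    g_use = core.adjusted_dosages(sub.genotypes, spectrum, cfg)
                    score = core.polaris_score(beta, g_use, set_id=sd.set_id)
                elif method == "PRS":
                    score = core.prs_score(beta, sub.genotypes, set_id=sd.set_id)
                else:
                    raise ValueError(f"unknown method {method!r}")
                res = settest.polaris_set_test(score, sub.phenotype,
                                               covariates=covariates,
                                               n_snps=sub.m)
                if keep_scores:
                    score_frames.append(pd.DataFrame({
                        "person": np.arange(sub.n), "set_id": sd.set_id,
                        "method": method, "score": score.values,
                    }))
        except ValueError as e:
            skipped[sd.set_id] = str(e)
            logger.warning("gene %s skipped: %s", sd.set_id, e)
            continue
        rows.append({"set_id": sd.set_id, "method": method, "n_snps": res.n_snps,
                     "statistic": res.statistic, "df": _format_df(res.df),
                     "p": res.p})

    results = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    summary_tbl = summarize_thresholds(results["p"]) if len(results) else \
        summarize_thresholds([])

    hits = []
    for row in results.itertuples():
        if row.p <= anneal_alpha and row.set_id in gene_pos:
            chrom, start, end = gene_pos[row.set_id]
            hits.append((row.set_id, chrom, start, end, row.p))
    loci = genio.anneal_significant_genes(hits, gap_bp=anneal_gap_bp) if hits else []

    return GenewiseResult(
        results=results, threshold_summary=summary_tbl, harmonization=rep,
        skipped=skipped, n_annealed_loci=len(loci),
        scores=pd.concat(score_frames, ignore_index=True) if score_frames else None,
    )
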