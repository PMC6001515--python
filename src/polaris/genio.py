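"""Genotype / summary-statistic I/O and harmonization.

This module owns the data plumbing around the scoring mathematics:
reading PLINK 1 binary filesets, reading discovery summary statistics,
aligning the two allele conventions, the standard per-SNP filters
(minor-allele-frequency filter, 2xMAF mean imputation of missing calls,
genomic-control adjustment), SNP-to-gene assignment and the merging of
significant genes into independent loci.

Conventions
-----------
* The counted ("effect") allele of a test-set SNP is the first allele
  (A1) of the .bim file; genotype values count copies of that allele.
* Summary statistics must declare their effect allele explicitly; effect
  sizes are log odds ratios.
* Missing genotypes are stored as NaN in a float matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("polaris")

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> copies of A1:  00 hom A1 = 2, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam fileset is internally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """Identity and metadata of one SNP in the test set."""

    id: str
    chrom: str
    pos: int
    allele1: str  # counted / effect allele (A1)
    allele2: str
    maf: float  # minor allele frequency, folded to [0, 0.5]

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"SNP {self.id}: alleles must differ")


@dataclass
class GenotypeDataset:
    """Individual-level genotypes with phenotype and optional covariates.

    ``genotypes`` is an N x M float matrix of counted-allele dosages in
    {0, 1, 2, NaN}; columns follow ``snps`` order.  ``phenotype`` is 0/1
    (control/case) with NaN for missing.
    """

    genotypes: np.ndarray
    snps: list[SnpRecord]
    phenotype: np.ndarray
    covariates: np.ndarray | None = None
    fam: pd.DataFrame | None = None  # FID/IID bookkeeping from .fam

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[1] != len(self.snps):
            raise ValueError(
                f"genotype matrix has {self.genotypes.shape[1]} columns "
                f"but {len(self.snps)} SNP records"
            )
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise ValueError("phenotype length does not match genotype rows")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.genotypes).any())

    def subset_snps(self, index: Sequence[int]) -> "GenotypeDataset":
        """New dataset restricted to the SNP columns in ``index`` (ordered)."""
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, index],
            snps=[self.snps[i] for i in index],
            phenotype=self.phenotype,
            covariates=self.covariates,
            fam=self.fam,
        )

    def subset_individuals(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[index],
            snps=self.snps,
            phenotype=self.phenotype[index],
            covariates=None if self.covariates is None else self.covariates[index],
            fam=None if self.fam is None else self.fam.iloc[index].reset_index(drop=True),
        )


@dataclass
class SummaryStats:
    """Per-SNP discovery effect sizes (log odds ratios).

    ``table`` columns: ``snp``, ``effect_allele``, ``other_allele``,
    ``beta`` (required); ``se``, ``p`` (optional, NaN when absent).
    """

    table: pd.DataFrame

    REQUIRED = ("snp", "effect_allele", "other_allele", "beta")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"summary statistics missing column {col!r}")
        for col in ("se", "p"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        self.table = self.table.astype(
            {"snp": str, "effect_allele": str, "other_allele": str,
             "beta": float, "se": float, "p": float})
        if self.table["snp"].duplicated().any():
            dups = self.table.loc[self.table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP ids in summary statistics: {dups[:5]}")
        if not np.isfinite(self.table["beta"]).all():
            raise ValueError("non-finite beta in summary statistics")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> pd.Series:
        return self.table["snp"]

    def beta_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Betas aligned to ``snp_ids`` order; KeyError if any id is absent."""
        lookup = self.table.set_index("snp")["beta"]
        return lookup.loc[list(snp_ids)].to_numpy()


@dataclass
class SetDefinition:
    """A named SNP set (typically a gene)."""

    set_id: str
    snp_ids: list[str]
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValueError(f"set {self.set_id}: empty SNP list")


@dataclass
class HarmonizationReport:
    """Accounting of the discovery/test allele reconciliation."""

    n_matched: int = 0
    n_inverted: int = 0
    n_excluded_ambiguous: int = 0
    n_excluded_mismatch: int = 0
    n_absent: int = 0
    mismatched_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {
            "matched": self.n_matched,
            "inverted": self.n_inverted,
            "excluded_ambiguous": self.n_excluded_ambiguous,
            "excluded_mismatch": self.n_excluded_mismatch,
            "absent_from_test": self.n_absent,
        }


@dataclass
class Locus:
    """A merged run of significant genes treated as one independent signal."""

    chrom: str
    start: int
    end: int
    genes: list[str]
    min_p: float


# ---------------------------------------------------------------------------
# PLINK 1 binary fileset
# ---------------------------------------------------------------------------

def _fold_maf(effect_freq: float) -> float:
    return float(min(effect_freq, 1.0 - effect_freq))


def compute_mafs(genotypes: np.ndarray) -> np.ndarray:
    """Folded minor-allele frequencies from the non-missing calls of each column."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(genotypes, axis=0) / 2.0
    if np.isnan(freq).any():
        bad = np.flatnonzero(np.isnan(freq))
        raise ValueError(f"all calls missing for SNP column(s) {bad.tolist()}")
    return np.minimum(freq, 1.0 - freq)


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` fileset (SNP-major .bed).

    Genotypes count copies of the .bim A1 allele (the effect-allele
    convention used throughout).  Phenotypes use the PLINK case/control
    coding: 1 = control -> 0, 2 = case -> 1, 0 or -9 -> missing.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic number (not SNP-major PLINK 1)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    codes = body.reshape(m, bytes_per_snp)
    # expand each byte into its four 2-bit genotype codes (LSB first)
    expanded = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        expanded[:, k::4] = (codes >> (2 * k)) & 0b11
    genotypes = _CODE_TO_DOSAGE[expanded[:, :n]].T  # N x M

    pheno_raw = fam["pheno"].astype(float)
    unknown = ~pheno_raw.isin([1, 2, 0, -9])
    if unknown.any():
        rows = (np.flatnonzero(unknown) + 1).tolist()
        raise PlinkFormatError(
            f"{prefix}.fam: unknown phenotype codes at row(s) {rows} "
            f"(expected 1/2 case-control or 0/-9 missing)"
        )
    phenotype = pheno_raw.map({1: 0.0, 2: 1.0, 0: np.nan, -9: np.nan}).to_numpy()

    mafs = compute_mafs(genotypes)
    snps = [
        SnpRecord(id=r.id, chrom=r.chrom, pos=int(r.pos),
                  allele1=r.a1, allele2=r.a2, maf=mafs[i])
        for i, r in enumerate(bim.itertuples())
    ]
    return GenotypeDataset(genotypes=genotypes, snps=snps, phenotype=phenotype,
                           fam=fam[["fid", "iid"]])


def write_plink(d: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``d`` as a PLINK 1 SNP-major fileset (inverse of :func:`read_plink`)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame({
        "chrom": [s.chrom for s in d.snps],
        "id": [s.id for s in d.snps],
        "cm": 0,
        "pos": [s.pos for s in d.snps],
        "a1": [s.allele1 for s in d.snps],
        "a2": [s.allele2 for s in d.snps],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    if d.fam is not None:
        fid, iid = d.fam["fid"], d.fam["iid"]
    else:
        fid = iid = [f"id{i + 1}" for i in range(d.n)]
    pheno = np.where(np.isnan(d.phenotype), -9, d.phenotype + 1).astype(int)
    fam = pd.DataFrame({"fid": fid, "iid": iid, "father": 0, "mother": 0,
                        "sex": 0, "pheno": pheno})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    n, m = d.n, d.m
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, n), dtype=np.uint8)
    g = d.genotypes
    for val, code in dosage_to_code.items():
        codes[(g == val).T] = code
    codes[np.isnan(g).T] = 1
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # pad bits ignored on read
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# summary statistics / gene models / set files
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path, effects_are_or: bool = False) -> SummaryStats:
    """Read whitespace-delimited summary statistics.

    Required columns SNP, A1 (effect allele), A2, BETA; optional SE, P.
    With ``effects_are_or`` the effect column is named OR and converted
    by natural log.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    effect_col = "OR" if effects_are_or else "BETA"
    needed = {"SNP", "A1", "A2", effect_col}
    if not needed.issubset(df.columns):
        raise ValueError(f"summary file {path}: missing columns {sorted(needed - set(df.columns))}")
    beta = np.log(df[effect_col]) if effects_are_or else df[effect_col]
    out = pd.DataFrame({
        "snp": df["SNP"].astype(str),
        "effect_allele": df["A1"].astype(str),
        "other_allele": df["A2"].astype(str),
        "beta": beta.astype(float),
        "se": df["SE"].astype(float) if "SE" in df.columns else np.nan,
        "p": df["P"].astype(float) if "P" in df.columns else np.nan,
    })
    return SummaryStats(out)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """BED-like gene model table: gene_id, chrom, start, end (tab-delimited).

    Filtering to known / protein-coding genes is the producer's
    responsibility; this reader takes the table at face value.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["gene_id", "chrom", "start", "end"],
                     dtype={"gene_id": str, "chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_set_file(path: str | Path) -> list[SetDefinition]:
    """MAGMA-style set file: ``set_id SNP1 SNP2 ...``, one set per line."""
    sets = []
    for line in Path(path).read_text().splitlines():
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 2:
            raise ValueError(f"set line with no SNPs: {line!r}")
        sets.append(SetDefinition(set_id=fields[0], snp_ids=fields[1:]))
    return sets


def write_scores(path: str | Path, d: GenotypeDataset, scores: Iterable) -> None:
    """Tab-delimited per-person score table: FID IID set_id method score."""
    if d.fam is not None:
        fid, iid = d.fam["fid"].to_numpy(), d.fam["iid"].to_numpy()
    else:
        fid = iid = np.array([f"id{i + 1}" for i in range(d.n)])
    frames = []
    for sv in scores:
        frames.append(pd.DataFrame({
            "FID": fid, "IID": iid, "set_id": sv.set_id,
            "method": sv.method, "score": sv.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization and filters
# ---------------------------------------------------------------------------

def harmonize(summary: SummaryStats, snps: Sequence[SnpRecord]) -> tuple[SummaryStats, HarmonizationReport]:
    """Align discovery summary statistics to the test set's allele convention.

    Keeps SNPs present in both inputs; inverts beta when the summary
    alleles are the test alleles reversed; removes strand-ambiguous
    (A/T, C/G) SNPs and SNPs whose alleles cannot be matched either way.
    The returned table carries the test set's (effect, other) alleles, so
    the operation is idempotent.
    """
    test = {s.id: s for s in snps}
    rep = HarmonizationReport()
    rows = []
    for row in summary.table.itertuples():
        rec = test.get(row.snp)
        if rec is None:
            rep.n_absent += 1
            continue
        if frozenset((rec.allele1, rec.allele2)) in AMBIGUOUS_PAIRS:
            rep.n_excluded_ambiguous += 1
            continue
        if (row.effect_allele, row.other_allele) == (rec.allele1, rec.allele2):
            beta = row.beta
            rep.n_matched += 1
        elif (row.effect_allele, row.other_allele) == (rec.allele2, rec.allele1):
            beta = -row.beta
            rep.n_inverted += 1
        else:
            rep.n_excluded_mismatch += 1
            rep.mismatched_ids.append(row.snp)
            logger.warning("harmonize: SNP %s alleles %s/%s do not match test %s/%s; excluded",
                           row.snp, row.effect_allele, row.other_allele,
                           rec.allele1, rec.allele2)
            continue
        rows.append((row.snp, rec.allele1, rec.allele2, beta, row.se, row.p))
    logger.info("harmonize: %s", rep.as_dict())
    out = pd.DataFrame(rows, columns=["snp", "effect_allele", "other_allele",
                                      "beta", "se", "p"])
    return SummaryStats(out), rep


def impute_missing(d: GenotypeDataset) -> GenotypeDataset:
    """Replace each missing genotype with 2 x MAF of its SNP.

    MAF is the folded minor-allele frequency computed from the non-missing
    calls of the test set itself.  A column with all calls missing is an
    error (its MAF is undefined).
    """
    if not d.has_missing():
        return d
    mafs = compute_mafs(d.genotypes)
    g = d.genotypes.copy()
    miss_r, miss_c = np.nonzero(np.isnan(g))
    g[miss_r, miss_c] = 2.0 * mafs[miss_c]
    return replace(d, genotypes=g)


def maf_filter(d: GenotypeDataset, threshold: float = 0.01) -> GenotypeDataset:
    """Drop SNPs with MAF strictly below ``threshold`` (PLINK convention)."""
    if not 0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = np.flatnonzero(d.mafs >= threshold)
    if keep.size == 0:
        raise ValueError(f"MAF filter at {threshold} removed every SNP")
    dropped = d.m - keep.size
    if dropped:
        logger.info("maf_filter: removed %d of %d SNPs below %g", dropped, d.m, threshold)
    return d.subset_snps(keep)


def assign_snps_to_sets(snps: Sequence[SnpRecord], genes: pd.DataFrame,
                        inclusive: bool = True) -> list[SetDefinition]:
    """Assign SNPs to genes by position: chromosome match and pos in [start, end].

    Boundaries are inclusive on both ends (1-based coordinates as in .bim);
    a SNP inside several overlapping genes joins every one of them.  Genes
    with no assigned SNP are omitted (counted in the log).
    """
    chroms = np.array([s.chrom for s in snps])
    pos = np.array([s.pos for s in snps])
    ids = np.array([s.id for s in snps])
    out, empty = [], 0
    for g in genes.itertuples():
        on_chrom = chroms == str(g.chrom)
        if inclusive:
            inside = on_chrom & (pos >= g.start) & (pos <= g.end)
        else:
            inside = on_chrom & (pos > g.start) & (pos < g.end)
        if not inside.any():
            empty += 1
            continue
        out.append(SetDefinition(set_id=g.gene_id, snp_ids=list(ids[inside]),
                                 chrom=str(g.chrom), start=int(g.start), end=int(g.end)))
    if empty:
        logger.info("assign_snps_to_sets: %d gene(s) had no SNPs and were omitted", empty)
    return out


def anneal_significant_genes(hits: pd.DataFrame | Iterable[tuple],
                             gap_bp: int = 250_000) -> list[Locus]:
    """Merge significant genes separated by less than ``gap_bp`` into loci.

    ``hits`` rows carry (gene, chrom, start, end, p); thresholding is the
    caller's job.  Merging is transitive along the sorted intervals on
    each chromosome; overlapping genes always merge.  The result is
    independent of input order.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(hits, columns=["gene", "chrom", "start", "end", "p"])
    loci: list[Locus] = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        cur: Locus | None = None
        for row in grp.itertuples():
            if cur is not None and row.start - cur.end < gap_bp:
                cur.end = max(cur.end, int(row.end))
                cur.genes.append(row.gene)
                cur.min_p = min(cur.min_p, float(row.p))
            else:
                cur = Locus(chrom=str(chrom), start=int(row.start), end=int(row.end),
                            genes=[row.gene], min_p=float(row.p))
                loci.append(cur)
    return loci


def genomic_control_adjust(summary: SummaryStats, lambda_gc: float) -> SummaryStats:
    """Deflate per-SNP association statistics by the genomic-control lambda.

    The per-SNP chi-square is divided by ``lambda_gc``; equivalently the
    standard error inflates by sqrt(lambda_gc).  P-values are recomputed
    from the adjusted statistic; betas are untouched.
    """
    if lambda_gc < 1:
        raise ValueError(f"lambda_gc must be >= 1 (deflation unsupported), got {lambda_gc}")
    t = summary.table.copy()
    have_se = np.isfinite(t["se"])
    have_p = np.isfinite(t["p"])
    if not (have_se | have_p).all():
        raise ValueError("genomic control needs SE or P for every SNP")
    if lambda_gc == 1:
        return SummaryStats(t)
    t.loc[have_se, "se"] = t.loc[have_se, "se"] * np.sqrt(lambda_gc)
    # recompute p from the adjusted Wald chi-square where SE is known
    chi = (t.loc[have_se, "beta"] / t.loc[have_se, "se"]) ** 2
    t.loc[have_se, "p"] = stats.chi2.sf(chi, df=1)
    only_p = have_p & ~have_se
    if only_p.any():
        chi = stats.chi2.isf(t.loc[only_p, "p"], df=1) / lambda_gc
        t.loc[only_p, "p"] = stats.chi2.sf(chi, df=1)
    return SummaryStats(t)
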