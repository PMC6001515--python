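"""Simulation harness: constructed-LD scenarios and rejection-rate experiments.

Scenario A ("one LD block") builds a 100-SNP set: a 10-SNP block whose
consecutive genotype pairs have a configured squared correlation r2,
plus 90 independent unassociated SNPs.  Block genotypes come from a
latent Gaussian with AR(1) correlation, thresholded to {0, 1, 2} at the
Hardy-Weinberg quantiles of the configured allele frequency; the latent
correlation is calibrated numerically so that the realised genotype
correlation hits the target (thresholding attenuates correlation, so the
latent value must exceed it).  One designated block SNP is causal with a
configurable odds ratio; disease status is drawn prospectively from a
logistic model whose intercept is solved so the expected case fraction
matches the design (30% by default).  The dataset is then split at
random into discovery and test halves.

Scenario B ("real-data LD") takes any supplied genotype panel and
induces association at a chosen SNP by phenotype flipping: controls
homozygous for the risk allele are relabelled cases, and an equal number
of cases homozygous for the protective allele are relabelled controls,
leaving genotypes and the total case count untouched.  A 115-SNP
synthetic block-structured panel is provided as a stand-in for
consortium data.

:func:`run_experiment` runs a scenario for R replicates, applies the
requested set tests to each, and reports the proportion of replicate
p-values below each nominal threshold with exact binomial confidence
intervals — the type-I error rate under a null configuration, power
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import core, settest
from .genio import GenotypeDataset, SnpRecord, compute_mafs

logger = logging.getLogger("polaris")

__all__ = [
    "ScenarioAConfig",
    "ExperimentResult",
    "calibrate_latent_rho",
    "simulate_scenario_a",
    "synthetic_block_panel",
    "induce_association_by_flips",
    "permute_phenotype",
    "run_experiment",
    "METHODS",
]

METHODS = ("POLARIS", "PRS", "PCA_FTEST_test_only", "PCA_FTEST_combined")

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ScenarioAConfig:
    """Design of the constructed-LD scenario.

    Defaults follow the study design this harness reproduces: 20,000
    individuals split equally into discovery and test, a 10-SNP LD block
    (consecutive-pair r2 = 0.8 in the strong-LD variant), 90 independent
    null SNPs, one causal block SNP at OR 1.1 and 30% cases.  The block
    allele frequency is 0.3 (the design leaves it open; a common-variant
    frequency keeps all genotype classes well populated).
    """

    n_total: int = 20_000
    split: tuple[float, float] = (0.5, 0.5)  # (test, discovery) fractions
    m_block: int = 10
    r2: float = 0.8
    m_null: int = 90
    causal_or: float = 1.1
    case_fraction: float = 0.30
    maf: float = 0.30
    causal_index: int | None = None  # block position; default middle
    sampling: str = "prospective"  # or "retrospective" (exact case count)
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0 <= self.r2 < 1:
            raise ValueError("r2 must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.sampling not in ("prospective", "retrospective"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass
class ExperimentResult:
    """Per-replicate set p-values and rejection proportions.

    ``pvalues`` is R x K (replicates x methods); ``rejection`` has one
    row per (method, threshold) with the exact proportion of replicate
    p-values strictly below the threshold and its Clopper-Pearson 95% CI.
    """

    pvalues: pd.DataFrame
    thresholds: tuple[float, ...]
    rejection: pd.DataFrame
    n_failures: int = 0
    failures: list[str] = field(default_factory=list)

    def rate(self, method: str, threshold: float) -> float:
        row = self.rejection[(self.rejection["method"] == method)
                             & (self.rejection["threshold"] == threshold)]
        return float(row["rate"].iloc[0])


# ---------------------------------------------------------------------------
# latent-Gaussian genotype machinery
# ---------------------------------------------------------------------------

def _hwe_thresholds(freq: float) -> tuple[float, float]:
    """Standard-normal cut points giving HWE genotype frequencies.

    G = 0 below the first, 1 between, 2 above; the counted allele has
    frequency ``freq`` so P(G=0) = (1-f)^2, P(G=1) = 2f(1-f).
    """
    p0 = (1.0 - freq) ** 2
    p1 = 2.0 * freq * (1.0 - freq)
    return stats.norm.ppf(p0), stats.norm.ppf(p0 + p1)


def _genotype_correlation(rho: float, freq: float) -> float:
    """Correlation of two HWE genotypes thresholded from latent normals
    with correlation ``rho`` (computed exactly from rectangle probabilities)."""
    if rho == 0:
        return 0.0
    t0, t1 = _hwe_thresholds(freq)
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

    def rect(lo1, hi1, lo2, hi2):
        big = 8.5  # effectively infinity for the standard normal
        lo1, hi1 = max(lo1, -big), min(hi1, big)
        lo2, hi2 = max(lo2, -big), min(hi2, big)
        return (bvn.cdf([hi1, hi2]) - bvn.cdf([lo1, hi2])
                - bvn.cdf([hi1, lo2]) + bvn.cdf([lo1, lo2]))

    inf = np.inf
    e_g1g2 = (1 * rect(t0, t1, t0, t1)
              + 2 * rect(t0, t1, t1, inf)
              + 2 * rect(t1, inf, t0, t1)
              + 4 * rect(t1, inf, t1, inf))
    mean = 2.0 * freq
    var = 2.0 * freq * (1.0 - freq)
    return float((e_g1g2 - mean ** 2) / var)


@lru_cache(maxsize=None)
def calibrate_latent_rho(r2: float, freq: float) -> float:
    """Latent AR(1) correlation whose thresholded genotypes have
    consecutive-pair squared correlation ``r2`` at allele frequency ``freq``."""
    if r2 == 0:
        return 0.0
    target = float(np.sqrt(r2))
    f = lambda rho: _genotype_correlation(rho, freq) - target
    hi = 0.9999
    if f(hi) < 0:
        raise ValueError(f"target r2={r2} unattainable at maf={freq}")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


def _threshold_genotypes(z: np.ndarray, freq: float) -> np.ndarray:
    t0, t1 = _hwe_thresholds(freq)
    return (z > t0).astype(float) + (z > t1)


def _solve_intercept(beta: float, freq: float, case_fraction: float) -> float:
    """Logistic intercept giving the design case fraction in expectation,
    averaging over the HWE genotype distribution of the causal SNP."""
    if beta == 0:
        return float(logit(case_fraction))
    probs = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
    gvals = np.array([0.0, 1.0, 2.0])

    def expected_rate(alpha):
        return float(probs @ expit(alpha + beta * gvals)) - case_fraction

    try:
        return float(optimize.brentq(expected_rate, -35.0, 35.0, xtol=1e-12))
    except ValueError as e:
        raise ValueError(
            f"case fraction {case_fraction} infeasible for effect {beta}"
        ) from e


def _make_snp_records(genotypes: np.ndarray, m_block: int) -> list[SnpRecord]:
    mafs = compute_mafs(genotypes)
    recs = []
    for i in range(genotypes.shape[1]):
        label = f"block_{i + 1}" if i < m_block else f"null_{i - m_block + 1}"
        recs.append(SnpRecord(id=label, chrom="1", pos=10_000 + 5_000 * i,
                              allele1="A", allele2="G", maf=float(mafs[i])))
    return recs


def _draw_scenario_a(config: ScenarioAConfig, rng: np.random.Generator,
                     n: int) -> tuple[np.ndarray, np.ndarray]:
    """One prospective draw of n individuals: (genotypes, phenotype)."""
    rho = calibrate_latent_rho(config.r2, config.maf)
    lags = np.abs(np.subtract.outer(np.arange(config.m_block),
                                    np.arange(config.m_block)))
    latent_cov = rho ** lags
    chol = np.linalg.cholesky(latent_cov)
    z = rng.standard_normal((n, config.m_block)) @ chol.T
    block = _threshold_genotypes(z, config.maf)
    nulls = rng.binomial(2, config.maf, size=(n, config.m_null)).astype(float)
    g = np.hstack([block, nulls])

    causal = config.causal_index if config.causal_index is not None else config.m_block // 2
    beta = float(np.log(config.causal_or))
    alpha = _solve_intercept(beta, config.maf, config.case_fraction)
    prob = expit(alpha + beta * g[:, causal])
    y = (rng.random(n) < prob).astype(float)
    return g, y


def simulate_scenario_a(config: ScenarioAConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Simulate one Scenario A dataset and split it into (discovery, test).

    Prospective sampling draws disease status from the logistic model, so
    the case fraction matches the design in expectation; retrospective
    sampling keeps drawing until exactly round(N * case_fraction) cases
    and the complementary number of controls are collected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_total

    if config.sampling == "prospective":
        g, y = _draw_scenario_a(config, rng, n)
    else:
        target_cases = round(n * config.case_fraction)
        g_parts, y_parts, n_cases, n_ctrls = [], [], 0, 0
        for _ in range(200):
            gb, yb = _draw_scenario_a(config, rng, n)
            g_parts.append(gb)
            y_parts.append(yb)
            n_cases += int(yb.sum())
            n_ctrls += int((1 - yb).sum())
            if n_cases >= target_cases and n_ctrls >= n - target_cases:
                break
        else:
            raise RuntimeError("retrospective sampling failed to accrue cases")
        g_all, y_all = np.vstack(g_parts), np.concatenate(y_parts)
        case_idx = np.flatnonzero(y_all == 1)[:target_cases]
        ctrl_idx = np.flatnonzero(y_all == 0)[: n - target_cases]
        idx = rng.permutation(np.concatenate([case_idx, ctrl_idx]))
        g, y = g_all[idx], y_all[idx]

    snps = _make_snp_records(g, config.m_block)
    full = GenotypeDataset(genotypes=g, snps=snps, phenotype=y)

    perm = rng.permutation(n)
    n_test = round(n * config.split[0])
    test = full.subset_individuals(perm[:n_test])
    discovery = full.subset_individuals(perm[n_test:])
    return discovery, test


def synthetic_block_panel(n: int, rng: np.random.Generator,
                          m: int = 115, block_size: int = 5,
                          r2: float = 0.6, maf: float = 0.3) -> GenotypeDataset:
    """Synthetic block-structured genotype panel (stand-in for real LD).

    ``m`` SNPs in consecutive blocks of ``block_size``, each block an
    AR(1)-correlated unit at consecutive-pair squared correlation ``r2``;
    blocks are mutually independent.  The phenotype is a null binary
    trait at 30% cases, so association must be induced afterwards (e.g.
    with :func:`induce_association_by_flips`).
    """
    cols = []
    for start in range(0, m, block_size):
        width = min(block_size, m - start)
        cfg = ScenarioAConfig(n_total=n, m_block=width, m_null=0, r2=r2,
                              maf=maf, causal_or=1.0)
        g_blk, _ = _draw_scenario_a(cfg, rng, n)
        cols.append(g_blk)
    g = np.hstack(cols)
    y = (rng.random(n) < 0.30).astype(float)
    mafs = compute_mafs(g)
    snps = [SnpRecord(id=f"panel_{i + 1}", chrom="2", pos=50_000 + 2_000 * i,
                      allele1="A", allele2="G", maf=float(mafs[i]))
            for i in range(m)]
    return GenotypeDataset(genotypes=g, snps=snps, phenotype=y)


# ---------------------------------------------------------------------------
# phenotype manipulation
# ---------------------------------------------------------------------------

def induce_association_by_flips(d: GenotypeDataset, snp_id: str, n_flips: int,
                                seed: int | np.random.Generator | None = None
                                ) -> GenotypeDataset:
    """Create association at ``snp_id`` by swapping case/control labels.

    Exactly ``n_flips`` controls homozygous for the counted (risk) allele
    become cases and ``n_flips`` cases homozygous for the other allele
    become controls, chosen uniformly at random.  Genotypes and the total
    case count are untouched, so the mechanism only redistributes labels
    along the genotype axis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        col = d.snp_ids.index(snp_id)
    except ValueError:
        raise KeyError(f"SNP {snp_id!r} not in dataset") from None
    g = d.genotypes[:, col]
    y = d.phenotype.copy()
    ctrl_hom_risk = np.flatnonzero((y == 0) & (g == 2))
    case_hom_prot = np.flatnonzero((y == 1) & (g == 0))
    feasible = min(ctrl_hom_risk.size, case_hom_prot.size)
    if n_flips > feasible:
        raise ValueError(
            f"cannot flip {n_flips} in each direction at {snp_id}: "
            f"maximum feasible is {feasible} "
            f"({ctrl_hom_risk.size} eligible controls, {case_hom_prot.size} eligible cases)"
        )
    if n_flips > 0:
        y[rng.choice(ctrl_hom_risk, size=n_flips, replace=False)] = 1.0
        y[rng.choice(case_hom_prot, size=n_flips, replace=False)] = 0.0
    return replace(d, phenotype=y)


def permute_phenotype(d: GenotypeDataset,
                      seed: int | np.random.Generator | None = None
                      ) -> GenotypeDataset:
    """Uniform random permutation of the phenotype vector (genotypes untouched)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return replace(d, phenotype=rng.permutation(d.phenotype))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Counter-based per-replicate stream: independent and re-runnable."""
    return np.random.default_rng(np.random.SeedSequence(master_seed,
                                                        spawn_key=(replicate,)))


def _score_and_test(discovery: GenotypeDataset, test: GenotypeDataset,
                    methods: tuple[str, ...]) -> dict[str, float]:
    """Fit discovery betas, score the test half, run every requested test."""
    out: dict[str, float] = {}
    need_scores = {"POLARIS", "PRS"} & set(methods)
    if need_scores:
        fit = settest.estimate_discovery_betas(discovery)
        have = set(fit.table["snp"])
        keep = [i for i, s in enumerate(test.snps) if s.id in have]
        sub = test.subset_snps(keep)
        beta = fit.table.set_index("snp")["beta"].loc[sub.snp_ids].to_numpy()
        if "POLARIS" in methods:
            c = core.correlation_matrix(sub.genotypes)
            spectrum = core.spectral_decompose(c)
            ridge = core.RidgeConfig.default_for(sub.n)
            g_adj = core.adjusted_dosages(sub.genotypes, spectrum, ridge)
            score = core.polaris_score(beta, g_adj)
            out["POLARIS"] = settest.polaris_set_test(
                score, sub.phenotype, n_snps=sub.m).p
        if "PRS" in methods:
            score = core.prs_score(beta, sub.genotypes)
            out["PRS"] = settest.polaris_set_test(
                score, sub.phenotype, n_snps=sub.m).p
    if "PCA_FTEST_test_only" in methods:
        out["PCA_FTEST_test_only"] = settest.pca_ftest_set_test(
            test.genotypes, test.phenotype).p
    if "PCA_FTEST_combined" in methods:
        g_all = np.vstack([test.genotypes, discovery.genotypes])
        y_all = np.concatenate([test.phenotype, discovery.phenotype])
        out["PCA_FTEST_combined"] = settest.pca_ftest_set_test(g_all, y_all).p
    return out


def rejection_table(pvalues: pd.DataFrame,
                    thresholds: tuple[float, ...]) -> pd.DataFrame:
    """Proportion of p-values strictly below each threshold, with exact
    (Clopper-Pearson) 95% binomial confidence intervals."""
    rows = []
    r = len(pvalues)
    for method in pvalues.columns:
        for thr in thresholds:
            k = int((pvalues[method] < thr).sum())
            ci = stats.binomtest(k, r).proportion_ci(confidence_level=0.95,
                                                     method="exact")
            rows.append({"method": method, "threshold": thr, "n_reject": k,
                         "n_replicates": r, "rate": k / r,
                         "ci_low": ci.low, "ci_high": ci.high})
    return pd.DataFrame(rows)


def run_experiment(scenario: ScenarioAConfig,
                   methods: tuple[str, ...] = ("POLARIS",),
                   n_replicates: int = 1000,
                   thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                   seed: int = 0) -> ExperimentResult:
    """Replicate a scenario end-to-end and tabulate rejection rates.

    Each replicate simulates a dataset, splits it, estimates per-SNP
    effects on the discovery half, scores and tests the whole 100-SNP
    set on the test half (POLARIS / PRS), and runs the PCA comparator on
    the test half alone and on the combined data, as requested.  Under a
    null scenario the rejection rate estimates the type-I error; with a
    causal SNP it estimates power.  The whole run is a pure function of
    (scenario, seed): replicate streams are derived from the master seed
    by counter, so individual replicates can be re-run in isolation.
    """
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")
    rows, failures = [], []
    for r in range(n_replicates):
        rng = _replicate_rng(seed, r)
        try:
            discovery, test = simulate_scenario_a(scenario, rng=rng)
            rows.append(_score_and_test(discovery, test, methods))
        except Exception as e:  # noqa: BLE001 — replicate failures are data
            failures.append(f"replicate {r}: {e}")
            if len(failures) > max(1, 0.01 * n_replicates):
                raise RuntimeError(
                    f"more than 1% of replicates failed; first: {failures[0]}"
                ) from e
    if failures:
        logger.warning("run_experiment: %d failed replicate(s)", len(failures))
    pvalues = pd.DataFrame(rows, columns=list(methods))
    return ExperimentResult(pvalues=pvalues, thresholds=tuple(thresholds),
                            rejection=rejection_table(pvalues, tuple(thresholds)),
                            n_failures=len(failures), failures=failures)
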