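"""Association layer: discovery effect estimation and set-level tests.

Three pieces live here:

* :func:`estimate_discovery_betas` — univariable logistic regression of
  case status on allele count, one fit per SNP, yielding the log odds
  ratios (with SE and Wald p) that a discovery study would publish.
  The fits are a vectorised Newton solver run across all SNPs at once;
  each fit is the ordinary 2-parameter (intercept + dosage) logistic
  MLE, identical to a per-SNP GLM fit.
* :func:`polaris_set_test` — logistic regression of phenotype on the
  per-person set score (plus optional covariates); the Wald z of the
  score coefficient gives the self-contained set p-value.  Quantitative
  phenotypes fall back to ordinary least squares with a t-test.
* :func:`pca_ftest_set_test` — the PCA comparator: principal components
  of the centered set genotype matrix, small-eigenvalue components
  dropped, linear regression of phenotype on the retained components,
  overall F-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genio import GenotypeDataset

logger = logging.getLogger("polaris")

__all__ = [
    "DiscoveryFit",
    "SetTestResult",
    "estimate_discovery_betas",
    "polaris_set_test",
    "pca_ftest_set_test",
]

# |log OR| beyond this is treated as (quasi-)separation and excluded
_SEPARATION_BETA = 15.0
_NEWTON_TOL = 1e-8
_NEWTON_MAXIT = 50


@dataclass
class DiscoveryFit:
    """Per-SNP logistic effect estimates from a discovery dataset.

    ``table`` columns: snp, effect_allele, other_allele, beta, se, p.
    ``excluded`` maps SNP id -> reason (monomorphic / separation /
    nonconvergence).
    """

    table: pd.DataFrame
    excluded: dict[str, str]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SetTestResult:
    """Outcome of one set-level association test."""

    set_id: str
    method: str  # POLARIS | PRS | PCA_FTEST
    statistic: float
    df: int | tuple[int, int]
    p: float
    n_snps: int
    n_components: int | None = None


def _logistic_newton_vectorized(y: np.ndarray, g: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(P(y=1)) = a_j + b_j g_j for every column j simultaneously.

    Returns (beta, se, converged).  Plain Newton-Raphson on the
    2-parameter score equations; the Hessian solve is the closed-form
    2x2 inverse per SNP.
    """
    n, m = g.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(_NEWTON_MAXIT):
        if not active.any():
            break
        ga = g[:, active]
        eta = a[active] + b[active] * ga
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = y[:, None] - mu
        w = mu * (1.0 - mu)
        u1 = r.sum(axis=0)
        u2 = (ga * r).sum(axis=0)
        s0 = w.sum(axis=0)
        s1 = (w * ga).sum(axis=0)
        s2 = (w * ga * ga).sum(axis=0)
        det = s0 * s2 - s1 * s1
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (s2 * u1 - s1 * u2) / det
            db = (-s1 * u1 + s0 * u2) / det
        bad = ~np.isfinite(da) | ~np.isfinite(db)
        da[bad] = 0.0
        db[bad] = 0.0
        a[active] += da
        b[active] += db
        done = (np.abs(da) < _NEWTON_TOL) & (np.abs(db) < _NEWTON_TOL) & ~bad
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        # freeze diverging fits so they do not overflow
        runaway = np.abs(b[active]) > 2 * _SEPARATION_BETA
        active[idx[done | runaway]] = False

    # standard errors from the observed information at the optimum
    eta = a + b * g
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = (w * g).sum(axis=0)
    s2 = (w * g * g).sum(axis=0)
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s0 / det)
    return b, se, converged


def estimate_discovery_betas(d: GenotypeDataset) -> DiscoveryFit:
    """Per-SNP univariable logistic regression of case status on allele count.

    Produces the discovery-study summary statistics (beta = log OR, SE,
    two-sided Wald p) consumed by the scoring step.  Monomorphic SNPs,
    separated fits and non-convergent fits are excluded with a reason
    rather than crashing.
    """
    y = d.phenotype
    if np.isnan(y).any():
        raise ValueError("discovery phenotype has missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("discovery phenotype must be binary 0/1")
    if d.n < 50:
        raise ValueError(f"need at least 50 individuals for discovery fits, got {d.n}")
    if d.has_missing():
        raise ValueError("impute missing genotypes before discovery fits")

    g = d.genotypes
    variances = g.var(axis=0)
    poly = variances > 0
    excluded: dict[str, str] = {}
    for i in np.flatnonzero(~poly):
        excluded[d.snps[i].id] = "monomorphic"

    beta = np.full(d.m, np.nan)
    se = np.full(d.m, np.nan)
    conv = np.zeros(d.m, dtype=bool)
    if poly.any():
        beta[poly], se[poly], conv[poly] = _logistic_newton_vectorized(y, g[:, poly])

    keep = []
    for i in np.flatnonzero(poly):
        sid = d.snps[i].id
        if np.abs(beta[i]) > _SEPARATION_BETA or not np.isfinite(se[i]):
            excluded[sid] = "separation"
        elif not conv[i]:
            excluded[sid] = "nonconvergence"
        else:
            keep.append(i)
    if excluded:
        logger.info("estimate_discovery_betas: excluded %d SNP(s): %s",
                    len(excluded), excluded)

    keep = np.array(keep, dtype=int)
    p = 2.0 * stats.norm.sf(np.abs(beta[keep] / se[keep]))
    table = pd.DataFrame({
        "snp": [d.snps[i].id for i in keep],
        "effect_allele": [d.snps[i].allele1 for i in keep],
        "other_allele": [d.snps[i].allele2 for i in keep],
        "beta": beta[keep],
        "se": se[keep],
        "p": p,
    })
    return DiscoveryFit(table=table, excluded=excluded)


def _is_binary(y: np.ndarray) -> bool:
    return set(np.unique(y)) <= {0.0, 1.0}


def polaris_set_test(score, phenotype: np.ndarray,
                     covariates: np.ndarray | None = None,
                     n_snps: int | None = None) -> SetTestResult:
    """Regression of phenotype on the per-person set score.

    Binary phenotypes use logistic regression and report the Wald z for
    the score coefficient (two-sided); if the logistic fit does not
    converge or its Wald SE degenerates, the likelihood-ratio statistic
    against the score-free model is used instead (logged).  Quantitative
    phenotypes use ordinary least squares with a t-test.  A constant
    score carries no information: p = 1 with a warning.
    """
    values = np.asarray(score.values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValueError("score and phenotype lengths differ")
    if n_snps is None:
        n_snps = getattr(score, "n_snps", 0)

    if np.ptp(values) == 0:
        warnings.warn(f"set {score.set_id}: constant score, no information")
        return SetTestResult(set_id=score.set_id, method=score.method,
                             statistic=0.0, df=1, p=1.0, n_snps=n_snps)

    exog = values[:, None]
    if covariates is not None:
        exog = np.column_stack([exog, covariates])
    exog = sm.add_constant(exog, prepend=True)

    if not _is_binary(y):
        res = sm.OLS(y, exog).fit()
        return SetTestResult(set_id=score.set_id, method=score.method,
                             statistic=float(res.tvalues[1]),
                             df=int(res.df_resid), p=float(res.pvalues[1]),
                             n_snps=n_snps)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=100)
            zstat = float(res.params[1] / res.bse[1])
            p = float(res.pvalues[1])
            ok = res.mle_retvals.get("converged", False) and np.isfinite(p) \
                and np.isfinite(res.bse[1]) and res.bse[1] < 1e3
        except Exception:  # perfect separation and friends
            ok = False
        if not ok:
            # likelihood-ratio fallback: full vs score-free model
            logger.info("polaris_set_test: Wald fit degenerate for set %s, "
                        "using likelihood-ratio test", score.set_id)
            exog0 = np.delete(exog, 1, axis=1)
            ll0 = sm.Logit(y, exog0).fit(disp=0, maxiter=200).llf
            try:
                ll1 = sm.Logit(y, exog).fit(disp=0, maxiter=200, method="bfgs").llf
            except Exception:
                ll1 = 0.0  # saturated bound under perfect separation
            lr = max(0.0, 2.0 * (ll1 - ll0))
            return SetTestResult(set_id=score.set_id, method=score.method,
                                 statistic=float(lr), df=1,
                                 p=float(stats.chi2.sf(lr, df=1)), n_snps=n_snps)
    return SetTestResult(set_id=score.set_id, method=score.method,
                         statistic=zstat, df=1, p=p, n_snps=n_snps)


def pca_ftest_set_test(g: np.ndarray, phenotype: np.ndarray,
                       variance_kept: float = 0.999,
                       set_id: str = "set") -> SetTestResult:
    """PCA/F-test comparator on a set's genotype matrix.

    The centered N x M genotype matrix is decomposed into principal
    components; components are retained, largest eigenvalue first, up to
    cumulative explained variance ``variance_kept`` (pure zero-variance
    directions never count).  The phenotype is regressed linearly on the
    retained components and the overall regression F-test supplies the
    set p-value.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.shape[0] != y.shape[0]:
        raise ValueError("genotypes and phenotype lengths differ")
    n, m = g.shape
    centered = g - g.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    nonzero = var > max(1e-12 * var[0], 1e-12) if var.size else np.array([], bool)
    var = var[nonzero]
    if var.size == 0:
        raise ValueError("set has no genotypic variance: zero retained components")
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_kept) + 1)
    k = min(k, var.size)
    if n <= k + 1:
        raise ValueError(f"too few individuals ({n}) for {k} components")
    pcs = u[:, :k] * s[:k]

    res = sm.OLS(y, sm.add_constant(pcs, prepend=True)).fit()
    return SetTestResult(set_id=set_id, method="PCA_FTEST",
                         statistic=float(res.fvalue),
                         df=(int(res.df_model), int(res.df_resid)),
                         p=float(res.f_pvalue), n_snps=m, n_components=k)
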