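"""LD-adjusted dosage mathematics.

A polygenic risk score (PRS) is the weighted allele count

    PRS_n = sum_i beta_i g_{n,i} = beta' g_n,

with per-SNP weights beta taken from an independent discovery study.
When SNPs are in linkage disequilibrium the correlated components carry
disproportionate variance.  The POLARIS adjustment removes the
anisotropy of the joint genotype distribution by rescaling each
principal axis of the M x M SNP correlation matrix C with the inverse
square root of its eigenvalue, stabilised by a ridge term:

    g~ = sqrt(1 + lambda0) (C + lambda0 I)^{-1/2} g,
    POLARIS_n = beta' g~_n,

with the suggested ridge lambda0 = 1/N (N individuals in the test set).
When all markers are uncorrelated (C = I) every eigenvalue is 1, the
transform is the identity and POLARIS coincides with the PRS.  With
lambda0 = 0 the transform is the pseudoinverse square root: spectral
components with a zero eigenvalue (no variance) are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationSpectrum",
    "RidgeConfig",
    "ScoreVector",
    "correlation_matrix",
    "spectral_decompose",
    "transform_matrix",
    "adjusted_dosages",
    "polaris_score",
    "prs_score",
]

# relative eigenvalue threshold for "lambda_k = 0" on the ridge-free pathway
ZERO_EIGENVALUE_RTOL = 1e-10

# above this set size the transform is applied as three products instead of
# materialising the M x M transform matrix
MATERIALIZE_LIMIT = 5_000


@dataclass(frozen=True)
class CorrelationSpectrum:
    """Eigenvalues (descending) and orthonormal eigenvectors of C.

    For a correlation matrix the eigenvalues sum to the trace M.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def m(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass(frozen=True)
class RidgeConfig:
    """Ridge stabiliser for the inverse-square-root transform.

    lambda0 >= 0 is added to every eigenvalue before inversion; the
    recommended default is 1/N.  ``mode`` selects whether the spectrum
    is taken from the correlation (default) or covariance matrix.
    """

    lambda0: float
    mode: str = "correlation"

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError(f"lambda0 must be >= 0, got {self.lambda0}")
        if self.mode not in ("correlation", "covariance"):
            raise ValueError(f"mode must be correlation or covariance, got {self.mode!r}")

    @classmethod
    def default_for(cls, n_individuals: int, mode: str = "correlation") -> "RidgeConfig":
        return cls(lambda0=1.0 / n_individuals, mode=mode)


@dataclass(frozen=True)
class ScoreVector:
    """One score per person for one SNP set."""

    values: np.ndarray
    set_id: str
    method: str  # "PRS" or "POLARIS"


def correlation_matrix(g: np.ndarray, mode: str = "correlation") -> np.ndarray:
    """SNP-SNP correlation (or covariance) matrix of an N x M genotype matrix.

    Missing values must have been imputed first.  In correlation mode a
    constant column is an error: its correlation is undefined.
    """
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    n, m = g.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    centered = g - g.mean(axis=0)
    if mode == "covariance":
        c = centered.T @ centered / (n - 1)
        return (c + c.T) / 2.0
    if mode != "correlation":
        raise ValueError(f"unknown mode {mode!r}")
    sd = centered.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant genotype column(s) at index {zero.tolist()}: "
                         "correlation undefined")
    z = centered / sd
    c = z.T @ z / (n - 1)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def spectral_decompose(c: np.ndarray) -> CorrelationSpectrum:
    """Symmetric eigendecomposition C = sum_k lambda_k x_k x_k'.

    Eigenvalues below -1e-8 mean the input is not a (near-)PSD
    correlation matrix and raise; tiny negatives from round-off are
    clipped to zero.  Eigenvalues are returned in descending order.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < -1e-8:
        raise ValueError(f"matrix is not positive semi-definite "
                         f"(min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    return CorrelationSpectrum(eigenvalues=vals[order], eigenvectors=vecs[:, order])


def _scaling_factors(spectrum: CorrelationSpectrum, ridge: RidgeConfig) -> np.ndarray:
    """Per-axis factors sqrt((1 + lambda0) / (lambda_k + lambda0)).

    On the ridge-free pathway zero-eigenvalue axes get factor 0 — those
    spectral terms are omitted (pseudoinverse behaviour).
    """
    lam = spectrum.eigenvalues
    if ridge.lambda0 == 0:
        zero = lam < ZERO_EIGENVALUE_RTOL * spectrum.m
        factors = np.zeros_like(lam)
        factors[~zero] = 1.0 / np.sqrt(lam[~zero])
        return factors
    return np.sqrt((1.0 + ridge.lambda0) / (lam + ridge.lambda0))


def transform_matrix(spectrum: CorrelationSpectrum, ridge: RidgeConfig) -> np.ndarray:
    """The symmetric transform T = sqrt(1+l0) (C + l0 I)^{-1/2} materialised."""
    x = spectrum.eigenvectors
    t = (x * _scaling_factors(spectrum, ridge)) @ x.T
    return (t + t.T) / 2.0


def adjusted_dosages(g: np.ndarray, spectrum: CorrelationSpectrum,
                     ridge: RidgeConfig) -> np.ndarray:
    """LD-adjusted dosages g~ = sqrt(1+l0) (C + l0 I)^{-1/2} g, per person.

    ``g`` is N x M in the same SNP order as the spectrum.  When the
    spectrum is isotropic (all eigenvalues equal, the C = I case) the
    transform is a scalar and is applied exactly, so g~ = g whenever
    C = I.  The monotone effect of the ridge is that larger lambda0
    pulls every scaling factor toward 1, hence g~ toward g.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[1] != spectrum.m:
        raise ValueError(f"genotype matrix has {g.shape[1] if g.ndim == 2 else '?'} "
                         f"columns, spectrum is for {spectrum.m} SNPs")
    factors = _scaling_factors(spectrum, ridge)
    if np.all(factors == factors[0]):
        # isotropic spectrum: the projectors sum to the identity
        return g * factors[0]
    if spectrum.m <= MATERIALIZE_LIMIT:
        return g @ transform_matrix(spectrum, ridge)
    return ((g @ spectrum.eigenvectors) * factors) @ spectrum.eigenvectors.T


def polaris_score(beta: np.ndarray, g_adj: np.ndarray, set_id: str = "set") -> ScoreVector:
    """POLARIS score per person: beta' g~ over the set's SNPs."""
    return _weighted_sum(beta, g_adj, set_id, "POLARIS")


def prs_score(beta: np.ndarray, g: np.ndarray, set_id: str = "set") -> ScoreVector:
    """Plain polygenic risk score per person: beta' g."""
    return _weighted_sum(beta, g, set_id, "PRS")


def _weighted_sum(beta: np.ndarray, g: np.ndarray, set_id: str, method: str) -> ScoreVector:
    beta = np.asarray(beta, dtype=float)
    g = np.asarray(g, dtype=float)
    if beta.ndim != 1 or g.ndim != 2 or g.shape[1] != beta.shape[0]:
        raise ValueError(f"beta length {beta.shape} does not match genotype "
                         f"matrix shape {g.shape}")
    return ScoreVector(values=g @ beta, set_id=set_id, method=method)
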