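"""Phylogenetic-signal statistics with analytic and Monte-Carlo inference.

Four classic tests of whether close relatives resemble each other more
than chance:

* Moran's I — autocorrelation of a trait over a (row-standardized) weight
  matrix; null expectation -1/(n-1), standard deviate computed under the
  randomization (permutation-moment) variance;
* Geary's C — the paired-difference analogue; null expectation 1, values
  below 1 indicating positive autocorrelation (lower-tailed test);
* Blomberg's K — a ratio-of-ratios scaling observed trait similarity
  against the Brownian-motion expectation derived from the tree's
  variance-covariance matrix; K = 1 matches BM, K -> 0 independence;
* Mantel — Pearson correlation of two distance matrices' strict lower
  triangles, with simultaneous row/column permutation of one matrix.

Permutation p-values use the add-one convention p = (1 + #{T_perm >= T_obs})
/(1 + n_perm) (ties counted toward the extreme tail), one-sided in the
direction that indicates signal for each statistic.

Each test is exposed both as an estimator class with a ``fit`` method and
fitted ``statistic_`` / ``p_value_`` attributes, and as plain functions
returning :class:`SignalTestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .matrices import SquareTaxonMatrix
from .phylo import bm_vcv

__all__ = [
    "SignalTestResult",
    "MoranTest",
    "GearyTest",
    "BlombergKTest",
    "MantelTest",
    "morans_i",
    "morans_i_mc",
    "gearys_c",
    "gearys_c_mc",
    "blombergs_k",
    "blombergs_k_mc",
    "mantel",
    "mantel_mc",
    "mantel_bootstrap",
]

_TIE_EPS = 1e-12


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class SignalTestResult:
    """One signal-test outcome: statistic, null reference, Monte-Carlo p."""

    test: str
    statistic: float
    expectation: float
    std_deviate: float | None = None
    p_mc: float | None = None
    n_perm: int = 0
    seed: int | None = None
    distance_model: str = ""
    group: str = "all"
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_mc is not None and self.p_mc < 0.05


def _as_weight_array(W) -> np.ndarray:
    if isinstance(W, SquareTaxonMatrix):
        W = W.values
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(np.diag(W), 0.0):
        raise ValueError("weight matrix must have a zero diagonal")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    return W


def _check_trait(z) -> np.ndarray:
    z = np.asarray(z, dtype=float).ravel()
    if np.ptp(z) == 0:
        raise UndefinedStatisticError("constant trait vector")
    return z


def _perm_matrix(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)


def _upper_p(null: np.ndarray, obs: float) -> float:
    return (1.0 + int((null >= obs - _TIE_EPS).sum())) / (1.0 + len(null))


def _lower_p(null: np.ndarray, obs: float) -> float:
    return (1.0 + int((null <= obs + _TIE_EPS).sum())) / (1.0 + len(null))


# ---------------------------------------------------------------- Moran / Geary

def _moran_moments(W: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Randomization-assumption mean and variance of Moran's I."""
    n = len(z)
    if n < 4:
        raise UndefinedStatisticError("randomization variance needs n >= 4")
    S0 = W.sum()
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    zc = z - z.mean()
    m2 = (zc**2).sum() / n
    m4 = (zc**4).sum() / n
    b2 = m4 / m2**2
    EI = -1.0 / (n - 1)
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * S0**2
    var = num / den - EI**2
    return EI, var


def _geary_var(W: np.ndarray, z: np.ndarray) -> float:
    """Randomization-assumption variance of Geary's C."""
    n = len(z)
    if n < 4:
        raise UndefinedStatisticError("randomization variance needs n >= 4")
    S0 = W.sum()
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    zc = z - z.mean()
    m2 = (zc**2).sum() / n
    m4 = (zc**4).sum() / n
    b2 = m4 / m2**2
    num = (
        (n - 1) * S1 * (n**2 - 3 * n + 3 - (n - 1) * b2)
        - 0.25 * (n - 1) * S2 * (n**2 + 3 * n - 6 - (n**2 - n + 2) * b2)
        + S0**2 * (n**2 - 3 - (n - 1) ** 2 * b2)
    )
    return num / (n * (n - 2) * (n - 3) * S0**2)


def _moran_stat(zc: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = len(zc)
    return float((n / S0) * (zc @ W @ zc) / (zc @ zc))


def _geary_stat(z: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = len(z)
    zc = z - z.mean()
    num = float((W * (z[:, None] - z[None, :]) ** 2).sum())
    return ((n - 1) / (2 * S0)) * num / float(zc @ zc)


class MoranTest(BaseEstimator):
    """Moran's I with permutation inference (upper-tailed for signal)."""

    def __init__(self, n_perm: int = 10_000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, z, W):
        z = _check_trait(z)
        W = _as_weight_array(W)
        n = len(z)
        if W.shape[0] != n:
            raise ValueError("trait/weights length mismatch")
        S0 = W.sum()
        zc = z - z.mean()
        self.statistic_ = _moran_stat(zc, W, S0)
        self.expectation_ = -1.0 / (n - 1)
        if n >= 4:  # randomization variance is undefined below n = 4
            _, var = _moran_moments(W, z)
            self.std_deviate_ = (self.statistic_ - self.expectation_) / np.sqrt(var)
        else:
            self.std_deviate_ = None
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            P = _perm_matrix(rng, n, self.n_perm)
            Z = zc[P]
            null = (n / S0) * ((Z @ W.T) * Z).sum(axis=1) / float(zc @ zc)
            self.null_distribution_ = null
            self.p_value_ = _upper_p(null, self.statistic_)
        else:
            self.null_distribution_ = None
            self.p_value_ = None
        return self

    def result(self, **kw) -> SignalTestResult:
        return SignalTestResult(
            "moran",
            self.statistic_,
            self.expectation_,
            self.std_deviate_,
            self.p_value_,
            self.n_perm,
            self.seed,
            **kw,
        )


class GearyTest(BaseEstimator):
    """Geary's C with permutation inference (lower-tailed: C < 1 = signal).

    The reported standard deviate is (1 - C)/sd so that, as for Moran's I,
    positive deviates indicate positive autocorrelation.
    """

    def __init__(self, n_perm: int = 10_000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, z, W):
        z = _check_trait(z)
        W = _as_weight_array(W)
        n = len(z)
        if W.shape[0] != n:
            raise ValueError("trait/weights length mismatch")
        S0 = W.sum()
        self.statistic_ = _geary_stat(z, W, S0)
        self.expectation_ = 1.0
        if n >= 4:
            var = _geary_var(W, z)
            self.std_deviate_ = (1.0 - self.statistic_) / np.sqrt(var)
        else:
            self.std_deviate_ = None
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            zc = z - z.mean()
            denom = float(zc @ zc)
            rs = W.sum(axis=1)
            cs = W.sum(axis=0)
            M = np.diag(rs + cs) - (W + W.T)
            P = _perm_matrix(rng, n, self.n_perm)
            Z = zc[P]  # centering is permutation-invariant
            num = ((Z @ M.T) * Z).sum(axis=1)
            null = ((n - 1) / (2 * S0)) * num / denom
            self.null_distribution_ = null
            self.p_value_ = _lower_p(null, self.statistic_)
        else:
            self.null_distribution_ = None
            self.p_value_ = None
        return self

    def result(self, **kw) -> SignalTestResult:
        return SignalTestResult(
            "geary",
            self.statistic_,
            self.expectation_,
            self.std_deviate_,
            self.p_value_,
            self.n_perm,
            self.seed,
            **kw,
        )


# ------------------------------------------------------------------ Blomberg K

def _k_quadratics(C: np.ndarray):
    n = C.shape[0]
    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise UndefinedStatisticError("singular BM covariance matrix") from exc
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    s = float(ones @ Ci1)  # 1' C^-1 1
    expected_ratio = (np.trace(C) - n / s) / (n - 1)
    return cho, Ci1, s, expected_ratio


def _k_of(Y: np.ndarray, cho, Ci1, s, expected_ratio) -> np.ndarray:
    """K for each column of Y (n x B)."""
    a = (Ci1 @ Y) / s  # phylogenetic mean per column
    D = Y - a[None, :]
    mse0 = (D**2).sum(axis=0)
    CiD = linalg.cho_solve(cho, D)
    mse = (D * CiD).sum(axis=0)
    return (mse0 / mse) / expected_ratio


class BlombergKTest(BaseEstimator):
    """Blomberg's K against the tree's BM variance-covariance matrix.

    K is the observed MSE0/MSE ratio (trait variance about the phylogenetic
    mean over the phylogenetically corrected mean square error) scaled by
    its expectation under Brownian motion; permutation inference shuffles
    trait values across tips (upper-tailed).
    """

    def __init__(self, n_perm: int = 10_000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, y, tree_or_C):
        y = _check_trait(y)
        if isinstance(tree_or_C, SquareTaxonMatrix):
            C = tree_or_C.values
        elif isinstance(tree_or_C, np.ndarray):
            C = tree_or_C
        else:
            C = bm_vcv(tree_or_C).values
        n = len(y)
        if C.shape != (n, n):
            raise ValueError("trait/covariance size mismatch")
        cho, Ci1, s, expected_ratio = _k_quadratics(C)
        self.statistic_ = float(_k_of(y[:, None], cho, Ci1, s, expected_ratio)[0])
        self.expectation_ = 1.0  # K scales so BM-evolved traits center on 1
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            P = _perm_matrix(rng, n, self.n_perm)
            null = _k_of(y[P].T, cho, Ci1, s, expected_ratio)
            self.null_distribution_ = null
            self.p_value_ = _upper_p(null, self.statistic_)
            sd = null.std(ddof=1)
            self.std_deviate_ = (self.statistic_ - null.mean()) / sd if sd > 0 else None
        else:
            self.null_distribution_ = None
            self.p_value_ = None
            self.std_deviate_ = None
        return self

    def result(self, **kw) -> SignalTestResult:
        return SignalTestResult(
            "blomberg_k",
            self.statistic_,
            self.expectation_,
            self.std_deviate_,
            self.p_value_,
            self.n_perm,
            self.seed,
            **kw,
        )


# ---------------------------------------------------------------------- Mantel

def _tri_vectors(D) -> np.ndarray:
    if isinstance(D, SquareTaxonMatrix):
        D = D.values
    D = np.asarray(D, dtype=float)
    return D


def _check_mantel_pair(DX, DY):
    X = _tri_vectors(DX)
    Y = _tri_vectors(DY)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("Mantel needs two square matrices of equal size")
    if isinstance(DX, SquareTaxonMatrix) and isinstance(DY, SquareTaxonMatrix):
        if DX.taxa != DY.taxa:
            raise ValueError("Mantel matrices have mismatched taxon order")
    return X, Y


def _pearson_rows(xv: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (B, m) against (B, m) (or (m,))."""
    if xv.ndim == 1:
        xv = xv[None, :]
    if yv.ndim == 1:
        yv = yv[None, :]
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


class MantelTest(BaseEstimator):
    """Mantel correlation of two distance matrices (upper-tailed MC test)."""

    def __init__(self, n_perm: int = 10_000, seed: int | None = None, chunk: int = 2_000):
        self.n_perm = n_perm
        self.seed = seed
        self.chunk = chunk

    def fit(self, DX, DY):
        X, Y = _check_mantel_pair(DX, DY)
        n = X.shape[0]
        iu, ju = np.tril_indices(n, k=-1)
        xv = X[iu, ju]
        yv = Y[iu, ju]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise UndefinedStatisticError("constant off-diagonal distances")
        self.statistic_ = float(_pearson_rows(xv, yv)[0])
        self.expectation_ = 0.0
        if self.n_perm:
            rng = np.random.default_rng(self.seed)
            null = np.empty(self.n_perm)
            done = 0
            while done < self.n_perm:
                b = min(self.chunk, self.n_perm - done)
                P = _perm_matrix(rng, n, b)
                yp = Y[P[:, iu], P[:, ju]]
                null[done : done + b] = _pearson_rows(xv[None, :], yp)
                done += b
            self.null_distribution_ = null
            self.p_value_ = _upper_p(null, self.statistic_)
            sd = null.std(ddof=1)
            self.std_deviate_ = (self.statistic_ - null.mean()) / sd if sd > 0 else None
        else:
            self.null_distribution_ = None
            self.p_value_ = None
            self.std_deviate_ = None
        return self

    def result(self, **kw) -> SignalTestResult:
        return SignalTestResult(
            "mantel",
            self.statistic_,
            self.expectation_,
            self.std_deviate_,
            self.p_value_,
            self.n_perm,
            self.seed,
            **kw,
        )


@dataclass
class BootstrapSample:
    """Bootstrap distribution of a Mantel correlation."""

    r: np.ndarray
    frac: float
    seed: int | None
    n_redrawn: int = 0

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.r, q)

    def exceedance(self, value: float) -> float:
        """Proportion of the bootstrap sample strictly below ``value``."""
        return float((self.r < value).mean())


def mantel_bootstrap(
    DX,
    DY,
    n_iter: int = 10_000,
    frac: float = 0.9,
    seed: int | None = None,
    chunk: int = 2_000,
) -> BootstrapSample:
    """Bootstrap the Mantel r by taxon subsampling.

    Each iteration draws ``ceil(frac * n)`` taxa *without replacement*
    (with-replacement draws would put zero self-distances into the
    submatrix) and recomputes r on the induced submatrices. Degenerate
    subsamples with constant off-diagonals are redrawn.
    """
    X, Y = _check_mantel_pair(DX, DY)
    n = X.shape[0]
    m = int(np.ceil(frac * n))
    if m < 4:
        raise ValueError(f"subsample size {m} too small (frac*n must be >= 4)")
    rng = np.random.default_rng(seed)
    iu, ju = np.tril_indices(m, k=-1)
    out = np.empty(n_iter)
    done = 0
    n_redrawn = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        idx = _perm_matrix(rng, n, b)[:, :m]
        xv = X[idx[:, iu], idx[:, ju]]
        yv = Y[idx[:, iu], idx[:, ju]]
        r = _pearson_rows(xv, yv)
        ok = np.isfinite(r)
        n_redrawn += int((~ok).sum())
        k = int(ok.sum())
        out[done : done + k] = r[ok]
        done += k
    return BootstrapSample(out, frac, seed, n_redrawn)


# ------------------------------------------------------------ functional forms

def morans_i(z, W, **kw) -> SignalTestResult:
    return MoranTest(n_perm=0).fit(z, W).result(**kw)


def morans_i_mc(z, W, n_perm: int = 10_000, seed: int | None = None, **kw) -> SignalTestResult:
    return MoranTest(n_perm=n_perm, seed=seed).fit(z, W).result(**kw)


def gearys_c(z, W, **kw) -> SignalTestResult:
    return GearyTest(n_perm=0).fit(z, W).result(**kw)


def gearys_c_mc(z, W, n_perm: int = 10_000, seed: int | None = None, **kw) -> SignalTestResult:
    return GearyTest(n_perm=n_perm, seed=seed).fit(z, W).result(**kw)


def blombergs_k(y, tree_or_C, **kw) -> SignalTestResult:
    return BlombergKTest(n_perm=0).fit(y, tree_or_C).result(**kw)


def blombergs_k_mc(
    y, tree_or_C, n_perm: int = 10_000, seed: int | None = None, **kw
) -> SignalTestResult:
    return BlombergKTest(n_perm=n_perm, seed=seed).fit(y, tree_or_C).result(**kw)


def mantel(DX, DY, **kw) -> SignalTestResult:
    return MantelTest(n_perm=0).fit(DX, DY).result(**kw)


def mantel_mc(DX, DY, n_perm: int = 10_000, seed: int | None = None, **kw) -> SignalTestResult:
    return MantelTest(n_perm=n_perm, seed=seed).fit(DX, DY).result(**kw)
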