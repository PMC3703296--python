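"""Phylogenetic size-correction of acoustic traits.

Body size constrains vocal production, and body size itself carries
phylogenetic signal, so every trait is first regressed on log snout-vent
length (logSVL) by phylogenetic generalized least squares (PGLS) under a
Brownian-motion covariance; the *ordinary-scale* residuals
``e = y - X beta_hat`` then enter the signal tests. Using GLS for the fit
but reporting ordinary residuals follows the standard phylogenetic
residual construction: the slope is estimated respecting phylogenetic
non-independence, while the residual stays in trait units per species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .audio import TRAIT_COLUMNS
from .matrices import SquareTaxonMatrix
from .phylo import bm_vcv, tip_labels


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def _chol(C: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "phylogenetic covariance matrix is not positive definite"
        ) from exc


class PGLSRegression(RegressorMixin, BaseEstimator):
    """Generalized least squares regression with a fixed error covariance.

    The design is ``[1, x]`` (intercept plus one covariate) for 1-D input,
    or ``[1, X]`` generally; coefficients solve
    ``beta = (X' C^-1 X)^-1 X' C^-1 y``. With ``covariance=None`` (or any
    multiple of the identity, e.g. a star phylogeny) the fit reduces
    exactly to ordinary least squares.

    Attributes (after ``fit``)
    --------------------------
    intercept_, coef_ : fitted coefficients.
    residuals_ : ordinary-scale residuals ``y - X beta``.
    whitened_residuals_ : ``L^-1 (y - X beta)`` for Cholesky C = LL'.
    """

    def __init__(self, covariance: np.ndarray | SquareTaxonMatrix | None = None):
        self.covariance = covariance

    def _cov_array(self, n: int) -> np.ndarray:
        C = self.covariance
        if C is None:
            return np.eye(n)
        if isinstance(C, SquareTaxonMatrix):
            C = C.values
        C = np.asarray(C, dtype=float)
        if C.shape != (n, n):
            raise ValueError(f"covariance shape {C.shape} does not match n={n}")
        return C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y length mismatch")
        Xd = np.column_stack([np.ones(n), X])
        C = self._cov_array(n)
        L = _chol(C)
        Xw = linalg.solve_triangular(L, Xd, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        q, r = np.linalg.qr(Xw)
        if np.linalg.matrix_rank(r) < Xd.shape[1]:
            raise SingularCovarianceError("design matrix is rank deficient")
        beta = linalg.solve_triangular(r, q.T @ yw, lower=False)
        self.n_features_in_ = X.shape[1]
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.residuals_ = y - Xd @ beta
        self.whitened_residuals_ = yw - Xw @ beta
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


@dataclass
class PGLSFit:
    """Result of one trait-on-logSVL phylogenetic regression."""

    intercept: float
    slope: float
    residuals: pd.Series  # keyed by species_id, ordinary scale
    group: str = "all"


def pgls_fit(
    y: Sequence[float],
    x: Sequence[float],
    C: SquareTaxonMatrix | np.ndarray,
    taxa: Sequence[str] | None = None,
    group: str = "all",
) -> PGLSFit:
    """Single-covariate PGLS of ``y`` on ``x`` under covariance ``C``."""
    if isinstance(C, SquareTaxonMatrix):
        if taxa is None:
            taxa = C.taxa
        C = C.reorder(list(taxa)).values
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    model = PGLSRegression(covariance=C).fit(x, y)
    index = list(taxa) if taxa is not None else list(range(len(y)))
    return PGLSFit(
        model.intercept_,
        float(model.coef_[0]),
        pd.Series(model.residuals_, index=index),
        group,
    )


def size_correct(
    traits: pd.DataFrame,
    tree,
    grouping: str = "all",
    trait_columns: Sequence[str] = tuple(TRAIT_COLUMNS),
    min_clade_size: int = 3,
) -> pd.DataFrame:
    """PGLS residuals of each trait against logSVL.

    With ``grouping='all'`` a single regression per trait uses the whole
    tree's BM covariance; with ``'per_clade'`` the tree is pruned to each
    clade and separate regressions are fitted (clades smaller than
    ``min_clade_size`` are skipped with a warning). Returns a DataFrame
    indexed by species with ``clade``, ``group`` and one ``<trait>_res``
    column per trait.
    """
    import warnings

    if grouping not in ("all", "per_clade"):
        raise ValueError("grouping must be 'all' or 'per_clade'")
    labels = set(tip_labels(tree))
    missing = sorted(set(traits.index) - labels)
    if missing:
        raise ValueError(f"trait species absent from tree: {missing}")
    groups: list[tuple[str, pd.DataFrame]]
    if grouping == "all":
        groups = [("all", traits)]
    else:
        groups = [(str(c), sub) for c, sub in traits.groupby("clade")]

    frames = []
    for name, sub in groups:
        if len(sub) < min_clade_size:
            warnings.warn(
                f"clade {name!r} has {len(sub)} species (<{min_clade_size}); skipped"
            )
            continue
        taxa = list(sub.index)
        C = bm_vcv(tree, taxa=taxa)
        out = pd.DataFrame(index=sub.index)
        out["clade"] = sub["clade"]
        out["group"] = name
        for col in trait_columns:
            fit = pgls_fit(sub[col].to_numpy(), sub["logsvl"].to_numpy(), C, taxa, name)
            out[f"{col}_res"] = fit.residuals
        frames.append(out)
    if not frames:
        raise ValueError("no group large enough to fit")
    res = pd.concat(frames)
    res.index.name = "species_id"
    return res


def standardize(residuals: pd.DataFrame, by_group: bool = True) -> pd.DataFrame:
    """Z-score each residual column (mean 0, sd 1 with n-1 denominator).

    With ``by_group`` (default) standardization is applied within each
    analysis group so per-clade residuals get equal weight inside their own
    clade; pass False to standardize across the whole table.
    """
    res_cols = [c for c in residuals.columns if c.endswith("_res")]
    if not res_cols:
        raise ValueError("no *_res columns to standardize")
    out = residuals.copy()

    def _z(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) < 2:
            raise ValueError("standardization needs at least two species")
        for c in res_cols:
            sd = df[c].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"zero-variance residual column {c!r}")
            df[c] = (df[c] - df[c].mean()) / sd
        return df

    if by_group and "group" in out.columns and out["group"].nunique() > 1:
        out = out.groupby("group", group_keys=False)[out.columns].apply(_z)
    else:
        out = _z(out)
    return out
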