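"""Multivariate trait distances and bootstrap forward stepwise selection.

A multivariate "call phenotype" distance is the Euclidean distance over a
subset of the standardized size-corrected residuals. Which subset best
tracks genetic relatedness is decided by a forward stepwise search: start
from the single trait with the highest Mantel correlation against the
genetic matrix, then repeatedly try to add the candidate that raises r the
most, accepting the addition only when the enlarged model's r exceeds at
least 95% of a 10,000-draw bootstrap sample of the incumbent model's r
(there being no formal test for comparing two Mantel coefficients). The
procedure runs on the whole sample only — never within clades — to avoid
over-fitting; clade-level rows then re-evaluate the whole-sample winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .matrices import SquareTaxonMatrix
from .signal_tests import (
    MantelTest,
    SignalTestResult,
    mantel_bootstrap,
    mantel_mc,
)

__all__ = [
    "euclidean_trait_distance",
    "ForwardStepwiseMantel",
    "forward_stepwise",
    "StepwiseStep",
    "StepwiseTrace",
]


def euclidean_trait_distance(
    residuals: pd.DataFrame, traits: Sequence[str]
) -> SquareTaxonMatrix:
    """Euclidean distance over selected standardized residual columns.

    ``traits`` may name columns directly (``cva_res``) or by trait
    (``cva``), in which case ``_res`` is appended.
    """
    if not traits:
        raise ValueError("trait subset must be nonempty")
    cols = []
    for t in traits:
        for cand in (t, f"{t}_res"):
            if cand in residuals.columns:
                cols.append(cand)
                break
        else:
            raise KeyError(f"unknown trait {t!r} (no column {t!r} or {t}_res)")
    X = residuals[cols].to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    return SquareTaxonMatrix(
        list(residuals.index), D, "distance", {"traits": list(traits)}
    )


@dataclass
class StepwiseStep:
    """One candidate evaluation in the forward search."""

    step: int
    candidate: str
    model_before: list[str]
    r_before: float
    r_after: float
    exceedance: float | None  # share of incumbent bootstrap r below r_after
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "candidate": self.candidate,
            "model_before": self.model_before,
            "r_before": self.r_before,
            "r_after": self.r_after,
            "exceedance": self.exceedance,
            "accepted": self.accepted,
        }


@dataclass
class StepwiseTrace:
    """Full log of the forward stepwise search and its outcome."""

    selected: list[str]
    final_r: float
    final_result: SignalTestResult | None
    steps: list[StepwiseStep] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "final_r": self.final_r,
            "final_p_mc": None if self.final_result is None else self.final_result.p_mc,
            "seed": self.seed,
            "steps": [s.to_dict() for s in self.steps],
        }


class ForwardStepwiseMantel(BaseEstimator):
    """Forward stepwise selection of a multivariate trait distance model.

    Parameters
    ----------
    n_boot : bootstrap iterations for each coefficient comparison.
    exceedance : acceptance threshold — the enlarged model's r must exceed
        this proportion of the incumbent's bootstrap sample (default 0.95).
    frac : taxon subsampling fraction for the bootstrap (without
        replacement).
    n_perm : permutations for the final model's Mantel significance test.
    seed : master seed; each bootstrap comparison is seeded independently
        as ``seed + 1000 * step + candidate_index`` so the selection result
        does not depend on candidate evaluation order.

    Attributes (after ``fit``)
    --------------------------
    selected_traits_ : the chosen trait subset, in order of inclusion.
    r_ : Mantel r of the selected model.
    trace_ : :class:`StepwiseTrace` logging every evaluated candidate.
    """

    def __init__(
        self,
        n_boot: int = 10_000,
        exceedance: float = 0.95,
        frac: float = 0.9,
        n_perm: int = 10_000,
        seed: int | None = None,
    ):
        self.n_boot = n_boot
        self.exceedance = exceedance
        self.frac = frac
        self.n_perm = n_perm
        self.seed = seed

    def _r(self, residuals: pd.DataFrame, genetic: SquareTaxonMatrix, traits) -> float:
        D = euclidean_trait_distance(residuals, traits)
        return MantelTest(n_perm=0).fit(D, genetic).statistic_

    def fit(self, residuals: pd.DataFrame, genetic: SquareTaxonMatrix, candidates=None):
        if candidates is None:
            candidates = [c[: -len("_res")] for c in residuals.columns if c.endswith("_res")]
        candidates = list(candidates)
        if not candidates:
            raise ValueError("no candidate traits")
        genetic = genetic.reorder(list(residuals.index))
        n = genetic.n
        if int(np.ceil(self.frac * n)) < 4:
            raise ValueError("sample too small for taxon-subsampling bootstrap")
        base_seed = 0 if self.seed is None else int(self.seed)

        # step 0: best single trait (ties broken lexicographically)
        singles = sorted(
            ((self._r(residuals, genetic, [c]), c) for c in candidates),
            key=lambda t: (-t[0], t[1]),
        )
        best_r, best_trait = singles[0]
        model = [best_trait]
        steps: list[StepwiseStep] = []
        remaining = [c for c in candidates if c != best_trait]

        step_no = 1
        while remaining:
            # evaluate every remaining candidate against the incumbent
            trials = sorted(
                ((self._r(residuals, genetic, model + [c]), c) for c in remaining),
                key=lambda t: (-t[0], t[1]),
            )
            r_new, cand = trials[0]
            incumbent_D = euclidean_trait_distance(residuals, model)
            boot_seed = base_seed + 1000 * step_no + candidates.index(cand)
            boot = mantel_bootstrap(
                incumbent_D, genetic, self.n_boot, self.frac, seed=boot_seed
            )
            exc = boot.exceedance(r_new)
            accepted = r_new > best_r and exc >= self.exceedance
            steps.append(
                StepwiseStep(step_no, cand, list(model), best_r, r_new, exc, accepted)
            )
            # log the rejected alternatives at this step too
            for r_alt, c_alt in trials[1:]:
                steps.append(
                    StepwiseStep(step_no, c_alt, list(model), best_r, r_alt, None, False)
                )
            if not accepted:
                break
            model.append(cand)
            best_r = r_new
            remaining.remove(cand)
            step_no += 1

        final = mantel_mc(
            euclidean_trait_distance(residuals, model),
            genetic,
            n_perm=self.n_perm,
            seed=base_seed,
        )
        self.selected_traits_ = model
        self.r_ = best_r
        self.final_result_ = final
        self.trace_ = StepwiseTrace(model, best_r, final, steps, self.seed)
        return self


def forward_stepwise(
    residuals: pd.DataFrame,
    genetic: SquareTaxonMatrix,
    candidates: Sequence[str] | None = None,
    n_boot: int = 10_000,
    exceedance: float = 0.95,
    frac: float = 0.9,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> StepwiseTrace:
    """Functional wrapper over :class:`ForwardStepwiseMantel`."""
    est = ForwardStepwiseMantel(n_boot, exceedance, frac, n_perm, seed)
    est.fit(residuals, genetic, candidates)
    return est.trace_
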