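"""Square taxon-keyed matrices: distances, proximities, weights, covariances.

Every pairwise structure in the pipeline (genetic distance, Abouheif
proximity, Moran weight matrix, Brownian-motion trait covariance) is a
symmetric-or-row-structured real matrix keyed by an ordered taxon list.
This module provides the one container they all share, plus TSV round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

VALID_KINDS = ("distance", "proximity", "weight", "covariance")


@dataclass
class SquareTaxonMatrix:
    """An n x n real matrix with an ordered taxon key.

    Parameters
    ----------
    taxa : ordered taxon identifiers (unique).
    values : (n, n) float array.
    kind : one of ``distance``, ``proximity``, ``weight``, ``covariance``.
        ``distance``/``proximity``/``covariance`` must be symmetric;
        ``distance`` must have a zero diagonal; ``weight`` matrices may be
        asymmetric (row standardization) and must have a zero diagonal.
    """

    taxa: list[str]
    values: np.ndarray
    kind: str = "distance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} taxa"
            )
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels in matrix key")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind in ("distance", "proximity", "covariance"):
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise ValueError(f"{self.kind} matrix must be symmetric")
        if self.kind in ("distance", "weight"):
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                raise ValueError(f"{self.kind} matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def index_of(self, taxa: Sequence[str]) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        return np.array([pos[t] for t in taxa], dtype=int)

    def reorder(self, taxa: Sequence[str]) -> "SquareTaxonMatrix":
        """Return the matrix restricted to / reordered by `taxa`."""
        idx = self.index_of(taxa)
        return SquareTaxonMatrix(
            list(taxa), self.values[np.ix_(idx, idx)], self.kind, dict(self.meta)
        )

    def subset(self, taxa: Sequence[str]) -> "SquareTaxonMatrix":
        return self.reorder(taxa)

    def offdiag(self) -> np.ndarray:
        """Strict lower-triangle vector (the canonical vectorization)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#kind={self.kind}\n")
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.values):
                fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SquareTaxonMatrix":
        path = Path(path)
        kind = "distance"
        with path.open() as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if lines and lines[0].startswith("#kind="):
            kind = lines[0].split("=", 1)[1].strip()
            lines = lines[1:]
        header = lines[0].split("\t")
        taxa = [t for t in header if t]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([float(x) for x in parts[1:]])
        return cls(taxa, np.array(rows), kind)
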