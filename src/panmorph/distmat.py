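"""Labeled symmetric between-taxon distance matrices.

Every stage of the analysis exchanges distance structure through
:class:`DistanceMatrix`: genotypic matrices **F** (Nei standard, chord,
F_ST, Patterson-PC Euclidean), phenotypic matrices **M** (per ontogenetic
stage) and quantitative-genetic matrices **Q** (Q_ST, per stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: recognised provenance kinds
KINDS = ("F_nei", "F_chord", "F_fst", "F_ppc", "M_pheno", "Q_qst", "generic")


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative labeled distance matrix.

    Parameters
    ----------
    labels : tuple of str
        Taxon labels, one per row/column.
    values : ndarray of shape (k, k)
        Pairwise distances.  ``inf`` entries are allowed (Nei's standard
        distance diverges for alternately fixed profiles).
    kind : str
        Provenance tag, one of :data:`KINDS`.
    stage : str, optional
        Ontogenetic stage for phenotypic / quantitative-genetic matrices.
    meta : dict
        Free-form metadata (estimator variants, h2, clamp records ...).
    """

    labels: tuple
    values: np.ndarray
    kind: str = "generic"
    stage: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = tuple(str(x) for x in self.labels)
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError(f"matrix shape {v.shape} does not match {k} labels")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T],
                           rtol=1e-8, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("diagonal is not zero")
        if np.any(v[finite] < -1e-10):
            raise ValueError("negative distances")
        # exact symmetrisation so downstream code may rely on it
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        v[v < 0] = 0.0
        self.values = v

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Condensed upper-triangle vector (scipy ``squareform`` order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)],
                              kind=self.kind, stage=self.stage,
                              meta=dict(self.meta))

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)
        side = {"kind": self.kind, "stage": self.stage, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(side, indent=1,
                                                        default=str))

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        kind, stage, meta = "generic", None, {}
        side = path.with_suffix(".json")
        if side.exists():
            d = json.loads(side.read_text())
            kind = d.get("kind", "generic")
            stage = d.get("stage")
            meta = d.get("meta", {})
        return cls(tuple(df.index), df.to_numpy(float), kind=kind,
                   stage=stage, meta=meta)
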