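"""Stage-wise phenotypic (M) and quantitative-genetic (Q) distance matrices.

P_ST -> Q_ST conversion under a heritability assumption: for a pair of
taxa, the between-group and pooled within-group variance components of the
leading shape PC scores give

    Q_ST = V_B / (V_B + 2 h2 V_W)

with h2 the assumed narrow-sense heritability (default 0.55) scaling the
within-group phenotypic variance down to its additive-genetic part.
V_B is the two-group ANOVA between-group variance component
((MSB - MSW)/n0, negative estimates clipped to 0); aggregation across PCs
sums the variance components, preserving the variance-ratio reading.
Under pure drift E[Q_ST] matches the neutral F_ST; Q_ST > F_ST is the
diversifying-selection signature, Q_ST < F_ST stabilizing selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .shapespace import ShapeSpace, stage_taxon_means


@dataclass
class QstConfig:
    h2: float = 0.55
    n_components: int = 3
    variance_pooling: bool = True
    aggregate: str = "sum"        # "sum" of components or "mean" of ratios

    def __post_init__(self):
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.aggregate not in ("sum", "mean"):
            raise ValueError("aggregate must be 'sum' or 'mean'")


# ----------------------------------------------------------------------

def pheno_distance_matrix(space: ShapeSpace, stage: str,
                          n_components: int | None = None) -> DistanceMatrix:
    """Euclidean distance in morphospace between taxon stage means (**M**).

    ``n_components`` defaults to the leading PCs jointly explaining >= 90%
    of the shape variance.
    """
    k = n_components or space.n_components_for(0.90)
    means = stage_taxon_means(space, n_components=k)
    taxa = list(means.index.get_level_values("taxon").unique())
    M = np.stack([means.loc[(t, stage)].to_numpy(float) for t in taxa])
    diff = M[:, None, :] - M[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceMatrix(taxa, D, kind="M_pheno", stage=stage,
                          meta={"n_components": k})


def qst_from_variances(vb, vw, h2: float) -> float:
    """Q_ST from summed between/within variance components."""
    vb, vw = float(np.sum(vb)), float(np.sum(vw))
    if vb == 0 and vw == 0:
        warnings.warn("zero between- and within-variance: Q_ST undefined, "
                      "returning 0")
        return 0.0
    return float(np.clip(vb / (vb + 2.0 * h2 * vw), 0.0, 1.0))


def _variance_components(A: np.ndarray, B: np.ndarray):
    """Two-group ANOVA components per column.

    Returns (V_B, V_W) arrays: the between-group variance component
    ((MSB - MSW)/n0, clipped at 0) and the pooled within-group variance.
    """
    nA, nB = len(A), len(B)
    N = nA + nB
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    grand = (nA * mA + nB * mB) / N
    msb = nA * (mA - grand) ** 2 + nB * (mB - grand) ** 2    # df = K-1 = 1
    ssw = ((A - mA) ** 2).sum(axis=0) + ((B - mB) ** 2).sum(axis=0)
    msw = ssw / (N - 2)
    n0 = (N - (nA ** 2 + nB ** 2) / N)                        # /(K-1)
    vb = np.clip((msb - msw) / n0, 0.0, None)
    return vb, msw


def qst_pairwise(space: ShapeSpace, stage: str, taxon_a: str, taxon_b: str,
                 config: QstConfig = QstConfig()) -> float:
    """Pairwise Q_ST from PC scores at one ontogenetic stage."""
    k = config.n_components
    A = space.cell_scores(taxon_a, stage)[:, :k]
    B = space.cell_scores(taxon_b, stage)[:, :k]
    if len(A) < 3 or len(B) < 3:
        raise ValueError("both cells need >= 3 specimens")
    vb, vw = _variance_components(A, B)
    if config.aggregate == "mean":
        qs = [qst_from_variances(b, w, config.h2) for b, w in zip(vb, vw)]
        return float(np.mean(qs))
    return qst_from_variances(vb, vw, config.h2)


def qst_matrix(space: ShapeSpace, stage: str,
               config: QstConfig = QstConfig()) -> DistanceMatrix:
    """All pairwise Q_ST values at a stage (**Q**_stage)."""
    taxa = list(dict.fromkeys(space.taxa))
    K = len(taxa)
    Q = np.zeros((K, K))
    for i, j in itertools.combinations(range(K), 2):
        Q[i, j] = Q[j, i] = qst_pairwise(space, stage, taxa[i], taxa[j],
                                         config)
    return DistanceMatrix(taxa, Q, kind="Q_qst", stage=stage,
                          meta={"h2": config.h2,
                                "n_components": config.n_components,
                                "aggregate": config.aggregate})


def h2_sensitivity(space: ShapeSpace, stage: str, h2_grid,
                   n_components: int = 3,
                   reference: DistanceMatrix | None = None):
    """Q matrices across an h2 grid, with Mantel r against a reference.

    Because h2 enters every pairwise Q_ST as a common scale factor on the
    within-group term, the *structure* of Q is nearly invariant to h2 when
    within-group variances are homogeneous across taxa; the returned Mantel
    correlations quantify that.  ``reference`` defaults to the first grid
    entry's matrix.
    """
    from .congruence import mantel
    h2_grid = list(h2_grid)
    if not h2_grid or not all(0 < h <= 1 for h in h2_grid):
        raise ValueError("h2 grid must be non-empty with values in (0, 1]")
    mats = [qst_matrix(space, stage,
                       QstConfig(h2=h, n_components=n_components))
            for h in h2_grid]
    ref = reference or mats[0]
    rows = []
    for h, m in zip(h2_grid, mats):
        if len(mats) > 1 or reference is not None:
            r = mantel(ref, m, scheme="entries").r
        else:
            r = 1.0
        rows.append({"h2": h, "mantel_r_vs_reference": r})
    return mats, pd.DataFrame(rows)
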