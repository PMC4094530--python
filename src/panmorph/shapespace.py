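"""Morphospace: PCA over vectorized morphometric maps.

Shape variation across specimens is decomposed by singular-value
decomposition of the mean-centered map vectors.  The resulting scores are
the coordinate system for everything downstream: taxon x stage mean
shapes, permutation tests on mean differences, ontogenetic trajectories
(the path of a taxon's stage means from infancy m2 to adulthood M3), and
trajectory length/direction comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd


@dataclass
class ShapeSpace:
    grand_mean: np.ndarray               # (G,)
    components: np.ndarray               # (r, G) orthonormal rows
    explained_variance_ratio: np.ndarray  # (r,)
    scores: np.ndarray                   # (n, r), zero column means
    taxa: np.ndarray                     # (n,)
    stages: np.ndarray                   # (n,)
    specimen_ids: np.ndarray             # (n,)
    grid_shape: tuple                    # (n_levels, n_angles)
    stage_order: tuple = ()

    @property
    def n_specimens(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def n_components_for(self, variance_fraction: float = 0.90) -> int:
        """Smallest number of leading PCs explaining >= the given fraction."""
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)

    def cell_scores(self, taxon: str, stage: str) -> np.ndarray:
        mask = (self.taxa == taxon) & (self.stages == stage)
        return self.scores[mask]

    def inverse(self, score_vec: np.ndarray) -> np.ndarray:
        """Map a (possibly truncated) score vector back to a map grid."""
        s = np.zeros(self.n_components)
        s[:len(score_vec)] = score_vec
        return (self.grand_mean + s @ self.components).reshape(self.grid_shape)


def fit_shape_pca(maps, taxa=None, stages=None, specimen_ids=None
                  ) -> ShapeSpace:
    """PCA of normalized morphometric maps.

    Labels default to each map's own taxon/stage/specimen_id attributes.
    Retains min(n-1, grid) components; component signs follow the
    convention that the largest-magnitude loading is positive.
    """
    maps = list(maps)
    if len(maps) < 3:
        raise ValueError("need at least 3 specimens")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent map grids: {shapes}")
    if not all(m.normalized for m in maps):
        raise ValueError("all maps must be normalized")
    if taxa is None:
        taxa = [m.taxon for m in maps]
    if stages is None:
        stages = [m.stage for m in maps]
    if specimen_ids is None:
        specimen_ids = [m.specimen_id or str(i) for i, m in enumerate(maps)]

    X = np.stack([m.vector() for m in maps])
    grand_mean = X.mean(axis=0)
    Xc = X - grand_mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(len(maps) - 1, X.shape[1])
    U, S, Vt = U[:, :r], S[:r], Vt[:r]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(r):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    total_var = float(np.sum(Xc ** 2))
    evr = (S ** 2 / total_var) if total_var > 0 else np.zeros(r)
    stage_order = []
    for s in stages:
        if s not in stage_order:
            stage_order.append(s)
    return ShapeSpace(
        grand_mean=grand_mean, components=Vt,
        explained_variance_ratio=evr, scores=U * S,
        taxa=np.asarray(taxa, dtype=object),
        stages=np.asarray(stages, dtype=object),
        specimen_ids=np.asarray(specimen_ids, dtype=object),
        grid_shape=maps[0].values.shape,
        stage_order=tuple(stage_order),
    )


def stage_taxon_means(space: ShapeSpace, n_components: int | None = None
                      ) -> pd.DataFrame:
    """Mean score vector per taxon x stage cell (MultiIndex DataFrame)."""
    k = n_components or space.n_components
    taxa = list(dict.fromkeys(space.taxa))
    stages = list(space.stage_order) or list(dict.fromkeys(space.stages))
    empty = [(t, s) for t in taxa for s in stages
             if not len(space.cell_scores(t, s))]
    if empty:
        raise ValueError(f"empty taxon x stage cells: {empty}")
    rows, idx = [], []
    for t in taxa:
        for s in stages:
            rows.append(space.cell_scores(t, s)[:, :k].mean(axis=0))
            idx.append((t, s))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["taxon", "stage"]),
        columns=[f"PC{i+1}" for i in range(k)])


# ----------------------------------------------------------------------
# permutation test on mean-shape differences

def mean_shape_permutation_test(space: ShapeSpace, stage: str, taxon_a: str,
                                taxon_b: str, n_perm: int = 999,
                                seed: int | None = None,
                                n_components: int | None = None,
                                max_exhaustive: int = 10_000) -> dict:
    """Permutation p for the distance between two cell means.

    Statistic: Euclidean distance between the taxon means in morphospace.
    Null: random relabeling of the pooled specimens within the stage.  When
    the number of distinct splits is at most ``max_exhaustive`` the split
    space is enumerated exactly; otherwise ``n_perm`` random relabelings
    give p = (b + 1)/(n_perm + 1).
    """
    k = n_components or space.n_components
    A = space.cell_scores(taxon_a, stage)[:, :k]
    B = space.cell_scores(taxon_b, stage)[:, :k]
    if len(A) < 3 or len(B) < 3:
        raise ValueError("both cells need >= 3 specimens")
    obs = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    pool = np.vstack([A, B])
    nA, n = len(A), len(pool)
    if comb(n, nA) <= max_exhaustive:
        count = total = 0
        for combo in itertools.combinations(range(n), nA):
            ia = np.asarray(combo)
            mask = np.zeros(n, dtype=bool)
            mask[ia] = True
            d = np.linalg.norm(pool[mask].mean(axis=0)
                               - pool[~mask].mean(axis=0))
            count += d >= obs - 1e-12
            total += 1
        return {"statistic": obs, "p": count / total, "method": "exhaustive",
                "n_perm": total}
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d = np.linalg.norm(pool[perm[:nA]].mean(axis=0)
                           - pool[perm[nA:]].mean(axis=0))
        b += d >= obs - 1e-12
    return {"statistic": obs, "p": (b + 1) / (n_perm + 1),
            "method": "sampled", "n_perm": n_perm}


# ----------------------------------------------------------------------
# trajectories

@dataclass
class Trajectory:
    """Ontogenetic trajectory of a taxon through morphospace."""

    taxon: str
    stages: tuple
    stage_means: np.ndarray      # (n_stages, k)

    def __post_init__(self):
        self.stage_means = np.asarray(self.stage_means, float)

    @property
    def length(self) -> float:
        """Sum of consecutive segment norms."""
        return float(np.sum(np.linalg.norm(np.diff(self.stage_means, axis=0),
                                           axis=1)))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from first to last stage mean."""
        d = self.stage_means[-1] - self.stage_means[0]
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero-length trajectory has no direction")
        return d / n


def build_trajectory(means: pd.DataFrame, taxon: str,
                     stages=None, n_components: int | None = None
                     ) -> Trajectory:
    """Trajectory from a stage_taxon_means table for one taxon."""
    sub = means.loc[taxon]
    stages = tuple(stages or sub.index)
    missing = [s for s in stages if s not in sub.index]
    if missing:
        raise ValueError(f"missing stages for {taxon!r}: {missing}")
    M = sub.loc[list(stages)].to_numpy(float)
    if n_components:
        M = M[:, :n_components]
    return Trajectory(taxon=taxon, stages=stages, stage_means=M)


def trajectory_angle(t1: Trajectory, t2: Trajectory) -> float:
    """Angle (degrees) between first-to-last direction vectors."""
    c = float(np.clip(t1.direction @ t2.direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def trajectory_comparison_test(space: ShapeSpace, taxon_a: str, taxon_b: str,
                               n_perm: int = 499, seed: int | None = None,
                               n_components: int | None = None) -> dict:
    """Permutation tests on trajectory direction and length differences.

    Observed statistics: the angle between the two taxa's first-to-last
    directions and the absolute trajectory-length difference.  The null
    reshuffles specimens between the two taxa *within each stage* (stage
    structure preserved) and recomputes both statistics.  The angle p is
    one-sided (angle exceeding chance); the length p is two-sided on the
    absolute difference.
    """
    k = n_components or space.n_components
    stages = list(space.stage_order)
    cells = {(t, s): space.cell_scores(t, s)[:, :k]
             for t in (taxon_a, taxon_b) for s in stages}

    def stats(cells_ab):
        mA = np.stack([cells_ab[(taxon_a, s)].mean(axis=0) for s in stages])
        mB = np.stack([cells_ab[(taxon_b, s)].mean(axis=0) for s in stages])
        tA = Trajectory(taxon_a, tuple(stages), mA)
        tB = Trajectory(taxon_b, tuple(stages), mB)
        return trajectory_angle(tA, tB), abs(tA.length - tB.length)

    obs_angle, obs_dlen = stats(cells)
    rng = np.random.default_rng(seed)
    ge_angle = ge_dlen = 0
    for _ in range(n_perm):
        perm_cells = {}
        for s in stages:
            pool = np.vstack([cells[(taxon_a, s)], cells[(taxon_b, s)]])
            nA = len(cells[(taxon_a, s)])
            order = rng.permutation(len(pool))
            perm_cells[(taxon_a, s)] = pool[order[:nA]]
            perm_cells[(taxon_b, s)] = pool[order[nA:]]
        ang, dl = stats(perm_cells)
        ge_angle += ang >= obs_angle - 1e-12
        ge_dlen += dl >= obs_dlen - 1e-12
    return {
        "angle_deg": obs_angle,
        "p_angle": (ge_angle + 1) / (n_perm + 1),
        "length_diff": obs_dlen,
        "p_length": (ge_dlen + 1) / (n_perm + 1),
        "n_perm": n_perm,
    }
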