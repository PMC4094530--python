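"""Genotype-phenotype congruence machinery.

Per ontogenetic stage the phenotypic distance structure (**M**, **Q**) is
compared with the neutral genotypic structure (**F**): principal
coordinates analysis turns each distance matrix into a taxon
constellation; Procrustes superimposition aligns the constellations;
Mantel tests and an individual-level resampling correlation quantify the
agreement.  Under drift alone the agreement is stage-constant; adaptive
divergence shows up as an ontogenetic decline.

Two Mantel null schemes are provided.  Label permutation (the classical
scheme, exhaustive for few taxa) has only 24 distinct relabelings for 4
taxa, so its smallest attainable p is 1/24; the entry-permutation scheme
shuffles the off-diagonal entries themselves (720 distinct orders for 4
taxa) and resolves smaller p values.  Reports carry both.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import factorial

import numpy as np

from .distmat import DistanceMatrix
from .gendist import GenotypeTable
from .qst import QstConfig, pheno_distance_matrix, qst_matrix
from .shapespace import ShapeSpace


@dataclass
class TaxonConstellation:
    """Centered PCO embedding of a between-taxon distance matrix."""

    labels: tuple
    coordinates: np.ndarray      # (k_taxa, k) centered
    eigenvalues: np.ndarray      # all eigenvalues, non-increasing
    source_kind: str = "generic"
    meta: dict = field(default_factory=dict)


def pco(matrix: DistanceMatrix, k: int | None = None) -> TaxonConstellation:
    """Classical scaling (principal coordinates analysis).

    Double-centers -1/2 J D^2 J, eigendecomposes, and keeps the top ``k``
    axes with positive eigenvalues (coordinates = eigenvectors *
    sqrt(eigenvalues)).  Axes for non-positive eigenvalues are dropped and
    zero-padded; negative eigenvalues are recorded in ``meta``.
    """
    n = matrix.n
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be <= number of taxa - 1")
    D2 = matrix.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.all(vals <= 1e-12) and np.any(np.abs(vals) > 1e-12):
        raise ValueError("all PCO eigenvalues non-positive")
    coords = np.zeros((n, k))
    for j in range(min(k, n)):
        if vals[j] > 1e-12:
            col = vecs[:, j] * np.sqrt(vals[j])
            i = int(np.argmax(np.abs(col)))
            coords[:, j] = col if col[i] >= 0 else -col
    return TaxonConstellation(
        labels=matrix.labels, coordinates=coords, eigenvalues=vals,
        source_kind=matrix.kind,
        meta={"negative_eigenvalues": vals[vals < -1e-12].tolist()})


# ----------------------------------------------------------------------
# Procrustes

def procrustes_superimpose(X: TaxonConstellation, Y: TaxonConstellation,
                           allow_scaling: bool = True):
    """Least-squares superimposition of two taxon constellations.

    Both configurations are centered and scaled to unit Frobenius norm;
    Y is rotated (reflections allowed, scaled if ``allow_scaling``) onto X.
    Returns ``(X0, Y_aligned, d)`` with the symmetric normalized Procrustes
    distance d (0 iff the constellations are similarity-equivalent).
    """
    if X.labels != Y.labels:
        raise ValueError("constellations must share labels")
    A = np.asarray(X.coordinates, float)
    B = np.asarray(Y.coordinates, float)
    k = max(A.shape[1], B.shape[1])
    A = np.pad(A, ((0, 0), (0, k - A.shape[1])))
    B = np.pad(B, ((0, 0), (0, k - B.shape[1])))
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("degenerate (zero-spread) constellation")
    A, B = A / na, B / nb
    U, s, Vt = np.linalg.svd(A.T @ B)
    R = (U @ Vt).T
    trace = float(s.sum())
    if allow_scaling:
        Y_al = trace * B @ R
        d = 1.0 - trace ** 2
    else:
        Y_al = B @ R
        d = 2.0 - 2.0 * trace
    return A, Y_al, float(max(d, 0.0))


# ----------------------------------------------------------------------
# Mantel

@dataclass
class MantelResult:
    r: float
    p: float
    scheme: str
    n_perm: int


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant off-diagonal entries: r undefined")
    return float(a @ b / (na * nb))


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, scheme: str = "auto") -> MantelResult:
    """One-sided Mantel test (positive association is the hypothesis).

    r is the Pearson correlation of the upper-triangle entries.  Schemes:

    ``labels``
        simultaneous row/column permutation of D2 -- exhaustive for up to
        6 taxa, otherwise ``n_perm`` random relabelings;
    ``entries``
        permutation of the off-diagonal entries themselves -- exhaustive
        for up to 4 taxa (720 orders);
    ``auto``
        ``labels``.

    p counts permutations with r >= observed (the identity included for
    exhaustive enumeration, (b+1)/(n_perm+1) otherwise).
    """
    if set(D1.labels) != set(D2.labels):
        raise ValueError("distance matrices must share labels")
    D2 = D2.reorder(D1.labels)
    n = D1.n
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    V2 = D2.values
    r_obs = _pearson(v1, V2[iu])

    if scheme == "auto":
        scheme = "labels"

    if scheme == "labels":
        if factorial(n) <= 5040:
            count = total = 0
            for perm in itertools.permutations(range(n)):
                p = np.asarray(perm)
                r = _pearson(v1, V2[np.ix_(p, p)][iu])
                count += r >= r_obs - 1e-12
                total += 1
            return MantelResult(r_obs, count / total, "labels_exhaustive",
                                total)
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            b += _pearson(v1, V2[np.ix_(p, p)][iu]) >= r_obs - 1e-12
        return MantelResult(r_obs, (b + 1) / (n_perm + 1), "labels_sampled",
                            n_perm)

    if scheme == "entries":
        v2 = V2[iu]
        m = len(v2)
        if factorial(m) <= 10_000:
            count = total = 0
            for perm in itertools.permutations(range(m)):
                r = _pearson(v1, v2[np.asarray(perm)])
                count += r >= r_obs - 1e-12
                total += 1
            return MantelResult(r_obs, count / total, "entries_exhaustive",
                                total)
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            b += _pearson(v1, rng.permutation(v2)) >= r_obs - 1e-12
        return MantelResult(r_obs, (b + 1) / (n_perm + 1), "entries_sampled",
                            n_perm)

    raise ValueError(f"unknown scheme {scheme!r}")


# ----------------------------------------------------------------------
# individual-level resampling correlation

@dataclass
class ResamplingResult:
    R2: float
    p: float
    r: float
    n_draws: int
    n_perm: int
    seed: int | None
    pheno_distances: np.ndarray | None = field(default=None, repr=False)
    geno_distances: np.ndarray | None = field(default=None, repr=False)


def resampling_correlation(space: ShapeSpace, stage: str,
                           table: GenotypeTable, n_draws: int = 1000,
                           n_perm: int = 999, seed: int | None = None,
                           n_components: int | None = None
                           ) -> ResamplingResult:
    """Correlation of individual-level phenotypic and genotypic distances.

    Each draw picks an unordered cross-taxon pair, one phenotyped specimen
    of the stage from each taxon (Euclidean distance in morphospace) and --
    independently -- one genotyped individual from each (allele-sharing
    distance).  Both distance samples are divided by their medians;
    R2 is the squared Pearson correlation over draws.  p is obtained by
    permuting the genotype-side distances across draws (breaking the
    taxon-pair pairing), (b+1)/(n_perm+1).
    """
    k = n_components or space.n_components_for(0.90)
    taxa = [t for t in dict.fromkeys(space.taxa) if t in set(table.taxon)]
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa shared between datasets")
    ph = {t: space.cell_scores(t, stage)[:, :k] for t in taxa}
    gn = {t: table.rows(t) for t in taxa}
    for t in taxa:
        if not len(ph[t]):
            raise ValueError(f"taxon {t!r} missing from phenotype data at "
                             f"stage {stage!r}")
        if not len(gn[t]):
            raise ValueError(f"taxon {t!r} missing from genotype data")
    pairs = list(itertools.combinations(taxa, 2))
    rng = np.random.default_rng(seed)
    pair_idx = rng.integers(len(pairs), size=n_draws)
    dp = np.empty(n_draws)
    dg = np.empty(n_draws)
    for i, pi in enumerate(pair_idx):
        a, b = pairs[pi]
        xa = ph[a][rng.integers(len(ph[a]))]
        xb = ph[b][rng.integers(len(ph[b]))]
        dp[i] = np.linalg.norm(xa - xb)
        ga = gn[a][rng.integers(len(gn[a]))]
        gb = gn[b][rng.integers(len(gn[b]))]
        diff = np.abs(ga - gb)
        dg[i] = np.nanmean(diff) / 2.0
    for name, d in (("phenotypic", dp), ("genotypic", dg)):
        med = np.median(d)
        if med <= 0:
            raise ValueError(f"non-positive median {name} distance")
        d /= med
    r = _pearson(dp, dg)
    R2 = r * r
    perm = np.stack([rng.permutation(dg) for _ in range(n_perm)])
    pc = perm - perm.mean(axis=1, keepdims=True)
    dpc = dp - dp.mean()
    rs = pc @ dpc / (np.linalg.norm(pc, axis=1) * np.linalg.norm(dpc))
    b = int(np.sum(rs ** 2 >= R2 - 1e-12))
    return ResamplingResult(R2=R2, p=(b + 1) / (n_perm + 1), r=r,
                            n_draws=n_draws, n_perm=n_perm, seed=seed,
                            pheno_distances=dp, geno_distances=dg)


# ----------------------------------------------------------------------
# stage-wise report

@dataclass
class CongruenceReport:
    stage: str
    mantel_r: float              # F-M, label scheme
    mantel_p: float
    mantel_p_entries: float      # F-M, entry scheme
    mantel_r_fq: float           # F-Q
    mantel_p_fq: float
    mantel_p_fq_entries: float
    resample_R2: float
    resample_p: float
    procrustes_d: float
    n_perm: int
    n_draws: int
    seeds: dict

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def stagewise_report(F: DistanceMatrix, space: ShapeSpace,
                     table: GenotypeTable, n_perm: int = 999,
                     n_draws: int = 1000, seed: int = 0,
                     qst_config: QstConfig = QstConfig(),
                     n_components: int | None = None,
                     plot_dir=None) -> list:
    """Per-stage congruence of genotypic vs phenotypic structure.

    For each ontogenetic stage: F-M Mantel (both null schemes), F-Q
    Mantel, the individual-level resampling correlation, and the
    Procrustes distance between the PCO constellations of F and M.  When
    ``plot_dir`` is given, a superimposed-constellation overlay and the
    resampling scatter are saved per stage.
    """
    reports = []
    stages = list(space.stage_order)
    for si, stage in enumerate(stages):
        M = pheno_distance_matrix(space, stage, n_components=n_components)
        Q = qst_matrix(space, stage, qst_config)
        seeds = {"mantel": seed + 101 + si, "resampling": seed + 201 + si}
        fm_lab = mantel(F, M, n_perm=n_perm, seed=seeds["mantel"],
                        scheme="labels")
        fm_ent = mantel(F, M, n_perm=n_perm, seed=seeds["mantel"],
                        scheme="entries")
        fq_lab = mantel(F, Q, n_perm=n_perm, seed=seeds["mantel"],
                        scheme="labels")
        fq_ent = mantel(F, Q, n_perm=n_perm, seed=seeds["mantel"],
                        scheme="entries")
        res = resampling_correlation(space, stage, table, n_draws=n_draws,
                                     n_perm=n_perm,
                                     seed=seeds["resampling"],
                                     n_components=n_components)
        cF = pco(F.reorder(M.labels), k=2)
        cM = pco(M, k=2)
        _, _, d = procrustes_superimpose(cF, cM)
        reports.append(CongruenceReport(
            stage=stage, mantel_r=fm_lab.r, mantel_p=fm_lab.p,
            mantel_p_entries=fm_ent.p, mantel_r_fq=fq_lab.r,
            mantel_p_fq=fq_lab.p, mantel_p_fq_entries=fq_ent.p,
            resample_R2=res.R2, resample_p=res.p, procrustes_d=d,
            n_perm=n_perm, n_draws=n_draws, seeds=seeds))
        if plot_dir is not None:
            _plot_stage(plot_dir, stage, cF, cM, space, table, res,
                        n_components, seeds["resampling"], n_draws)
    return reports


def reports_to_json(reports, path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)


def _plot_stage(plot_dir, stage, cF, cM, space, table, res, n_components,
                seed, n_draws):
    from pathlib import Path
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    A, B, d = procrustes_superimpose(cF, cM)
    fig, ax = plt.subplots(figsize=(4, 4))
    for i, lab in enumerate(cF.labels):
        ax.plot([A[i, 0], B[i, 0]], [A[i, 1], B[i, 1]], "-", color="0.7")
        ax.plot(A[i, 0], A[i, 1], "o", color="tab:blue")
        ax.plot(B[i, 0], B[i, 1], "s", color="black")
        ax.annotate(lab, (A[i, 0], A[i, 1]), fontsize=7)
    ax.set_title(f"{stage}: F (blue) vs M (black), d={d:.3f}")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(plot_dir / f"overlay_{stage}.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(res.geno_distances, res.pheno_distances, ".", ms=3, alpha=0.4)
    ax.set_xlabel("genotypic distance (median-normalized)")
    ax.set_ylabel("phenotypic distance (median-normalized)")
    ax.set_title(f"{stage}: R2={res.R2:.2f}, p={res.p:.3f}")
    fig.tight_layout()
    fig.savefig(plot_dir / f"scatter_{stage}.png", dpi=120)
    plt.close(fig)
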