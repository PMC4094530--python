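"""Synthetic diaphysis surfaces and genotypes with known divergence.

The generator emulates the study design this package analyses: four *Pan*
taxa sampled at four dental stages (m2, M1, M2, M3), phenotyped as
closed-tube femoral diaphysis meshes and genotyped at biallelic SNP-like
loci drawn under a pure-drift (Balding-Nichols) model.

Phenotype model.  The subperiosteal surface is a tube in cylindrical
coordinates::

    r(theta, z) = r0(z) + ridge(theta, z) + sum_d e_d * phi_d(theta, z)
                  + selection(theta, z) + noise(theta, z)

* ``ridge`` is a Gaussian bump in theta centered on the posterior direction
  (180 deg; the linea-aspera analogue).  Its amplitude grows with the
  effective developmental age ``stage_index * heterochrony_rate(taxon)``,
  so per-taxon rate multipliers produce heterochronic length differences
  between ontogenetic trajectories.
* ``phi_d`` are fixed low-order Fourier deformation modes; the per-taxon
  coefficient vectors ``e`` carry the between-taxon shape signal.  In the
  drift-congruent presets they are *block means of the realized standardized
  allele-frequency displacements* of the genotype draw, which makes
  phenotypic divergence literally proportional to genotypic drift.
* ``selection`` is an optional per-taxon random mode displacement growing
  linearly with stage index: a diversifying, non-drift signal that
  decouples adult phenotype from neutral genotype (heterochronic preset).
* ``noise`` is smooth correlated within-taxon noise built from low-order
  modes (white vertex jitter would dominate the curvature signal).

Genotype model.  Per locus an ancestral frequency p0 ~ U(0.05, 0.95); each
taxon's frequency is Beta-distributed with mean p0 and variance
F_k p0 (1-p0) (Balding-Nichols); individuals are Binomial(2, p_k).  The
per-taxon drift levels F_k are derived from the prescribed pairwise
``fst_matrix`` via a star-model least-squares decomposition; under this
generator the frequency-level Hudson pairwise F_ST equals (F_i + F_j)/2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .gendist import GenotypeTable
from .mesh import DiaphysisMesh

DEFAULT_TAXA = ("troglodytes", "schweinfurthii", "verus", "paniscus")
DEFAULT_STAGES = ("m2", "M1", "M2", "M3")
#: per-taxon drift levels behind the default fst_matrix
DEFAULT_FK = (0.08, 0.12, 0.30, 0.60)

RIDGE_THETA_DEG = 180.0     # posterior
RIDGE_SIGMA_DEG = 14.0
RIDGE_Z_CENTER = 0.55
RIDGE_Z_SIGMA = 0.25


def _default_fst_matrix(fk=DEFAULT_FK) -> np.ndarray:
    fk = np.asarray(fk, float)
    M = 0.5 * (fk[:, None] + fk[None, :])
    np.fill_diagonal(M, 0.0)
    return M


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic study.

    ``pheno_effect`` maps taxon -> deformation-mode coefficient vector (mm);
    ``None`` means "derive from the realized genotypic drift" at simulation
    time (see :func:`simulate_scenario`).
    """

    taxa: tuple = DEFAULT_TAXA
    stages: tuple = DEFAULT_STAGES
    n_pheno_per_cell: int = 10
    n_geno_per_taxon: int = 20
    n_loci: int = 1000
    fst_matrix: np.ndarray = field(default_factory=_default_fst_matrix)
    pheno_effect: dict | None = None
    heterochrony_rates: dict = field(default_factory=dict)
    noise_sd: float = 0.04              # mm, smooth surface noise
    seed: int = 0
    # shape-model scales
    drift_effect_scale: float = 0.1     # mm per unit standardized drift
    stage_effect_scale: float = 0.0     # mm per stage index (selection-like)
    shared_growth_scale: float = 0.0    # mm per stage index x rate (common
                                        # developmental direction, traversed
                                        # at taxon-specific heterochrony rate)
    ridge_scale: float = 0.6            # mm per unit effective age
    n_modes: int = 24
    # geometry
    n_theta: int = 96
    n_z: int = 80
    base_radius: float = 9.0            # mm at stage m2
    stage_radius_step: float = 1.5
    base_length: float = 110.0          # mm at stage m2
    stage_length_step: float = 35.0
    flare: float = 0.0                  # end-flare of the radial profile

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.stages = tuple(self.stages)
        self.fst_matrix = np.asarray(self.fst_matrix, float)
        if not self.heterochrony_rates:
            self.heterochrony_rates = {t: 1.0 for t in self.taxa}
        self.validate()

    def validate(self):
        k = len(self.taxa)
        F = self.fst_matrix
        if F.shape != (k, k):
            raise ValueError("fst_matrix shape does not match taxa")
        if not np.allclose(F, F.T):
            raise ValueError("fst_matrix must be symmetric")
        if not np.allclose(np.diag(F), 0):
            raise ValueError("fst_matrix diagonal must be zero")
        if np.any(F < 0) or np.any(F >= 1):
            raise ValueError("fst_matrix entries must lie in [0, 1)")
        for name in ("n_pheno_per_cell", "n_geno_per_taxon", "n_loci",
                     "n_modes", "n_theta", "n_z"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for t, r in self.heterochrony_rates.items():
            if r <= 0:
                raise ValueError(f"heterochrony rate for {t!r} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def stage_index(self, stage: str) -> int:
        return self.stages.index(stage)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


# ----------------------------------------------------------------------
# presets

def preset(name: str, **overrides) -> ScenarioConfig:
    """Named study scenarios.

    ``neutral_congruent``: equal heterochrony rates, no selection term;
    phenotypic divergence is pure (realized) drift at every stage, so the
    genotype-phenotype congruence is stage-constant.

    ``heterochronic_divergence``: taxon-specific heterochrony rates plus a
    selection-like per-stage mode displacement.  At the infant (m2) stage
    divergence is still drift-dominated; toward adulthood (M3) the non-drift
    signal dominates -- the drift-early / selection-late signature.
    """
    if name == "neutral_congruent":
        cfg = ScenarioConfig(ridge_scale=0.2, stage_effect_scale=0.0)
    elif name == "heterochronic_divergence":
        rates = dict(zip(DEFAULT_TAXA, (1.0, 0.7, 1.35, 1.7)))
        cfg = ScenarioConfig(ridge_scale=0.8, stage_effect_scale=0.4,
                             heterochrony_rates=rates)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return cfg.replace(**overrides) if overrides else cfg


# ----------------------------------------------------------------------
# star-model decomposition

def star_model_fk(fst_matrix: np.ndarray):
    """Per-taxon drift levels F_k from pairwise targets, star model.

    Solves t_ij ~= (F_i + F_j)/2 by least squares (exact under the
    Balding-Nichols generator).  Returns ``(fk, residual)`` where residual
    is the max absolute misfit; raises if any fitted F_k is negative.
    """
    F = np.asarray(fst_matrix, float)
    k = F.shape[0]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    A = np.zeros((len(pairs), k))
    b = np.empty(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, i] = A[r, j] = 0.5
        b[r] = F[i, j]
    fk, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(fk < -1e-9):
        raise ValueError(
            "fst_matrix is not representable by non-negative per-taxon "
            f"F_k under the star model (fitted F_k = {fk})")
    fk = np.clip(fk, 0.0, None)
    if np.any(fk >= 1):
        raise ValueError("star-model F_k >= 1; lower the fst_matrix")
    residual = float(np.max(np.abs(A @ fk - b))) if pairs else 0.0
    return fk, residual


# ----------------------------------------------------------------------
# deformation basis

def _mode_basis(n_modes: int, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Fixed low-order smooth modes phi_d(theta, z), shape (D, nz, ntheta).

    Angular frequencies 2..5 crossed with axial profiles cos(k pi z),
    k = 0..2, and phases {0, pi/2}; all modes are bounded by 1.  Frequency-1 modes are
    excluded: they are translation-like and nearly invisible to the
    curvature descriptor.
    """
    combos = []
    for m in (2, 3, 4, 5):
        for kz in (0, 1, 2):
            for phase in (0.0, np.pi / 2):
                combos.append((m, kz, phase))
    combos = combos[:n_modes]
    if len(combos) < n_modes:
        raise ValueError("n_modes too large for the fixed basis (max 24)")
    T, Z = np.meshgrid(theta, z)       # (nz, ntheta)
    basis = np.empty((len(combos), *T.shape))
    for d, (m, kz, phase) in enumerate(combos):
        axial = np.cos(kz * np.pi * Z)
        basis[d] = np.cos(m * T - phase) * axial
    return basis


def ridge_amplitude(scenario: ScenarioConfig, taxon: str, stage: str) -> float:
    """Posterior-ridge amplitude (mm): ridge_scale x stage_index x rate."""
    age = scenario.stage_index(stage) * scenario.heterochrony_rates[taxon]
    return scenario.ridge_scale * age


def _selection_vector(scenario: ScenarioConfig, taxon: str) -> np.ndarray:
    """Per-taxon selection-like mode displacement (per unit stage index)."""
    if scenario.stage_effect_scale == 0:
        return np.zeros(scenario.n_modes)
    ti = scenario.taxa.index(taxon)
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(917, ti)))
    v = rng.normal(size=scenario.n_modes)
    return v * (scenario.stage_effect_scale / np.linalg.norm(v))


def _shared_growth_vector(scenario: ScenarioConfig) -> np.ndarray:
    """Common ontogenetic mode direction (unit norm), shared by all taxa.

    Taxa traverse it at ``heterochrony_rate x shared_growth_scale`` mm per
    stage index: the morphospace picture of heterochrony -- statistically
    shared trajectory directions with taxon-specific lengths.
    """
    if scenario.shared_growth_scale == 0:
        return np.zeros(scenario.n_modes)
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(919,)))
    v = np.zeros(scenario.n_modes)
    # confine growth to the lowest angular frequency (gentlest curvature
    # response), where the map reacts most nearly linearly to amplitude
    width = min(6, scenario.n_modes)
    v[:width] = rng.normal(size=width)
    return v / np.linalg.norm(v)


# ----------------------------------------------------------------------
# mesh generation

def make_diaphysis(scenario: ScenarioConfig, taxon: str, stage: str,
                   individual_seed: int) -> DiaphysisMesh:
    """One closed-tube diaphysis mesh for a taxon x stage cell member.

    Deterministic given (scenario.seed, taxon, stage, individual_seed).
    Requires ``scenario.pheno_effect`` to be resolved (a dict of mode
    coefficient vectors); use :func:`simulate_scenario` or
    :func:`resolve_drift_effects` for drift-derived effects.
    """
    if taxon not in scenario.taxa:
        raise ValueError(f"unknown taxon {taxon!r}")
    if stage not in scenario.stages:
        raise ValueError(f"unknown stage {stage!r}")
    if scenario.pheno_effect is None:
        raise ValueError(
            "scenario.pheno_effect unresolved; call simulate_scenario() or "
            "resolve_drift_effects() first, or supply explicit effects")
    si = scenario.stage_index(stage)
    L = scenario.base_length + scenario.stage_length_step * si
    r0 = scenario.base_radius + scenario.stage_radius_step * si

    theta = np.arange(scenario.n_theta) * (2 * np.pi / scenario.n_theta)
    zt = np.linspace(0.0, 1.0, scenario.n_z)
    T, Z = np.meshgrid(theta, zt)

    r = r0 * (1.0 + scenario.flare * (2 * Z - 1) ** 2)

    amp = ridge_amplitude(scenario, taxon, stage)
    if amp != 0:
        dth = np.angle(np.exp(1j * (T - np.deg2rad(RIDGE_THETA_DEG))))
        sig = np.deg2rad(RIDGE_SIGMA_DEG)
        r += amp * np.exp(-0.5 * (dth / sig) ** 2) \
            * np.exp(-0.5 * ((Z - RIDGE_Z_CENTER) / RIDGE_Z_SIGMA) ** 2)

    basis = _mode_basis(scenario.n_modes, theta, zt)
    e = np.asarray(scenario.pheno_effect[taxon], float)
    e = e + si * _selection_vector(scenario, taxon)
    # shared growth is parameterized around the mid-ontogenetic shape so
    # the first-to-last chord follows the common tangent direction
    si_c = si - 0.5 * (len(scenario.stages) - 1)
    e = e + (si_c * scenario.heterochrony_rates[taxon]
             * scenario.shared_growth_scale * _shared_growth_vector(scenario))
    r += np.tensordot(e, basis, axes=1)

    if scenario.noise_sd > 0:
        ti = scenario.taxa.index(taxon)
        rng = np.random.default_rng(np.random.SeedSequence(
            scenario.seed, spawn_key=(ti, si, int(individual_seed))))
        r += _smooth_noise(rng, scenario.noise_sd, T, Z)

    r = np.clip(r, 0.2 * r0, None)      # keep the tube star-shaped

    verts = np.column_stack([
        (r * np.cos(T)).ravel(), (r * np.sin(T)).ravel(), (Z * L).ravel()])
    faces = _tube_faces(scenario.n_z, scenario.n_theta, len(verts))
    verts = np.vstack([verts, [[0, 0, 0.0]], [[0, 0, L]]])
    return DiaphysisMesh(
        vertices=verts, faces=faces,
        proximal_end=np.array([0.0, 0.0, L]),
        distal_end=np.array([0.0, 0.0, 0.0]),
        taxon=taxon, stage=stage,
        specimen_id=f"{taxon}_{stage}_{individual_seed}",
        anterior=np.array([1.0, 0.0, 0.0]),
    )


def _smooth_noise(rng, sd, T, Z):
    """Smooth correlated surface noise with spatial sd ~= ``sd`` (mm).

    Low-order Fourier modes on (theta, z) with random amplitudes scaled so
    the spatial variance of the summed field averages sd^2.
    """
    out = np.zeros_like(T)
    # same angular band as the deformation modes so the curvature
    # transform (gain ~ m^2 - 1) weighs noise and signal alike
    combos = [(m, k) for m in range(2, 6) for k in range(0, 3)]
    amps = rng.normal(0.0, 1.0, size=len(combos))
    phases = rng.uniform(0, 2 * np.pi, size=len(combos))
    scale = sd / np.sqrt(len(combos))
    for (m, k), a, ph in zip(combos, amps, phases):
        mean_sq = 0.5 * (0.5 if k > 0 else 1.0)   # spatial mean of phi^2
        axial = np.cos(k * np.pi * Z) if k > 0 else np.ones_like(Z)
        out += (a * scale / np.sqrt(mean_sq)) * np.cos(m * T - ph) * axial
    return out


def _tube_faces(n_z, n_theta, n_grid):
    faces = []
    for j in range(n_z - 1):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = (j + 1) * n_theta + i
            d = (j + 1) * n_theta + (i + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    lo, hi = n_grid, n_grid + 1
    for i in range(n_theta):
        b = (i + 1) % n_theta
        faces.append((lo, b, i))                          # distal cap
        top = (n_z - 1) * n_theta
        faces.append((hi, top + i, top + b))              # proximal cap
    return np.asarray(faces, dtype=np.int64)


def make_phenotype_sample(scenario: ScenarioConfig) -> list:
    """All taxon x stage cells, ``n_pheno_per_cell`` meshes each."""
    meshes = []
    for taxon in scenario.taxa:
        for stage in scenario.stages:
            for i in range(scenario.n_pheno_per_cell):
                meshes.append(make_diaphysis(scenario, taxon, stage, i))
    return meshes


# ----------------------------------------------------------------------
# genotypes

def make_genotypes(scenario: ScenarioConfig, return_frequencies: bool = False):
    """Balding-Nichols genotypes for all taxa.

    Per locus: p0 ~ U(0.05, 0.95); p_k ~ Beta with mean p0 and variance
    F_k p0 (1-p0) (p_k = p0 exactly when F_k = 0); genotypes Binomial(2, p_k).
    """
    fk, _ = star_model_fk(scenario.fst_matrix)
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(101,)))
    L = scenario.n_loci
    p0 = rng.uniform(0.05, 0.95, size=L)
    K = len(scenario.taxa)
    pk = np.empty((K, L))
    for k in range(K):
        F = fk[k]
        if F == 0:
            pk[k] = p0
        else:
            a = p0 * (1 - F) / F
            b = (1 - p0) * (1 - F) / F
            pk[k] = rng.beta(a, b)
    n = scenario.n_geno_per_taxon
    geno = np.empty((K * n, L))
    taxon = np.empty(K * n, dtype=object)
    for k, t in enumerate(scenario.taxa):
        geno[k * n:(k + 1) * n] = rng.binomial(2, pk[k], size=(n, L))
        taxon[k * n:(k + 1) * n] = t
    ids = tuple(f"{t}_{i}" for k, t in enumerate(scenario.taxa)
                for i in range(n))
    table = GenotypeTable(geno, taxon, individual_ids=ids)
    if return_frequencies:
        return table, p0, pk
    return table


def resolve_drift_effects(scenario: ScenarioConfig, p0: np.ndarray,
                          pk: np.ndarray) -> dict:
    """Mode coefficients proportional to realized drift displacements.

    Loci are split into ``n_modes`` contiguous blocks; each coefficient is
    the block mean of the standardized displacement
    (p_k - p0)/sqrt(p0(1-p0)) scaled by sqrt(block size), which has variance
    F_k under the Balding-Nichols model, times ``drift_effect_scale``.
    """
    D = scenario.n_modes
    L = len(p0)
    std = (pk - p0[None, :]) / np.sqrt(p0 * (1 - p0))[None, :]
    bounds = np.linspace(0, L, D + 1).astype(int)
    eff = {}
    for k, t in enumerate(scenario.taxa):
        e = np.empty(D)
        for d in range(D):
            lo, hi = bounds[d], bounds[d + 1]
            e[d] = std[k, lo:hi].sum() / np.sqrt(hi - lo)
        eff[t] = scenario.drift_effect_scale * e
    return eff


@dataclass
class SyntheticDataset:
    """Bundle of a resolved scenario with its meshes and genotypes."""

    scenario: ScenarioConfig
    meshes: list
    genotypes: GenotypeTable
    ancestral_freqs: np.ndarray
    taxon_freqs: np.ndarray
    star_fk: np.ndarray
    star_residual: float


def simulate_scenario(scenario: ScenarioConfig) -> SyntheticDataset:
    """Draw genotypes, resolve drift-derived effects, build all meshes."""
    table, p0, pk = make_genotypes(scenario, return_frequencies=True)
    if scenario.pheno_effect is None:
        eff = resolve_drift_effects(scenario, p0, pk)
        scenario = scenario.replace(pheno_effect=eff)
    fk, res = star_model_fk(scenario.fst_matrix)
    meshes = make_phenotype_sample(scenario)
    return SyntheticDataset(scenario, meshes, table, p0, pk, fk, res)
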