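import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import panmorph as pm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


TAXA = ("troglodytes", "schweinfurthii", "verus", "paniscus")


def tiny_preset(name: str, seed: int = 0, **overrides) -> "pm.ScenarioConfig":
    """Preset at reduced mesh/sample resolution for fast simulation tests."""
    kw = dict(n_pheno_per_cell=4, n_geno_per_taxon=12, n_loci=400,
              n_theta=48, n_z=40)
    kw.update(overrides)
    return pm.preset(name, **kw).replace(seed=seed)


def zero_effects(scenario) -> dict:
    return {t: np.zeros(scenario.n_modes) for t in scenario.taxa}


def tube_mesh(radius_fn, length=100.0, n_theta=256, n_z=50,
              taxon="x", stage="m2", specimen_id="tube"):
    """Analytic tube mesh: radius_fn(theta_array) -> radii (polar form)."""
    from panmorph.mesh import DiaphysisMesh
    from panmorph.synthetic import _tube_faces
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    r = np.broadcast_to(np.asarray(radius_fn(th), float), (n_theta,))
    z = np.linspace(0.0, length, n_z)
    V = np.vstack([
        np.column_stack([r * np.cos(th), r * np.sin(th),
                         np.full(n_theta, zz)]) for zz in z])
    F = _tube_faces(n_z, n_theta, len(V))
    V = np.vstack([V, [0, 0, 0.0], [0, 0, length]])
    return DiaphysisMesh(V, F, [0, 0, length], [0, 0, 0.0],
                         taxon, stage, specimen_id)


def circle_section(radius=12.0, n=180):
    ang = np.arange(n) * (360.0 / n)
    pts = np.column_stack([radius * np.cos(np.radians(ang)),
                           radius * np.sin(np.radians(ang))])
    return pm.CrossSection(level=0.5, outline=pts, angles=ang)


@pytest.fixture(scope="session")
def neutral_dataset():
    """One tiny neutral-congruent simulation shared across tests."""
    return pm.simulate_scenario(tiny_preset("neutral_congruent", seed=7))


@pytest.fixture(scope="session")
def neutral_space(neutral_dataset):
    maps = pm.build_normalized_maps(neutral_dataset.meshes, 30, 48, 5)
    return pm.fit_shape_pca(maps)
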