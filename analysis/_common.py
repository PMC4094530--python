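"""Shared setup for the numbered analysis scripts.

All scripts analyse the same seeded heterochronic_divergence cohort
(4 taxa x 4 stages x 10 femora, 1000 SNP loci) and are individually
re-runnable: the simulation is deterministic, so each script recomputes
what it needs instead of depending on a previous script's on-disk state.
"""

from pathlib import Path

import panmorph as pm

SEED = 42
MAP_GRID = dict(n_levels=50, n_angles=90, window=5)
RESULTS = Path(__file__).resolve().parent.parent / "results"
FIGURES = RESULTS / "figures"

_cache = {}


def dataset() -> "pm.SyntheticDataset":
    if "data" not in _cache:
        scen = pm.preset("heterochronic_divergence").replace(seed=SEED)
        _cache["data"] = pm.simulate_scenario(scen)
    return _cache["data"]


def shape_space() -> "pm.ShapeSpace":
    if "space" not in _cache:
        maps = pm.build_normalized_maps(dataset().meshes, **MAP_GRID)
        _cache["maps"] = maps
        _cache["space"] = pm.fit_shape_pca(maps)
    return _cache["space"]


def maps() -> list:
    shape_space()
    return _cache["maps"]


def outdirs():
    RESULTS.mkdir(exist_ok=True)
    FIGURES.mkdir(exist_ok=True)
    return RESULTS, FIGURES
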