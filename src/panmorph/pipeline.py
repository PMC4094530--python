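"""End-to-end orchestration of the morphometric-genetic congruence run.

``run(config)`` executes: synthetic data (or user meshes/genotypes) ->
morphometric maps -> shape PCA -> trajectories and mean-shape tests ->
genotypic distance matrices -> stage-wise M/Q matrices and congruence
tests -> squared-change-parsimony LCA reconstruction, writing every table
as CSV/JSON, figure-style PNGs, and a manifest.  All randomness derives
from a single master seed via a documented counter scheme, so two runs
with the same config are numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .congruence import reports_to_json, stagewise_report
from .gendist import GenotypeTable, build_F_matrices
from .mesh import load_sample
from .morphmap import build_normalized_maps, render_map
from .phylo import PhyloTree, lca_trajectory
from .qst import QstConfig, h2_sensitivity
from .shapespace import (build_trajectory, fit_shape_pca,
                         mean_shape_permutation_test, stage_taxon_means,
                         trajectory_comparison_test)
from .synthetic import ScenarioConfig, preset, simulate_scenario

log = logging.getLogger("panmorph")


class UserInputError(ValueError):
    """A problem in the user's configuration or data (CLI exit code 1)."""


@dataclass
class RunConfig:
    mode: str = "synthetic"                  # or "user-data"
    scenario_preset: str = "heterochronic_divergence"
    scenario_overrides: dict = field(default_factory=dict)
    mesh_manifest: str | None = None         # user-data mode
    genotype_csv: str | None = None
    # morphometric map grid
    n_levels: int = 50
    n_angles: int = 90
    window: int = 5
    # analysis
    n_components: int | None = None          # None -> 90% variance rule
    qst: QstConfig = field(default_factory=QstConfig)
    n_perm: int = 999
    n_draws: int = 1000
    tree_newick: str | None = None
    h2_grid: tuple = (0.3, 0.55, 0.9)
    out_dir: str = "panmorph_run"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qst" in raw and isinstance(raw["qst"], dict):
            raw["qst"] = QstConfig(**raw["qst"])
        try:
            return cls(**raw)
        except TypeError as e:
            raise UserInputError(f"bad config: {e}") from e

    def stage_seed(self, counter: int) -> int:
        """Child seed: (master * 1000 + counter) mod 2^31."""
        return (self.master_seed * 1000 + counter) % (2 ** 31)


def _build_dataset(config: RunConfig):
    if config.mode == "synthetic":
        scenario = preset(config.scenario_preset,
                          **config.scenario_overrides)
        scenario = scenario.replace(seed=config.stage_seed(1))
        return simulate_scenario(scenario)
    if config.mode != "user-data":
        raise UserInputError(f"unknown mode {config.mode!r}")
    if not config.mesh_manifest or not config.genotype_csv:
        raise UserInputError("user-data mode needs mesh_manifest and "
                             "genotype_csv paths")
    for p in (config.mesh_manifest, config.genotype_csv):
        if not Path(p).exists():
            raise UserInputError(f"input path does not exist: {p}")
    meshes = load_sample(config.mesh_manifest)
    table = GenotypeTable.from_csv(config.genotype_csv)

    @dataclass
    class _UserData:
        meshes: list
        genotypes: GenotypeTable
        scenario = None
        star_fk = None

    return _UserData(meshes, table)


def validate_inputs(config: RunConfig) -> dict:
    """Sanity report on meshes, labels and genotypes (fatal vs warning)."""
    report = {"fatal": [], "warnings": []}
    try:
        data = _build_dataset(config)
    except UserInputError as e:
        report["fatal"].append(str(e))
        return report
    taxa = sorted({m.taxon for m in data.meshes})
    stages = list(dict.fromkeys(m.stage for m in data.meshes))
    for t in taxa:
        for s in stages:
            n = sum(1 for m in data.meshes
                    if m.taxon == t and m.stage == s)
            if n == 0:
                report["fatal"].append(f"empty taxon x stage cell ({t}, {s})")
            elif n < 3:
                report["warnings"].append(
                    f"cell ({t}, {s}) has only {n} specimens")
    for m in data.meshes:
        tm = m.to_trimesh()
        if not tm.is_watertight:
            report["fatal"].append(
                f"mesh {m.specimen_id} is not watertight (hole?)")
    gt = set(data.genotypes.taxa)
    missing = set(taxa) - gt
    if missing:
        report["fatal"].append(f"taxa missing from genotypes: {missing}")
    return report


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def save_csv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, **kw)
        files.append(name)
        return path

    stage_name = "simulate"
    try:
        log.info("stage: simulate/load")
        data = _build_dataset(config)

        stage_name = "morphmap"
        log.info("stage: morphometric maps (%d meshes)", len(data.meshes))
        maps = build_normalized_maps(data.meshes, config.n_levels,
                                     config.n_angles, config.window)

        stage_name = "shape_space"
        space = fit_shape_pca(maps)
        k = config.n_components or space.n_components_for(0.90)
        save_csv(pd.DataFrame({
            "component": np.arange(1, space.n_components + 1),
            "explained_variance_ratio": space.explained_variance_ratio,
        }), "explained_variance.csv", index=False)
        scores = pd.DataFrame(space.scores,
                              columns=[f"PC{i+1}"
                                       for i in range(space.n_components)])
        scores.insert(0, "stage", space.stages)
        scores.insert(0, "taxon", space.taxa)
        scores.insert(0, "specimen_id", space.specimen_ids)
        save_csv(scores, "scores.csv", index=False)

        means = stage_taxon_means(space, n_components=k)
        save_csv(means, "stage_taxon_means.csv")

        taxa = list(dict.fromkeys(space.taxa))
        trajs = {t: build_trajectory(means, t) for t in taxa}
        save_csv(pd.DataFrame(
            [{"taxon": t, "length": tr.length,
              **{f"dir_PC{i+1}": d for i, d in enumerate(tr.direction)}}
             for t, tr in trajs.items()]), "trajectories.csv", index=False)

        traj_tests = {}
        shape_tests = []
        import itertools as _it
        for i, (a, b) in enumerate(_it.combinations(taxa, 2)):
            traj_tests[f"{a}|{b}"] = trajectory_comparison_test(
                space, a, b, n_perm=min(config.n_perm, 499),
                seed=config.stage_seed(300 + i), n_components=k)
            for s in space.stage_order:
                res = mean_shape_permutation_test(
                    space, s, a, b, n_perm=config.n_perm,
                    seed=config.stage_seed(400 + i), n_components=k)
                shape_tests.append({"stage": s, "taxon_a": a, "taxon_b": b,
                                    **res})
        (out / "trajectory_tests.json").write_text(
            json.dumps(traj_tests, indent=1))
        files.append("trajectory_tests.json")
        save_csv(pd.DataFrame(shape_tests), "mean_shape_tests.csv",
                 index=False)

        stage_name = "genetic_distances"
        log.info("stage: genotypic distance matrices")
        F = build_F_matrices(data.genotypes)
        for kind, mat in F.items():
            mat.to_csv(out / f"{kind}.csv")
            files.extend([f"{kind}.csv", f"{kind}.json"])

        stage_name = "congruence"
        log.info("stage: stage-wise congruence")
        reports = stagewise_report(
            F["F_ppc"], space, data.genotypes, n_perm=config.n_perm,
            n_draws=config.n_draws, seed=config.stage_seed(500),
            qst_config=config.qst, n_components=k,
            plot_dir=out / "figures")
        reports_to_json(reports, out / "congruence_table.json")
        files.append("congruence_table.json")
        save_csv(pd.DataFrame([r.to_dict() for r in reports]),
                 "congruence_table.csv", index=False)

        stage_name = "quantitative_genetics"
        from .qst import pheno_distance_matrix, qst_matrix
        for s in space.stage_order:
            pheno_distance_matrix(space, s, n_components=k).to_csv(
                out / f"M_{s}.csv")
            qst_matrix(space, s, config.qst).to_csv(out / f"Q_{s}.csv")
            files.extend([f"M_{s}.csv", f"M_{s}.json",
                          f"Q_{s}.csv", f"Q_{s}.json"])
        _, h2_table = h2_sensitivity(space, space.stage_order[-1],
                                     config.h2_grid,
                                     n_components=config.qst.n_components)
        save_csv(h2_table, "h2_sensitivity.csv", index=False)

        stage_name = "lca"
        log.info("stage: LCA reconstruction")
        tree = (PhyloTree.from_newick(Path(config.tree_newick).read_text())
                if config.tree_newick else PhyloTree.default_pan_tree(taxa))
        lca_traj, lca_maps = lca_trajectory(tree, means, space=space)
        save_csv(pd.DataFrame(
            lca_traj.stage_means,
            index=pd.Index(lca_traj.stages, name="stage"),
            columns=[f"PC{i+1}"
                     for i in range(lca_traj.stage_means.shape[1])]),
            "lca_trajectory.csv")
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for m in lca_maps:
            render_map(m, figdir / f"lca_map_{m.stage}.png")

        _figures(out, space, trajs, lca_traj, maps, taxa)
    except Exception as e:
        log.error("pipeline failed at stage %r: %s", stage_name, e)
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {e}"
                           ) from e

    cfg_dict = asdict(config)
    cfg_blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "panmorph_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "seed_scheme": "stage_seed(c) = (master*1000 + c) mod 2^31",
        "n_components_used": int(k),
        "files": sorted(set(files)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out


def _figures(out: Path, space, trajs, lca_traj, maps, taxa):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    # morphospace with trajectories (PC1-PC2)
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = dict(zip(taxa, "osv^D*"))
    for t in taxa:
        mask = space.taxa == t
        ax.scatter(space.scores[mask, 0], space.scores[mask, 1], s=12,
                   alpha=0.4, marker=markers.get(t, "o"), label=t)
        tr = trajs[t]
        ax.plot(tr.stage_means[:, 0], tr.stage_means[:, 1], "-o", ms=4)
    ax.plot(lca_traj.stage_means[:, 0], lca_traj.stage_means[:, 1], "--D",
            color="gray", ms=5, label="LCA")
    evr = space.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100*evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100*evr[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "morphospace_trajectories.png", dpi=120)
    plt.close(fig)

    # mean-map grid, infant vs adult per taxon
    stages = list(space.stage_order)
    show = [stages[0], stages[-1]]
    fig, axes = plt.subplots(len(show), len(taxa),
                             figsize=(2.2 * len(taxa), 2.2 * len(show)))
    by_cell = {}
    for m in maps:
        by_cell.setdefault((m.taxon, m.stage), []).append(m.values)
    vals = [np.mean(by_cell[(t, s)], axis=0) for t in taxa for s in show]
    vmin = min(v.min() for v in vals)
    vmax = max(np.percentile(v, 99) for v in vals)
    for r, s in enumerate(show):
        for c, t in enumerate(taxa):
            ax = axes[r, c]
            ax.imshow(np.mean(by_cell[(t, s)], axis=0), origin="lower",
                      aspect="auto", vmin=vmin, vmax=vmax, cmap="viridis",
                      extent=[0, 360, 0, 1])
            if r == 0:
                ax.set_title(t, fontsize=8)
            if c == 0:
                ax.set_ylabel(s)
            ax.set_xticks([0, 90, 180, 270, 360])
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(figdir / "mean_map_grid.png", dpi=120)
    plt.close(fig)
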