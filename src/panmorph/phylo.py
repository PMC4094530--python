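"""Rooted taxon tree and squared-change parsimony reconstruction.

Ancestral (internal-node) shape states are reconstructed by minimizing the
branch-length-weighted sum of squared changes along the tree -- the
maximum-likelihood point estimate under Brownian motion.  Setting the
gradient to zero gives a sparse linear system in the internal-node values,
solved exactly per coordinate.  Applied stage by stage, the root values
trace the inferred ontogenetic trajectory of the last common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .shapespace import ShapeSpace, Trajectory


@dataclass
class PhyloTree:
    """Rooted tree as parent pointers with branch lengths.

    ``parent[i]`` is the parent index of node i (-1 for the root);
    ``length[i]`` is the branch length from i to its parent (ignored for
    the root).  Tips carry taxon names.
    """

    names: list                        # per-node labels (tips + internal)
    parent: np.ndarray                 # (N,) int
    length: np.ndarray                 # (N,) float
    tip_indices: dict = field(default_factory=dict)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        if not self.tip_indices:
            children = set(self.parent[self.parent >= 0])
            self.tip_indices = {self.names[i]: i
                                for i in range(len(self.names))
                                if i not in children}

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    @property
    def tips(self) -> tuple:
        return tuple(self.tip_indices)

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, default_length: float = 1.0
                    ) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        names, parent, length = [], [], []
        for i, nd in enumerate(nodes):
            if nd.taxon is not None:
                names.append(nd.taxon.label)
            else:
                names.append(nd.label or f"node{i}")
            parent.append(index[id(nd.parent_node)]
                          if nd.parent_node is not None else -1)
            bl = nd.edge.length
            length.append(default_length if bl is None else float(bl))
        return cls(names, np.array(parent), np.array(length))

    @classmethod
    def default_pan_tree(cls, taxa=("troglodytes", "schweinfurthii",
                                    "verus", "paniscus")) -> "PhyloTree":
        """(((troglodytes, schweinfurthii), verus), paniscus), unit branches.

        *P. paniscus* is the outgroup to the three *P. troglodytes*
        subspecies; branch lengths default to 1 (relative time units,
        overridable via Newick input).
        """
        t, s, v, p = taxa
        return cls.from_newick(
            f"((({t}:1,{s}:1)ts:1,{v}:1)tsv:1,{p}:1)root;")


def squared_change_parsimony(tree: PhyloTree, tip_values: dict,
                             weighted: bool = True) -> dict:
    """Internal-node values minimizing sum (delta value)^2 / branch length.

    ``tip_values`` maps tip name -> scalar or vector; the reconstruction is
    solved independently per coordinate via the graph-Laplacian linear
    system.  ``weighted=False`` uses unit branch lengths.  Returns a dict
    internal-node name -> value array, including the root.
    """
    N = tree.n_nodes
    tips = tree.tip_indices
    missing = set(tips) - set(tip_values)
    if missing:
        raise ValueError(f"missing tip values for {sorted(missing)}")
    X = np.stack([np.atleast_1d(np.asarray(tip_values[name], float))
                  for name in tips])
    L = np.zeros((N, N))
    for i in range(N):
        p = tree.parent[i]
        if p < 0:
            continue
        bl = tree.length[i] if weighted else 1.0
        if bl <= 0:
            raise ValueError(f"non-positive branch length at node "
                             f"{tree.names[i]!r}")
        w = 1.0 / bl
        L[i, i] += w
        L[p, p] += w
        L[i, p] -= w
        L[p, i] -= w
    tip_idx = np.array([tips[name] for name in tips])
    internal = np.setdiff1d(np.arange(N), tip_idx)
    A = L[np.ix_(internal, internal)]
    B = -L[np.ix_(internal, tip_idx)] @ X
    sol = np.linalg.solve(A, B)
    return {tree.names[i]: sol[j] for j, i in enumerate(internal)}


def scp_objective(tree: PhyloTree, tip_values: dict, internal_values: dict,
                  weighted: bool = True) -> float:
    """The weighted sum-of-squared-changes objective (for verification)."""
    vals = {}
    for name, i in tree.tip_indices.items():
        vals[i] = np.atleast_1d(np.asarray(tip_values[name], float))
    for i in range(tree.n_nodes):
        if i not in vals:
            vals[i] = np.atleast_1d(
                np.asarray(internal_values[tree.names[i]], float))
    total = 0.0
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        bl = tree.length[i] if weighted else 1.0
        total += float(np.sum((vals[i] - vals[p]) ** 2) / bl)
    return total


def lca_trajectory(tree: PhyloTree, means: pd.DataFrame,
                   space: ShapeSpace | None = None,
                   weighted: bool = True):
    """Squared-change-parsimony trajectory of the root (LCA).

    ``means`` is a stage_taxon_means table.  Per stage the tip means are
    reconstructed onto the tree; the root values across stages form the LCA
    trajectory.  If ``space`` is given the root score vectors are also
    mapped back through the PCA (grand_mean + scores . components) into
    reconstructed LCA morphometric maps.

    Returns ``(trajectory, root_maps)`` where ``root_maps`` is a list of
    normalized-map objects (or None without ``space``).
    """
    stages = list(means.index.get_level_values("stage").unique())
    root_name = tree.names[tree.root]
    root_vals = []
    for s in stages:
        tip_values = {t: means.loc[(t, s)].to_numpy(float)
                      for t in tree.tips}
        rec = squared_change_parsimony(tree, tip_values, weighted=weighted)
        root_vals.append(rec[root_name])
    traj = Trajectory(taxon="LCA", stages=tuple(stages),
                      stage_means=np.stack(root_vals))
    root_maps = None
    if space is not None:
        from .morphmap import MorphometricMap
        root_maps = []
        for s, v in zip(stages, root_vals):
            grid = space.inverse(v)
            root_maps.append(MorphometricMap(
                values=grid, normalized=True,
                diaphyseal_length=float("nan"),
                median_radius=float("nan"),
                taxon="LCA", stage=s, specimen_id=f"LCA_{s}",
                meta={"reconstruction": "squared-change parsimony"}))
    return traj, root_maps
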