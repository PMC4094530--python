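"""Stage-wise genotype-phenotype congruence and Q_ST.

The central comparison: per dental stage, Mantel and resampling
correlations between the neutral genotypic distances (D_PPC) and the
phenotypic (M) / quantitative-genetic (Q) distances, plus the Procrustes
overlay of the PCO taxon constellations and an h2 sensitivity check.
"""

import numpy as np
import pandas as pd

import panmorph as pm
from panmorph.qst import QstConfig
from _common import SEED, dataset, outdirs, shape_space


def main():
    results, figures = outdirs()
    data = dataset()
    space = shape_space()

    F = pm.patterson_pc_distance(data.genotypes)
    reports = pm.stagewise_report(
        F, space, data.genotypes, n_perm=999, n_draws=1000, seed=SEED,
        qst_config=QstConfig(), plot_dir=figures)
    table = pd.DataFrame([r.to_dict() for r in reports])
    table.to_csv(results / "congruence_table.csv", index=False)
    pm.congruence.reports_to_json(reports, results / "congruence_table.json")

    for stage in data.scenario.stages:
        pm.pheno_distance_matrix(space, stage).to_csv(
            results / f"M_{stage}.csv")
        pm.qst_matrix(space, stage, QstConfig()).to_csv(
            results / f"Q_{stage}.csv")

    _, h2_table = pm.h2_sensitivity(space, "M3", [0.3, 0.55, 0.9])
    h2_table.to_csv(results / "h2_sensitivity.csv", index=False)

    show = table[["stage", "mantel_r", "mantel_p_entries", "resample_R2",
                  "resample_p", "mantel_r_fq", "procrustes_d"]]
    print("stage-wise F-M / F-Q congruence:")
    print(show.round(3).to_string(index=False))

    q_m3 = pm.qst_matrix(space, "M3", QstConfig()).offdiag().mean()
    gen_f = data.scenario.fst_matrix[np.triu_indices(4, 1)].mean()
    print(f"\nmean Q_ST at M3 = {q_m3:.2f} vs generating F_ST = "
          f"{gen_f:.2f}: Q_ST >> F_ST at adulthood (diversifying "
          "selection signature)")
    print("congruence is highest at m2 and collapses toward M3 -- the "
          "drift-early / selection-late pattern")
    print(f"h2 sensitivity: Mantel r vs reference >= "
          f"{h2_table['mantel_r_vs_reference'].min():.3f} across the grid")


if __name__ == "__main__":
    main()
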