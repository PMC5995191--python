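"""Run a scaled-down version of the full benchmark: a small scenario grid,
two aligners (true-alignment baseline and the builtin progressive aligner),
win-matrix statistics, depth profiles and quality-accuracy correlations.

The full study grid (72 scenarios, 10 trees x 10 sequence sets) is
`default_grid()`; this example shrinks it to run in about a minute.
"""

import pandas as pd

from asrbench import (
    GridConfig, baseline_adapter, builtin_adapter, compare_aligners,
    depth_profile, indel_bias, quality_vs_accuracy, run_scenario, scenario_grid,
)

grid = scenario_grid(GridConfig(
    taxa=[16], sampling_fractions=[0.25, 0.99], heights=[0.8, 1.2],
    indel_rates=[0.05], n_tree_reps=2, n_seq_reps=2,
))
print(f"{len(grid)} scenarios")

adapters = [baseline_adapter(), builtin_adapter()]
table = pd.concat(
    [run_scenario(spec, adapters, master_seed=2026) for spec in grid],
    ignore_index=True,
)
print(f"{len(table)} node-level records")
print("\nmean accuracy by scenario and aligner:")
print(table.groupby(["scenario_id", "aligner"])["accuracy"].mean().unstack().round(3))

wins, pvals = compare_aligners(table, alpha=0.01)
print("\nwin matrix (row beat column in N scenarios, FDR-adjusted p < 0.01):")
print(wins)

print("\naccuracy by distance to root (baseline, 4 bins):")
prof = depth_profile(table, n_bins=4)
print(prof[prof["aligner"] == "baseline"][["depth_mid", "n", "mean_accuracy"]].round(3))

print("\nindel bias (length ratio > 1 means overlong reconstructions):")
print(indel_bias(table)[["aligner", "mean_insertion_error", "mean_deletion_error",
                         "mean_length_ratio"]].round(3))

print("\nMSA quality vs reconstruction accuracy (pooled across aligners):")
corr = quality_vs_accuracy(table)
print(corr[corr["aligner"] == "pooled"][["metric", "pearson_r", "r2",
                                         "spearman_rho"]].round(3))
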