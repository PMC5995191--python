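"""Scenario grid, adapters, builtin aligner, statistics of the benchmark."""

import itertools

import numpy as np
import pandas as pd
import pytest

from asrbench import (
    AdapterError,
    ConfigurationError,
    GridConfig,
    IndelParams,
    RateModel,
    ScenarioSpec,
    TreeSimParams,
    baseline_adapter,
    builtin_adapter,
    builtin_progressive_align,
    compare_aligners,
    default_grid,
    depth_profile,
    evolve,
    external_adapter,
    indel_bias,
    pairwise_align,
    quality_vs_accuracy,
    run_scenario,
    scenario_grid,
    simulate_tree,
)
from asrbench.benchmark_pipeline import check_degapped_identity

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


# -- grid ------------------------------------------------------------------


def test_default_grid_has_72_scenarios_and_36_tree_configurations():
    grid = default_grid()
    assert len(grid) == 72
    tree_configs = {(s.n_taxa, s.sampling_fraction, s.height) for s in grid}
    assert len(tree_configs) == 36


def test_single_values_give_single_scenario():
    grid = scenario_grid(GridConfig(taxa=[16], sampling_fractions=[0.5],
                                    heights=[1.0], indel_rates=[0.05]))
    assert len(grid) == 1


def test_empty_axis_rejected():
    with pytest.raises(ConfigurationError, match="heights"):
        scenario_grid(GridConfig(heights=[]))


def test_grid_order_is_deterministic():
    assert [s.scenario_id for s in default_grid()] == [s.scenario_id for s in default_grid()]


# -- run_scenario ----------------------------------------------------------

SMALL = ScenarioSpec(n_taxa=8, sampling_fraction=0.5, height=0.5, indel_rate=0.05,
                     root_length=60, n_tree_reps=1, n_seq_reps=1)


def test_row_count_is_internal_nodes_per_replicate_per_aligner():
    table = run_scenario(SMALL, [baseline_adapter()], master_seed=5)
    assert len(table) == 7  # n_taxa - 1
    assert set(table["status"]) == {"ok"}
    assert (table.groupby(["tree_rep", "seq_rep", "aligner"]).size() == 7).all()


def test_run_scenario_is_deterministic():
    t1 = run_scenario(SMALL, [baseline_adapter(), builtin_adapter()], master_seed=9)
    t2 = run_scenario(SMALL, [baseline_adapter(), builtin_adapter()], master_seed=9)
    pd.testing.assert_frame_equal(t1, t2)


def test_easy_regime_baseline_is_near_perfect():
    spec = ScenarioSpec(n_taxa=8, sampling_fraction=0.99, height=0.1, indel_rate=0.0,
                        root_length=60, n_tree_reps=2, n_seq_reps=1)
    table = run_scenario(spec, [baseline_adapter()], master_seed=2)
    assert table["accuracy"].mean() > 0.95


def test_failed_external_adapter_marks_rows_missing():
    bad = external_adapter("broken", "false {in} {out}")
    table = run_scenario(SMALL, [baseline_adapter(), bad], master_seed=5)
    broken = table[table["aligner"] == "broken"]
    assert len(broken) == 7
    assert set(broken["status"]) == {"failed"}
    assert broken["accuracy"].isna().all()
    # downstream statistics ignore the missing cells without error
    assert indel_bias(table)["aligner"].tolist() == ["baseline"]


def test_mafft_external_adapter_round_trips():
    adapter = external_adapter("mafft", "mafft --quiet --retree 1 {in}")
    table = run_scenario(SMALL, [adapter], master_seed=5)
    assert set(table["status"]) == {"ok"}
    assert table["accuracy"].between(0, 1).all()


# -- builtin progressive aligner ------------------------------------------


def test_identical_sequences_align_gap_free():
    msa = builtin_progressive_align({f"s{i}": "ACDEFGHIK" for i in range(5)})
    assert all(v == "ACDEFGHIK" for v in msa.values())


def test_two_sequences_reduce_to_pairwise_alignment():
    a, b = "MKVLITTAG", "MKVITTG"
    msa = builtin_progressive_align({"x": a, "y": b})
    assert (msa["x"], msa["y"]) == pairwise_align(a, b)


def test_builtin_alignment_preserves_sequences_on_random_inputs():
    rng = np.random.default_rng(17)
    from asrbench import AMINO_ACIDS

    for trial in range(30):
        n = int(rng.integers(3, 7))
        seqs = {
            f"s{i}": "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 30)))
            for i in range(n)
        }
        msa = builtin_progressive_align(seqs)
        check_degapped_identity(msa, seqs, "builtin")
        assert len({len(v) for v in msa.values()}) == 1


def test_degapped_identity_check_catches_corruption():
    with pytest.raises(AdapterError):
        check_degapped_identity({"a": "AC-"}, {"a": "AD"}, "x")


# -- statistics ------------------------------------------------------------


def _toy_table(acc_by_aligner, scenario="s1"):
    rows = []
    for aligner, accs in acc_by_aligner.items():
        for i, a in enumerate(accs):
            rows.append({
                "scenario_id": scenario, "tree_rep": 0, "seq_rep": 0,
                "aligner": aligner, "node": f"N{i}", "distance_to_root": 0.5,
                "insertion_error": 0.0, "deletion_error": 0.0,
                "substitution_error": 1 - a, "accuracy": a,
                "length_ratio": 1.0, "pairwise_alignment_length": 10,
                "msa_length": 10, "sp_score": a, "modeler_score": a,
                "tc_score": a, "cline_shift": a, "status": "ok",
            })
    return pd.DataFrame(rows)


def test_identical_accuracies_yield_no_wins():
    table = _toy_table({"a": [0.5] * 6, "b": [0.5] * 6})
    wins, pvals = compare_aligners(table)
    assert wins.values.sum() == 0
    assert (pvals["pvalue"] == 1.0).all()


def test_exact_mww_p_matches_rank_permutation_enumeration():
    table = _toy_table({"a": [0.9] * 4, "b": [0.1] * 4})
    _, pvals = compare_aligners(table)
    # oracle: enumerate all C(8,4) group assignments of the pooled sample
    vals = [0.9] * 4 + [0.1] * 4
    obs_u = sum(1.0 if x > y else 0.5 if x == y else 0.0
                for x in vals[:4] for y in vals[4:])
    count = total = 0
    for idx in itertools.combinations(range(8), 4):
        g1 = [vals[i] for i in idx]
        g2 = [vals[i] for i in range(8) if i not in idx]
        u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in g1 for y in g2)
        total += 1
        if abs(u - 8.0) >= abs(obs_u - 8.0):
            count += 1
    assert pvals["pvalue"].iloc[0] == pytest.approx(count / total)


def test_win_requires_adjusted_p_strictly_below_alpha():
    table = _toy_table({"a": [0.9] * 4, "b": [0.1] * 4})
    _, pvals = compare_aligners(table, alpha=0.05)
    p = pvals["p_adjusted"].iloc[0]
    wins_eq, _ = compare_aligners(table, alpha=p)       # p < p is False
    wins_above, _ = compare_aligners(table, alpha=p + 1e-9)
    assert wins_eq.values.sum() == 0
    assert wins_above.loc["a", "b"] == 1
    assert wins_above.loc["b", "a"] == 0


def test_depth_profile_single_depth_single_bin():
    table = _toy_table({"a": [0.2, 0.4, 0.6]})
    prof = depth_profile(table, n_bins=4)
    occupied = prof[prof["n"] > 0]
    assert len(occupied) == 1
    assert occupied["mean_accuracy"].iloc[0] == pytest.approx(0.4)


def test_depth_profile_recovers_linear_relation():
    rows = _toy_table({"a": [0.0] * 40})
    depths = np.linspace(0, 1, 40)
    rows["distance_to_root"] = depths
    rows["accuracy"] = 1 - depths
    prof = depth_profile(rows, n_bins=8)
    for rec in prof.itertuples():
        assert rec.mean_accuracy == pytest.approx(1 - rec.depth_mid, abs=1 / 8)


def test_depth_profile_matches_hand_grouping():
    rng = np.random.default_rng(0)
    table = _toy_table({"a": list(rng.random(20))})
    table["distance_to_root"] = rng.random(20)
    prof = depth_profile(table, n_bins=4)
    edges = np.linspace(table["distance_to_root"].min(),
                        table["distance_to_root"].max(), 5)
    for b in range(4):
        lo, hi = edges[b], edges[b + 1]
        sel = [
            a for a, d in zip(table["accuracy"], table["distance_to_root"])
            if (lo <= d < hi) or (b == 3 and d == hi)
        ]
        row = prof[(prof["aligner"] == "a") & (prof["bin"] == b)].iloc[0]
        assert row["n"] == len(sel)
        if sel:
            assert row["mean_accuracy"] == pytest.approx(np.mean(sel))


def test_indel_bias_perfect_reconstructions():
    table = _toy_table({"a": [1.0] * 5})
    out = indel_bias(table)
    assert out["mean_length_ratio"].iloc[0] == 1.0
    assert out["mean_insertion_error"].iloc[0] == 0.0


def test_indel_bias_detects_overlong_reconstructions():
    table = _toy_table({"a": [0.8] * 5})
    table["length_ratio"] = 1.25
    table["insertion_error"] = 0.2
    table["deletion_error"] = 0.0
    out = indel_bias(table)
    assert out["mean_length_ratio"].iloc[0] > 1
    assert out["mean_insertion_error"].iloc[0] > 0
    # independent recomputation from the raw records
    assert out["median_length_ratio"].iloc[0] == pytest.approx(
        float(np.median(table["length_ratio"]))
    )


def test_quality_accuracy_correlations():
    tables = []
    rng = np.random.default_rng(1)
    accs = rng.random(10)
    for i, a in enumerate(accs):
        t = _toy_table({"a": [a]}, scenario=f"sc{i}")
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    out = quality_vs_accuracy(table)
    row = out[(out["aligner"] == "a") & (out["metric"] == "sp_score")].iloc[0]
    assert row["pearson_r"] == pytest.approx(1.0)
    assert row["spearman_rho"] == pytest.approx(1.0)
    # anti-monotone metric
    table["tc_score"] = 1 - table["accuracy"]
    out = quality_vs_accuracy(table)
    row = out[(out["aligner"] == "a") & (out["metric"] == "tc_score")].iloc[0]
    assert row["spearman_rho"] == pytest.approx(-1.0)


def test_quality_accuracy_direct_formula_oracle():
    rng = np.random.default_rng(2)
    accs = rng.random(10)
    quality = rng.random(10)
    tables = []
    for i, (a, q) in enumerate(zip(accs, quality)):
        t = _toy_table({"a": [a]}, scenario=f"sc{i}")
        t["sp_score"] = q
        tables.append(t)
    out = quality_vs_accuracy(pd.concat(tables, ignore_index=True))
    row = out[(out["aligner"] == "a") & (out["metric"] == "sp_score")].iloc[0]
    x, y = quality, accs
    r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert row["pearson_r"] == pytest.approx(r, abs=1e-12)
    assert row["r2"] == pytest.approx(r * r, abs=1e-12)


def test_zero_variance_quality_flagged_undefined():
    tables = [_toy_table({"a": [a]}, scenario=f"sc{i}")
              for i, a in enumerate([0.2, 0.5, 0.9])]
    table = pd.concat(tables, ignore_index=True)
    table["sp_score"] = 0.7
    out = quality_vs_accuracy(table)
    row = out[(out["aligner"] == "a") & (out["metric"] == "sp_score")].iloc[0]
    assert not row["defined"]
    row2 = out[(out["aligner"] == "a") & (out["metric"] == "tc_score")].iloc[0]
    assert row2["defined"]
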