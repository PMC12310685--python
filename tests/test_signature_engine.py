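"""Sensitivity labeling and DS/DRS signatures against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_expression
from oracles import bh_stepup, welch_oracle

from drsynergy import (
    IC50Table,
    SignatureParams,
    SimulationConfig,
    call_significant,
    compute_drs,
    compute_ds,
    label_sensitivity,
    select_condition,
    simulate_cohort,
)
from drsynergy.errors import (
    EmptySelectionError,
    InsufficientDataError,
    UnknownDrugError,
    ValidationError,
)
from drsynergy.signature_engine import RESISTANT, SENSITIVE, SensitivityLabeling
from drsynergy.workflows import cohort_signatures


def ic50_table(values: dict, drug="d1"):
    return IC50Table(
        pd.DataFrame(
            {"drug": drug, "cell_line": list(values), "ic50": list(values.values())}
        )
    )


# ---------------------------------------------------------------------------
# sensitivity labeling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ic50s, expected_threshold, expected_sensitive",
    [
        # odd count: median is the central value, which labels resistant
        ({"c1": 1, "c2": 2, "c3": 3, "c4": 4, "c5": 5}, 3.0, {"c1", "c2"}),
        # even count: midpoint of the two central order statistics
        ({"c1": 1, "c2": 3}, 2.0, {"c1"}),
        # ties at the median go to resistant
        ({"c1": 2, "c2": 2, "c3": 2, "c4": 5}, 2.0, set()),
        # all equal: every value >= median, so all resistant
        ({"c1": 7, "c2": 7, "c3": 7}, 7.0, set()),
    ],
)
def test_median_split_matches_hand_labels(ic50s, expected_threshold, expected_sensitive):
    labeling = label_sensitivity(ic50_table(ic50s), "d1")
    assert labeling.threshold == expected_threshold
    assert set(labeling.sensitive) == expected_sensitive
    assert set(labeling.resistant) == set(ic50s) - expected_sensitive


def test_unknown_drug_and_single_cell_line_errors():
    table = ic50_table({"c1": 1.0, "c2": 2.0})
    with pytest.raises(UnknownDrugError):
        label_sensitivity(table, "nope")
    with pytest.raises(InsufficientDataError):
        label_sensitivity(ic50_table({"c1": 1.0}), "d1")


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    values=st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=20),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_labeling_is_invariant_to_positive_rescaling(values, scale):
    base = {f"c{i}": v for i, v in enumerate(values)}
    scaled = {c: v * scale for c, v in base.items()}
    a = label_sensitivity(ic50_table(base), "d1")
    b = label_sensitivity(ic50_table(scaled), "d1")
    assert a.status.equals(b.status)


# ---------------------------------------------------------------------------
# condition selection
# ---------------------------------------------------------------------------

def _mixed_condition_expr():
    meta = {
        "s1": ("dA", "c1", "treated", "10uM", "24h"),
        "s2": ("dA", "c2", "treated", "10uM", "24h"),
        "s3": ("dA", "c1", "treated", "1uM", "24h"),
        "s4": ("dA", "c1", "treated", "10uM", "6h"),
        "s5": ("", "c1", "control", "", ""),
        "s6": ("", "c2", "control", "", ""),
    }
    genes = {"g1": [1, 2, 3, 4, 5, 6], "g2": [0, 0, 0, 0, 0, 0]}
    return make_expression(genes, meta)


def test_canonical_filter_keeps_matching_treated_and_all_controls():
    expr = _mixed_condition_expr()
    out = select_condition(expr, "10uM", "24h")
    assert set(out.values.columns) == {"s1", "s2", "s5", "s6"}
    assert len(out.control_samples()) == 2


def test_filter_with_no_matching_treated_raises_empty_selection():
    with pytest.raises(EmptySelectionError, match="0.5uM"):
        select_condition(_mixed_condition_expr(), "0.5uM", "24h")


def test_cohort_stamped_at_canonical_condition_keeps_all_treated(tiny_cohort):
    expr = select_condition(tiny_cohort.expression, "10uM", "24h")
    assert expr.n_samples == tiny_cohort.expression.n_samples


# ---------------------------------------------------------------------------
# DS
# ---------------------------------------------------------------------------

def _two_group_expr(treated_vals, control_vals, gene="g1"):
    meta = {}
    genes = {gene: list(treated_vals) + list(control_vals)}
    for i in range(len(treated_vals)):
        meta[f"t{i}"] = ("dA", f"c{i}", "treated", "10uM", "24h")
    for i in range(len(control_vals)):
        meta[f"u{i}"] = ("", f"c{i}", "control", "", "")
    return make_expression(genes, meta)


def test_ds_delta_is_mean_treated_minus_mean_control():
    sig = compute_ds(_two_group_expr([2, 4], [1, 1]), "dA")
    assert sig.table["delta"].iloc[0] == pytest.approx(2.0)


def test_ds_sign_flag_negates_delta_and_t():
    expr = _two_group_expr([2, 4, 6], [1, 1, 2])
    plain = compute_ds(expr, "dA").table
    flipped = compute_ds(expr, "dA", SignatureParams(flip_sign=True)).table
    assert flipped["delta"].iloc[0] == pytest.approx(-plain["delta"].iloc[0])
    assert flipped["t_stat"].iloc[0] == pytest.approx(-plain["t_stat"].iloc[0])
    assert flipped["p_value"].iloc[0] == pytest.approx(plain["p_value"].iloc[0])


def test_identical_groups_give_zero_deltas_and_no_calls(rng):
    vals = rng.normal(size=4)
    expr = _two_group_expr(vals, vals)
    sig = compute_ds(expr, "dA")
    assert (sig.table["delta"] == 0).all()
    assert (sig.table["direction"] == "ns").all()


def test_degenerate_zero_variance_groups_are_flagged():
    sig = compute_ds(_two_group_expr([1, 1], [0, 0]), "dA").table
    assert bool(sig["degenerate"].iloc[0])
    assert sig["p_value"].iloc[0] == 0.0
    same = compute_ds(_two_group_expr([3, 3], [3, 3]), "dA").table
    assert same["p_value"].iloc[0] == 1.0 and same["delta"].iloc[0] == 0.0


def test_too_few_replicates_raises():
    with pytest.raises(InsufficientDataError):
        compute_ds(_two_group_expr([2], [1, 1]), "dA")


def test_ds_matches_brute_force_welch_per_gene(rng):
    """Seeded 1000-gene x 20-sample fixture vs. an explicit per-gene loop."""
    n_genes, n_each = 1000, 10
    data = rng.normal(size=(n_genes, 2 * n_each))
    meta = {f"t{i}": ("dA", f"c{i}", "treated", "10uM", "24h") for i in range(n_each)}
    meta |= {f"u{i}": ("", f"c{i}", "control", "", "") for i in range(n_each)}
    genes = {f"g{i}": data[i] for i in range(n_genes)}
    sig = compute_ds(make_expression(genes, meta), "dA").table
    for i in range(n_genes):
        delta, t, p = welch_oracle(data[i, :n_each], data[i, n_each:])
        assert sig["delta"].iloc[i] == pytest.approx(delta, rel=1e-10)
        assert sig["t_stat"].iloc[i] == pytest.approx(t, rel=1e-10)
        assert sig["p_value"].iloc[i] == pytest.approx(p, rel=1e-10)


# ---------------------------------------------------------------------------
# DRS
# ---------------------------------------------------------------------------

def _drs_fixture(resistant_vals, sensitive_vals):
    cells = [f"r{i}" for i in range(len(resistant_vals))] + [
        f"s{i}" for i in range(len(sensitive_vals))
    ]
    meta = {f"{c}.trt": ("dA", c, "treated", "10uM", "24h") for c in cells}
    genes = {"g1": list(resistant_vals) + list(sensitive_vals)}
    expr = make_expression(genes, meta)
    status = pd.Series(
        [RESISTANT] * len(resistant_vals) + [SENSITIVE] * len(sensitive_vals), index=cells
    )
    return expr, SensitivityLabeling(drug="dA", status=status, threshold=1.0)


def test_drs_delta_is_resistant_mean_minus_sensitive_mean():
    expr, labeling = _drs_fixture([5, 7], [1, 3])
    sig = compute_drs(expr, labeling, "dA")
    assert sig.table["delta"].iloc[0] == pytest.approx(4.0)


def test_all_resistant_labeling_raises_insufficient_data():
    expr, labeling = _drs_fixture([5, 7, 6, 8], [])
    with pytest.raises(InsufficientDataError):
        compute_drs(expr, labeling, "dA")


def test_swapping_group_labels_negates_delta_and_t_keeps_p():
    expr, labeling = _drs_fixture([5.0, 7.0, 6.5], [1.0, 3.0, 2.2])
    swapped = SensitivityLabeling(
        drug="dA",
        status=labeling.status.map({RESISTANT: SENSITIVE, SENSITIVE: RESISTANT}),
        threshold=labeling.threshold,
    )
    a = compute_drs(expr, labeling, "dA").table
    b = compute_drs(expr, swapped, "dA").table
    assert b["delta"].iloc[0] == pytest.approx(-a["delta"].iloc[0])
    assert b["t_stat"].iloc[0] == pytest.approx(-a["t_stat"].iloc[0])
    assert b["p_value"].iloc[0] == pytest.approx(a["p_value"].iloc[0])


def test_drs_recovers_planted_program_with_low_false_discovery():
    """One 100-gene program, 80 lines, effect 1.5: recall >= 90%, FDP <= 10%."""
    cohort = simulate_cohort(
        SimulationConfig(
            n_cell_lines=80, n_drugs=2, n_programs=1, genes_per_program=100,
            resistance_effect=1.5, seed=42,
        )
    )
    sig = cohort_signatures(cohort, kind="DRS")["D00"]
    up, down = call_significant(sig, 0.0, 0.05)
    planted = set(cohort.truth.program_genes["P0"])
    called = up | down
    recall = len(up & planted) / len(planted)
    fdp = len(called - planted) / max(len(called), 1)
    assert recall >= 0.9
    assert fdp <= 0.1


def test_null_cohort_drs_pvalues_are_uniform():
    cohort = simulate_cohort(
        SimulationConfig(n_cell_lines=80, n_drugs=2, resistance_effect=0.0, seed=3)
    )
    sig = cohort_signatures(cohort, kind="DRS")["D00"]
    ks = stats.kstest(sig.table["p_value"], "uniform").statistic
    assert ks < 0.05


def test_baseline_compartment_also_carries_the_planted_signal(tiny_cohort):
    cohort = simulate_cohort(SimulationConfig(n_cell_lines=60, n_drugs=2, seed=5))
    sig = cohort_signatures(cohort, kind="DRS", compartment="baseline")["D00"]
    planted = set(cohort.truth.program_genes[cohort.truth.drug_program["D00"]])
    up, _ = call_significant(sig, 0.0, 0.05)
    assert len(up & planted) / len(planted) >= 0.9


# ---------------------------------------------------------------------------
# significance calling / BH
# ---------------------------------------------------------------------------

def test_bh_qvalues_match_hand_stepup(rng):
    data = rng.normal(size=(20, 8))
    meta = {f"t{i}": ("dA", f"c{i}", "treated", "10uM", "24h") for i in range(4)}
    meta |= {f"u{i}": ("", f"c{i}", "control", "", "") for i in range(4)}
    sig = compute_ds(make_expression({f"g{i}": data[i] for i in range(20)}, meta), "dA").table
    expected = bh_stepup(sig["p_value"])
    assert np.allclose(sig["q_value"], expected, rtol=1e-12)
    # step-up output is monotone in p-value rank and never below raw p
    ordered = sig.sort_values("p_value")
    assert (np.diff(ordered["q_value"]) >= -1e-15).all()
    assert (sig["q_value"] >= sig["p_value"] - 1e-15).all()


def test_call_significant_partitions_by_sign_at_loose_thresholds(rng):
    data = rng.normal(size=(30, 10))
    meta = {f"t{i}": ("dA", f"c{i}", "treated", "10uM", "24h") for i in range(5)}
    meta |= {f"u{i}": ("", f"c{i}", "control", "", "") for i in range(5)}
    sig = compute_ds(make_expression({f"g{i}": data[i] for i in range(30)}, meta), "dA")
    up, down = call_significant(sig, 0.0, 1.0)
    t = sig.table
    assert up == set(t.loc[t["delta"] > 0, "gene"])
    assert down == set(t.loc[t["delta"] < 0, "gene"])
    assert not (up & down)


def test_call_significant_threshold_below_min_q_gives_empty_sets():
    expr = _two_group_expr([2, 4, 3], [1, 1, 2])
    sig = compute_ds(expr, "dA")
    up, down = call_significant(sig, 0.0, min(sig.table["q_value"]) / 2)
    assert up == set() and down == set()


def test_threshold_validation():
    expr = _two_group_expr([2, 4], [1, 1])
    sig = compute_ds(expr, "dA")
    with pytest.raises(ValidationError):
        call_significant(sig, -1.0, 0.05)
    with pytest.raises(ValidationError):
        call_significant(sig, 0.0, 0.0)
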