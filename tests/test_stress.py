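"""Stress indices, 10-grade scoring, RCI/PCI classification, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenotrial import (
    DerivedIndexConfig,
    classify_groups,
    compare_extreme_groups,
    compute_derived_indices,
    compute_rci_pci,
    compute_stress_indices,
    score_indices,
    stress_score_table,
    welch_from_summary,
)

positive_yields = st.lists(
    st.floats(min_value=0.5, max_value=50.0), min_size=3, max_size=15
)


# ---------------------------------------------------------------------------
# indices


def test_index_hand_arithmetic():
    out = compute_stress_indices([16.0, 10.0], [4.0, 9.0])
    row = out.iloc[0]
    assert row["MP"] == pytest.approx(10.0)
    assert row["GMP"] == pytest.approx(8.0)
    assert row["TOL"] == pytest.approx(12.0)


def test_ssi_through_stress_intensity():
    out = compute_stress_indices([10.0, 10.0], [5.0, 10.0])
    assert out.attrs["SI"] == pytest.approx(0.25)
    assert out["SSI"].tolist() == pytest.approx([2.0, 0.0])


def test_stress_neutral_genotype():
    out = compute_stress_indices([8.0, 12.0], [8.0, 6.0])
    row = out.iloc[0]  # Yp == Ys
    assert row["TOL"] == 0.0 and row["SSI"] == 0.0
    assert row["GMP"] == row["MP"] == 8.0


def test_errors_on_invalid_yields():
    with pytest.raises(ValueError, match="no population-level stress"):
        compute_stress_indices([5.0, 5.0], [6.0, 6.0])
    with pytest.raises(ValueError, match="positive"):
        compute_stress_indices([5.0, 0.0], [1.0, 1.0])


@settings(derandomize=True, max_examples=60)
@given(positive_yields, st.floats(min_value=0.1, max_value=0.9))
def test_index_identities(yp, loss):
    """AM-GM, the STI/GMP identity, and TOL=0 iff Yp=Ys."""
    yp = np.asarray(yp)
    ys = yp * (1 - loss) * np.linspace(0.8, 1.0, yp.size)
    out = compute_stress_indices(yp, ys)
    assert (out["GMP"] <= out["MP"] + 1e-12).all()
    sti = out["GMP"] ** 2 / out.attrs["Yp_mean"] ** 2
    assert np.abs(out["STI"] - sti).max() < 1e-12
    assert np.all((out["TOL"] == 0) == (out["Yp"] == out["Ys"]))


def test_uniform_loss_gives_unit_ssi():
    yp = np.array([4.0, 9.0, 25.0])
    out = compute_stress_indices(yp, 0.7 * yp)
    assert np.abs(out["SSI"] - 1.0).max() < 1e-12


# ---------------------------------------------------------------------------
# scoring


def test_score_endpoints_and_half_up_rounding():
    scores = score_indices([0.0, 4.5, 9.0])
    assert scores.tolist() == [1, 6, 10]  # round(5.5) -> 6, half-up


def test_score_orientation_flip_for_susceptibility():
    ssi = pd.Series([0.2, 1.0, 1.8], index=["best", "mid", "worst"])
    scores = score_indices(ssi, orientation="lower_better")
    assert scores["best"] == 10 and scores["worst"] == 1


def test_constant_input_scores_neutral():
    assert score_indices([3.0, 3.0, 3.0]).tolist() == [5, 5, 5]


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        score_indices([])


def test_decile_variant_matches_rank_deciles():
    values = np.arange(20, dtype=float)
    scores = score_indices(values, variant="decile")
    assert scores.min() == 1 and scores.max() == 10
    assert (np.diff(scores) >= 0).all()
    assert np.bincount(scores)[1:].tolist() == [2] * 10


@settings(derandomize=True, max_examples=40)
@given(
    st.lists(st.integers(min_value=-50, max_value=50).map(float), min_size=3,
             max_size=12, unique=True),
    st.floats(min_value=0.5, max_value=4.0),
    st.floats(min_value=-10.0, max_value=10.0),
)
@pytest.mark.parametrize("variant", ["minmax", "decile"])
def test_scores_invariant_under_increasing_affine_maps(variant, values, a, b):
    base = score_indices(values, variant=variant)
    mapped = score_indices([a * v + b for v in values], variant=variant)
    assert base.tolist() == mapped.tolist()


# ---------------------------------------------------------------------------
# RCI / PCI and groups


def test_rci_pci_are_score_means():
    scores = pd.DataFrame(
        {"SSI": [4], "TOL": [6], "MP": [10], "GMP": [10], "STI": [10]}
    )
    out = compute_rci_pci(scores)
    assert out["RCI"].iloc[0] == pytest.approx(5.0)
    assert out["PCI"].iloc[0] == pytest.approx(10.0)
    ones = compute_rci_pci(pd.DataFrame({k: [1] for k in scores.columns}))
    assert ones["RCI"].iloc[0] == ones["PCI"].iloc[0] == 1.0


def test_quadrant_corners_and_partition():
    table = pd.DataFrame(
        {"RCI": [10.0, 1.0, 8.0, 2.0], "PCI": [10.0, 1.0, 2.0, 8.0]},
        index=["best", "worst", "resilient", "productive"],
    )
    groups = classify_groups(table)
    assert groups["best"] == "A" and groups["worst"] == "D"
    assert groups["resilient"] == "C" and groups["productive"] == "B"


def test_boundary_values_count_as_high():
    table = pd.DataFrame({"RCI": [5.0, 5.0], "PCI": [5.0, 5.0]})
    assert (classify_groups(table) == "A").all()


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_groups_partition_and_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 20)
    table = pd.DataFrame(
        {"RCI": rng.uniform(1, 10, n), "PCI": rng.uniform(1, 10, n)},
        index=[f"G{i}" for i in range(n)],
    )
    groups = classify_groups(table)
    assert set(groups.unique()) <= {"A", "B", "C", "D"}
    assert len(groups) == n
    perm = rng.permutation(n)
    shuffled = classify_groups(table.iloc[perm])
    assert (shuffled.sort_index() == groups.sort_index()).all()
    assert not (set(groups[groups == "A"].index) & set(groups[groups == "D"].index))


def test_stress_score_table_planted_extremes():
    yp = pd.Series([20.0, 24.0, 10.0, 12.0], index=list("abcd"))
    ys = pd.Series([18.0, 12.0, 9.5, 4.0], index=list("abcd"))
    table = stress_score_table(yp, ys)
    assert table.loc["a", "group"] == "A"
    assert table.loc["d", "group"] == "D"


# ---------------------------------------------------------------------------
# group comparison


def test_identical_groups_trivially_non_significant():
    values = pd.DataFrame({"y": [1.0, 1.0, 1.0, 1.0]}, index=list("wxyz"))
    groups = pd.Series(["A", "A", "D", "D"], index=list("wxyz"))
    out = compare_extreme_groups(values, groups)
    assert out.iloc[0]["t"] == 0.0 and out.iloc[0]["p"] == 1.0


def test_welch_from_summary_hand_example():
    t, df, p = welch_from_summary(154.0, 4.0, 5, 139.0, 1.0, 4)
    assert t == pytest.approx(15 / np.sqrt(17), rel=1e-12)
    assert p < 0.05


def test_small_group_comparison_skipped_with_warning():
    values = pd.DataFrame({"y": [1.0, 2.0, 3.0]}, index=list("xyz"))
    groups = pd.Series(["A", "D", "D"], index=list("xyz"))
    with pytest.warns(UserWarning, match="skipped"):
        out = compare_extreme_groups(values, groups)
    assert out.empty


def test_significance_stars_track_alpha_levels():
    rng = np.random.default_rng(5)
    a = rng.normal(10, 0.1, 6)
    d = rng.normal(0, 0.1, 6)
    values = pd.DataFrame({"big": np.concatenate([a, d]),
                           "null": rng.normal(size=12)},
                          index=[f"G{i}" for i in range(12)])
    groups = pd.Series(["A"] * 6 + ["D"] * 6, index=values.index)
    out = compare_extreme_groups(values, groups).set_index("trait")
    assert out.loc["big", "stars"] == "**" and out.loc["big", "significant"]
    assert out.loc["null", "stars"] == "" and not out.loc["null", "significant"]


# ---------------------------------------------------------------------------
# derived indices


def test_wue_formula_direct_division():
    table = pd.DataFrame({"BDw": [15.0], "water": [7.5], "PHg": [100.0],
                          "NC": [2.0]})
    out = compute_derived_indices(table)
    assert out["WUE"].iloc[0] == pytest.approx(2.0)
    assert out["PNUE"].iloc[0] == pytest.approx(50.0)
    # inputs untouched
    assert (out["BDw"] == table["BDw"]).all()


def test_zero_denominator_raises_named_error():
    table = pd.DataFrame({"BDw": [15.0], "water": [0.0], "PHg": [1.0],
                          "NC": [2.0]})
    with pytest.raises(ValueError, match="WUE"):
        compute_derived_indices(table)


def test_missing_input_column_named():
    table = pd.DataFrame({"BDw": [15.0]})
    with pytest.raises(ValueError, match="SPW"):
        compute_derived_indices(table)


def test_formula_swap_changes_only_derived_columns():
    table = pd.DataFrame({"BDw": [10.0, 20.0], "water": [5.0, 5.0],
                          "PHg": [50.0, 80.0], "NC": [1.5, 2.5]})
    default = compute_derived_indices(table)
    swapped = compute_derived_indices(
        table,
        DerivedIndexConfig(formulas={"WUE": (("BDw", "water"),
                                             lambda b, w: 0.5 * b / w)}),
    )
    assert (swapped["BDw"] == table["BDw"]).all()
    assert np.allclose(swapped["WUE"], 0.5 * default["WUE"])
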