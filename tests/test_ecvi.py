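"""Alkire-Foster index: cutoffs, identities, decompositions, SEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climvuln.ecvi import (
    Indicator,
    IndicatorSchema,
    adjusted_index,
    af_statistics,
    apply_deprivation_cutoffs,
    compute_ecvi,
    decompose_by_dimension,
    decompose_by_indicator,
    decompose_by_subgroup,
    default_schema,
    estimate_se,
    weighted_score,
)


def small_schema(weights=(0.4, 0.3, 0.2, 0.1), rule="upper_quartile"):
    return IndicatorSchema(
        [
            Indicator(f"ind{i}", "exposure", rule, w)
            for i, w in enumerate(weights)
        ]
    )


def flags_frame(mat, ids=None):
    mat = np.asarray(mat)
    ids = ids or [f"ind{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, columns=ids,
                        index=pd.Index([f"R{i}" for i in range(len(mat))], name="region_id"))


# ------------------------------------------------------------- cutoffs


def test_upper_quartile_rule_matches_sort_oracle():
    vals = [1.0, 2, 3, 4, 5, 6, 7, 8]
    panel = pd.DataFrame({"region_id": [f"R{i}" for i in range(8)], "ind0": vals})
    schema = IndicatorSchema([Indicator("ind0", "exposure", "upper_quartile", 1.0)])
    flags = apply_deprivation_cutoffs(panel, schema)
    # explicit sort oracle: Q3 by linear interpolation = 6.25
    srt = sorted(vals)
    pos = 0.75 * (len(srt) - 1)
    q3 = srt[int(pos)] + (pos - int(pos)) * (srt[int(pos) + 1] - srt[int(pos)])
    expected = [int(v >= q3) for v in vals]
    assert list(flags["ind0"]) == expected == [0, 0, 0, 0, 0, 0, 1, 1]


def test_lower_quartile_rule_inclusive():
    panel = pd.DataFrame({"region_id": list("abcde"), "ind0": [1.0, 2, 3, 4, 5]})
    schema = IndicatorSchema([Indicator("ind0", "exposure", "lower_quartile", 1.0)])
    flags = apply_deprivation_cutoffs(panel, schema)
    q1 = np.percentile([1, 2, 3, 4, 5], 25)
    assert list(flags["ind0"]) == [int(v <= q1) for v in [1, 2, 3, 4, 5]]


def test_income_rule_strictly_below_threshold():
    panel = pd.DataFrame(
        {"region_id": list("abcd"), "income": [296.8, 296.79, 400.0, 100.0]}
    )
    schema = IndicatorSchema(
        [Indicator("income", "susceptibility", "below_absolute", 1.0, threshold=296.8)]
    )
    flags = apply_deprivation_cutoffs(panel, schema)
    assert list(flags["income"]) == [0, 1, 0, 1]  # boundary value is NOT deprived


def test_degenerate_distribution_flags_all_with_warning():
    panel = pd.DataFrame({"region_id": list("abcd"), "ind0": [2.0] * 4})
    schema = IndicatorSchema([Indicator("ind0", "exposure", "upper_quartile", 1.0)])
    with pytest.warns(UserWarning, match="degenerate"):
        flags = apply_deprivation_cutoffs(panel, schema)
    assert list(flags["ind0"]) == [1, 1, 1, 1]


def test_missing_indicator_value_is_hard_error():
    panel = pd.DataFrame({"region_id": list("abcd"), "ind0": [1.0, np.nan, 3.0, 4.0]})
    schema = IndicatorSchema([Indicator("ind0", "exposure", "upper_quartile", 1.0)])
    with pytest.raises(ValueError, match="ind0"):
        apply_deprivation_cutoffs(panel, schema)


# ------------------------------------------------------- weighted score


def test_weighted_score_dimension_totals():
    schema = default_schema()
    exposure_ids = [i.indicator_id for i in schema if i.dimension == "exposure"]
    mat = np.zeros((1, 18), dtype=int)
    flags = flags_frame(mat, ids=schema.ids)
    flags[exposure_ids] = 1
    assert weighted_score(flags, schema).iloc[0] == pytest.approx(1 / 3)
    flags[:] = 0
    assert weighted_score(flags, schema).iloc[0] == 0.0
    flags[:] = 1
    assert weighted_score(flags, schema).iloc[0] == pytest.approx(1.0)


# ------------------------------------------------------------- core AF


def test_ecvi_hand_example_two_regions():
    res = compute_ecvi(np.array([1 / 3, 0.20]), np.array([100.0, 100.0]), k_p=0.25)
    assert res.ch == pytest.approx(0.5)
    assert res.di == pytest.approx(1 / 3)
    assert res.ecvi == pytest.approx(1 / 6)


def test_ecvi_empty_censored_set():
    res = compute_ecvi(np.array([0.1, 0.2]), None, k_p=0.9)
    assert (res.ch, res.di, res.ecvi) == (0.0, 0.0, 0.0)


def test_adjusted_index_is_product():
    assert adjusted_index(0.5, 0.4) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        adjusted_index(1.2, 0.4)


def test_scale_invariance_in_populations(rng):
    c = rng.random(12)
    pop = rng.uniform(1e4, 1e6, 12)
    a = af_statistics(c, pop, 0.3)
    b = af_statistics(c, pop * 7.3, 0.3)
    assert a == pytest.approx(b)


def test_monotonicity_flipping_a_flag_never_decreases_ecvi(rng):
    schema = small_schema()
    for _ in range(25):
        mat = (rng.random((8, 4)) < 0.4).astype(int)
        pop = rng.uniform(1, 10, 8)
        flags = flags_frame(mat)
        base = af_statistics(weighted_score(flags, schema).to_numpy(), pop, 0.3)[2]
        i, j = rng.integers(0, 8), rng.integers(0, 4)
        if mat[i, j] == 1:
            continue
        mat2 = mat.copy()
        mat2[i, j] = 1
        higher = af_statistics(
            weighted_score(flags_frame(mat2), schema).to_numpy(), pop, 0.3
        )[2]
        assert higher >= base - 1e-15


def test_ch_ecvi_nonincreasing_di_nondecreasing_in_kp(rng):
    c = rng.random(20)
    pop = rng.uniform(1, 5, 20)
    grid = np.linspace(0.05, 1.0, 20)
    stats = np.array([af_statistics(c, pop, k) for k in grid])
    ch, di, ecvi = stats.T
    assert np.all(np.diff(ch) <= 1e-15)
    assert np.all(np.diff(ecvi) <= 1e-15)
    positive = ch > 0
    assert np.all(np.diff(di[positive]) >= -1e-15)


# -------------------------------------------------------- decompositions


def test_subgroup_single_group_contribution_one(rng):
    c = rng.random(6)
    pop = rng.uniform(1, 5, 6)
    table = decompose_by_subgroup(c, pop, np.array(["all"] * 6), k_p=0.2)
    assert table["contribution"].iloc[0] == pytest.approx(1.0)


def test_subgroup_identity_weighted_sum_equals_pooled(rng):
    for _ in range(20):
        n = 10
        c = rng.random(n)
        pop = rng.uniform(1e3, 1e6, n)
        groups = np.array(["A"] * 6 + ["B"] * 4)
        kp = rng.uniform(0.05, 0.9)
        pooled = af_statistics(c, pop, kp)[2]
        table = decompose_by_subgroup(c, pop, groups, kp)
        assert table["weighted_ECVI"].sum() == pytest.approx(pooled, abs=1e-12)
        if pooled > 0:
            assert table["contribution"].sum() == pytest.approx(1.0, abs=1e-12)


def test_subgroup_only_vulnerable_group_contributes():
    c = np.array([0.8, 0.9, 0.0, 0.1])
    pop = np.ones(4)
    table = decompose_by_subgroup(c, pop, np.array(["A", "A", "B", "B"]), 0.5)
    by = table.set_index("subgroup")["contribution"]
    assert by["A"] == pytest.approx(1.0)
    assert by["B"] == pytest.approx(0.0)


def test_indicator_identity_and_contribution_sum(rng):
    schema = default_schema()
    for _ in range(10):
        mat = (rng.random((15, 18)) < 0.35).astype(int)
        flags = flags_frame(mat, ids=schema.ids)
        pop = rng.uniform(1e4, 1e6, 15)
        kp = 0.25
        c = weighted_score(flags, schema).to_numpy()
        ecvi = af_statistics(c, pop, kp)[2]
        table = decompose_by_indicator(flags, schema, pop, kp)
        assert (table["weight"] * table["censored_headcount"]).sum() == pytest.approx(
            ecvi, abs=1e-12
        )
        if ecvi > 0:
            assert table["contribution"].sum() == pytest.approx(1.0, abs=1e-12)
            dims = decompose_by_dimension(table)
            assert dims["contribution"].sum() == pytest.approx(1.0, abs=1e-12)


def test_indicator_single_deprivation_contributes_all():
    schema = small_schema(weights=(0.4, 0.3, 0.2, 0.1))
    mat = np.array([[1, 0, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0]])
    flags = flags_frame(mat)
    table = decompose_by_indicator(flags, schema, None, k_p=0.35)
    assert table.set_index("indicator_id")["contribution"]["ind0"] == pytest.approx(1.0)


# --------------------------------------------------------- random panels


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_af_identities_on_random_panels(data):
    """Subgroup and indicator identities hold to 1e-12 on random panels."""
    n = data.draw(st.integers(4, 15))
    I = data.draw(st.integers(2, 8))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    w = rng.random(I) + 0.1
    w = w / w.sum()
    schema = IndicatorSchema(
        [Indicator(f"ind{i}", "exposure", "upper_quartile", wi) for i, wi in enumerate(w)]
    )
    mat = (rng.random((n, I)) < 0.4).astype(int)
    flags = flags_frame(mat)
    pop = rng.uniform(1.0, 1e5, n)
    kp = float(rng.uniform(0.05, 0.95))
    c = weighted_score(flags, schema).to_numpy()
    ch, di, ecvi = af_statistics(c, pop, kp)
    assert ecvi == pytest.approx(ch * di, abs=1e-15)
    if ch > 0:
        assert di >= kp - 1e-12
    groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    sub = decompose_by_subgroup(c, pop, groups, kp)
    assert sub["weighted_ECVI"].sum() == pytest.approx(ecvi, abs=1e-12)
    ind = decompose_by_indicator(flags, schema, pop, kp)
    assert (ind["weight"] * ind["censored_headcount"]).sum() == pytest.approx(
        ecvi, abs=1e-12
    )


# ------------------------------------------------------- standard errors


def test_se_zero_when_regions_identical():
    c = np.full(8, 0.4)
    pop = np.full(8, 100.0)
    for method in ("bootstrap", "linearization"):
        se = estimate_se(c, pop, 0.25, method=method, n_bootstrap=200, seed=1)
        assert se == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_bootstrap_matches_closed_form_two_point():
    # x_i = c_i * vulnerable_i is a two-point variable {0.5, 0};
    # the resampled-mean SD is sqrt(v^2 p(1-p) / n)
    c = np.array([0.5] * 4 + [0.0] * 6)
    se = estimate_se(c, None, 0.25, method="bootstrap", n_bootstrap=5000, seed=7)
    p = 0.4
    closed = np.sqrt(0.5**2 * p * (1 - p) / 10)
    assert se[2] == pytest.approx(closed, rel=0.05)


def test_linearization_variance_halves_when_regions_doubled(rng):
    c = rng.random(10)
    pop = rng.uniform(1, 5, 10)
    se1 = estimate_se(c, pop, 0.3, method="linearization")
    se2 = estimate_se(np.tile(c, 2), np.tile(pop, 2), 0.3, method="linearization")
    assert se2[2] ** 2 == pytest.approx(se1[2] ** 2 / 2, rel=1e-9)


def test_small_bootstrap_warns():
    with pytest.warns(UserWarning, match="bootstrap"):
        estimate_se(np.array([0.1, 0.5, 0.9]), None, 0.25, n_bootstrap=10, seed=0)


# ------------------------------------------------------------ the schema


def test_default_schema_structure():
    schema = default_schema()
    assert len(schema) == 18
    w = pd.Series(schema.weights, index=schema.ids)
    dims = pd.Series(schema.dimensions, index=schema.ids)
    assert w.sum() == pytest.approx(1.0)
    for dim, expected_n in (("exposure", 7), ("susceptibility", 5), ("adaptive_capacity", 6)):
        members = w[dims == dim]
        assert len(members) == expected_n
        assert members.nunique() == 1  # equal within dimension
        assert members.sum() == pytest.approx(1 / 3)


def test_income_threshold_presets():
    assert [i for i in default_schema() if i.rule == "below_absolute"][0].threshold == 296.8
    alt = default_schema(income_threshold=255.0)
    assert [i for i in alt if i.rule == "below_absolute"][0].threshold == 255.0
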