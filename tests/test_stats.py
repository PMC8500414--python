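"""ANOVA, within-subject CIs, Cook's distance, cluster permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sst

from trajerp.stats import (
    CONDITION_ORDER,
    ClusterPermutationTest,
    DegenerateDataError,
    RepeatedMeasures2x2,
    _max_cluster_stats,
    cooks_distance,
    cousineau_morey_ci,
    form_clusters,
    pointwise_t,
    signflip_null,
)

from conftest import make_cell_matrix


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

matrix_strategy = arrays(
    float,
    st.tuples(st.integers(3, 12), st.just(4)),
    elements=st.floats(-10, 10, allow_nan=False, width=32),
)


@settings(deadline=None, max_examples=40)
@given(values=matrix_strategy)
def test_f_equals_squared_paired_t(values):
    """For two-level within factors, each effect's F is the square of the
    paired t test on the corresponding marginal means."""
    m = make_cell_matrix(values)
    res = RepeatedMeasures2x2(m).fit()
    v = m.to_numpy()
    pairs = {
        "expectation": (v[:, 2:].mean(axis=1), v[:, :2].mean(axis=1)),
        "shape_status": (v[:, [0, 2]].mean(axis=1), v[:, [1, 3]].mean(axis=1)),
    }
    for effect, (a, b) in pairs.items():
        if np.allclose(a, b):
            continue  # degenerate: paired t undefined or zero
        t, p = sst.ttest_rel(a, b)
        if not np.isfinite(t):
            continue
        assert res.anova_table.loc[effect, "F"] == pytest.approx(t**2, rel=1e-8)
        assert res.anova_table.loc[effect, "p"] == pytest.approx(p, rel=1e-6)


def test_anova_matches_statsmodels_reference():
    rng = np.random.default_rng(10)
    m = make_cell_matrix(rng.normal(size=(9, 4)))
    res = RepeatedMeasures2x2(m).fit()
    from statsmodels.stats.anova import AnovaRM

    rows = []
    for subj, row in m.iterrows():
        for cond in CONDITION_ORDER:
            e, s = cond.split("_")
            rows.append(dict(subject=subj, expectation=e, status=s, value=row[cond]))
    ref = AnovaRM(
        pd.DataFrame(rows), "value", "subject", within=["expectation", "status"]
    ).fit().anova_table
    assert res.anova_table.loc["expectation", "F"] == pytest.approx(
        ref.loc["expectation", "F Value"]
    )
    assert res.anova_table.loc["shape_status", "F"] == pytest.approx(
        ref.loc["status", "F Value"]
    )
    assert res.anova_table.loc["interaction", "F"] == pytest.approx(
        ref.loc["expectation:status", "F Value"]
    )
    assert res.anova_table.loc["interaction", "p"] == pytest.approx(
        ref.loc["expectation:status", "Pr > F"]
    )


def test_partial_eta_sq_is_ss_ratio():
    rng = np.random.default_rng(11)
    m = make_cell_matrix(rng.normal(size=(7, 4)))
    res = RepeatedMeasures2x2(m).fit()
    v = m.to_numpy()
    n = len(v)
    # explicit sums of squares for the expectation effect
    scores = v[:, 2:].mean(axis=1) - v[:, :2].mean(axis=1)
    ss_eff = n * scores.mean() ** 2
    ss_err = ((scores - scores.mean()) ** 2).sum()
    expected = ss_eff / (ss_eff + ss_err)
    assert res.anova_table.loc["expectation", "partial_eta_sq"] == pytest.approx(
        expected
    )


def test_constant_cells_give_zero_f():
    m = make_cell_matrix(np.tile(np.array([1.0, 1.0, 1.0, 1.0]), (5, 1)) * np.arange(1, 6)[:, None])
    res = RepeatedMeasures2x2(m).fit()
    assert (res.anova_table["F"] == 0.0).all()


def test_factor_swap_exchanges_main_effects():
    rng = np.random.default_rng(12)
    v = rng.normal(size=(8, 4))
    res = RepeatedMeasures2x2(make_cell_matrix(v)).fit()
    # swapping factor roles = reordering columns [pc, pn, uc, un] -> [pc, uc, pn, un]
    swapped = v[:, [0, 2, 1, 3]]
    res2 = RepeatedMeasures2x2(make_cell_matrix(swapped)).fit()
    assert res.anova_table.loc["expectation", "F"] == pytest.approx(
        res2.anova_table.loc["shape_status", "F"]
    )
    assert res.anova_table.loc["interaction", "F"] == pytest.approx(
        res2.anova_table.loc["interaction", "F"]
    )


def test_zero_error_variance_warns_infinite_f():
    v = np.tile(np.array([0.0, 0.0, 1.0, 1.0]), (4, 1))  # identical effect, no noise
    with pytest.warns(UserWarning, match="zero error variance"):
        res = RepeatedMeasures2x2(make_cell_matrix(v)).fit()
    assert np.isinf(res.anova_table.loc["expectation", "F"])


def test_incomplete_matrix_rejected():
    m = make_cell_matrix(np.ones((3, 4)))
    m.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        RepeatedMeasures2x2(m)


# ---------------------------------------------------------------------------
# Cousineau-Morey intervals

def test_cm_ci_zero_interaction_variance():
    # every subject = grand pattern + own offset -> centred data identical
    pattern = np.array([1.0, 2.0, 3.0, 4.0])
    v = pattern[None, :] + np.array([0.0, 5.0, -3.0])[:, None]
    ci = cousineau_morey_ci(make_cell_matrix(v))
    assert np.allclose(ci.to_numpy(), 0.0)


def test_cm_ci_hand_computed_n3():
    v = np.array(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 1.0, 5.0, 2.0],
         [0.0, 3.0, 2.0, 6.0]]
    )
    # spreadsheet-style oracle
    centred = v - v.mean(axis=1, keepdims=True) + v.mean()
    sem = centred.std(axis=0, ddof=1) / np.sqrt(3)
    expected = sem * sst.t.ppf(0.975, 2) * np.sqrt(4.0 / 3.0)
    got = cousineau_morey_ci(make_cell_matrix(v)).to_numpy()
    assert np.allclose(got, expected)


@settings(deadline=None, max_examples=25)
@given(
    scale=st.floats(0.1, 10),
    offsets=st.lists(st.floats(-100, 100), min_size=4, max_size=4),
)
def test_cm_ci_scaling_and_subject_offset_invariance(scale, offsets):
    rng = np.random.default_rng(13)
    v = rng.normal(size=(4, 4))
    base = cousineau_morey_ci(make_cell_matrix(v)).to_numpy()
    assert np.allclose(
        cousineau_morey_ci(make_cell_matrix(v * scale)).to_numpy(),
        base * scale, atol=1e-9,
    )
    shifted = v + np.asarray(offsets)[:, None]
    assert np.allclose(
        cousineau_morey_ci(make_cell_matrix(shifted)).to_numpy(), base, atol=1e-9
    )


# ---------------------------------------------------------------------------
# Cook's distance

def test_cooks_identical_subjects_zero():
    v = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1))
    d = cooks_distance(make_cell_matrix(v))
    assert np.allclose(d["cooks_d"], 0.0)
    assert not d["flagged"].any()


def test_cooks_flags_displaced_subject():
    rng = np.random.default_rng(14)
    v = rng.normal(size=(8, 4))
    v[3] += 25.0
    d = cooks_distance(make_cell_matrix(v))
    assert d["cooks_d"].idxmax() == "S3"
    assert d.loc["S3", "flagged"]


def test_cooks_matches_regression_oracle():
    rng = np.random.default_rng(15)
    v = rng.normal(size=(5, 4))
    got = cooks_distance(make_cell_matrix(v), contrast="mean")["cooks_d"].to_numpy()
    import statsmodels.api as sm

    y = v.mean(axis=1)
    fit = sm.OLS(y, np.ones((5, 1))).fit()
    expected = fit.get_influence().cooks_distance[0]
    assert np.allclose(got, expected)


def test_cooks_needs_more_than_two_subjects():
    with pytest.raises(DegenerateDataError):
        cooks_distance(make_cell_matrix(np.ones((2, 4))))


# ---------------------------------------------------------------------------
# pointwise t and clusters

def test_pointwise_t_hand_formula():
    # subject values 0.5, 1.0, 1.0, 1.5 at every timepoint:
    # mean 1, sd sqrt(1/6)... use the documented example instead:
    waves = np.array([[0.5], [1.5], [0.5], [1.5]]) * np.ones((1, 10))
    # mean 1.0, sd = 0.5773.., n=4
    t = pointwise_t(waves)
    expected = 1.0 / (waves[:, 0].std(ddof=1) / 2.0)
    assert np.allclose(t, expected)


def test_pointwise_t_degenerate_zero_handled():
    with pytest.warns(UserWarning, match="zero between-subject variance"):
        t = pointwise_t(np.zeros((3, 5)))
    assert np.allclose(t, 0.0)


def test_pointwise_t_antisymmetry():
    rng = np.random.default_rng(16)
    x = rng.normal(size=(6, 40))
    assert np.allclose(pointwise_t(-x), -pointwise_t(x))


@pytest.mark.parametrize(
    "t_series,threshold,expected",
    [
        ([0, 3, 3, 0], 2.0, [(1, 2, 6.0)]),
        ([3, -3], 2.0, [(0, 0, 3.0), (1, 1, -3.0)]),
        ([1, 1.5, -1], 2.0, []),
        ([0, -2.5, -2.5, 2.5, 0], 2.0, [(1, 2, -5.0), (3, 3, 2.5)]),
    ],
)
def test_form_clusters_examples(t_series, threshold, expected):
    got = [
        (c.start_idx, c.end_idx, c.summed_t)
        for c in form_clusters(np.array(t_series, float), threshold)
    ]
    assert got == expected


def test_form_clusters_min_length_and_bad_threshold():
    t = np.array([3.0, 0.0, 3.0, 3.0])
    assert len(form_clusters(t, 2.0, min_length=2)) == 1
    with pytest.raises(ValueError):
        form_clusters(t, 0.0)


@settings(deadline=None, max_examples=30)
@given(
    tmat=arrays(
        float, st.tuples(st.integers(1, 6), st.integers(1, 40)),
        elements=st.floats(-5, 5, allow_nan=False, width=32),
    )
)
def test_vectorised_max_cluster_matches_scalar_path(tmat):
    """The permutation fast path agrees with per-row cluster formation."""
    fast = _max_cluster_stats(tmat, 2.0)
    for row, got in zip(tmat, fast):
        clusters = form_clusters(row, 2.0)
        expected = max((abs(c.summed_t) for c in clusters), default=0.0)
        assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# sign-flip permutation null

def test_null_all_zero_waveforms():
    null = signflip_null(np.zeros((4, 20)), n_perm=50, height_threshold=2.0, seed=0)
    assert np.allclose(null, 0.0)


def test_null_seed_determinism():
    rng = np.random.default_rng(17)
    x = rng.normal(size=(6, 50))
    a = signflip_null(x, 200, 2.0, seed=5)
    b = signflip_null(x, 200, 2.0, seed=5)
    c = signflip_null(x, 200, 2.0, seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_montecarlo_null_converges_to_exhaustive_n3():
    """With 3 subjects the 8 equally likely sign patterns are enumerable;
    the Monte-Carlo null must reproduce their distribution."""
    rng = np.random.default_rng(18)
    x = rng.normal(0.8, 1.0, size=(3, 30))
    exact = signflip_null(x, 0, 2.0, exhaustive=True)
    assert len(exact) == 8
    mc = signflip_null(x, 8000, 2.0, seed=1)
    # compare survival functions at the exact null's support points
    for q in np.unique(exact):
        p_exact = (exact >= q - 1e-12).mean()
        p_mc = (mc >= q - 1e-12).mean()
        se = np.sqrt(p_exact * (1 - p_exact) / 8000)
        assert abs(p_mc - p_exact) < 4 * se + 1e-3


# ---------------------------------------------------------------------------
# the full cluster test

def test_cluster_test_detects_injected_effect_and_reports_window():
    rng = np.random.default_rng(19)
    times = np.arange(-100.0, 501.0, 4.0)
    effect = np.where((times >= 200) & (times <= 300), -1.0, 0.0)
    waves = effect[None, :] + rng.normal(0, 0.8, size=(16, len(times)))
    res = ClusterPermutationTest(waves, times, n_perm=500).fit(seed=2)
    assert res.any_significant
    sig = res.clusters[res.clusters.significant]
    # the significant cluster overlaps the injected window
    assert ((sig.start_ms <= 300) & (sig.end_ms >= 200)).any()
    assert res.height_threshold == pytest.approx(sst.t.ppf(0.975, 15))


def test_cluster_test_p_floor_and_determinism():
    rng = np.random.default_rng(20)
    times = np.arange(100.0)
    waves = rng.normal(1.0, 0.5, size=(8, 100))
    r1 = ClusterPermutationTest(waves, times, n_perm=300).fit(seed=3)
    r2 = ClusterPermutationTest(waves, times, n_perm=300).fit(seed=3)
    assert r1.clusters.equals(r2.clusters)
    assert (r1.clusters["p"] >= 1.0 / 301).all()


def test_cluster_test_rejects_zero_permutations():
    with pytest.raises(ValueError, match="n_perm"):
        ClusterPermutationTest(np.zeros((3, 10)), np.arange(10.0), n_perm=0)


def test_height_threshold_df35_matches_reference_value():
    """At 36 subjects the two-tailed 5% critical t is 2.0301 (df = 35)."""
    res = ClusterPermutationTest(
        np.random.default_rng(21).normal(size=(36, 20)), np.arange(20.0), n_perm=1
    )
    assert res.height_threshold == pytest.approx(2.0301, abs=5e-4)
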