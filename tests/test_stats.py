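"""Regional aggregation, t-tests, BH correction, sex bootstrap, cognition OLS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortexage import (
    LbaMap,
    Parcellation,
    SurfaceSample,
    benjamini_hochberg,
    build_hierarchy,
    cognition_regression,
    cohort_difference_tests,
    geodesic_parcellation,
    region_vs_ca_tests,
    regional_means,
    sex_bootstrap,
)


def hand_t_pooled(a, b):
    """Textbook equal-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


@pytest.fixture
def toy_parc():
    # two regions over 4 vertices, plus one wall vertex
    return Parcellation(labels=np.array([0, 0, 1, 1, -1]))


def test_regional_means_examples(toy_parc):
    const = LbaMap(lba=np.full(5, 3.3))
    assert regional_means(const, toy_parc) == {0: pytest.approx(3.3), 1: pytest.approx(3.3)}
    toy = LbaMap(lba=np.array([1.0, 1.0, 2.0, 4.0, 99.0]))
    means = regional_means(toy, toy_parc)
    assert means[0] == pytest.approx(1.0) and means[1] == pytest.approx(3.0)


def test_regional_means_matches_loop_oracle(rng):
    labels = rng.integers(0, 5, size=50)
    labels[:3] = -1
    parc = Parcellation(labels=labels)
    vals = rng.standard_normal(50)
    got = regional_means(LbaMap(lba=vals), parc)
    for r in parc.region_ids:
        assert got[r] == pytest.approx(np.mean([vals[i] for i in range(50) if labels[i] == r]))


def test_regional_means_respects_wall_removed_maps(rng):
    labels = np.array([0, 0, 1, 1, -1])
    parc = Parcellation(labels=labels)
    keep = np.array([0, 1, 2, 3])
    m = LbaMap(lba=np.array([1.0, 3.0, 5.0, 7.0]), vertex_index=keep)
    means = regional_means(m, parc)
    assert means[0] == pytest.approx(2.0) and means[1] == pytest.approx(6.0)


def test_region_vs_ca_identical_vectors(toy_parc):
    cas = np.array([70.0, 72.0, 74.0])
    regional = np.tile(cas[:, None], (1, 2))
    df = region_vs_ca_tests(regional, cas, toy_parc)
    assert np.allclose(df["t"], 0.0) and np.allclose(df["p"], 1.0)
    assert not df["significant"].any()


def test_region_vs_ca_matches_hand_formula(toy_parc):
    lba = np.array([70.0, 72.0, 74.0])
    cas = np.array([60.0, 62.0, 64.0])
    regional = np.tile(lba[:, None], (1, 2))
    df = region_vs_ca_tests(regional, cas, toy_parc)
    assert df["t"].iloc[0] == pytest.approx(hand_t_pooled(lba, cas), abs=1e-12)
    assert df["mean"].iloc[0] == pytest.approx(10.0)


def test_region_vs_ca_shift_invariance(toy_parc, rng):
    lba = rng.uniform(60, 90, size=8)
    cas = rng.uniform(60, 90, size=8)
    regional = np.tile(lba[:, None], (1, 2))
    d1 = region_vs_ca_tests(regional, cas, toy_parc)
    d2 = region_vs_ca_tests(regional + 5.0, cas + 5.0, toy_parc)
    assert np.allclose(d1["t"], d2["t"], atol=1e-10)


def test_bh_step_up_by_hand():
    # step-up on {0.01, 0.02, 0.03, 0.04}: p_(i) * 4 / i, cummin from the top
    adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, 0.04, atol=1e-12)


@given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_monotone_and_bounded(pvals):
    p = np.array(pvals)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0 + 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_cohort_difference_identical_cohorts(toy_parc, rng):
    a = rng.standard_normal((6, 2))
    df = cohort_difference_tests(a, a.copy(), toy_parc)
    assert np.allclose(df["mean"], 0.0) and np.allclose(df["p"], 1.0)


def test_cohort_difference_shifted_cohort(toy_parc, rng):
    a = rng.standard_normal((6, 2))
    df = cohort_difference_tests(a + 2.0, a, toy_parc)
    assert np.allclose(df["mean"], 2.0, atol=1e-12)


def test_cohort_difference_matches_hand_formula(toy_parc, rng):
    a = rng.standard_normal((7, 2)) + 1.0
    b = rng.standard_normal((9, 2))
    df = cohort_difference_tests(a, b, toy_parc)
    for j in range(2):
        assert df["t"].iloc[j] == pytest.approx(hand_t_pooled(a[:, j], b[:, j]), abs=1e-12)


def test_geodesic_parcellation_covers_cortex():
    h = build_hierarchy((0, 1))
    mesh, wall = h.finest, h.medial_wall[-1]
    parc = geodesic_parcellation(mesh, wall, regions_per_hemisphere=4)
    assert (parc.labels[wall] == -1).all()
    assert (parc.labels[~wall] >= 0).all()
    assert len(parc.region_ids) == 8
    # deterministic
    parc2 = geodesic_parcellation(mesh, wall, regions_per_hemisphere=4)
    assert np.array_equal(parc.labels, parc2.labels)


# --------------------------------------------------------------- sex bootstrap
def make_sex_cohort(cas, sexes):
    return [SurfaceSample(features=np.zeros((3, 5)), ca=float(c), sex=int(s))
            for c, s in zip(cas, sexes)]


def test_sex_bootstrap_identical_maps_degenerate_at_zero():
    cas = [60.2, 60.7, 61.3, 61.8]
    cohort = make_sex_cohort(cas, [1, 0, 1, 0])
    gbags = np.array([1.5, 1.5, 1.5, 1.5])
    out = sex_bootstrap(cohort, gbags, reps=50, seed=0)
    assert np.allclose(out["global"], 0.0)


def test_sex_bootstrap_single_pair_point_mass():
    cohort = make_sex_cohort([70.1, 70.9], [1, 0])
    gbags = np.array([2.0, -1.0])
    out = sex_bootstrap(cohort, gbags, reps=30, seed=1)
    assert np.allclose(out["global"], 3.0)


def test_sex_bootstrap_recovers_known_offset(rng):
    cas = rng.uniform(60, 80, size=200)
    sexes = rng.integers(0, 2, size=200)
    gbags = rng.standard_normal(200) * 0.5 + 1.0 * sexes  # +1 y male offset
    cohort = make_sex_cohort(cas, sexes)
    out = sex_bootstrap(cohort, gbags, reps=500, seed=2)
    lo, hi = out["global_ci"]
    assert lo <= 1.0 <= hi
    assert out["global_mean"] == pytest.approx(1.0, abs=0.3)


def test_sex_bootstrap_reproducible_and_errors(rng):
    cas = rng.uniform(60, 70, size=40)
    sexes = rng.integers(0, 2, size=40)
    gbags = rng.standard_normal(40)
    cohort = make_sex_cohort(cas, sexes)
    a = sex_bootstrap(cohort, gbags, reps=100, seed=7)
    b = sex_bootstrap(cohort, gbags, reps=100, seed=7)
    assert np.array_equal(a["global"], b["global"])
    males_only = make_sex_cohort([60.5, 61.5], [1, 1])
    with pytest.raises(ValueError):
        sex_bootstrap(males_only, np.zeros(2), reps=10, seed=0)


# ------------------------------------------------------------------ cognition
def make_cog_cohort(bags, scores, cas, sexes, edu, test="composite"):
    return [
        SurfaceSample(features=np.zeros((3, 5)), ca=float(c), sex=int(s),
                      education_years=float(e), scores={test: float(sc)})
        for sc, c, s, e in zip(scores, cas, sexes, edu)
    ], np.asarray(bags, float)


def test_cognition_regression_exact_linear_relation(rng):
    n = 60
    cas = rng.uniform(60, 90, size=n)
    sexes = rng.integers(0, 2, size=n)
    edu = rng.uniform(8, 20, size=n)
    score = rng.standard_normal(n)
    score_z = (score - score.mean()) / score.std()
    bags = 2.0 * score_z
    cohort, bags = make_cog_cohort(bags, score, cas, sexes, edu)
    res = cognition_regression(cohort, bags, "composite")
    assert res["beta"] == pytest.approx(2.0, abs=1e-8)
    assert res["p"] < 1e-12
    assert res["transform"]["flipped"] is False


def test_cognition_regression_sign_flip_orients_higher_worse(rng):
    n = 50
    cas = rng.uniform(60, 90, size=n)
    sexes = rng.integers(0, 2, size=n)
    edu = rng.uniform(8, 20, size=n)
    score = rng.standard_normal(n)  # pretend MMSE: higher = better
    bags = -1.5 * (score - score.mean()) / score.std()  # worse memory, higher gap
    cohort, bags = make_cog_cohort(bags, score, cas, sexes, edu, test="MMSE")
    res = cognition_regression(cohort, bags, "MMSE")
    assert res["transform"]["flipped"] is True
    assert res["beta"] == pytest.approx(1.5, abs=1e-8)  # positive after flip


def test_cognition_regression_tmtb_ceiling_exclusion(rng):
    n = 40
    cas = rng.uniform(60, 90, size=n)
    scores = rng.uniform(50, 250, size=n)
    scores[:5] = 300.0  # ceiling values must be dropped
    cohort, bags = make_cog_cohort(rng.standard_normal(n), scores, cas,
                                   rng.integers(0, 2, size=n),
                                   rng.uniform(8, 20, size=n), test="TMT_B")
    res = cognition_regression(cohort, bags, "TMT_B")
    assert res["n"] == n - 5


def test_cognition_regression_collinear_sex_rejected(rng):
    n = 30
    cohort, bags = make_cog_cohort(
        rng.standard_normal(n), rng.standard_normal(n),
        rng.uniform(60, 90, size=n), np.zeros(n), rng.uniform(8, 20, size=n)
    )
    with pytest.raises(ValueError, match="sex"):
        cognition_regression(cohort, bags, "composite")


def test_cognition_regression_null_calibration():
    """Independent score and gap: p > 0.05 in >= 90 % of 100 null replicates."""
    n = 500
    rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(100):
        cas = rng.uniform(60, 90, size=n)
        sexes = rng.integers(0, 2, size=n)
        edu = rng.uniform(8, 20, size=n)
        score = rng.standard_normal(n)
        bags = rng.standard_normal(n)  # independent of score
        cohort, b = make_cog_cohort(bags, score, cas, sexes, edu)
        res = cognition_regression(cohort, b, "composite")
        if res["p"] <= 0.05:
            rejections += 1
    assert rejections <= 10
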