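"""Interrater reliability: slicing, agreement, kappa, alpha, diagnostics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import semannot as sa
from semannot.errors import MetricsUndefinedError

from oracle_utils import naive_slice


def test_slice_example():
    tier = sa.AnnotationTier("r", "A", [sa.Segment(0, 100, "take-knife-drawer")])
    series = sa.slice_tier(tier, resolution=50, horizon=200)
    assert series.labels == ["take-knife-drawer", "take-knife-drawer", "NONE", "NONE"]


def test_gap_free_tier_has_no_none_before_end(tier_factory):
    tier = tier_factory([(130, "a-x"), (70, "b-y"), (200, "a-x")])
    series = sa.slice_tier(tier, resolution=10, horizon=tier.end)
    assert "NONE" not in series.labels


def test_slicer_matches_per_millisecond_oracle(tier_factory):
    rng = np.random.default_rng(99)
    for _ in range(20):
        pairs = [
            (int(rng.integers(1, 400)), str(rng.choice(["a-x", "b-y", "c-z"])))
            for _ in range(int(rng.integers(1, 10)))
        ]
        tier = tier_factory(pairs)
        horizon = tier.end + int(rng.integers(0, 300))
        res = int(rng.integers(1, 60))
        assert sa.slice_tier(tier, res, horizon).labels == naive_slice(tier, res, horizon)


def test_identical_tiers_perfect_metrics(tier_factory):
    a = tier_factory([(500, "take-a-b"), (700, "put-a-b"), (300, "other")])
    result = sa.interrater(a, a)
    assert result.agreement == 1.0 and result.kappa == 1.0 and result.alpha == 1.0


def test_hand_computed_kappa():
    # A=[x,x,y,y], B=[x,y,y,y]: p_o=0.75, p_e=0.5*0.25+0.5*0.75=0.5, kappa=0.5
    result = sa.score_series(["x", "x", "y", "y"], ["x", "y", "y", "y"])
    assert result.agreement == pytest.approx(0.75)
    assert result.kappa == pytest.approx(0.5)
    assert result.n_slices == 4
    assert result.confusion.loc["x", "x"] == 1 and result.confusion.loc["y", "y"] == 2


def test_kappa_near_zero_under_independent_null():
    rng = np.random.default_rng(20180823)
    n = 100_000
    a = [str(x) for x in rng.integers(0, 4, n)]
    b = [str(x) for x in rng.integers(0, 4, n)]
    result = sa.score_series(a, b)
    assert abs(result.kappa) < 0.02


def test_kappa_matches_sklearn_oracle():
    rng = np.random.default_rng(5)
    a = [str(x) for x in rng.integers(0, 5, 4000)]
    b = [str(x) for x in np.where(rng.random(4000) < 0.6, a, rng.integers(0, 5, 4000))]
    result = sa.score_series(a, b)
    assert result.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_alpha_approaches_kappa_for_large_n():
    rng = np.random.default_rng(17)
    n = 100_000
    a = [str(x) for x in rng.integers(0, 3, n)]
    b = [str(x) for x in np.where(rng.random(n) < 0.7, a, rng.integers(0, 3, n))]
    result = sa.score_series(a, b)
    assert abs(result.alpha - result.kappa) < 1.0 / n * 10


def test_kappa_equals_agreement_when_chance_is_zero():
    # disjoint label sets: p_e = 0
    result = sa.score_series(["x"] * 10, ["y"] * 10)
    assert result.kappa == pytest.approx(result.agreement) == 0.0


def test_metrics_invariant_under_label_renaming():
    rng = np.random.default_rng(8)
    a = [f"l{x}" for x in rng.integers(0, 4, 2000)]
    b = [f"l{x}" for x in rng.integers(0, 4, 2000)]
    mapping = {"l0": "w", "l1": "x", "l2": "y", "l3": "z"}
    r1 = sa.score_series(a, b)
    r2 = sa.score_series([mapping[x] for x in a], [mapping[x] for x in b])
    assert r1.agreement == r2.agreement
    assert r1.kappa == pytest.approx(r2.kappa)
    assert r1.alpha == pytest.approx(r2.alpha)


def test_swapping_annotators_transposes_confusion(tier_factory):
    a = tier_factory([(500, "take-a-b"), (500, "put-a-b")])
    b = tier_factory([(400, "take-a-b"), (600, "other")])
    r_ab = sa.interrater(a, b)
    r_ba = sa.interrater(b, a)
    assert r_ab.agreement == r_ba.agreement
    assert r_ab.kappa == pytest.approx(r_ba.kappa)
    assert (r_ab.confusion.values == r_ba.confusion.values.T).all()


def test_class_level_coarsens_ground_level(tier_factory):
    a = tier_factory([(500, "take-knife-drawer"), (500, "put-knife-board")])
    b = tier_factory([(500, "take-knife-board"), (500, "put-knife-board")])
    ground = sa.interrater(a, b)
    klass = sa.interrater(a, b, class_level=True)
    assert ground.agreement == pytest.approx(0.5)
    assert klass.agreement == pytest.approx(1.0)


def test_both_tiers_empty_is_undefined():
    empty = sa.AnnotationTier("r", "A", [])
    with pytest.raises(MetricsUndefinedError):
        sa.interrater(empty, empty)


def test_different_runs_rejected(tier_factory):
    a = tier_factory([(100, "other")], run_id="r1")
    b = tier_factory([(100, "other")], run_id="r2")
    with pytest.raises(ValueError, match="different runs"):
        sa.interrater(a, b)


# -- disagreement diagnostics ------------------------------------------------


def test_diff_identical_tiers_empty(tier_factory):
    a = tier_factory([(500, "take-a-b"), (700, "put-a-b")])
    assert sa.diff_segments(a, a) == []


def test_uniform_shift_classified_as_boundary_shift(tier_factory):
    a = tier_factory([(1000, "take-a-b"), (1000, "put-a-b"), (1000, "other")])
    b = tier_factory([(1000, "take-a-b"), (1000, "put-a-b"), (1000, "other")], start=200)
    diffs = sa.diff_segments(a, b, window=1000)
    assert diffs
    assert all(d.kind == "boundary_shift" for d in diffs)


def test_substitution_classified(tier_factory):
    a = tier_factory([(5000, "take-a-b")])
    b = tier_factory([(5000, "put-a-b")])
    (diff,) = sa.diff_segments(a, b, window=1000)
    assert diff.kind == "substitution"
    assert (diff.label_a, diff.label_b) == ("take-a-b", "put-a-b")


def test_diff_duration_complements_agreement(brownie_domain):
    config = sa.GeneratorConfig(seed=23, max_plan_length=25, jitter_sd=400, confusion_rate=0.2)
    rng = config.rng()
    _, tier = sa.gen_plan(brownie_domain, config, rng=rng)
    corrupt = sa.corrupt_tier(tier, config, rng=rng, label_pool=brownie_domain.labels())
    horizon = max(tier.end, corrupt.end)
    result = sa.interrater(tier, corrupt, resolution=1)
    diff_ms = sum(d.end - d.start for d in sa.diff_segments(tier, corrupt))
    assert diff_ms == pytest.approx((1 - result.agreement) * horizon, abs=1)


# -- learning curve ----------------------------------------------------------


def test_learning_curve_flat_for_identical_pairs(tier_factory):
    t = tier_factory([(500, "take-a-b"), (500, "put-a-b")])
    results, diffs, slope = sa.learning_curve([(t, t), (t, t), (t, t)])
    assert [r.agreement for r in results] == [1.0, 1.0, 1.0]
    assert diffs == [0.0, 0.0]
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_learning_curve_differences(tier_factory):
    def pair(agree_pct):
        a = tier_factory([(100, "x-l")])
        b = tier_factory([(agree_pct, "x-l"), (100 - agree_pct, "y-l")])
        return a, b

    pairs = [pair(50), pair(73), pair(96)]
    results, diffs, slope = sa.learning_curve(pairs, resolution=1)
    assert [r.agreement for r in results] == pytest.approx([0.50, 0.73, 0.96])
    assert diffs == pytest.approx([0.23, 0.23])
    assert slope == pytest.approx(0.23)


def test_learning_curve_positive_slope_for_decreasing_jitter(brownie_domain):
    base = sa.GeneratorConfig(seed=31, max_plan_length=25, confusion_rate=0.0)
    rng = base.rng()
    plan_tier = [sa.gen_plan(brownie_domain, base, rng=rng)[1] for _ in range(4)]
    pairs = []
    for tier, jitter in zip(plan_tier, [900.0, 500.0, 200.0, 30.0]):
        cfg = sa.GeneratorConfig(seed=base.seed, jitter_sd=jitter, confusion_rate=0.0)
        pairs.append((tier, sa.corrupt_tier(tier, cfg, rng=rng)))
    _, _, slope = sa.learning_curve(pairs)
    assert slope > 0
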