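"""Point assignment: scores, initializer choice and the affine maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nomolog as nl
from nomolog.model_meta import ModelSpec, PredictorSpec
from conftest import build, random_built


def pred(coef, lo, hi, name="x", dtype="continuous"):
    return PredictorSpec(name=name, coef=coef, min=lo, max=hi,
                         dtype=dtype, position="up")


@pytest.mark.parametrize("coef,lo,hi,expected", [
    (0.5492, 0.0, 1.0, 0.5492),   # binary underlying-disease predictor
    (0.0, -3.0, 9.0, 0.0),
    (-0.0771, 0.0, 20.0, 1.542),  # negative coefficient, width 20
])
def test_absolute_max_beta(coef, lo, hi, expected):
    assert nl.absolute_max_beta(pred(coef, lo, hi)) == pytest.approx(expected)


class TestInitializer:
    def test_cmv_initializer_is_prednisone(self, cmv):
        # scores: 3.22, 0.0696, 0.5492, 4.815, 1.542 -> index 3
        assert nl.select_initializer(cmv.model) == 3
        assert cmv.scales.scales[3].max_points == 100.0

    def test_tie_breaks_to_file_order(self):
        model = ModelSpec(0.0, None, (pred(1.0, 0.0, 1.0, "a"),
                                      pred(-1.0, 0.0, 1.0, "b")))
        assert nl.select_initializer(model) == 0

    def test_single_predictor(self):
        model = ModelSpec(0.0, None, (pred(0.3, 0.0, 2.0),))
        assert nl.select_initializer(model) == 0

    def test_all_zero_scores_raise(self):
        model = ModelSpec(0.0, None, (pred(0.0, 0.0, 1.0),))
        with pytest.raises(nl.ModelConstructionError,
                           match="no informative predictor"):
            nl.select_initializer(model)


def test_max_points_is_score_ratio_times_pmax():
    p = pred(0.5492, 0.0, 1.0)
    assert nl.point_engine.max_points(p, initializer_score=2.746) == pytest.approx(20.0)
    assert nl.point_engine.max_points(p, nl.absolute_max_beta(p)) == 100.0
    with pytest.raises(nl.ModelConstructionError):
        nl.point_engine.max_points(p, initializer_score=0.0)


class TestValueToPoints:
    def test_boundaries_follow_orientation(self):
        up = build(ModelSpec(0.0, None, (pred(2.0, 1.0, 5.0),)))
        s, p = up.scales.scales[0], up.model.predictors[0]
        assert nl.value_to_points(s, p, 1.0) == 0.0
        assert nl.value_to_points(s, p, 5.0) == 100.0
        down = build(ModelSpec(0.0, None, (pred(-2.0, 1.0, 5.0),)))
        s, p = down.scales.scales[0], down.model.predictors[0]
        assert nl.value_to_points(s, p, 5.0) == 0.0
        assert nl.value_to_points(s, p, 1.0) == 100.0

    def test_midpoint_interpolates_linearly(self):
        b = build(ModelSpec(0.0, None, (pred(1.0, 0.0, 1.0),)))
        s, p = b.scales.scales[0], b.model.predictors[0]
        assert nl.value_to_points(s, p, 0.5) == pytest.approx(50.0)

    def test_strict_mode_rejects_out_of_range(self):
        b = build(ModelSpec(0.0, None, (pred(1.0, 0.0, 1.0),)))
        s, p = b.scales.scales[0], b.model.predictors[0]
        with pytest.raises(ValueError, match="outside its range"):
            nl.value_to_points(s, p, 1.5)
        assert nl.value_to_points(s, p, 1.5, strict=False) == 100.0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_sign_of_coefficient(self, seed):
        b = random_built(seed, d=3)
        rng = np.random.default_rng(seed + 1000)
        for s, p in zip(b.scales.scales, b.model.predictors):
            vs = np.sort(rng.uniform(p.min, p.max, size=20))
            pts = [nl.value_to_points(s, p, v) for v in vs]
            diffs = np.diff(pts)
            assert np.all(diffs >= -1e-12) if p.coef >= 0 else np.all(diffs <= 1e-12)


def test_points_to_value_inverts_value_to_points():
    b = random_built(3, d=4)
    rng = np.random.default_rng(42)
    for s, p in zip(b.scales.scales, b.model.predictors):
        for v in rng.uniform(p.min, p.max, size=25):
            pts = nl.value_to_points(s, p, v)
            assert nl.points_to_value(s, p, pts) == pytest.approx(v, abs=1e-9 * max(1, abs(v)))
    s, p = b.scales.scales[0], b.model.predictors[0]
    assert nl.points_to_value(s, p, 0.0) == (p.min if p.coef >= 0 else p.max)


@settings(derandomize=True, max_examples=200)
@given(lo=st.floats(-50.0, 50.0), span=st.floats(0.01, 100.0),
       coef=st.floats(-5.0, 5.0).filter(lambda c: abs(c) > 1e-3),
       frac=st.floats(0.0, 1.0))
def test_affine_map_round_trip_property(lo, span, coef, frac):
    """value -> points -> value is the identity over the whole range,
    for either coefficient sign."""
    p = pred(coef, lo, lo + span)
    b = build(ModelSpec(0.0, None, (p,)))
    scale = b.scales.scales[0]
    v = lo + frac * span
    pts = nl.value_to_points(scale, p, v)
    assert 0.0 <= pts <= 100.0
    back = nl.points_to_value(scale, p, pts)
    assert back == pytest.approx(v, abs=1e-7 * max(1.0, abs(lo) + span))


def test_points_to_value_rejects_degenerate_scale():
    model = ModelSpec(0.0, None, (pred(1.0, 0.0, 1.0, "a"),
                                  pred(0.0, 0.0, 1.0, "b")))
    b = build(model)
    with pytest.raises(ValueError, match="zero-length"):
        nl.points_to_value(b.scales.scales[1], model.predictors[1], 0.0)


class TestScaleSetInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_initializer_attains_pmax_and_others_do_not_exceed(self, seed):
        b = random_built(seed, d=5)
        maxima = [s.max_points for s in b.scales.scales]
        assert maxima[b.scales.initializer_index] == 100.0
        assert all(0.0 <= m <= 100.0 + 1e-12 for m in maxima)

    @pytest.mark.parametrize("c", [2.0, 0.5, 3.7, 1e3])
    def test_rescaling_all_coefficients_leaves_scales_unchanged(self, c):
        model = nl.random_model(nl.FixtureConfig(d=4, seed=11))
        scaled = ModelSpec(model.intercept, model.threshold, tuple(
            PredictorSpec(p.name, p.coef * c, p.min, p.max, p.dtype, p.position)
            for p in model.predictors))
        a, b = build(model).scales, build(scaled).scales
        assert a.initializer_index == b.initializer_index
        for sa, sb in zip(a.scales, b.scales):
            assert sa.max_points == pytest.approx(sb.max_points, rel=1e-12)

    def test_custom_pmax_scales_everything(self):
        model = nl.cmv_model()
        s50 = nl.build_point_scales(model, p_max=50.0)
        s100 = nl.build_point_scales(model, p_max=100.0)
        for a, b in zip(s50.scales, s100.scales):
            assert a.max_points == pytest.approx(b.max_points / 2.0)
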