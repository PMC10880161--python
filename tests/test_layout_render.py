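"""Geometry computation and figure rendering."""

import pytest

import nomolog as nl
from nomolog.model_meta import ModelSpec, PredictorSpec
from conftest import build


class TestGenerateTicks:
    def test_round_number_span(self):
        assert nl.generate_ticks(0.0, 100.0, 11) == [
            0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]

    def test_unit_span(self):
        assert nl.generate_ticks(0.0, 1.0, 6) == [0, 0.2, 0.4, 0.6, 0.8, 1.0]

    def test_degenerate_span_keeps_endpoints_only(self):
        assert nl.generate_ticks(5.0, 5.0001, 11) == [5.0, 5.0001]

    def test_endpoints_always_included(self):
        ticks = nl.generate_ticks(3.0, 97.0, 11)
        assert ticks[0] == 3.0 and ticks[-1] == 97.0

    @pytest.mark.parametrize("lo,hi,target", [
        (0.0, 7.3, 5), (-12.0, 45.0, 11), (0.01, 0.92, 8), (100.0, 5000.0, 11)])
    def test_count_within_band_and_sorted(self, lo, hi, target):
        ticks = nl.generate_ticks(lo, hi, target)
        assert target / 2 <= len(ticks) <= 2 * target
        assert ticks == sorted(ticks)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            nl.generate_ticks(1.0, 1.0, 5)
        with pytest.raises(ValueError):
            nl.generate_ticks(0.0, 1.0, 1)


class TestComputeLayout:
    def test_cmv_has_eight_axis_slots(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        kinds = [a.kind for a in g.axes]
        assert kinds[0] == "points_ruler"
        assert kinds[-2:] == ["total_ruler", "probability_panel"]
        assert kinds.count("predictor") == 5
        assert len(g.axes) == 3 + g.n_predictor_axes == 8

    def test_nominal_group_merges_onto_one_axis(self):
        b = build(nl.random_model(nl.FixtureConfig(
            d=2, seed=0, range_styles=("nominal-3", "unit"))))
        g = nl.compute_layout(b.model, b.scales, b.pm)
        pred_axes = [a for a in g.axes if a.kind == "predictor"]
        assert len(pred_axes) == 2
        merged = next(a for a in pred_axes if len(a.predictor_indices) == 3)
        assert merged.style == "dashed"
        labels = [t[1] for t in merged.ticks]
        assert set(labels) >= {"L1", "L2", "L3"}

    def test_axis_styles_follow_data_types(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        by_name = {a.name: a for a in g.axes if a.kind == "predictor"}
        assert by_name["age"].style == "solid"
        assert by_name["gender"].style == "dashed"
        assert by_name["underlying_disease"].style == "dashed"
        assert by_name["gender"].label_side == "down"

    def test_negative_binary_orientation(self):
        model = ModelSpec(0.0, None, (
            PredictorSpec("flag", -1.0, 0.0, 1.0, "discrete", "up"),))
        b = build(model)
        g = nl.compute_layout(b.model, b.scales, b.pm)
        axis = next(a for a in g.axes if a.kind == "predictor")
        ticks = dict((label, x) for x, label in axis.ticks)
        assert ticks["1"] == pytest.approx(0.0)   # value 1 sits at 0 points
        assert ticks["0"] == pytest.approx(1.0)   # value 0 at the axis maximum

    def test_predictor_ticks_consistent_with_point_engine(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        for axis in g.axes:
            if axis.kind != "predictor" or len(axis.predictor_indices) != 1:
                continue
            i = axis.predictor_indices[0]
            pred_i, scale = cmv.model.predictors[i], cmv.scales.scales[i]
            for x, label in axis.ticks:
                v = float(label)
                expected = nl.value_to_points(scale, pred_i, v) / cmv.scales.p_max
                assert x == pytest.approx(expected, abs=1e-9)

    def test_threshold_marker_at_probability_preimage(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        expected = nl.probability_to_total_points(
            cmv.pm, cmv.model.threshold) / cmv.pm.total_max_points
        assert g.threshold_x == pytest.approx(expected, abs=1e-12)

    def test_curve_passes_through_half_probability_point(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        x_half = nl.probability_to_total_points(cmv.pm, 0.5) / cmv.pm.total_max_points
        nearest = min(g.curve, key=lambda pair: abs(pair[0] - x_half))
        assert nearest[1] == pytest.approx(0.5, abs=0.01)

    def test_unattainable_threshold_warns_and_omits_marker(self):
        model = ModelSpec(5.0, 0.01, (
            PredictorSpec("x", 1.0, 0.0, 1.0, "continuous", "up"),))
        b = build(model)
        with pytest.warns(UserWarning, match="not attainable"):
            g = nl.compute_layout(b.model, b.scales, b.pm)
        assert g.threshold_x is None

    def test_all_ticks_normalized(self, cmv):
        g = nl.compute_layout(cmv.model, cmv.scales, cmv.pm)
        for axis in g.axes:
            for x, label in axis.ticks:
                assert -1e-12 <= x <= 1.0 + 1e-12
                assert label


@pytest.fixture(scope="module")
def cmv_geometry(cmv):
    return nl.compute_layout(cmv.model, cmv.scales, cmv.pm)


class TestRender:

    def test_png_has_requested_pixel_dimensions(self, cmv_geometry, tmp_path):
        from PIL import Image

        opts = cmv_geometry.options.with_overrides(width=8.0, height=6.0, dpi=50)
        g = nl.NomogramGeometry(cmv_geometry.axes, cmv_geometry.curve,
                                cmv_geometry.threshold_x,
                                cmv_geometry.threshold_value,
                                cmv_geometry.p_max,
                                cmv_geometry.total_max_points, opts)
        path = nl.render(g, tmp_path / "n.png")
        with Image.open(path) as img:
            assert img.size == (400, 300)

    def test_pdf_written_and_parseable_header(self, cmv_geometry, tmp_path):
        path = nl.render(cmv_geometry, tmp_path / "n.pdf")
        assert path.read_bytes()[:5] == b"%PDF-"

    def test_svg_groups_and_styles(self, cmv_geometry, tmp_path):
        from lxml import etree

        path = nl.render(cmv_geometry, tmp_path / "n.svg")
        tree = etree.parse(str(path))
        dashed = {}
        for el in tree.iter():
            gid = el.get("id") or ""
            if gid.startswith("predictor-axis"):
                styles = [p.get("style", "") for p in el.iter()
                          if p.tag.endswith("path")]
                dashed[gid] = any("stroke-dasharray" in s for s in styles)
        assert len(dashed) == 5
        # predictor order: age, gender, disease, prednisone, cd34
        assert [dashed[f"predictor-axis-{i}"] for i in range(5)] == [
            False, True, True, False, False]
        ids = {el.get("id") for el in tree.iter()}
        assert {"points-ruler", "total-ruler", "probability-panel",
                "threshold-marker"} <= ids

    def test_unknown_format_rejected(self, cmv_geometry, tmp_path):
        with pytest.raises(ValueError, match="unsupported format"):
            nl.render(cmv_geometry, tmp_path / "n.tiff")
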