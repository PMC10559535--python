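"""Curve preprocessing, characteristic points, and the 32-parameter features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enose.calibration import DividerCircuit
from enose.curves import (
    CURVE_LENGTH,
    FEATURE_NAMES,
    SAMPLE_RATE,
    CharacteristicPoints,
    CurveError,
    FilterConfig,
    ResponseCurve,
    compute_differences,
    compute_slopes,
    compute_statistics,
    encode_identifier,
    estimate_ppm_features,
    extract_points,
    featurize,
    preprocess,
    read_acquisition,
)

T = np.arange(CURVE_LENGTH) / SAMPLE_RATE


def make_curve(samples, **kw):
    return ResponseCurve(samples=np.asarray(samples, dtype=float), **kw)


class TestPreprocess:
    def test_constant_curve_becomes_zero(self):
        out = preprocess(make_curve(np.full(CURVE_LENGTH, 3.7)))
        assert np.allclose(out.samples, 0.0)
        assert out.samples.size == CURVE_LENGTH

    def test_median_stage_suppresses_single_spike(self):
        v = np.zeros(CURVE_LENGTH)
        v[7000] = 5.0
        out = preprocess(make_curve(v))
        assert out.samples.max() < v.max()

    def test_baseline_and_peak_recovered_within_one_percent(self):
        b, p = 1.5, 2.0
        v = b + p * np.exp(-((T - 60.0) ** 2) / (2 * 8.0**2))
        out = preprocess(make_curve(v))
        assert out.samples.max() == pytest.approx(p, rel=0.01)
        # baseline is subtracted: first second sits at ~0
        assert abs(out.samples[:125].mean()) < 1e-6

    def test_window_longer_than_curve_rejected(self):
        with pytest.raises(CurveError):
            preprocess(make_curve(np.zeros(10)), FilterConfig(average_window=11))


class TestExtractPoints:
    def test_triangle_peak_location_and_value(self):
        v = np.interp(T, [0.0, 80.0, 120.0], [0.0, 2.0, 0.0])
        p = extract_points(make_curve(v))
        assert p.VB == pytest.approx(2.0)
        assert p.tB == pytest.approx(80.0)

    def test_monotone_curve_peaks_at_right_edge(self):
        p = extract_points(make_curve(np.linspace(0.0, 1.0, CURVE_LENGTH)))
        assert p.VB == pytest.approx(p.VC)
        assert p.tB == pytest.approx((CURVE_LENGTH - 1) / SAMPLE_RATE)

    def test_sine_curve_closed_form(self):
        v = np.sin(np.pi * T / 120.0)
        p = extract_points(make_curve(v))
        assert p.VA == pytest.approx(math.sin(math.pi / 3.0), abs=1e-6)
        assert p.VB == pytest.approx(1.0, abs=1e-6)
        assert p.tB == pytest.approx(60.0)
        # t = 120 s clamps to the final sample (index 14999)
        assert p.VC == pytest.approx(math.sin(math.pi * (14999 / 125.0) / 120.0), abs=1e-12)

    def test_short_curve_rejected(self):
        with pytest.raises(CurveError):
            extract_points(make_curve(np.zeros(1000)))


def points(VA=0.0, VD=0.0, VB=0.0, VE=0.0, VC=0.0, tB=80.0):
    return CharacteristicPoints(VA=VA, VD=VD, VB=VB, VE=VE, VC=VC, tB=tB)


class TestSlopesAndDifferences:
    def test_rise_slope_arithmetic(self):
        s = compute_slopes(points(VA=1.0, VB=2.0, tB=80.0))
        assert s["slope_AB"] == pytest.approx((2.0 - 1.0) / (80.0 - 40.0))

    def test_flat_points_give_zero_slopes(self):
        s = compute_slopes(points(VA=1.0, VD=1.0, VB=1.0, VE=1.0, VC=1.0))
        assert all(v == 0.0 for v in s.values())

    def test_three_slope_hand_example(self):
        s = compute_slopes(points(VD=1.2, VE=1.8, VB=2.0, tB=80.0))
        assert s["slope_DE"] == pytest.approx((1.8 - 1.2) / 40.0)  # 0.015
        assert s["slope_DB"] == pytest.approx((2.0 - 1.2) / 20.0)  # 0.04
        assert s["slope_BE"] == pytest.approx((1.8 - 2.0) / 20.0)  # -0.01

    def test_degenerate_time_base_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            s = compute_slopes(points(VB=2.0, tB=40.0))  # tB == tA
        assert s["slope_AB"] == 0.0

    def test_difference_arithmetic(self):
        d = compute_differences(points(VA=1.0, VB=2.0))
        assert d["dif_BA"] == pytest.approx(1.0)
        d0 = compute_differences(points(VA=1.0, VD=1.0, VB=1.0, VE=1.0, VC=1.0))
        assert all(v == 0.0 for v in d0.values())

    def test_sine_difference_closed_form(self):
        v = np.sin(np.pi * T / 120.0)
        p = extract_points(make_curve(v))
        d = compute_differences(p)
        expected = 1.0 - math.sin(math.pi * (14999 / 125.0) / 120.0)
        assert d["dif_BC"] == pytest.approx(expected, abs=1e-6)


@settings(derandomize=True, max_examples=100)
@given(
    volts=st.lists(st.floats(-5.0, 5.0), min_size=5, max_size=5),
    tB=st.floats(0.5, 119.5),
)
def test_differences_nonnegative_when_vb_is_maximum(volts, tB):
    va, vd, ve, vc, bump = volts
    vb = max(va, vd, ve, vc) + abs(bump)
    p = points(VA=va, VD=vd, VB=vb, VE=ve, VC=vc, tB=tB)
    assert all(v >= 0.0 for v in compute_differences(p).values())


@settings(derandomize=True, max_examples=100)
@given(v0=st.floats(-5, 5), v1=st.floats(-5, 5), t0=st.floats(0, 50), t1=st.floats(60, 120))
def test_slope_negates_when_voltages_swap(v0, v1, t0, t1):
    """Reversing the rise (swapping the two voltages over the same time
    base) negates a slope."""
    from enose.curves import _slope

    assert _slope(v1, v0, t1, t0, "x") == pytest.approx(-_slope(v0, v1, t1, t0, "x"))


class TestStatistics:
    def test_constant_curve(self):
        s = compute_statistics(make_curve(np.full(500, 2.5)))
        assert s["std"] == 0.0 and s["iqr"] == 0.0 and s["cv"] == 0.0
        assert s["skewness"] == 0.0
        assert s["mean"] == s["median"] == s["mode"] == pytest.approx(2.5)

    def test_tiny_hand_checkable_sample(self):
        s = compute_statistics(make_curve([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert s["mean"] == pytest.approx(3.0)
        assert s["median"] == pytest.approx(3.0)
        assert s["p75"] == pytest.approx(4.0)  # linear-interpolation quantile
        assert s["iqr"] == pytest.approx(2.0)

    def test_symmetric_curve_has_zero_skewness(self):
        v = np.sin(2 * np.pi * np.arange(1000) / 1000.0)
        s = compute_statistics(make_curve(v))
        assert abs(s["skewness"]) < 1e-9

    def test_mode_picks_most_populated_bin(self):
        v = np.concatenate([np.full(80, 1.005), np.linspace(0.0, 3.0, 20)])
        s = compute_statistics(make_curve(v))
        assert s["mode"] == pytest.approx(1.005, abs=0.01)


class TestPpmFeatures:
    def test_zero_alpha_and_missing_gases_get_sentinel(self, sensor_models):
        model = sensor_models["TGS-2611E00"]
        out = estimate_ppm_features(points(VB=2.0), model)
        assert out["ppm_air"] == 0.0  # alpha = 0, non-invertible
        assert out["ppm_ethanol"] == 0.0  # alpha = 0
        assert out["ppm_propane"] == 0.0  # not characterized
        assert out["ppm_co"] == 0.0  # not characterized
        assert out["ppm_methane"] > 0.0

    def test_vb_outside_divider_range_gives_all_sentinels(self, sensor_models):
        model = sensor_models["TGS-2611E00"]
        out = estimate_ppm_features(points(VB=0.0), model)
        assert all(v == 0.0 for v in out.values())

    def test_inversion_identity_at_one_ppm(self, sensor_models):
        # choose VB so the rescaled divider resistance equals methane's A
        circ = DividerCircuit()
        model = sensor_models["TGS-2611E00"]
        a = model.calibrations["methane"].A
        r_target = a * circ.reference_resistance
        vb = circ.supply_voltage * circ.load_resistance / (circ.load_resistance + r_target)
        out = estimate_ppm_features(points(VB=vb), model, circ)
        assert out["ppm_methane"] == pytest.approx(1.0, rel=1e-9)


class TestIdentifier:
    def test_grid_corners(self):
        assert encode_identifier("TGS-2611E00", 0) == 0
        assert encode_identifier("TGS-2620", 31) == 331

    def test_injective_over_all_128_combinations(self):
        from enose.calibration import MODEL_IDS

        codes = {encode_identifier(m, s) for m in MODEL_IDS for s in range(32)}
        assert len(codes) == 128

    def test_unknown_model_rejected(self):
        with pytest.raises(CurveError):
            encode_identifier("TGS-9999", 0)


class TestFeaturize:
    def test_vector_has_32_finite_values(self, sensor_models):
        v = 0.5 + np.interp(T, [0.0, 80.0, 120.0], [0.0, 2.0, 0.5])
        vec = featurize(make_curve(v), sensor_models["TGS-2611E00"])
        assert vec.shape == (32,)
        assert np.all(np.isfinite(vec))
        assert len(FEATURE_NAMES) == 32

    def test_flat_nonzero_curve_policy(self, sensor_models):
        vec = featurize(make_curve(np.full(CURVE_LENGTH, 2.0)), sensor_models["TGS-2611E00"])
        named = dict(zip(FEATURE_NAMES, vec))
        assert all(named[k] == 0.0 for k in FEATURE_NAMES if k.startswith(("slope_", "dif_", "ppm_")))
        assert named["std"] == 0.0

    def test_featurize_is_deterministic(self, sensor_models):
        v = 0.5 + np.interp(T, [0.0, 80.0, 120.0], [0.0, 2.0, 0.5])
        m = sensor_models["TGS-2611E00"]
        assert np.array_equal(featurize(make_curve(v), m), featurize(make_curve(v), m))

    def test_model_mismatch_rejected(self, sensor_models):
        with pytest.raises(CurveError):
            featurize(make_curve(np.zeros(CURVE_LENGTH), model_id="TGS-2620"),
                      sensor_models["TGS-2611E00"])


class TestAcquisitionIO:
    def test_round_trip_of_generated_file(self, desk_cohort):
        manifest, _ = desk_cohort
        curves = read_acquisition(manifest[0].path)
        assert len(curves) == 32
        assert all(c.samples.size == CURVE_LENGTH for c in curves)
        assert curves[0].provenance.patient_id == manifest[0].patient_id
        assert curves[5].socket_index == 5

    def test_bad_header_rejected(self, desk_cohort, tmp_path):
        manifest, _ = desk_cohort
        text = manifest[0].path.read_text().replace("s00", "sensor0", 1)
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        bad.with_suffix(".json").write_text(manifest[0].path.with_suffix(".json").read_text())
        with pytest.raises(CurveError):
            read_acquisition(bad)
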