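import numpy as np
import pytest
from hypothesis import given, strategies as st

from keraspec import pretreat as pt
from keraspec.deconv import TDComponent, TDFit
from keraspec.spectra import Spectrum


def _nmr(axis, intensity, modality="h1_mas", **kw):
    return Spectrum(modality=modality, axis=axis, intensity=intensity,
                    sample_id="S1", **kw)


# -- cubic-spline alignment -------------------------------------------------

def test_interpolation_identity_on_same_axis():
    x = np.linspace(-8, 14, 120)
    sp = _nmr(x, np.sin(x))
    out = pt.interpolate_to_axis(sp, x)
    np.testing.assert_allclose(out.intensity, sp.intensity, atol=1e-12)


def test_interpolation_exact_for_cubic_polynomial():
    x = np.linspace(0, 10, 60)
    poly = lambda t: 0.3 * t ** 3 - 2 * t ** 2 + t - 4
    sp = _nmr(x, poly(x))
    target = np.linspace(0.5, 9.5, 83)
    out = pt.interpolate_to_axis(sp, target)
    np.testing.assert_allclose(out.intensity, poly(target), atol=1e-9)


def test_interpolation_aligns_two_samples_to_common_axis():
    target = np.linspace(-100, 100, 401)
    a = pt.interpolate_to_axis(
        _nmr(np.linspace(-120, 120, 700), np.ones(700), "h1_wideline"),
        target)
    b = pt.interpolate_to_axis(
        _nmr(np.linspace(-110, 115, 650), np.ones(650), "h1_wideline"),
        target)
    np.testing.assert_array_equal(a.axis, b.axis)


def test_interpolation_refuses_extrapolation():
    sp = _nmr(np.linspace(0, 1, 30), np.zeros(30))
    with pytest.raises(ValueError, match="span"):
        pt.interpolate_to_axis(sp, np.linspace(-0.5, 0.5, 10))


# -- Savitzky-Golay second derivative --------------------------------------

def test_sg_reproduces_constant_curvature_of_quadratic():
    x = np.linspace(0, 5, 101)
    a, b, c = 1.7, -0.4, 2.2
    sp = _nmr(x, a * x ** 2 + b * x + c)
    out = pt.sg_second_derivative(sp, 11)
    np.testing.assert_allclose(out.intensity, 2 * a, atol=1e-9)
    assert out.derivative_order == 2


def test_sg_matches_finite_difference_oracle_for_sine():
    x = np.linspace(0, 2 * np.pi, 400)
    sp = _nmr(x, np.sin(x))
    out = pt.sg_second_derivative(sp, 11)
    # window-dependent bound from a central finite-difference oracle
    h = x[1] - x[0]
    dense = (np.sin(x + h) - 2 * np.sin(x) + np.sin(x - h)) / h ** 2
    bound = np.abs(dense - (-np.sin(x))).max() + 5e-4
    half = 5
    np.testing.assert_allclose(out.intensity, -np.sin(out.axis),
                               atol=max(bound, 1e-6))
    assert out.n_points == sp.n_points - 2 * half


def test_sg_lineage_token_records_window():
    x = np.linspace(0, 5, 101)
    out = pt.sg_second_derivative(_nmr(x, x ** 2), 11)
    assert out.lineage[-1] == "sg2der(w=11)"


@pytest.mark.parametrize("window", [4, 3, 10])
def test_sg_rejects_bad_windows(window):
    sp = _nmr(np.linspace(0, 5, 101), np.zeros(101))
    with pytest.raises(ValueError):
        pt.sg_second_derivative(sp, window)


# -- truncation and exclusion ----------------------------------------------

def test_truncation_keeps_wideline_window():
    x = np.linspace(-120, 120, 961)
    out = pt.truncate(_nmr(x, np.ones_like(x), "h1_wideline"), -102, 102)
    assert out.axis.min() >= -102 and out.axis.max() <= 102
    # count oracle: linear scan
    assert out.n_points == int(sum(1 for v in x if -102 <= v <= 102))


def test_truncation_to_full_span_is_identity():
    x = np.linspace(2.8, 185.2, 500)
    sp = _nmr(x, np.sin(x), "c13_cpmas")
    out = pt.truncate(sp, x.min(), x.max())
    np.testing.assert_array_equal(out.intensity, sp.intensity)


def test_ftir_crystal_interference_regions_are_removed():
    x = np.arange(650.0, 4000.0, 2.0)
    out = pt.exclude_regions(_nmr(x, np.ones_like(x), "ftir"),
                             pt.FTIR_EXCLUDED_REGIONS)
    assert not np.any((out.axis >= 1711) & (out.axis <= 2669))
    assert not np.any((out.axis >= 3400) & (out.axis <= 4000))
    oracle = sum(1 for v in x
                 if not (1711 <= v <= 2669) and not (3400 <= v <= 4000))
    assert out.n_points == oracle


def test_empty_exclusion_list_is_identity():
    x = np.linspace(650, 4000, 100)
    sp = _nmr(x, np.ones(100), "ftir")
    out = pt.exclude_regions(sp, [])
    np.testing.assert_array_equal(out.axis, sp.axis)


# -- normalization ----------------------------------------------------------

@given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 50))
def test_normalization_unit_area_and_scale_invariance(scale, seed):
    rng = np.random.default_rng(seed)
    x = np.linspace(-8, 14.2, 200)
    y = rng.normal(size=200) + 2.0
    a = pt.normalize_total_area(_nmr(x, y))
    b = pt.normalize_total_area(_nmr(x, y * scale))
    area = np.trapezoid(np.abs(a.intensity), a.axis)
    assert area == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)


def test_normalization_is_idempotent():
    x = np.linspace(0, 10, 100)
    once = pt.normalize_total_area(_nmr(x, np.sin(x) + 2))
    twice = pt.normalize_total_area(once)
    np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)


def test_zero_area_spectrum_cannot_be_normalized():
    with pytest.raises(ValueError, match="zero-area"):
        pt.normalize_total_area(_nmr(np.linspace(0, 1, 30), np.zeros(30)))


def test_signed_area_normalization_matches_absolute_for_positive_profiles():
    x = np.linspace(0, 10, 80)
    sp = _nmr(x, np.sin(x) + 2.0)
    a = pt.normalize_total_area(sp)
    b = pt.normalize_total_area(sp, signed=True)
    np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)


def test_polynomial_baseline_is_removed_exactly():
    x = np.linspace(0, 10, 120)
    signal = np.exp(-0.5 * ((x - 5) / 0.4) ** 2)
    baseline = 1.5 + 0.3 * x - 0.02 * x ** 2
    out = pt.subtract_baseline(_nmr(x, signal + baseline), degree=2)
    # the fitted quadratic absorbs the planted baseline plus the small
    # quadratic component of the peak itself
    residual_poly = np.polynomial.polynomial.polyfit(
        x, signal, 2)
    expected = signal - np.polynomial.polynomial.polyval(x, residual_poly)
    np.testing.assert_allclose(out.intensity, expected, atol=1e-9)


# -- DTG preparation --------------------------------------------------------

def _dtg(intensity=None, weight=20.0):
    x = np.arange(40.0, 500.0, 0.5)
    y = np.full_like(x, 0.004) if intensity is None else intensity
    return Spectrum(modality="dtg", axis=x, intensity=y, sample_id="S1",
                    sample_weight=weight)


def test_dtg_axis_is_one_degree_bins():
    out = pt.dtg_prepare(_dtg())
    assert out.n_points == 454
    assert out.axis[0] == 44.0 and out.axis[-1] == 497.0


def test_dtg_constant_curve_normalized_by_weight():
    out = pt.dtg_prepare(_dtg(weight=20.0))
    # 0.004 g/min over a 0.02 g sample = 20 %/min
    np.testing.assert_allclose(out.intensity, 100 * 0.004 / 0.020)


def test_dtg_bin_means_match_groupby_oracle(rng):
    x = np.arange(40.0, 500.0, 0.5)
    y = rng.normal(size=x.size)
    out = pt.dtg_prepare(_dtg(intensity=y, weight=10.0))
    for T in (44, 200, 497):
        mask = (x >= T) & (x < T + 1)
        expected = y[mask].mean() * 100 / 0.010
        assert out.intensity[int(T) - 44] == pytest.approx(expected)


def test_dtg_requires_sample_weight():
    sp = _dtg()
    object.__setattr__(sp, "sample_weight", None)
    with pytest.raises(ValueError, match="weight"):
        pt.dtg_prepare(sp)


# -- TD normalization -------------------------------------------------------

def _tdfit(amplitudes=(60.0, 25.0, 15.0)):
    comps = (
        TDComponent(amplitudes[0] / sum(amplitudes), 1.1e-5, "abragam", 9e4),
        TDComponent(amplitudes[1] / sum(amplitudes), 6e-5, "exponential"),
        TDComponent(amplitudes[2] / sum(amplitudes), 3e-4, "exponential"),
    )
    return TDFit(components=comps, residual_rms=0.0,
                 total_amplitude=float(sum(amplitudes)))


def test_td_normalized_model_equals_one_at_origin():
    t = np.concatenate([[0.0], np.geomspace(1e-6, 1e-3, 100)])
    fit = _tdfit()
    decay = Spectrum(modality="tdnmr", axis=t, intensity=fit.evaluate(t),
                     sample_id="S1")
    out = pt.td_normalize(decay, fit)
    assert out.intensity[0] == pytest.approx(1.0, abs=1e-9)


def test_td_normalization_divides_by_amplitude_sum():
    t = np.geomspace(1e-6, 1e-3, 50)
    decay = Spectrum(modality="tdnmr", axis=t, intensity=np.ones(50),
                     sample_id="S1")
    out = pt.td_normalize(decay, _tdfit((100.0, 0.0, 0.0)))
    np.testing.assert_allclose(out.intensity, 0.01)


# -- replicate averaging ----------------------------------------------------

def test_average_of_identical_replicates_is_identity():
    x = np.linspace(0, 10, 50)
    reps = [_nmr(x, np.sin(x)) for _ in range(3)]
    out = pt.average_replicates(reps)
    np.testing.assert_allclose(out.intensity, np.sin(x))
    assert out.replicate == -1


def test_average_of_zero_and_two_is_one():
    x = np.linspace(0, 10, 50)
    out = pt.average_replicates([_nmr(x, np.zeros(50)),
                                 _nmr(x, np.full(50, 2.0))])
    np.testing.assert_allclose(out.intensity, 1.0)


def test_average_matches_column_mean_oracle(rng):
    x = np.linspace(0, 10, 50)
    curves = rng.normal(size=(4, 50))
    out = pt.average_replicates([_nmr(x, c) for c in curves])
    np.testing.assert_allclose(out.intensity, curves.mean(axis=0))


def test_average_rejects_mismatched_axes():
    with pytest.raises(ValueError, match="axes"):
        pt.average_replicates([_nmr(np.linspace(0, 10, 50), np.zeros(50)),
                               _nmr(np.linspace(0, 11, 50), np.zeros(50))])
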