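"""Feature bank: segmentation, per-feature behaviour, degenerate rules.

Deeper oracle-equivalence checks against independent direct-formula
implementations live in the acceptance suite; here each operation's
contract and its analytically known special cases are exercised.
"""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import preictal as p
from preictal.features import wavelet_approx_energy

T0 = dt.datetime(2021, 3, 1, 0, 0, 0)
FS = 256.0
W = 1280


def _record(sig, fs=FS):
    sig = np.atleast_2d(sig)
    return p.EEGRecord(sig, fs, [f"ch{i}" for i in range(sig.shape[0])], T0)


@pytest.fixture(scope="module")
def noise():
    return np.random.default_rng(1234).standard_normal((50, W))


# -- segmentation -----------------------------------------------------------

@pytest.mark.parametrize("dur_s,expected", [(60.0, 12), (61.0, 12), (5.0, 1)])
def test_segment_window_counts(dur_s, expected, rng):
    rec = _record(rng.standard_normal(int(dur_s * FS)))
    win = p.segment_windows(rec, p.WindowSpec(fs=FS))
    assert win.shape == (expected, 1, W)


def test_segment_too_short_raises(rng):
    rec = _record(rng.standard_normal(int(4 * FS)))
    with pytest.raises(ValueError, match="shorter than one"):
        p.segment_windows(rec, p.WindowSpec(fs=FS))


def test_window_spec_integer_samples():
    with pytest.raises(ValueError, match="integer sample count"):
        p.WindowSpec(fs=3.0, window_s=0.1)


# -- relative band powers ----------------------------------------------------

def test_pure_tone_band_concentration():
    t = np.arange(W) / FS
    frac, total, deg = p.relative_band_powers(np.sin(2 * np.pi * 10 * t),
                                              p.DEFAULT_BANDS, FS)
    i = [b.name for b in p.DEFAULT_BANDS].index("band_8_13")
    assert frac[i] >= 0.99
    assert not deg
    assert all(f <= 0.01 for j, f in enumerate(frac) if j != i)


def test_white_noise_band_fraction_flat(noise):
    frac, _, _ = p.relative_band_powers(noise, p.DEFAULT_BANDS, FS)
    # flat spectrum: fraction ~ bandwidth / total analysed bandwidth
    assert frac[:, 0].mean() == pytest.approx(3.5 / 127.5, rel=0.15)
    assert frac[:, -1].mean() == pytest.approx(25.0 / 127.5, rel=0.15)


def test_band_fraction_partition_subset(noise):
    frac, _, _ = p.relative_band_powers(noise, p.DEFAULT_BANDS, FS)
    s = frac.sum(axis=1)
    assert np.all(s <= 1.0 + 1e-9)       # notch gaps 47-53 / 97-103 excluded
    assert np.all(s > 0.8)


def test_constant_window_degenerate_flag():
    frac, total, deg = p.relative_band_powers(np.full(W, 3.3),
                                              p.DEFAULT_BANDS, FS)
    assert deg and np.all(frac == 0.0)


# -- ratios ------------------------------------------------------------------

def test_band_ratio_count_and_symmetry():
    powers = np.full(8, 0.125)
    r = p.band_ratios(powers)
    assert r.shape == (28,)
    assert np.allclose(r, 1.0, atol=1e-9)


def test_band_ratio_zero_guard():
    r = p.band_ratios(np.array([1.0, 0.0]))
    assert np.isfinite(r).all() and r[0] > 1e9


@given(st.integers(2, 8))
@settings(max_examples=10, deadline=None)
def test_band_ratio_pair_count(nb):
    r = p.band_ratios(np.ones(nb))
    assert r.shape == (nb * (nb - 1) // 2,)


# -- spectral edge -----------------------------------------------------------

def test_sef_pure_tone():
    t = np.arange(W) / FS
    edge, power_at, deg = p.spectral_edge(np.sin(2 * np.pi * 10 * t), 0.5, FS)
    assert abs(edge - 10.0) <= FS / W + 1e-9  # within one frequency bin


def test_sef_white_noise_midpoint(noise):
    edge, _, _ = p.spectral_edge(noise, 0.5, FS)
    assert abs(edge.mean() - 64.25) < 5.0


def test_sef_limit_near_one(noise):
    edge, _, _ = p.spectral_edge(noise[0], 1.0 - 1e-9, FS)
    assert edge >= 120.0


def test_sef_invalid_fraction(noise):
    with pytest.raises(ValueError):
        p.spectral_edge(noise[0], 1.5, FS)


# -- moments -----------------------------------------------------------------

def test_moments_constant_window():
    mean, var, skew, kurt, deg = p.statistical_moments(np.full(W, 2.5))
    assert (mean, var, skew, kurt) == (2.5, 0.0, 0.0, 0.0) and deg


def test_moments_gaussian_kurtosis(noise):
    *_, kurt, deg = p.statistical_moments(noise)
    assert np.all(np.abs(kurt - 3.0) < 0.4)


def test_skewness_oddness(noise):
    x = noise[0] ** 2  # clearly skewed
    *_, s_pos, _, _ = p.statistical_moments(x)
    *_, s_neg, _, _ = p.statistical_moments(-x)
    assert s_neg == pytest.approx(-s_pos, rel=1e-12)


# -- Hjorth ------------------------------------------------------------------

def test_hjorth_matches_direct_formula(noise):
    act, mob, comp, deg = p.hjorth(noise)
    for i, x in enumerate(noise[:10]):
        v0 = x.var()
        v1 = np.diff(x).var()
        v2 = np.diff(x, 2).var()
        assert act[i] == pytest.approx(v0, rel=1e-12)
        assert mob[i] == pytest.approx(np.sqrt(v1 / v0), rel=1e-12)
        assert comp[i] == pytest.approx(np.sqrt(v2 / v1) / np.sqrt(v1 / v0),
                                        rel=1e-12)


def test_hjorth_scale_invariance(noise):
    act1, mob1, comp1, _ = p.hjorth(noise[0])
    act2, mob2, comp2, _ = p.hjorth(7.0 * noise[0])
    assert act2 == pytest.approx(49.0 * act1, rel=1e-12)
    assert mob2 == pytest.approx(mob1, rel=1e-12)
    assert comp2 == pytest.approx(comp1, rel=1e-12)


def test_hjorth_degenerate():
    act, mob, comp, deg = p.hjorth(np.zeros(W))
    assert (act, mob, comp) == (0.0, 0.0, 0.0) and deg


# -- decorrelation time ------------------------------------------------------

def test_decorrelation_sine():
    for f in (4.0, 10.0, 25.0):
        t = np.arange(W) / FS
        lag, flag = p.decorrelation_time(np.sin(2 * np.pi * f * t), FS)
        assert abs(lag - 1 / (4 * f)) <= 1.0 / FS + 1e-12
        assert not flag


def test_decorrelation_white_noise(noise):
    lag, flag = p.decorrelation_time(noise, FS)
    # delta-correlated: first crossing at the first lags
    assert np.median(lag) <= 2.0 / FS
    assert (lag <= 2.0 / FS).mean() > 0.5


def test_decorrelation_slow_ramp_saturates():
    lag, flag = p.decorrelation_time(np.linspace(0, 1, W), FS)
    assert flag and lag == pytest.approx(W / FS)


# -- wavelet energies --------------------------------------------------------

def test_wavelet_zero_window():
    assert np.all(p.wavelet_energies(np.zeros(W)) == 0.0)


def test_wavelet_energy_conservation(noise):
    Ed = p.wavelet_energies(noise)
    Ea = wavelet_approx_energy(noise)
    sig = (noise ** 2).sum(axis=1)
    assert np.allclose(Ed.sum(axis=1) + Ea, sig, rtol=1e-6)


def test_wavelet_tone_level_mapping():
    t = np.arange(W) / FS
    E = p.wavelet_energies(np.sin(2 * np.pi * 64 * t))
    assert np.argmax(E) == 0  # D1 covers the top dyadic band
    E10 = p.wavelet_energies(np.sin(2 * np.pi * 10 * t))
    assert np.argmax(E10) == 3  # D4 ~ 8-16 Hz at 256 Hz


def test_wavelet_short_window_rejected():
    with pytest.raises(ValueError, match="too short"):
        p.wavelet_energies(np.zeros(100))


# -- extraction --------------------------------------------------------------

def test_feature_count_54_per_channel(rng):
    rec = _record(rng.standard_normal((2, int(20 * FS))))
    fm = p.extract_features(rec)
    assert fm.n_features == 2 * 54
    assert len(set(fm.feature_names)) == fm.n_features
    assert fm.feature_names[0].startswith("ch0/")


def test_ten_twenty_montage_column_count(rng):
    # 19 channels x 54 features
    rec = p.EEGRecord(rng.standard_normal((19, int(10 * FS))), FS,
                      list(p.TEN_TWENTY_CHANNELS), T0)
    fm = p.extract_features(rec)
    assert fm.n_features == 1026


def test_labels_360_preictal_windows_per_seizure(rng):
    dur = 3 * 3600.0
    rec = _record(rng.standard_normal(int(dur * 64)), fs=64.0)
    ann = p.SeizureAnnotation.from_seconds([7200.0], T0)
    fm = p.extract_features(rec, bands=p.bands_for_fs(64.0), annotations=ann,
                            preictal_min=30.0, families=("moments",))
    assert (fm.labels == 1).sum() == 360
    assert fm.n_windows == int(dur / 5)


def test_no_nan_and_flags(rng):
    sig = rng.standard_normal((1, int(30 * FS)))
    sig[0, : int(5 * FS)] = 1.0  # one constant window
    fm = p.extract_features(_record(sig))
    assert np.isfinite(fm.values).all()
    assert fm.flags[0].any() and not fm.flags[1].any()


def test_dc_offset_invariance(rng):
    x = rng.standard_normal((1, int(10 * FS)))
    fm0 = p.extract_features(_record(x))
    fm1 = p.extract_features(_record(x + 100.0))
    names = fm0.feature_names
    mean_cols = [i for i, n in enumerate(names) if n.endswith("/mean")]
    other = [i for i, n in enumerate(names)
             if not n.endswith(("/mean", "/wavelet_D8", "/decorr_time"))]
    # spectral, Hjorth, variance etc. invariant to DC shift (decorrelation
    # time deliberately sees the raw window, so it is exempt) ...
    np.testing.assert_allclose(fm0.values[:, other], fm1.values[:, other],
                               rtol=1e-6, atol=1e-9)
    # ... while the mean shifts by exactly the offset
    np.testing.assert_allclose(fm1.values[:, mean_cols],
                               fm0.values[:, mean_cols] + 100.0, rtol=1e-12)


def test_feature_matrix_save_load_roundtrip(tmp_path, rng):
    rec = _record(rng.standard_normal(int(20 * FS)))
    fm = p.extract_features(rec, annotations=p.SeizureAnnotation.from_seconds(
        [15.0], T0), preictal_min=30.0)
    fm.save(tmp_path / "fm")
    back = p.FeatureMatrix.load(tmp_path / "fm")
    np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
    assert back.feature_names == fm.feature_names
    np.testing.assert_array_equal(back.labels, fm.labels)
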