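"""Spectral grid, leaf optics and source-spectrum construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from canopyflux.spectra import (
    BAND_EDGES,
    N_BANDS,
    LeafOptics,
    SpectrumGrid,
    band_index,
    leaf_absorptance,
    make_led_spectrum,
    make_white_spectrum,
    read_leaf_optics_csv,
    read_spectrum_csv,
    weighted_absorption_fraction,
    write_leaf_optics_csv,
)


def _optics(R, T):
    return LeafOptics(
        reflectance=SpectrumGrid(np.full(N_BANDS, R) if np.isscalar(R) else R, kind="coefficient"),
        transmittance=SpectrumGrid(np.full(N_BANDS, T) if np.isscalar(T) else T, kind="coefficient"),
    )


class TestGrid:
    def test_band_structure(self):
        assert N_BANDS == 60
        assert np.all(np.diff(BAND_EDGES) == 5.0)
        assert BAND_EDGES[0] == 400.0 and BAND_EDGES[-1] == 700.0
        assert band_index(446.0) == 9  # [445, 450)
        with pytest.raises(ValueError):
            band_index(700.0)

    def test_flux_spectrum_rejects_negative(self):
        v = np.zeros(N_BANDS)
        v[3] = -1.0
        with pytest.raises(ValueError):
            SpectrumGrid(v)

    def test_coefficient_bounds(self):
        with pytest.raises(ValueError):
            SpectrumGrid(np.full(N_BANDS, 1.2), kind="coefficient")


class TestAbsorptance:
    def test_arithmetic(self):
        a = leaf_absorptance(_optics(0.10, 0.08))
        assert np.allclose(a.values, 0.82)

    def test_black_leaf(self):
        a = leaf_absorptance(_optics(0.0, 0.0))
        assert np.allclose(a.values, 1.0)

    def test_r_plus_t_violation_names_band(self):
        R = np.full(N_BANDS, 0.1)
        T = np.full(N_BANDS, 0.1)
        R[30], T[30] = 0.5, 0.6
        with pytest.raises(ValueError, match=r"\[550, 555\)"):
            _optics(R, T)

    def test_conservation_r_t_a(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(0, 0.5, N_BANDS)
        T = rng.uniform(0, 0.5, N_BANDS)
        o = _optics(R, T)
        assert np.allclose(o.reflectance.values + o.transmittance.values + o.absorptance().values, 1.0)


class TestWeightedAbsorption:
    def test_flat_absorptance(self):
        o = _optics(0.05, 0.05)
        src = make_white_spectrum(100.0)
        assert weighted_absorption_fraction(o, src) == pytest.approx(0.9)

    def test_monochromatic_band(self):
        R = np.full(N_BANDS, 0.2)
        T = np.full(N_BANDS, 0.2)
        idx = band_index(662.0)
        R[idx], T[idx] = 0.03, 0.03
        o = _optics(R, T)
        mono = np.zeros(N_BANDS)
        mono[idx] = 50.0
        assert weighted_absorption_fraction(o, SpectrumGrid(mono)) == pytest.approx(0.94)

    def test_linear_absorptance_flat_source_brute_force(self):
        # independent per-band summation oracle at full precision
        a = np.linspace(0.80, 0.95, N_BANDS)
        o = _optics((1 - a) * 0.5, (1 - a) * 0.5)
        flat = SpectrumGrid(np.full(N_BANDS, 2.5))
        expected = 0.0
        total = 0.0
        for b in range(N_BANDS):
            expected += a[b] * 2.5
            total += 2.5
        expected /= total
        got = weighted_absorption_fraction(o, flat)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(a.mean(), abs=1e-12)

    def test_zero_flux_source_raises(self):
        with pytest.raises(ValueError, match="zero total flux"):
            weighted_absorption_fraction(_optics(0.1, 0.1), SpectrumGrid(np.zeros(N_BANDS)))

    @settings(derandomize=True, max_examples=40)
    @given(
        a=arrays(float, N_BANDS, elements=st.floats(0.0, 1.0)),
        s=arrays(float, N_BANDS, elements=st.floats(0.0, 10.0)),
        scale=st.floats(0.1, 100.0),
    )
    def test_bounds_and_rescaling_invariance(self, a, s, scale):
        if s.sum() <= 0:
            s = s + 0.1
        o = _optics((1 - a) * 0.4, (1 - a) * 0.6)
        src = SpectrumGrid(s)
        f = weighted_absorption_fraction(o, src)
        nz = s > 0
        assert a[nz].min() - 1e-9 <= f <= a[nz].max() + 1e-9
        assert weighted_absorption_fraction(o, src.scaled(scale)) == pytest.approx(f, rel=1e-9)


class TestLedSpectrum:
    def test_normalization_and_peak(self):
        s = make_led_spectrum(663.0, 25.0, 100.0)
        assert s.total == pytest.approx(100.0)
        assert np.argmax(s.values) == band_index(663.0)

    def test_blue_green_overlap_negligible(self):
        b = make_led_spectrum(446.0, 20.0, 100.0)
        g = make_led_spectrum(530.0, 20.0, 100.0)
        overlap = np.minimum(b.values, g.values).sum() / 100.0
        assert overlap < 0.01

    def test_zero_flux(self):
        assert make_led_spectrum(530.0, 25.0, 0.0).total == 0.0

    def test_peak_outside_par_raises(self):
        with pytest.raises(ValueError):
            make_led_spectrum(720.0)


class TestWhiteSpectrum:
    @pytest.mark.parametrize(
        "lo,hi,expected", [(0, 20, 13.0), (20, 40, 55.0), (40, 60, 32.0)]
    )
    def test_regional_partitions(self, lo, hi, expected):
        s = make_white_spectrum(100.0)
        assert s.values[lo:hi].sum() == pytest.approx(expected, abs=1e-9)

    def test_zero_flux(self):
        assert make_white_spectrum(0.0).total == 0.0


class TestIO:
    def test_spectrum_roundtrip(self, tmp_path):
        s = make_led_spectrum(530.0, 25.0, 42.0)
        p = tmp_path / "s.csv"
        s.to_csv(p)
        back = read_spectrum_csv(p)
        assert np.allclose(back.values, s.values)

    def test_spectrum_grid_validation(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"wavelength_nm": np.arange(400, 700, 10), "value": 1.0}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(ValueError, match="5-nm band grid"):
            read_spectrum_csv(tmp_path / "bad.csv")

    def test_leaf_optics_roundtrip(self, tmp_path):
        from canopyflux.synthetic import gen_leaf_optics

        o = gen_leaf_optics("green")
        p = tmp_path / "optics.csv"
        write_leaf_optics_csv(o, p)
        back = read_leaf_optics_csv(p, "green")
        assert np.allclose(back.reflectance.values, o.reflectance.values, atol=1e-6)
        assert np.allclose(back.transmittance.values, o.transmittance.values, atol=1e-6)
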