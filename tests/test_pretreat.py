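"""Scatter corrections, gap-segment derivatives and pretreatment codes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutspec import pretreat

#: every pretreatment string printed in routine model tables (one per model row)
PUBLISHED_CODES = [
    "MSC 1,5,5,1", "SNV+detrend 2,5,5,1", "SNV 2,5,5,1", "MSC 2,10,10,1",
    "SNV+detrend 2,5,5,1", "SNV 0,0,1,1", "MSC 0,0,1,1", "SNV 2,10,10,1",
    "MSC 2,5,5,1", "Detrend 2,10,10,1", "None 0,0,1,1", "SNV 2,10,10,1",
    "SNV 1,5,5,1", "SNV+detrend 2,5,5,1", "MSC 1,5,5,1", "SNV 1,5,5,1",
    "SNV+detrend 2,5,5,1", "MSC 1,5,5,1", "SNV 2,10,10,1", "SNV+detrend 2,5,5,1",
]


def _spectra(n=6, bands=216, seed=0):
    rng = np.random.default_rng(seed)
    wl = 950.0 + 3.25 * np.arange(bands)
    base = np.exp(-0.5 * ((wl - 1300.0) / 80.0) ** 2)
    X = (
        rng.uniform(0.5, 1.5, size=(n, 1)) * base
        + rng.uniform(-0.1, 0.1, size=(n, 1))
        + 0.01 * rng.normal(size=(n, bands))
    )
    return X, wl


class TestParse:
    @pytest.mark.parametrize("text", sorted(set(PUBLISHED_CODES)))
    def test_round_trip_over_published_codes(self, text):
        code = pretreat.parse_code(text)
        assert pretreat.parse_code(code.serialize()) == code

    def test_parse_fields(self):
        code = pretreat.parse_code("SNV+detrend 2,5,5,1")
        assert code.scatter_ops == ("snv", "detrend")
        assert (code.d, code.g, code.s1, code.s2) == (2, 5, 5, 1)

    def test_invalid_codes(self):
        with pytest.raises(ValueError):
            pretreat.parse_code("OSC 1,5,5,1")
        with pytest.raises(ValueError):
            pretreat.parse_code("SNV 1,0,1,1")  # derivative needs a gap
        with pytest.raises(ValueError):
            pretreat.parse_code("SNV 1,5,5")


class TestSNV:
    def test_output_standardized(self):
        X, _ = _spectra()
        out = pretreat.snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        X, _ = _spectra(n=3)
        np.testing.assert_allclose(pretreat.snv(a * X + b), pretreat.snv(X), atol=1e-9)

    def test_constant_spectrum_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pretreat.snv(np.ones((2, 10)))


class TestDetrend:
    def test_exact_quadratic_annihilated(self):
        wl = np.linspace(950, 1650, 100)
        X = np.vstack([2 + 0.01 * wl - 3e-6 * wl**2, 1 - 0.002 * wl + 1e-6 * wl**2])
        np.testing.assert_allclose(pretreat.detrend(X, wl), 0.0, atol=1e-9)

    def test_output_orthogonal_to_polynomial_basis(self):
        X, wl = _spectra()
        out = pretreat.detrend(X, wl)
        for basis in (np.ones_like(wl), wl, wl**2):
            b = basis / np.linalg.norm(basis)
            np.testing.assert_allclose(out @ b, 0.0, atol=1e-9)

    def test_matches_explicit_least_squares(self):
        """Oracle: quadratic + Gaussian band leaves the band's LS residual."""
        wl = np.linspace(950, 1650, 150)
        band = np.exp(-0.5 * ((wl - 1250) / 30) ** 2)
        quad = 1 + 0.002 * wl + 1e-6 * wl**2
        out = pretreat.detrend((quad + band)[None, :], wl)[0]
        V = np.vander((wl - wl.mean()) / wl.std(), 3, increasing=True)
        proj = V @ np.linalg.lstsq(V, band, rcond=None)[0]
        np.testing.assert_allclose(out, band - proj, atol=1e-8)


class TestMSC:
    def test_affine_distortion_recovered(self):
        _, wl = _spectra()
        ref = np.exp(-0.5 * ((wl - 1300) / 60) ** 2)
        out = pretreat.msc((2.0 * ref + 3.0)[None, :], ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_reference_is_fixed_point(self):
        _, wl = _spectra()
        ref = np.exp(-0.5 * ((wl - 1300) / 60) ** 2)
        np.testing.assert_allclose(pretreat.msc(ref[None, :], ref)[0], ref, atol=1e-10)

    def test_regression_oracle(self):
        """Corrected spectra regress on the reference with slope 1, offset 0."""
        X, _ = _spectra(n=8, seed=3)
        ref = X.mean(axis=0)
        out = pretreat.msc(X, ref)
        refc = ref - ref.mean()
        for row in out:
            slope = (row - row.mean()) @ refc / (refc @ refc)
            intercept = row.mean() - slope * ref.mean()
            assert abs(slope - 1) < 1e-9 and abs(intercept) < 1e-9

    def test_zero_slope_errors(self):
        _, wl = _spectra()
        ref = np.sin(wl / 30)
        flat = np.full((1, wl.size), 2.0) + 1e-12 * np.cos(wl / 30)
        with pytest.raises(ValueError, match="slope"):
            pretreat.msc(flat, ref)


class TestGapSegmentDerivative:
    @pytest.mark.parametrize("d, g, s1, s2", [(1, 4, 5, 1), (2, 5, 5, 5), (1, 1, 1, 1)])
    def test_constant_goes_to_zero(self, d, g, s1, s2):
        X = np.full((2, 80), 3.7)
        out, _ = pretreat.gap_segment_derivative(X, np.arange(80.0), d, g, s1, s2)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_second_derivative_zero(self):
        wl = np.arange(100.0)
        X = (2.0 + 0.3 * wl)[None, :]
        out, _ = pretreat.gap_segment_derivative(X, wl, 2, 5, 5, 1)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_identity_code(self):
        X, wl = _spectra()
        out, wl_out = pretreat.gap_segment_derivative(X, wl, 0, 0, 1, 1)
        np.testing.assert_array_equal(out, X)
        np.testing.assert_array_equal(wl_out, wl)

    def test_band_support_bookkeeping(self):
        X, wl = _spectra(bands=60)
        out, wl_out = pretreat.gap_segment_derivative(X, wl, 2, 5, 5, 5)
        # each smoothing of width 5 trims 4 bands, the gap trims 2*5 more
        assert out.shape[1] == wl_out.size == 60 - 4 - 10 - 4

    def test_support_exhausted(self):
        with pytest.raises(ValueError):
            pretreat.gap_segment_derivative(np.zeros((1, 8)), np.arange(8.0), 2, 5, 1, 1)


class TestApplyCode:
    def test_none_code_is_identity(self):
        X, wl = _spectra()
        out, wl_out, _ = pretreat.apply_code(X, wl, "None 0,0,1,1")
        np.testing.assert_array_equal(out, X)
        np.testing.assert_array_equal(wl_out, wl)

    def test_snv_invariance_propagates(self):
        X, wl = _spectra()
        out1, _, _ = pretreat.apply_code(X, wl, "SNV 2,5,5,1")
        out2, _, _ = pretreat.apply_code(1.7 * X - 0.4, wl, "SNV 2,5,5,1")
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_msc_transform_requires_fit(self):
        X, wl = _spectra()
        fp = pretreat.FittedPretreatment(pretreat.parse_code("MSC 1,5,5,1"))
        with pytest.raises(ValueError, match="fit"):
            fp.transform(X, wl)

    def test_transform_replays_fit(self):
        X, wl = _spectra(n=10)
        fp = pretreat.FittedPretreatment(pretreat.parse_code("MSC 2,5,5,1"))
        fitted = fp.fit(X, wl)[0]
        np.testing.assert_allclose(fp.transform(X, wl), fitted, atol=1e-12)

    @pytest.mark.parametrize("text", sorted(set(PUBLISHED_CODES)))
    def test_published_codes_run_on_216_bands(self, text):
        X, wl = _spectra(bands=216)
        out, wl_out, _ = pretreat.apply_code(X, wl, text)
        assert np.isfinite(out).all()
        assert out.shape[1] == wl_out.size >= 1

    def test_serialization_round_trip(self):
        X, wl = _spectra(n=5)
        fp = pretreat.FittedPretreatment(pretreat.parse_code("MSC 2,5,5,1"))
        fp.fit(X, wl)
        back = pretreat.FittedPretreatment.from_dict(fp.to_dict())
        np.testing.assert_allclose(back.transform(X, wl), fp.transform(X, wl), atol=0)
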