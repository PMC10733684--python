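"""Spectral data model and preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import nirconfound as nc
from nirconfound.spectra import (
    PreprocessParams,
    SampleRecord,
    SpectraError,
    Spectrum,
    WavelengthGrid,
    average_replicates,
    drop_zero_variance_channels,
    impute_missing_replicates,
    preprocess_inventory,
    sg_first_derivative,
)
from .conftest import make_inventory


def sg_oracle(y: np.ndarray, window: int, poly: int) -> np.ndarray:
    """Independent Savitzky-Golay derivative: least-squares polynomial fit in
    each window, analytic first derivative at the centre; edge values from the
    first/last full window's polynomial evaluated at the edge offsets."""
    n = y.size
    h = window // 2
    out = np.empty(n)
    x = np.arange(window, dtype=float)
    for i in range(n):
        start = min(max(i - h, 0), n - window)
        coef = np.polynomial.polynomial.polyfit(x, y[start : start + window], poly)
        dcoef = np.polynomial.polynomial.polyder(coef)
        out[i] = np.polynomial.polynomial.polyval(i - start, dcoef)
    return out


def spectrum_of(values, n=None):
    values = np.asarray(values, dtype=float)
    return Spectrum(nc.default_grid(values.size), values)


class TestSGDerivative:
    def test_constant_spectrum_has_zero_derivative(self):
        s = spectrum_of(np.full(64, 3.7))
        d = sg_first_derivative(s)
        assert np.allclose(d.intensities, 0.0, atol=1e-12)

    def test_linear_ramp_gives_constant_slope(self):
        m = 0.25
        s = spectrum_of(m * np.arange(64))
        d = sg_first_derivative(s)
        assert np.allclose(d.intensities, m, atol=1e-10)

    def test_matches_windowed_polyfit_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0.5, 0.2, 64)
        d = sg_first_derivative(spectrum_of(y))
        assert np.allclose(d.intensities, sg_oracle(y, 13, 2), atol=1e-9)

    def test_output_length_preserved(self):
        s = spectrum_of(np.random.default_rng(0).normal(size=40))
        assert len(sg_first_derivative(s).intensities) == 40

    def test_too_short_spectrum_rejected(self):
        s = spectrum_of(np.ones(9))
        with pytest.raises(SpectraError, match="shorter than window"):
            sg_first_derivative(s, PreprocessParams(window_length=13))

    @given(
        hnp.arrays(np.float64, 40, elements=st.floats(-1, 1)),
        hnp.arrays(np.float64, 40, elements=st.floats(-1, 1)),
        st.floats(-3, 3),
        st.floats(-3, 3),
    )
    def test_linearity(self, x, y, a, b):
        """D(a x + b y) = a D(x) + b D(y)."""
        dx = sg_first_derivative(spectrum_of(x)).intensities
        dy = sg_first_derivative(spectrum_of(y)).intensities
        dz = sg_first_derivative(spectrum_of(a * x + b * y)).intensities
        assert np.allclose(dz, a * dx + b * dy, atol=1e-9)

    def test_derivative_commutes_with_replicate_averaging(self, tiny_inventory):
        pre_then_avg = [
            average_replicates(s)
            for s in preprocess_inventory(tiny_inventory).samples
        ]
        for rec, d_avg in zip(tiny_inventory.samples, pre_then_avg):
            avg_then_pre = sg_first_derivative(average_replicates(rec))
            assert np.allclose(avg_then_pre.intensities, d_avg.intensities, atol=1e-9)


class TestAverageReplicates:
    def test_single_replicate_identity(self):
        inv = make_inventory(samples=[dict(sample_id="A", day=7, n_reps=1)])
        s = inv.samples[0]
        assert np.array_equal(average_replicates(s).intensities,
                              s.replicates[0].intensities)

    def test_two_constant_replicates(self):
        grid = nc.default_grid(16)
        rec = SampleRecord("A", 7, replicates=[
            Spectrum(grid, np.zeros(16), 1), Spectrum(grid, np.full(16, 2.0), 2)])
        assert np.allclose(average_replicates(rec).intensities, 1.0)

    def test_mean_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        grid = nc.default_grid(20)
        reps = [Spectrum(grid, rng.normal(size=20), i + 1) for i in range(3)]
        rec = SampleRecord("A", 7, replicates=reps)
        expected = sum(r.intensities for r in reps) / 3.0
        assert np.allclose(average_replicates(rec).intensities, expected, atol=1e-12)

    def test_no_replicates_is_an_error(self):
        rec = SampleRecord("A", 7)
        with pytest.raises(SpectraError, match="no replicates"):
            average_replicates(rec)


class TestDropZeroVariance:
    def _with_constant_channels(self, channels):
        inv = make_inventory(n_channels=32)
        for s in inv.samples:
            for spec in s.replicates:
                spec.intensities[list(channels)] = 0.7
        return inv

    def test_constant_channel_removed(self):
        inv = self._with_constant_channels([5])
        out, kept = drop_zero_variance_channels(inv)
        assert 5 not in kept and len(kept) == 31
        assert len(out.grid) == 31

    def test_no_constant_channels_is_identity(self, tiny_inventory):
        out, kept = drop_zero_variance_channels(tiny_inventory)
        assert len(kept) == len(tiny_inventory.grid)
        assert out is tiny_inventory

    def test_matches_brute_force_scan(self):
        inv = self._with_constant_channels([0, 13, 31])
        _, kept = drop_zero_variance_channels(inv)
        stacked = np.stack([sp.intensities for s in inv.samples for sp in s.replicates])
        brute = [j for j in range(stacked.shape[1]) if np.ptp(stacked[:, j]) > 0]
        assert list(kept) == brute

    def test_idempotent(self):
        inv = self._with_constant_channels([2, 3])
        once, kept1 = drop_zero_variance_channels(inv)
        twice, kept2 = drop_zero_variance_channels(once)
        assert len(kept2) == len(kept1) == 30

    def test_all_constant_is_degenerate(self):
        inv = self._with_constant_channels(range(32))
        with pytest.raises(SpectraError, match="constant"):
            drop_zero_variance_channels(inv)


class TestImputeReplicates:
    def test_missing_replicate_filled_with_first(self):
        inv = make_inventory(samples=[dict(sample_id="A", day=7, n_reps=2)])
        out = impute_missing_replicates(inv)
        reps = out.samples[0].replicates
        assert len(reps) == 3
        assert np.array_equal(reps[2].intensities, reps[0].intensities)

    def test_complete_sample_unchanged(self, tiny_inventory):
        out = impute_missing_replicates(tiny_inventory)
        assert all(len(s.replicates) == 3 for s in out.samples)
        for before, after in zip(tiny_inventory.samples, out.samples):
            for b, a in zip(before.replicates, after.replicates):
                assert np.array_equal(b.intensities, a.intensities)

    def test_count_audit_on_full_roster(self, default_dataset):
        incomplete_before = [s.sample_id for s in default_dataset.samples
                             if len(s.replicates) < 3]
        out = impute_missing_replicates(default_dataset)
        assert len(incomplete_before) == 2
        assert out.n_spectra() == 81 * 3
        changed = [
            s.sample_id for s, o in zip(default_dataset.samples, out.samples)
            if len(s.replicates) != len(o.replicates)
        ]
        assert sorted(changed) == sorted(incomplete_before)


class TestInvariantsAndValidation:
    def test_day_must_be_7_or_28(self):
        with pytest.raises(SpectraError, match="S1"):
            SampleRecord("S1", day=14)

    def test_growth_factors_mutually_exclusive(self):
        with pytest.raises(SpectraError, match="BMP-9 and TGF"):
            SampleRecord("S1", day=7, bmp9=True, tgfb1=True)

    def test_controls_carry_no_constituents(self):
        with pytest.raises(SpectraError, match="controls"):
            SampleRecord("S1", day=7, is_control=True, hav=True)
        # M-PER storage of a control is allowed (buffer, not a culture additive)
        SampleRecord("S2", day=7, is_control=True, mper=True)

    def test_grid_must_increase(self):
        with pytest.raises(SpectraError, match="increasing"):
            WavelengthGrid(np.array([1.0, 3.0, 2.0]))

    def test_preprocess_params_validated(self):
        with pytest.raises(SpectraError):
            PreprocessParams(window_length=12)
        with pytest.raises(SpectraError):
            PreprocessParams(poly_order=13)
        with pytest.raises(SpectraError):
            PreprocessParams(derivative_order=3)
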