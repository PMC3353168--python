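import numpy as np
import pytest

from chronowave import (
    MorletParams,
    TimeSeries,
    apply_edge_correction,
    cone_of_influence,
    morlet_cwt,
    period_grid,
)
from chronowave.cwt import _amplitude_constant


def brute_force_cwt(values, dt, params):
    """Independent time-domain oracle: direct circular convolution with the
    analytic Morlet kernel on the zero-padded record."""
    n = len(values)
    npad = 1 << int(np.ceil(np.log2(n)))
    xp = np.zeros(npad)
    xp[:n] = values - values.mean() if params.demean else values
    periods, scales = period_grid(params, n, dt)
    amp = _amplitude_constant(params.omega0)
    out = np.empty((len(scales), n), dtype=complex)
    shifts = np.arange(-3, 4) * npad  # circular images of the kernel
    for j, s in enumerate(scales):
        for t in range(n):
            tau = (t - np.arange(npad))[None, :] * dt + (shifts * dt)[:, None]
            kernel = (
                amp
                * dt
                / (s * np.sqrt(2.0 * np.pi))
                * np.exp(-(tau**2) / (2.0 * s**2))
                * np.exp(1j * params.omega0 * tau / s)
            ).sum(axis=0)
            out[j, t] = np.sum(xp * kernel)
    return out


class TestPeriodGrid:
    def test_degenerate_single_period(self):
        p = MorletParams(min_period=24, max_period=24)
        periods, scales = period_grid(p, 240, 1.0)
        assert periods.tolist() == [24.0]

    def test_octave_count(self):
        p = MorletParams(min_period=6, max_period=48, voices_per_octave=8)
        periods, _ = period_grid(p, 240, 1.0)
        assert len(periods) == 25  # 3 octaves * 8 voices + 1

    def test_scale_period_ratio_closed_form(self):
        p = MorletParams(omega0=6.0)
        periods, scales = period_grid(p, 240, 1.0)
        ratio = scales / periods
        expected = (6.0 + np.sqrt(38.0)) / (4.0 * np.pi)
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)
        assert expected == pytest.approx(0.9681, abs=2e-4)


class TestMorletCwt:
    def test_zero_signal_zero_coefficients(self):
        res = morlet_cwt(TimeSeries(np.zeros(64)), MorletParams(edge_mode="none"))
        assert np.all(res.coefficients == 0)

    def test_missing_values_rejected(self):
        ts = TimeSeries([1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        with pytest.raises(ValueError, match="fill_missing"):
            morlet_cwt(ts, MorletParams())

    def test_matches_time_domain_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=200)
        params = MorletParams(min_period=6, max_period=32, voices_per_octave=4,
                              edge_mode="none")
        res = morlet_cwt(TimeSeries(values, dt=1.0), params)
        oracle = brute_force_cwt(values, 1.0, params)
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(res.coefficients, oracle, atol=1e-6 * scale)

    def test_amplitude_calibration_across_grid(self, cosine24):
        # unit cosine at every grid period reads ~1 at the record center
        params = MorletParams(edge_mode="none")
        periods, _ = period_grid(params, 480, 1.0)
        t = np.arange(480.0)
        for P in periods[:: len(periods) // 8]:
            res = morlet_cwt(TimeSeries(np.cos(2 * np.pi * t / P)), params)
            j = int(np.argmin(np.abs(res.periods - P)))
            center = np.abs(res.coefficients[j, 240])
            assert 0.98 <= center <= 1.02, f"period {P}: {center}"

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 128))
        params = MorletParams(edge_mode="none", demean=False,
                              min_period=6, max_period=32, voices_per_octave=4)
        wx = morlet_cwt(TimeSeries(x), params).coefficients
        wy = morlet_cwt(TimeSeries(y), params).coefficients
        wmix = morlet_cwt(TimeSeries(2.0 * x - 3.0 * y), params).coefficients
        np.testing.assert_allclose(wmix, 2.0 * wx - 3.0 * wy, atol=1e-9)

    def test_translation_covariance_interior(self):
        # power-of-two length: padding adds nothing, shift is exactly circular
        rng = np.random.default_rng(2)
        x = rng.normal(size=256)
        params = MorletParams(edge_mode="none", demean=False,
                              min_period=6, max_period=32, voices_per_octave=4)
        w = morlet_cwt(TimeSeries(x), params)
        wk = morlet_cwt(TimeSeries(np.roll(x, 17)), params)
        shifted = np.roll(w.coefficients, 17, axis=1)
        interior = w.edge_valid & np.roll(w.edge_valid, 17, axis=1)
        np.testing.assert_allclose(
            wk.coefficients[interior], shifted[interior], atol=1e-6
        )


class TestConeOfInfluence:
    def test_boundary_column_fully_masked(self):
        params = MorletParams()
        coi = cone_of_influence(params, 240, 1.0)
        assert coi[0] == 0.0
        res = morlet_cwt(TimeSeries(np.zeros(240)), params)
        assert not res.edge_valid[:, 0].any()

    def test_center_of_long_record_unmasked(self):
        params = MorletParams()
        coi = cone_of_influence(params, 2000, 1.0)
        assert coi[1000] >= 48.0

    def test_invert_efold_at_period_24(self):
        params = MorletParams()
        s24 = 24.0 / params.fourier_factor
        t_star = np.sqrt(2.0) * s24  # distance where period 24 becomes valid
        coi = cone_of_influence(params, 240, 1.0)
        i = int(np.ceil(t_star))
        assert coi[i - 1] < 24.0 <= coi[i] * (1 + 0.05)

    def test_symmetric_and_monotone_toward_center(self):
        coi = cone_of_influence(MorletParams(), 241, 1.0)
        np.testing.assert_allclose(coi, coi[::-1])
        assert np.all(np.diff(coi[:120]) >= 0)


class TestEdgeCorrection:
    def test_none_is_identity(self, cosine24):
        res = morlet_cwt(cosine24, MorletParams(edge_mode="none"))
        out = apply_edge_correction(res, "none")
        np.testing.assert_array_equal(out.coefficients, res.coefficients)

    def test_reweight_improves_edge_amplitude(self, cosine24):
        raw = morlet_cwt(cosine24, MorletParams(edge_mode="none"))
        rew = apply_edge_correction(raw, "reweight")
        j = int(np.argmin(np.abs(raw.periods - 24.0)))
        t_edge = 48  # 10% in from the left edge
        assert abs(np.abs(rew.coefficients[j, t_edge]) - 1.0) < abs(
            np.abs(raw.coefficients[j, t_edge]) - 1.0
        )

    def test_reweight_leaves_interior_unchanged(self, cosine24):
        raw = morlet_cwt(cosine24, MorletParams(edge_mode="none"))
        rew = apply_edge_correction(raw, "reweight")
        j = int(np.argmin(np.abs(raw.periods - 24.0)))
        assert np.abs(
            rew.coefficients[j, 240] - raw.coefficients[j, 240]
        ) < 1e-6 * np.abs(raw.coefficients[j, 240])

    def test_truncate_masks_edges_not_values(self, signal_a, signal_a_cwt):
        raw = morlet_cwt(signal_a, MorletParams(edge_mode="none"))
        np.testing.assert_array_equal(
            signal_a_cwt.coefficients, raw.coefficients
        )
        assert not signal_a_cwt.edge_valid[:, 0].any()
        assert not signal_a_cwt.edge_valid[:, -1].any()
        # wedge shape: more rows masked near edges than at the center
        n_valid = signal_a_cwt.edge_valid.sum(axis=0)
        assert n_valid[5] < n_valid[120]

    def test_unknown_mode_rejected(self, cosine24):
        res = morlet_cwt(cosine24, MorletParams(edge_mode="none"))
        with pytest.raises(ValueError):
            apply_edge_correction(res, "mirror")

    def test_double_correction_rejected(self, cosine24):
        res = morlet_cwt(cosine24, MorletParams(edge_mode="reweight"))
        with pytest.raises(ValueError):
            apply_edge_correction(res, "truncate")
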