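"""Diffusion-model forward/inverse physics tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnirs.physics import (
    DEFAULT_GATE_SET,
    ExtinctionTable,
    GatedSeries,
    GateSet,
    OpticalProperties,
    TPSFRecord,
    estimate_mua_from_pair,
    gate_tpsf,
    mbll_delta_hbo,
    reflectance_mua_free,
    rhbo_series,
    semi_infinite_reflectance,
)
from tdnirs.physics import _boundary_coefficient

from conftest import make_forward_gated


def oracle_reflectance(t, mua, musp, n, rho):
    """Independently coded extrapolated-boundary DE reflectance.

    Written from the image-source construction (dipole of an isotropic
    source at z0 and its negative image across the extrapolated plane),
    deliberately structured differently from the implementation.
    """
    c = 0.299792458
    v = c / n
    d = 1.0 / (3.0 * musp)
    r_eff = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    zb = 2.0 * d * (1.0 + r_eff) / (1.0 - r_eff)
    z_src = 1.0 / musp
    z_img = -(z_src + 2.0 * zb)

    def fluence_term(z):
        r2 = rho**2 + z**2
        return abs(z) * np.exp(-r2 / (4.0 * d * v * t))

    norm = 0.5 * (4.0 * np.pi * d * v) ** -1.5 * t ** -2.5 * np.exp(-mua * v * t)
    return norm * (fluence_term(z_src) + fluence_term(z_img))


class TestReflectance:
    def test_monotone_in_absorption(self):
        lo = semi_infinite_reflectance(1000.0, OpticalProperties(mua=0.01, musp=1.0))
        hi = semi_infinite_reflectance(1000.0, OpticalProperties(mua=0.02, musp=1.0))
        assert hi < lo

    def test_late_time_log_slope(self):
        """d ln R / dt -> -(mua*v + 5/(2t)) far beyond the diffusion time."""
        props = OpticalProperties(mua=0.01, musp=1.0)
        t1, t2 = 40000.0, 40400.0
        slope = (
            np.log(semi_infinite_reflectance(t2, props) / semi_infinite_reflectance(t1, props))
            / (t2 - t1)
        )
        tm = 0.5 * (t1 + t2)
        expected = -(props.mua * props.v_mm_per_ps + 2.5 / tm)
        assert slope == pytest.approx(expected, rel=0.01)

    def test_delta_mua_late_time_slope_identity(self):
        """An added absorption changes the late-time log ratio by -dmua*v*dt."""
        base = OpticalProperties(mua=0.01, musp=1.0)
        bumped = OpticalProperties(mua=0.015, musp=1.0)
        t1, t2 = 30000.0, 35000.0
        ratio_change = (
            np.log(semi_infinite_reflectance(t2, bumped) / semi_infinite_reflectance(t1, bumped))
            - np.log(semi_infinite_reflectance(t2, base) / semi_infinite_reflectance(t1, base))
        )
        assert ratio_change == pytest.approx(-0.005 * base.v_mm_per_ps * (t2 - t1), rel=1e-6)

    def test_matches_independent_oracle(self):
        props = OpticalProperties(mua=0.01, musp=1.0, n_tissue=1.4, rho=30.0)
        got = semi_infinite_reflectance(1500.0, props)
        want = oracle_reflectance(1500.0, 0.01, 1.0, 1.4, 30.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_boundary_variant_positive_and_smaller_prefactor(self):
        props = OpticalProperties(mua=0.01, musp=1.0)
        r = semi_infinite_reflectance(np.array([500.0, 1500.0]), props, boundary="zero")
        assert np.all(r > 0)

    def test_invalid_arguments_raise(self):
        props = OpticalProperties(mua=0.01, musp=1.0)
        with pytest.raises(ValueError):
            semi_infinite_reflectance(-5.0, props)
        with pytest.raises(ValueError):
            OpticalProperties(mua=-0.01, musp=1.0)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.01, musp=1.0, n_tissue=0.9)


class TestGating:
    def _record(self, counts):
        n_bins = counts.shape[1]
        return TPSFRecord(
            channel_id=1,
            wavelength_nm=760.0,
            bin_edges_ps=np.linspace(0.0, 4000.0, n_bins + 1),
            counts=counts,
            frame_times_s=np.arange(counts.shape[0], dtype=float),
        )

    def test_zero_counts_gate_to_zero(self):
        rec = self._record(np.zeros((3, 80)))
        gated = gate_tpsf(rec)
        assert np.all(gated.values == 0)

    def test_unit_counts_count_whole_bins(self):
        rec = self._record(np.ones((2, 80)))  # 50 ps bins
        gated = gate_tpsf(rec, GateSet(((500.0, 1000.0), (1500.0, 2000.0), (2500.0, 3000.0))))
        assert np.all(gated.values == 10)  # 10 whole 50 ps bins per gate

    def test_partial_bins_excluded(self):
        rec = self._record(np.ones((1, 80)))
        # gate end mid-bin: bin centered at 925 is in, bin at 975 is out
        gated = gate_tpsf(rec, GateSet(((500.0, 970.0), (1500.0, 2000.0), (2500.0, 3000.0))))
        assert gated.values[0, 0, 0, 0] == 9

    def test_gate_outside_support_names_gate(self):
        rec = self._record(np.ones((1, 80)))
        with pytest.raises(ValueError, match="4100"):
            gate_tpsf(rec, GateSet(((500.0, 1000.0), (1500.0, 2000.0), (3900.0, 4100.0))))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_bin_loop(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5.0, (4, 80)).astype(float)
        rec = self._record(counts)
        gate_set = DEFAULT_GATE_SET
        gated = gate_tpsf(rec, gate_set)
        centers = rec.bin_centers_ps
        for g, (a, b) in enumerate(gate_set.gates):
            for f in range(4):
                total = 0.0
                for j, c in enumerate(centers):
                    if a <= c < b:
                        total += counts[f, j]
                assert gated.values[0, 0, g, f] == total


class TestMBLL:
    def _gated_from_od(self, dod, ext, pathlengths):
        """Forward MBLL: intensities realizing a programmed dOD trajectory."""
        n_frames = dod.shape[-1]
        base = 1000.0
        vals = base * np.exp(-dod)  # (ch, wl, gate, T)
        return GatedSeries(
            values=vals,
            channel_ids=tuple(range(1, dod.shape[0] + 1)),
            wavelengths_nm=tuple(ext.wavelengths_nm),
            gate_set=DEFAULT_GATE_SET,
            frame_times_s=np.arange(n_frames, dtype=float),
        )

    def test_identity_input_gives_zero(self):
        ext = ExtinctionTable.default()
        dod = np.zeros((2, 2, 3, 30))
        gated = self._gated_from_od(dod, ext, None)
        series = mbll_delta_hbo(gated, (0.0, 10.0), ext)
        for s in series:
            assert np.allclose(s.values, 0.0)

    def test_round_trip_recovers_programmed_concentrations(self):
        """Forward MBLL synthesis then inversion is exact to machine precision."""
        ext = ExtinctionTable.default()
        e = ext.matrix((760.0, 850.0))
        rng = np.random.default_rng(0)
        n_frames = 40
        hbo = np.concatenate([np.zeros(10), rng.normal(0, 2.0, n_frames - 10)])
        hbr = np.concatenate([np.zeros(10), rng.normal(0, 1.0, n_frames - 10)])
        from tdnirs.physics import pathlengths_from_gates

        lengths = pathlengths_from_gates(DEFAULT_GATE_SET)
        dod = np.zeros((1, 2, 3, n_frames))
        for g in range(3):
            dod[0, :, g, :] = lengths[g] * (e @ np.vstack([hbo, hbr]))
        gated = self._gated_from_od(dod, ext, lengths)
        series = mbll_delta_hbo(gated, (0.0, 10.0), ext)
        for s in series:
            np.testing.assert_allclose(s.values[0], hbo, atol=1e-12)

    def test_linearity_of_inversion(self):
        ext = ExtinctionTable.default()
        rng = np.random.default_rng(1)
        dod = np.zeros((1, 2, 3, 20))
        dod[..., 5:] = rng.normal(0, 0.01, (1, 2, 3, 15))
        s1 = mbll_delta_hbo(self._gated_from_od(dod, ext, None), (0.0, 5.0), ext)
        s2 = mbll_delta_hbo(self._gated_from_od(2 * dod, ext, None), (0.0, 5.0), ext)
        for a, b in zip(s1, s2):
            np.testing.assert_allclose(b.values, 2 * a.values, atol=1e-12)

    def test_dead_baseline_channel_flagged(self):
        ext = ExtinctionTable.default()
        vals = np.full((2, 2, 3, 20), 100.0)
        vals[1] = 0.0
        gated = GatedSeries(
            values=vals,
            channel_ids=(1, 2),
            wavelengths_nm=(760.0, 850.0),
            gate_set=DEFAULT_GATE_SET,
            frame_times_s=np.arange(20.0),
        )
        series = mbll_delta_hbo(gated, (0.0, 5.0), ext)
        assert 2 in series[0].bad_channels
        assert np.all(np.isnan(series[0].values[1]))


class TestMuaEstimation:
    def test_forward_inverse_within_two_percent(self):
        for true_mua in (0.008, 0.012, 0.02):
            gated = make_forward_gated(true_mua, DEFAULT_GATE_SET)
            for pair in (1, 2):
                est = estimate_mua_from_pair(
                    gated, pair, OpticalProperties(mua=0.01, musp=1.0)
                )
                assert est.values[0, 0, 0] == pytest.approx(true_mua, rel=0.02)

    def test_midpoint_error_grows_with_gate_width(self):
        """Closed-form midpoint inverse: exact as width -> 0, bias monotone."""
        errs = []
        for width in (50.0, 150.0, 300.0, 500.0):
            gates = tuple((c - width / 2, c + width / 2) for c in (750.0, 1750.0, 2750.0))
            gated = make_forward_gated(0.012, GateSet(gates))
            est = estimate_mua_from_pair(
                gated, 1, OpticalProperties(mua=0.01, musp=1.0), method="midpoint"
            )
            errs.append(abs(est.values[0, 0, 0] - 0.012))
        assert np.all(np.diff(errs) > 0)
        assert errs[0] < 0.012 * 0.002  # near-exact at 50 ps

    def test_more_late_light_means_less_absorption(self):
        gated = make_forward_gated(0.012, DEFAULT_GATE_SET)
        bumped = GatedSeries(
            values=gated.values.copy(),
            channel_ids=gated.channel_ids,
            wavelengths_nm=gated.wavelengths_nm,
            gate_set=gated.gate_set,
            frame_times_s=gated.frame_times_s,
        )
        bumped.values[:, :, 1, :] *= 1.5  # more photons in the later gate of pair 1
        props = OpticalProperties(mua=0.01, musp=1.0)
        m0 = estimate_mua_from_pair(gated, 1, props).values[0, 0, 0]
        m1 = estimate_mua_from_pair(bumped, 1, props).values[0, 0, 0]
        assert m1 < m0

    def test_vanishing_absorption_floored_and_counted(self):
        """The mua -> 0 boundary case is floored at the configured value."""
        gated = make_forward_gated(1e-6, DEFAULT_GATE_SET)
        est = estimate_mua_from_pair(gated, 1, OpticalProperties(mua=0.01, musp=1.0))
        assert est.n_floored == est.values.size
        assert np.all(est.values == pytest.approx(1e-4))

    def test_nonpositive_intensity_flagged_missing(self):
        gated = make_forward_gated(0.012, DEFAULT_GATE_SET)
        gated.values[0, 0, 1, 0] = 0.0
        est = estimate_mua_from_pair(gated, 1, OpticalProperties(mua=0.01, musp=1.0))
        assert est.n_missing == 1
        assert np.isnan(est.values[0, 0, 0])


class TestRHbO:
    def _mua_estimate(self, mua_values):
        from tdnirs.physics import MuaEstimate

        return MuaEstimate(
            values=mua_values,
            pair=1,
            wavelengths_nm=(760.0, 850.0),
            channel_ids=tuple(range(1, mua_values.shape[0] + 1)),
            frame_times_s=np.arange(mua_values.shape[-1], dtype=float),
        )

    def test_task_equals_rest_gives_unity(self):
        mua = np.full((3, 2, 40), 0.01)
        mua[:, 1, :] = 0.015
        series = rhbo_series(self._mua_estimate(mua), (0.0, 10.0))
        assert np.allclose(series.values, 1.0)

    def test_global_mua_scale_cancels(self):
        rng = np.random.default_rng(3)
        mua = 0.01 + 0.001 * rng.random((2, 2, 40))
        r1 = rhbo_series(self._mua_estimate(mua), (0.0, 10.0))
        r2 = rhbo_series(self._mua_estimate(2 * mua), (0.0, 10.0))
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-12)

    def test_channel_gain_invariance_through_full_chain(self):
        """A per-channel gain on the raw intensities leaves RHbO unchanged."""
        gated = make_forward_gated(0.012, DEFAULT_GATE_SET, n_frames=10)
        scaled = GatedSeries(
            values=gated.values * 3.7,
            channel_ids=gated.channel_ids,
            wavelengths_nm=gated.wavelengths_nm,
            gate_set=gated.gate_set,
            frame_times_s=gated.frame_times_s,
        )
        props = OpticalProperties(mua=0.01, musp=1.0)
        r1 = rhbo_series(estimate_mua_from_pair(gated, 2, props), (0.0, 5.0))
        r2 = rhbo_series(estimate_mua_from_pair(scaled, 2, props), (0.0, 5.0))
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-12)

    def test_negative_baseline_hbo_flags_channel(self):
        mua = np.full((2, 2, 20), 0.01)
        mua[1, 0, :] = 0.03  # wavelength imbalance driving HbO negative
        mua[1, 1, :] = 0.001
        series = rhbo_series(self._mua_estimate(mua), (0.0, 5.0))
        assert 2 in series.bad_channels
        assert np.all(np.isnan(series.values[1]))
        assert np.all(np.isfinite(series.values[0]))


class TestDomainTypes:
    def test_gate_set_validation(self):
        with pytest.raises(ValueError):
            GateSet(((500.0, 400.0), (1500.0, 2000.0), (2500.0, 3000.0)))
        with pytest.raises(ValueError):
            GateSet(((500.0, 1600.0), (1500.0, 2000.0), (2500.0, 3000.0)))
        with pytest.raises(ValueError):
            GateSet(((500.0, 1000.0), (1500.0, 2000.0)))

    def test_extinction_matrix_invertible(self):
        e = ExtinctionTable.default().matrix((760.0, 850.0))
        assert np.linalg.cond(e) < 100

    def test_boundary_coefficient_reasonable(self):
        # internal reflection factor for n ~ 1.4 is around 2-3
        assert 1.5 < _boundary_coefficient(1.4) < 4.0

    def test_reflectance_factorizes_into_m_times_exp(self):
        props = OpticalProperties(mua=0.013, musp=1.0)
        t = np.array([800.0, 2400.0])
        full = semi_infinite_reflectance(t, props)
        m = reflectance_mua_free(t, props)
        np.testing.assert_allclose(
            full, m * np.exp(-props.mua * props.v_mm_per_ps * t), rtol=1e-12
        )
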