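"""Multi-slice SSFP sequence simulation: offsets, saturation, readout, MTR."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intermtr import (
    FULL_RELAXATION,
    MagnetizationState,
    ProtocolParams,
    SliceGeometry,
    TissuePoolParams,
    accumulation_curve,
    delay_sweep,
    dummy_slices_needed,
    evolve_free,
    evolve_pulse,
    flip_angle_sweep,
    get_protocol,
    make_rf_pulse,
    mtr_percent,
    offset_frequency,
    simulate_imaging_slice,
    simulate_mt_weighted,
    simulate_reference,
    simulate_saturation_slice,
)


class TestOffsetFrequency:
    def test_phantom_geometry_worked_values(self, phantom_geometry):
        assert offset_frequency(-1, phantom_geometry) == pytest.approx(-3840.0)
        assert abs(offset_frequency(-6, phantom_geometry)) == pytest.approx(23040.0)
        assert offset_frequency(0, phantom_geometry) == 0.0

    def test_comparison_geometry(self):
        geometry = SliceGeometry(
            rf_bandwidth_hz=4000.0 / 3.0, slice_thickness_mm=5.0, interslice_gap_mm=7.0
        )
        assert abs(offset_frequency(-1, geometry)) == pytest.approx(3200.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(-20, 20))
    def test_antisymmetric_and_linear_in_n(self, phantom_geometry, n):
        delta = offset_frequency(n, phantom_geometry)
        assert delta == -offset_frequency(-n, phantom_geometry)
        assert delta == pytest.approx(n * offset_frequency(1, phantom_geometry))

    def test_ascending_flips_sign(self, phantom_geometry):
        asc = replace(phantom_geometry, slice_order="ascending")
        assert offset_frequency(1, asc) == -offset_frequency(1, phantom_geometry)


class TestSaturationSlice:
    def test_reduces_longitudinal_magnetization(self, wm, fast_protocol):
        eq = MagnetizationState.equilibrium(wm)
        out = simulate_saturation_slice(eq, wm, fast_protocol, 3840.0)
        assert out.mz_free < eq.mz_free
        assert out.mx_free == 0.0 and out.my_free == 0.0  # spoiled

    def test_no_mt_tissue_nearly_unaffected(self, saline, fast_protocol):
        """Direct (non-MT) saturation at >= 3 kHz is below 1% over a slice."""
        protocol = replace(fast_protocol, n_pe_steps=128, n_dummy_pe=30)
        eq = MagnetizationState.equilibrium(saline)
        out = simulate_saturation_slice(eq, saline, protocol, 3840.0)
        assert abs(out.mz_free - eq.mz_free) / eq.mz_free < 0.01

    def test_matches_pulse_by_pulse_loop(self, wm, fast_protocol):
        """The compiled slice train equals an explicit loop of the public
        single-pulse and free-evolution operators with end-of-TR spoiling."""
        state = MagnetizationState.equilibrium(wm)
        fast = simulate_saturation_slice(state, wm, fast_protocol, -3840.0)
        pulse = make_rf_pulse(
            fast_protocol.flip_deg,
            fast_protocol.rf_duration,
            bandwidth_hz=fast_protocol.geometry.rf_bandwidth_hz,
            offset_hz=-3840.0,
        )
        loop = state
        for _ in range(fast_protocol.n_dummy_pe + fast_protocol.n_pe_steps):
            loop = evolve_pulse(loop, pulse, wm, tol=fast_protocol.integration_rtol)
            loop = evolve_free(
                loop, fast_protocol.tr - fast_protocol.rf_duration, wm
            )
            loop = MagnetizationState(0.0, 0.0, loop.mz_free, loop.mz_restricted)
        assert fast.mz_free == pytest.approx(loop.mz_free, rel=1e-12)
        assert fast.mz_restricted == pytest.approx(loop.mz_restricted, rel=1e-12)

    def test_zero_offset_rejected(self, wm, fast_protocol):
        with pytest.raises(ValueError):
            simulate_saturation_slice(
                MagnetizationState.equilibrium(wm), wm, fast_protocol, 0.0
            )


def no_mt_tissue(t1=1.1, t2=0.085):
    return TissuePoolParams(
        t1_free=t1, t2_free=t2, t1_restricted=1.0, t2_restricted=10e-6,
        pool_ratio_F=0.0, exchange_rate_kr=0.0, g_zero=0.0,
    )


class TestImagingSlice:
    def test_no_mt_limit_matches_alternating_phase_steady_state(self):
        """With no restricted pool and a hard pulse, the trace converges to
        M0 sin(a) (1-E1) / (1 - (E1-E2) cos(a) - E1 E2)."""
        tissue = no_mt_tissue()
        tr, alpha = 4.56e-3, math.radians(50.0)
        protocol = ProtocolParams(
            geometry=SliceGeometry(1600.0, 4.0, 5.6),
            tr=tr,
            te=0.025e-3,  # read right after the (hard) pulse
            flip_deg=50.0,
            n_pe_steps=1500,
            n_dummy_pe=0,
            rf_duration=0.05e-3,
            rf_shape="rect",
            n_prior_slices=0,
        )
        signal = simulate_imaging_slice(
            MagnetizationState.equilibrium(tissue), tissue, protocol
        )
        e1, e2 = math.exp(-tr / tissue.t1_free), math.exp(-tr / tissue.t2_free)
        expected = (
            tissue.m0_free * math.sin(alpha) * (1 - e1)
            / (1 - (e1 - e2) * math.cos(alpha) - e1 * e2)
        )
        assert signal.trace[-1] == pytest.approx(expected, rel=0.01)

    def test_zero_flip_gives_zero_trace(self, wm, fast_protocol):
        protocol = replace(fast_protocol, flip_deg=0.0)
        signal = simulate_imaging_slice(
            MagnetizationState.equilibrium(wm), wm, protocol
        )
        assert np.all(signal.trace == 0.0)

    def test_center_k_index_conventions(self, fast_protocol):
        assert replace(fast_protocol, pe_order="centric").center_k_index == 0
        linear = replace(fast_protocol, pe_order="linear", n_pe_steps=128)
        assert linear.center_k_index == 63  # ceil(128/2) = 64, 1-based
        pf = replace(linear, partial_fourier=0.75)
        assert pf.center_k_index == 47  # ceil(128*0.75/2) = 48, 1-based

    def test_saturated_start_gives_smaller_signal(self, wm, fast_protocol):
        eq = MagnetizationState.equilibrium(wm)
        from_eq = simulate_imaging_slice(eq, wm, fast_protocol)
        state = eq
        for offset in fast_protocol.prior_slice_offsets():
            state = simulate_saturation_slice(state, wm, fast_protocol, offset)
        weighted = simulate_imaging_slice(state, wm, fast_protocol)
        assert weighted.center_k_signal < from_eq.center_k_signal


class TestMTWeightedAndReference:
    def test_reference_full_relaxation_equals_equilibrium_readout(self, wm, fast_protocol):
        ref = simulate_reference(wm, fast_protocol, delay=FULL_RELAXATION)
        direct = simulate_imaging_slice(
            MagnetizationState.equilibrium(wm), wm, fast_protocol
        )
        np.testing.assert_array_equal(ref.trace, direct.trace)

    def test_zero_delay_reference_equals_mt_weighted(self, wm, fast_protocol):
        ref0 = simulate_reference(wm, fast_protocol, delay=0.0)
        mt = simulate_mt_weighted(wm, fast_protocol)
        np.testing.assert_array_equal(ref0.trace, mt.trace)

    def test_no_prior_slices_degenerates_to_reference(self, wm, fast_protocol):
        protocol = replace(fast_protocol, n_prior_slices=0)
        mt = simulate_mt_weighted(wm, protocol)
        ref = simulate_reference(wm, protocol, delay=FULL_RELAXATION)
        np.testing.assert_array_equal(mt.trace, ref.trace)

    def test_deterministic_bit_identical(self, wm, fast_protocol):
        a = simulate_mt_weighted(wm, fast_protocol)
        b = simulate_mt_weighted(wm, fast_protocol)
        assert a.center_k_signal == b.center_k_signal
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_saline_shows_no_mt_contrast(self, saline):
        """The no-MT control: MT-weighted equals reference within 1%."""
        protocol = get_protocol("phantom", n_pe_steps=64, n_dummy_pe=16)
        mt = simulate_mt_weighted(saline, protocol).center_k_signal
        ref = simulate_reference(saline, protocol, delay=FULL_RELAXATION).center_k_signal
        assert abs(mtr_percent(mt, ref)) < 1.0

    def test_centric_mtr_exceeds_linear(self, wm, fast_protocol):
        protocol = replace(fast_protocol, n_pe_steps=64, n_dummy_pe=16)
        mtrs = {}
        for order in ("centric", "linear"):
            p = replace(protocol, pe_order=order)
            mt = simulate_mt_weighted(wm, p).center_k_signal
            ref = simulate_reference(wm, p, delay=FULL_RELAXATION).center_k_signal
            mtrs[order] = mtr_percent(mt, ref)
        assert mtrs["centric"] >= mtrs["linear"]


class TestMTRPercent:
    def test_arithmetic(self):
        assert mtr_percent(1.0, 1.0) == 0.0
        assert mtr_percent(0.6, 1.0) == pytest.approx(40.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mtr_percent(0.5, 0.0)
        with pytest.raises(ValueError):
            mtr_percent(0.5, -1.0)

    @settings(derandomize=True, max_examples=30)
    @given(mt=st.floats(0.0, 2.0), ref=st.floats(1e-3, 2.0))
    def test_bounded_above_by_100(self, mt, ref):
        assert mtr_percent(mt, ref) <= 100.0


class TestAccumulation:
    def test_curve_starts_at_equilibrium_and_decreases(self, wm, gm, fast_protocol):
        for tissue in (wm, gm):
            curve = accumulation_curve(tissue, fast_protocol, 4)
            assert curve[0] == tissue.m0_free
            assert np.all(np.diff(curve) <= 1e-12)

    def test_plateau_matches_independent_loop_oracle(self, wm, fast_protocol):
        """The curve plateau agrees with an independently coded pulse-by-pulse
        loop over prepended prior slices, and is bounded below by the true
        steady state (an infinite pulse chain at the base offset)."""
        curve = accumulation_curve(wm, fast_protocol, 6)
        assert abs(curve[-1] - curve[-2]) / curve[-2] < 1e-3  # plateaued
        base = offset_frequency(-1, fast_protocol.geometry)
        pulses_per_slice = fast_protocol.n_dummy_pe + fast_protocol.n_pe_steps
        state = MagnetizationState.equilibrium(wm)
        for j in range(8, 0, -1):  # slice at j*base down to the base offset
            pulse = make_rf_pulse(
                fast_protocol.flip_deg,
                fast_protocol.rf_duration,
                bandwidth_hz=fast_protocol.geometry.rf_bandwidth_hz,
                offset_hz=j * base,
            )
            for _ in range(pulses_per_slice):
                state = evolve_pulse(state, pulse, wm)
                state = evolve_free(
                    state, fast_protocol.tr - fast_protocol.rf_duration, wm
                )
                state = MagnetizationState(0.0, 0.0, state.mz_free, state.mz_restricted)
        assert curve[-1] == pytest.approx(state.mz_free, rel=0.02)
        # true steady state: infinite chain of base-offset pulses
        fixed = MagnetizationState.equilibrium(wm)
        for _ in range(40):
            prev = fixed.mz_free
            fixed = simulate_saturation_slice(fixed, wm, fast_protocol, base)
            if abs(fixed.mz_free - prev) < 1e-10:
                break
        assert curve[-1] >= fixed.mz_free

    def test_dummy_slices_needed_on_constructed_sequence(self):
        # geometric approach to a plateau: relative changes 0.25, 0.167, 0.1, 0.056
        curve = 0.5 + 0.5 * 0.5 ** np.arange(6)
        assert dummy_slices_needed(curve, 0.06) == 4
        assert dummy_slices_needed(np.ones(4), 0.01) == 1

    def test_dummy_slices_sentinel_on_nonconverging_curve(self):
        with pytest.warns(RuntimeWarning):
            assert dummy_slices_needed(2.0 ** -np.arange(4), 0.01) is None


class TestSweeps:
    def test_flip_angle_sweep_single_point_matches_direct_call(self, wm, fast_protocol):
        table = flip_angle_sweep(wm, fast_protocol, [fast_protocol.flip_deg])
        mt = simulate_mt_weighted(wm, fast_protocol).center_k_signal
        ref = simulate_reference(wm, fast_protocol).center_k_signal
        assert table.loc[0, "mtr_percent"] == mtr_percent(mt, ref)

    def test_wm_mtr_increases_with_flip_angle(self, wm, fast_protocol):
        table = flip_angle_sweep(wm, fast_protocol, [15.0, 45.0, 90.0])
        mtrs = table["mtr_percent"].to_numpy()
        assert np.all(np.diff(mtrs) > 0)

    def test_delay_sweep_monotone_nondecreasing(self, wm, fast_protocol):
        protocol = replace(fast_protocol, reference_delay=6.0)
        table = delay_sweep(wm, protocol, [0.0, 1.0, 3.0, 8.0])
        mtrs = table["mtr_percent"].to_numpy()
        assert np.all(np.diff(mtrs) >= 0)
        assert table.loc[3, "mtr_percent"] > table.loc[1, "mtr_percent"]

    def test_empty_grid_rejected(self, wm, fast_protocol):
        with pytest.raises(ValueError):
            flip_angle_sweep(wm, fast_protocol, [])


class TestProtocolPresets:
    def test_presets_load_with_printed_parameters(self):
        p = get_protocol("flip_angle_experiment")
        assert p.tr == pytest.approx(4.11e-3)
        assert p.n_pe_steps == 128 and p.n_dummy_pe == 30
        assert math.isinf(p.reference_delay)
        wb = get_protocol("whole_brain_bssfp")
        assert wb.geometry.slice_thickness_mm == 3.0
        assert wb.reference_delay == 6.0
        assert abs(offset_frequency(-1, wb.geometry)) == pytest.approx(3840.0)

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            get_protocol("nonexistent")
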