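"""EPG engine: operator semantics, closed forms, and the Bloch oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wt2map import (
    EPGState,
    RelaxationParams,
    SequenceParams,
    epg_cpmg,
    relax_and_shift,
    rf_rotation,
    simulate_voxel_signal,
)
from wt2map.epg import epg_cpmg_batch, slice_profile_train
from wt2map.rf_profiles import SliceProfileTable, rectangular_profile
from wt2map.validation import bloch_isochromat_cpmg


def _state_norm(state: EPGState) -> float:
    return float(
        np.sum(np.abs(state.f_plus) ** 2)
        + np.sum(np.abs(state.f_minus[1:]) ** 2)
        + np.sum(np.abs(state.z) ** 2)
    )


class TestRotation:
    def test_zero_flip_is_identity(self):
        state = EPGState.equilibrium(8)
        state.f_plus[2] = 0.3 + 0.1j
        out = rf_rotation(state, 0.0, 0.7)
        np.testing.assert_allclose(out.f_plus, state.f_plus)
        np.testing.assert_allclose(out.f_minus, state.f_minus)
        np.testing.assert_allclose(out.z, state.z)

    def test_90_excitation_from_equilibrium(self):
        state = EPGState.equilibrium(8)
        out = rf_rotation(state, np.pi / 2, 0.0)
        assert abs(abs(out.f_plus[0]) - 1.0) < 1e-12
        assert abs(out.z[0]) < 1e-12

    def test_perfect_refocusing_swaps_conjugate_orders(self):
        """A 180 pulse with CPMG phase moves F(+1) to F(-1) (conjugated)
        and inverts longitudinal states."""
        state = EPGState(max_order=8)
        state.f_plus[1] = 0.5 + 0.2j
        state.z[2] = 0.3 + 0.1j
        out = rf_rotation(state, np.pi, np.pi / 2)
        # f_minus stores the conjugate-transverse component, so the
        # y-phase 180 deposits -F(+1) there
        assert abs(out.f_minus[1] + state.f_plus[1]) < 1e-12
        assert abs(abs(out.f_minus[1]) - abs(state.f_plus[1])) < 1e-12
        assert abs(out.f_plus[1]) < 1e-12
        assert abs(out.z[2] + state.z[2]) < 1e-12

    def test_nonfinite_flip_rejected(self):
        with pytest.raises(ValueError):
            rf_rotation(EPGState.equilibrium(4), np.nan)


class TestRelaxAndShift:
    def test_zero_duration_only_shifts(self):
        state = EPGState(max_order=6)
        state.f_plus[0] = 0.5
        state.f_minus[0] = 0.5
        state.f_minus[1] = 0.2j
        before = _state_norm(state)
        out = relax_and_shift(state, 0.0, RelaxationParams(1000, 50))
        assert abs(out.f_plus[1]) == pytest.approx(0.5)
        assert abs(out.f_plus[0]) == pytest.approx(0.2)
        assert _state_norm(out) == pytest.approx(before, rel=1e-12)

    def test_quasi_infinite_relaxation_preserves_magnitudes(self):
        state = EPGState(max_order=6)
        state.f_plus[1] = 0.4 - 0.3j
        out = relax_and_shift(state, 100.0, RelaxationParams(1e12, 1e12))
        assert abs(out.f_plus[2]) == pytest.approx(0.5, abs=1e-9)

    def test_transverse_scaling_factor(self):
        state = EPGState(max_order=6)
        state.f_plus[1] = 1.0
        out = relax_and_shift(state, 5.45, RelaxationParams(1400, 50))
        assert abs(out.f_plus[2]) == pytest.approx(np.exp(-5.45 / 50), rel=1e-12)

    def test_order_overflow_raises(self):
        state = EPGState(max_order=2)
        state.f_plus[2] = 0.1
        with pytest.raises(OverflowError):
            relax_and_shift(state, 1.0, RelaxationParams(1000, 50))


class TestCpmg:
    @pytest.mark.parametrize("t2", [30.0, 50.0, 80.0])
    @pytest.mark.parametrize("t1", [600.0, 1400.0])
    def test_perfect_refocusing_closed_form(self, t1, t2):
        """Exact 180s leave no stimulated pathways: echo n = exp(-n*esp/T2),
        independent of T1."""
        seq = SequenceParams()
        echoes = epg_cpmg(RelaxationParams(t1, t2), seq)
        expected = np.exp(-seq.echo_times / t2)
        np.testing.assert_allclose(echoes, expected, atol=1e-9)

    def test_infinite_t2_perfect_refocusing_gives_unity(self):
        seq = SequenceParams(n_echoes=10)
        echoes = epg_cpmg(RelaxationParams(1e12, 1e12), seq)
        np.testing.assert_allclose(echoes, 1.0, atol=1e-9)

    @pytest.mark.parametrize("b1", [0.5, 0.8, 1.2])
    def test_matches_isochromat_bloch_oracle(self, b1):
        """EPG and a 256-isochromat brute-force Bloch simulation agree."""
        seq = SequenceParams()
        exc, ref = b1 * np.pi / 2, b1 * np.pi
        echoes = epg_cpmg(
            RelaxationParams(1400, 50), seq,
            exc_flip=exc, ref_flips=np.full(seq.n_echoes, ref),
        )
        oracle = bloch_isochromat_cpmg(1400, 50, seq.n_echoes, seq.echo_spacing,
                                       exc_flip=exc, ref_flip=ref)
        np.testing.assert_allclose(echoes, oracle, atol=1e-6)

    def test_stimulated_echoes_prolong_apparent_decay(self):
        """With sub-180 refocusing, stimulated pathways push later echoes
        above the pure T2 decay (individual echoes alternate even/odd, but
        the train as a whole decays slower than exp(-t/T2))."""
        seq = SequenceParams()
        t2 = 40.0
        echoes = epg_cpmg(
            RelaxationParams(1400, t2), seq,
            exc_flip=np.pi / 2, ref_flips=np.full(seq.n_echoes, 0.7 * np.pi),
        )
        ratio = echoes / np.exp(-seq.echo_times / t2)
        assert np.any(ratio[1:] > 1 + 1e-6)
        # effective decay time between first and last echo exceeds T2
        t2_eff = (seq.echo_times[-1] - seq.echo_times[0]) / np.log(echoes[0] / echoes[-1])
        assert t2_eff > t2

    def test_echoes_monotone_in_t2(self):
        seq = SequenceParams(n_echoes=12)
        ref = np.full(12, 0.85 * np.pi)
        prev = None
        for t2 in [25.0, 40.0, 60.0, 80.0]:
            echoes = epg_cpmg(RelaxationParams(1400, t2), seq,
                              exc_flip=np.pi / 2, ref_flips=ref)
            if prev is not None:
                assert np.all(echoes >= prev - 1e-12)
            prev = echoes

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ValueError):
            RelaxationParams(1400, -5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        b1=st.floats(0.4, 1.4),
        t2=st.floats(20.0, 150.0),
        t1=st.floats(200.0, 2000.0),
    )
    def test_batch_engine_matches_scalar_path(self, b1, t2, t1):
        """The vectorized dictionary engine and the per-state scalar EPG
        are the same physics."""
        t1 = max(t1, t2)
        seq = SequenceParams(n_echoes=9)
        scalar = epg_cpmg(
            RelaxationParams(t1, t2), seq,
            exc_flip=b1 * np.pi / 2, ref_flips=np.full(9, b1 * np.pi),
        )
        batch = epg_cpmg_batch(t1, t2, b1 * np.pi / 2, b1 * np.pi, 9, seq.echo_spacing)
        np.testing.assert_allclose(batch, scalar, atol=1e-12)


class TestVoxelSignal:
    def test_fat_fraction_weights(self, seq17, rect_profile):
        water = simulate_voxel_signal(50, 0.0, 1.0, seq17, rect_profile)
        fat_a = simulate_voxel_signal(30, 1.0, 1.0, seq17, rect_profile)
        fat_b = simulate_voxel_signal(70, 1.0, 1.0, seq17, rect_profile)
        np.testing.assert_allclose(fat_a, fat_b)  # wT2 irrelevant at FF=1
        half = simulate_voxel_signal(50, 0.5, 1.0, seq17, rect_profile)
        np.testing.assert_allclose(half, 0.5 * water + 0.5 * fat_a, atol=1e-14)

    def test_rectangular_profile_collapses_to_hard_pulse(self, seq17, rect_profile):
        sig = simulate_voxel_signal(50, 0.0, 1.0, seq17, rect_profile)
        hard = epg_cpmg(RelaxationParams(1400, 50), seq17)
        sat = seq17.saturation_factor(1400)
        np.testing.assert_allclose(sig, sat * hard, atol=1e-12)

    def test_constant_profile_table_degenerate(self, seq17):
        """A multi-point but constant profile equals the hard-pulse result."""
        table = SliceProfileTable(
            positions=np.linspace(-1, 1, 9),
            exc_flip=np.full(9, np.pi / 2),
            ref_flip=np.full(9, np.pi),
        )
        train = slice_profile_train(RelaxationParams(1400, 50), seq17, table)
        hard = epg_cpmg(RelaxationParams(1400, 50), seq17)
        np.testing.assert_allclose(train, hard, atol=1e-12)

    def test_tr_saturation_factors(self, seq17, rect_profile):
        sat_on = simulate_voxel_signal(50, 0.0, 1.0, seq17, rect_profile)
        seq_off = SequenceParams(apply_tr_saturation=False)
        sat_off = simulate_voxel_signal(50, 0.0, 1.0, seq_off, rect_profile)
        expected = 1.0 - np.exp(-seq17.tr / 1400.0)
        np.testing.assert_allclose(sat_on, expected * sat_off, rtol=1e-12)

    def test_invalid_inputs_rejected(self, seq17, rect_profile):
        with pytest.raises(ValueError):
            simulate_voxel_signal(50, 1.2, 1.0, seq17, rect_profile)
        with pytest.raises(ValueError):
            simulate_voxel_signal(50, 0.2, -0.5, seq17, rect_profile)

    def test_all_amplitudes_nonnegative_finite(self, seq17, sinc_profile):
        sig = simulate_voxel_signal(35, 0.3, 0.7, seq17, sinc_profile)
        assert sig.shape == (17,)
        assert np.all(np.isfinite(sig)) and np.all(sig >= 0)


def test_sequence_params_validation():
    with pytest.raises(ValueError):
        SequenceParams(n_echoes=0)
    with pytest.raises(ValueError):
        SequenceParams(echo_spacing=-1)
    with pytest.raises(ValueError):
        SequenceParams(tr=100.0)  # shorter than the echo train
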