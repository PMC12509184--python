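"""Spin-rotation propagation and excitation-sculpting profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsuppress import (
    ExcitationProfile,
    HardPulse,
    InvalidParameterError,
    PresatConfig,
    PulseTrain,
    SequenceSpec,
    build_w5,
    element_rotation,
    presat_steady_state,
    sculpting_profile,
)
from qsuppress.simulate import _propagate


def rotation_matrix_oracle(train: PulseTrain, offset: float) -> np.ndarray:
    """Independent 3x3 rotation-matrix propagation of the same train."""

    def axis_angle(axis, angle):
        axis = np.asarray(axis, dtype=float)
        n = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]]
        )
        return (
            np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        )

    R = np.eye(3)
    npulses = len(train.elements)
    for i, p in enumerate(train.elements):
        ph = np.deg2rad(p.phase)
        if p.duration == 0:
            R = axis_angle(
                [np.cos(ph), np.sin(ph), 0.0], np.deg2rad(p.flip_angle)
            ) @ R
        else:
            rf = p.rf_amplitude
            veff = np.hypot(rf, offset)
            R = axis_angle(
                [rf * np.cos(ph), rf * np.sin(ph), offset],
                2 * np.pi * veff * p.duration,
            ) @ R
        if i < npulses - 1:
            R = axis_angle([0, 0, 1.0], 2 * np.pi * offset * train.delays[i]) @ R
    return R


_PAULI = [
    np.array([[0, 1], [1, 0]], dtype=complex),
    np.array([[0, -1j], [1j, 0]], dtype=complex),
    np.array([[1, 0], [0, -1]], dtype=complex),
]


def su2_to_so3(alpha: complex, beta: complex) -> np.ndarray:
    """SO(3) image of an SU(2) element via the conjugation map
    R_ij = Tr(sigma_i U sigma_j U^dagger) / 2."""
    U = np.array([[alpha, -np.conj(beta)], [beta, np.conj(alpha)]])
    return np.array(
        [
            [
                0.5 * np.real(np.trace(si @ U @ sj @ U.conj().T))
                for sj in _PAULI
            ]
            for si in _PAULI
        ]
    )


class TestElementRotation:
    def test_ideal_180_inverts_at_any_offset(self):
        train = PulseTrain((HardPulse(180.0),), (), 1800.0)
        for off in (0.0, 537.0, -2200.0):
            rot = element_rotation(train, off)
            assert abs(rot.beta) == pytest.approx(1.0, abs=1e-12)

    def test_w5_identity_on_resonance(self):
        rot = element_rotation(build_w5(1800.0), 0.0)
        assert abs(rot.beta) < 1e-12

    @given(
        offset=st.floats(-3000, 3000),
        rf=st.one_of(st.none(), st.floats(500, 50e3)),
    )
    @settings(max_examples=40, deadline=None)
    def test_unitarity(self, offset, rf):
        rot = element_rotation(build_w5(1800.0, rf_amplitude=rf), offset)
        assert rot.unitarity_defect() < 1e-9

    @pytest.mark.parametrize("rf", [None, 25e3, 3e3])
    @pytest.mark.parametrize("offset", [0.0, 313.0, -1117.0, 2401.5])
    def test_agrees_with_rotation_matrix_oracle(self, rf, offset):
        """Cayley-Klein propagation and independent 3x3 rotation-matrix
        propagation describe the same net rotation."""
        train = build_w5(1800.0, rf_amplitude=rf)
        rot = element_rotation(train, offset)
        R_ck = su2_to_so3(rot.alpha, rot.beta)
        R_oracle = rotation_matrix_oracle(train, offset)
        assert np.allclose(R_ck, R_oracle, atol=1e-8)


class TestSculptingProfile:
    def test_zero_on_resonance(self, w5_1800_profile):
        i0 = np.argmin(np.abs(w5_1800_profile.offsets))
        assert w5_1800_profile.retained_fraction[i0] < 1e-20

    def test_first_null_at_1800(self, w5_1800_profile):
        i = np.argmin(np.abs(w5_1800_profile.offsets - 1800.0))
        assert w5_1800_profile.retained_fraction[i] < 1e-20

    def test_inversion_band_plateau(self):
        """Brute-force maximization over one period: the profile plateaus
        near unity across the middle of the inversion band; halfway
        between nulls (+-900 Hz) the retained fraction is within 5e-4 of
        the global maximum."""
        offs = np.arange(-1800.0, 1800.5, 1.0)
        prof = sculpting_profile(
            SequenceSpec(build_w5(1800.0)), offs
        ).retained_fraction
        peak = prof.max()
        assert peak == pytest.approx(1.0, abs=1e-4)
        at_900 = prof[np.abs(np.abs(offs) - 900.0) < 0.5]
        assert np.all(peak - at_900 < 5e-4)

    def test_periodicity_of_idealized_train(self):
        offs = np.arange(-800.0, 800.0, 37.0)
        spec = SequenceSpec(build_w5(1800.0))
        base = sculpting_profile(spec, offs).retained_fraction
        shifted = sculpting_profile(spec, offs + 1800.0).retained_fraction
        assert np.allclose(base, shifted, atol=1e-8)

    def test_even_symmetry(self, w5_1800_profile):
        assert np.allclose(
            w5_1800_profile.retained_fraction,
            w5_1800_profile.retained_fraction[::-1],
            atol=1e-8,
        )

    def test_double_echo_is_square_of_single(self):
        offs = np.arange(-2000.0, 2000.0, 111.0)
        train = build_w5(1800.0)
        single = sculpting_profile(
            SequenceSpec(train, echo_count=1), offs
        ).retained_fraction
        double = sculpting_profile(
            SequenceSpec(train, echo_count=2), offs
        ).retained_fraction
        assert np.allclose(double, single**2, atol=1e-12)

    def test_perfect_echo_flag_does_not_change_profile(self):
        offs = np.arange(-1000.0, 1000.0, 77.0)
        train = build_w5(1800.0)
        a = sculpting_profile(SequenceSpec(train), offs)
        b = sculpting_profile(SequenceSpec(train, perfect_echo=True), offs)
        assert np.array_equal(a.retained_fraction, b.retained_fraction)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            sculpting_profile(SequenceSpec(build_w5(1800.0)), np.array([]))

    def test_retained_fraction_bounded(self, w5_1800_profile):
        frac = w5_1800_profile.retained_fraction
        assert np.all(frac >= 0.0)
        assert np.all(frac <= 1.0 + 1e-9)


class TestExcitationProfileContainer:
    def test_offsets_must_increase(self):
        with pytest.raises(InvalidParameterError):
            ExcitationProfile(
                offsets=np.array([0.0, 0.0, 1.0]),
                retained_fraction=np.array([1.0, 1.0, 1.0]),
            )

    def test_normalized_scales_to_unit_plateau(self, w5_1800_profile):
        norm = w5_1800_profile.normalized()
        assert norm.retained_fraction.max() == pytest.approx(1.0)
        assert norm.normalization == "plateau-normalized"

    def test_interp_outside_grid_rejected(self, w5_1800_profile):
        with pytest.raises(InvalidParameterError):
            w5_1800_profile.interp(np.array([9000.0]))


class TestPresatSteadyState:
    def test_no_irradiation_leaves_mz(self):
        cfg = PresatConfig(rf_field=0.0, duration=15.0, T1=3.0, T2=0.5)
        assert presat_steady_state(cfg, 0.0) == 1.0

    def test_strong_field_saturates(self):
        cfg = PresatConfig(rf_field=5000.0, duration=15.0, T1=3.0, T2=0.5)
        assert presat_steady_state(cfg, 0.0) < 1e-6

    def test_on_resonance_closed_form(self):
        cfg = PresatConfig(rf_field=29.5, duration=15.0, T1=3.0, T2=0.5)
        expected = 1.0 / (1.0 + (2 * np.pi * 29.5) ** 2 * 3.0 * 0.5)
        assert presat_steady_state(cfg, 0.0) == pytest.approx(expected)

    @pytest.mark.parametrize("offset", [0.0, 40.0, -250.0])
    def test_matches_bloch_linear_solve(self, offset):
        """Oracle: steady state of the full Bloch equations solved as a
        3x3 linear system."""
        T1, T2, nu1 = 3.85, 0.4, 29.5
        w1, d = 2 * np.pi * nu1, 2 * np.pi * offset
        A = np.array(
            [[-1 / T2, d, 0], [-d, -1 / T2, w1], [0, -w1, -1 / T1]]
        )
        mz = np.linalg.solve(A, np.array([0.0, 0.0, -1 / T1]))[2]
        cfg = PresatConfig(rf_field=nu1, duration=15.0, T1=T1, T2=T2)
        assert presat_steady_state(cfg, offset) == pytest.approx(mz, abs=1e-12)

    def test_monotone_in_rf_field(self):
        fields = [8.0, 12.0, 29.5, 50.0, 100.0]
        vals = [
            presat_steady_state(
                PresatConfig(rf_field=f, duration=15.0, T1=3.0, T2=0.5), 25.0
            )
            for f in fields
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(InvalidParameterError):
            presat_steady_state(
                PresatConfig(rf_field=10.0, duration=1.0, T1=0.0, T2=0.5), 0.0
            )
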