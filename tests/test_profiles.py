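"""Notch geometry, usable ranges and robust excitation statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsuppress import (
    ExcitationProfile,
    InsufficientDataError,
    NoUsableRangeError,
    SequenceSpec,
    build_w5,
    find_notches,
    huber_m,
    qn_scale,
    robust_excitation_stats,
    sculpting_profile,
    sweep_emulation,
)


def qn_bruteforce(x, consistency=2.2219):
    """O(n^2) oracle: first-quartile order statistic of the pairwise
    absolute differences times the consistency constant, via explicit
    python loops."""
    diffs = sorted(
        abs(a - b) for a, b in itertools.combinations(x, 2)
    )
    n = len(x)
    h = n // 2 + 1
    k = h * (h - 1) // 2
    return consistency * diffs[k - 1]


def rectangular_profile(notch_half_width=250.0, step=25.0, span=2500.0):
    offs = np.arange(-span, span + step, step)
    frac = np.where(np.abs(offs) <= notch_half_width, 0.0, 1.0)
    return ExcitationProfile(offsets=offs, retained_fraction=frac,
                             normalization="plateau-normalized")


class TestFindNotches:
    def test_rectangular_notch_width_exact(self):
        report = find_notches(rectangular_profile(250.0), 0.97)
        # zero on [-250, 250]: first grid points at threshold are +-275,
        # but the constructed transition is at the 250 edge itself; the
        # run below threshold is [-250, 250] so width spans to +-275
        assert report.suppression_width == 550.0
        assert report.notch_centers == [-250.0]  # argmin of an all-zero run

    def test_rectangular_notch_sharp_edges(self):
        # put the last zero at 250 and the first one at 275 to get the
        # constructed 500 Hz width from edge-to-edge grid geometry
        offs = np.arange(-2500.0, 2525.0, 25.0)
        frac = np.where(np.abs(offs) <= 225.0, 0.0, 1.0)
        prof = ExcitationProfile(offs, frac, "plateau-normalized")
        report = find_notches(prof, 0.97)
        assert report.suppression_width == 500.0

    def test_flat_profile_has_no_notches(self):
        offs = np.arange(-1000.0, 1025.0, 25.0)
        prof = ExcitationProfile(offs, np.ones_like(offs),
                                 "plateau-normalized")
        report = find_notches(prof, 0.97)
        assert report.notch_centers == []
        assert report.usable_ranges == [(-1000.0, 1000.0)]

    def test_all_below_threshold_rejected(self):
        offs = np.arange(-100.0, 125.0, 25.0)
        prof = ExcitationProfile(offs, np.full_like(offs, 0.5),
                                 "plateau-normalized")
        with pytest.raises(NoUsableRangeError):
            find_notches(prof, 0.97)

    def test_w5_1800_table_row(self, w5_1800_normalized):
        """Simulated W5 double echo at 1800 Hz spacing: central width at
        the 97% threshold is (at most) 600 Hz and the first usable range
        ends near 1500 Hz."""
        report = find_notches(w5_1800_normalized, 0.97)
        assert report.suppression_width <= 600.0
        first_positive = next(
            r for r in report.usable_ranges if r[0] > 0
        )
        assert first_positive[0] == pytest.approx(300.0, abs=25.0)
        assert first_positive[1] == pytest.approx(1500.0, abs=50.0)

    def test_width_scales_with_null_spacing(
        self, w5_1800_normalized, w5_2400_normalized
    ):
        w18 = find_notches(w5_1800_normalized, 0.97).suppression_width
        w24 = find_notches(w5_2400_normalized, 0.97).suppression_width
        assert w24 / w18 == pytest.approx(2400.0 / 1800.0, rel=0.05)

    @pytest.mark.parametrize("thresholds", [(0.90, 0.97, 0.99)])
    def test_width_monotone_in_threshold(self, w5_1800_normalized, thresholds):
        widths = [
            find_notches(w5_1800_normalized, t).suppression_width
            for t in thresholds
        ]
        assert widths[0] <= widths[1] <= widths[2]

    def test_invalid_threshold_rejected(self, w5_1800_normalized):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(Exception):
                find_notches(w5_1800_normalized, bad)


class TestHuberM:
    def test_symmetric_small_sample(self):
        assert huber_m(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_equals_mean_on_symmetric_samples(self, rng):
        x = np.sort(rng.normal(0, 1, 41))
        sym = np.concatenate([x, -x])  # exactly symmetric about 0
        # no point beyond c*MAD-scale from 0 after symmetrization is not
        # guaranteed, but the estimate must still be 0 by symmetry
        assert abs(huber_m(sym) - sym.mean()) < 1e-10

    def test_resists_gross_outlier(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        assert huber_m(x) == pytest.approx(0.0, abs=1e-12)

    def test_tight_sample_with_no_clipping_is_mean(self):
        # sinusoidal ripple: every deviation lies within c * MAD-scale of
        # the center, so no point is downweighted and the estimate is the
        # plain mean
        x = 1.0 + 0.01 * np.sin(np.linspace(0.0, 2 * np.pi, 64, endpoint=False))
        assert huber_m(x) == pytest.approx(x.mean(), abs=1e-10)


class TestQn:
    @pytest.mark.parametrize("n", [2, 5, 8, 33, 200])
    def test_matches_bruteforce_oracle_exactly(self, rng, n):
        x = rng.normal(10.0, 3.0, n)
        assert qn_scale(x) == qn_bruteforce(list(x))

    def test_outlier_sample(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        assert qn_scale(x) == qn_bruteforce(list(x)) == 0.0

    def test_close_to_statsmodels_on_large_normal(self, rng):
        """Cross-check against the independent statsmodels implementation
        (which applies finite-sample corrections, hence the tolerance)."""
        from statsmodels.robust.scale import qn_scale as sm_qn

        x = rng.normal(0, 2.0, 500)
        assert qn_scale(x) == pytest.approx(sm_qn(x), rel=0.02)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equality_property(self, xs):
        assert qn_scale(np.array(xs)) == pytest.approx(
            qn_bruteforce(xs), rel=1e-12, abs=1e-12
        )


class TestRobustExcitationStats:
    def test_w5_relative_uncertainty_same_order_as_experiment(
        self, w5_1800_normalized
    ):
        """The simulated plateau ripple gives a relative excitation
        uncertainty of the same order as experimentally determined values
        (which include acquisition noise): tenths of a percent to a few
        percent."""
        report = find_notches(w5_1800_normalized, 0.97)
        report = robust_excitation_stats(
            w5_1800_normalized, [(300.0, 1500.0)], report
        )
        assert 0.05 < report.relative_excitation_uncertainty < 5.0
        assert 0.9 < report.robust_location <= 1.0

    def test_normality_assessed_but_robust_path_taken(
        self, w5_1800_normalized
    ):
        report = robust_excitation_stats(
            w5_1800_normalized, [(300.0, 1500.0)]
        )
        assert 0.0 <= report.normality_p <= 1.0
        # robust fields are always populated regardless of the p-value
        assert report.robust_scale_qn is not None
        assert report.robust_scale_mad is not None

    def test_too_few_points_rejected(self, w5_1800_normalized):
        with pytest.raises(InsufficientDataError):
            robust_excitation_stats(w5_1800_normalized, [(300.0, 360.0)])


class TestSweepEmulation:
    def test_grid_span(self):
        spec = SequenceSpec(build_w5(1800.0))
        prof = sweep_emulation(spec, step=25.0, count=200)
        assert prof.offsets.size == 200
        assert prof.offsets[-1] - prof.offsets[0] == pytest.approx(4975.0)

    def test_zero_noise_equals_simulated_profile(self):
        spec = SequenceSpec(build_w5(1800.0))
        swept = sweep_emulation(spec, step=25.0, count=64)
        direct = sculpting_profile(spec, swept.offsets)
        assert np.array_equal(swept.retained_fraction,
                              direct.retained_fraction)

    def test_seeded_noise_reproducible(self):
        spec = SequenceSpec(build_w5(1800.0))
        a = sweep_emulation(spec, 25.0, 100, noise_sigma=0.01, seed=5)
        b = sweep_emulation(spec, 25.0, 100, noise_sigma=0.01, seed=5)
        c = sweep_emulation(spec, 25.0, 100, noise_sigma=0.01, seed=6)
        assert np.array_equal(a.retained_fraction, b.retained_fraction)
        assert not np.array_equal(a.retained_fraction, c.retained_fraction)
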