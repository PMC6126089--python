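"""Multipeak fitting: initialization, recovery, invariances, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from sarcospace import (
    FitConfig,
    GaussianPeak,
    InsufficientStriationsError,
    IntensityProfile,
    InvalidInputError,
    MultiPeakFit,
    filter_peaks,
    fit_multipeak,
    initialize_peaks,
)
from tests.conftest import make_profile_arrays


def _profile(x, y):
    return IntensityProfile(x, y)


class TestInitialize:
    def test_noiseless_ten_bands_found_at_true_centers(self):
        centers = 2.5 + np.arange(10) * 2.0
        x, y = make_profile_arrays(centers, [800.0] * 10, [0.3] * 10, span=(0, 26.46))
        init = initialize_peaks(_profile(x, y))
        assert init.n_peaks == 10
        got = np.array([p.center for p in init.peaks])
        assert np.all(np.abs(got - centers) <= 0.27)  # within one sample

    def test_pure_ramp_raises_insufficient_striations(self):
        x = np.arange(0, 27, 0.27)
        y = 100.0 + 5.0 * x
        with pytest.raises(InsufficientStriationsError, match="insufficient striations"):
            initialize_peaks(_profile(x, y))

    def test_low_prominence_band_not_a_candidate(self):
        centers = 2.5 + np.arange(10) * 2.0
        amps = [800.0] * 10
        amps[4] = 40.0  # 5% of the others, below the 10% prominence floor
        x, y = make_profile_arrays(centers, amps, [0.3] * 10, span=(0, 26.46))
        init = initialize_peaks(_profile(x, y), FitConfig(min_prominence_frac=0.1))
        assert init.n_peaks == 9

    def test_baseline_guess_tracks_lower_envelope(self):
        x, y = make_profile_arrays([10.0, 14.0], [500.0, 500.0], [0.3, 0.3], a=8.0, b=50.0)
        init = initialize_peaks(_profile(x, y))
        assert init.slope_a == pytest.approx(8.0, abs=1.0)
        assert init.intercept_b == pytest.approx(50.0, abs=15.0)


class TestFit:
    def test_noiseless_parameters_recovered_exactly(self):
        """Zero noise: the global minimum is the generating parameter set."""
        centers = [3.0, 5.1, 6.9, 9.2]
        amps = [700.0, 900.0, 650.0, 820.0]
        sigmas = [0.25, 0.3, 0.35, 0.28]
        x, y = make_profile_arrays(centers, amps, sigmas, a=4.0, b=120.0, span=(0, 13.5))
        fit = fit_multipeak(_profile(x, y))
        assert fit.converged
        assert fit.n_peaks == 4
        assert fit.slope_a == pytest.approx(4.0, rel=1e-6, abs=1e-6)
        assert fit.intercept_b == pytest.approx(120.0, rel=1e-6)
        for peak, c, a, s in zip(fit.peaks, centers, amps, sigmas):
            assert peak.center == pytest.approx(c, rel=1e-6)
            assert peak.amplitude == pytest.approx(a, rel=1e-6)
            assert peak.sigma == pytest.approx(s, rel=1e-6)
        assert fit.rss < 1e-10
        assert fit.r_squared == pytest.approx(1.0)

    def test_translation_invariance_of_centers(self):
        centers = [4.0, 6.0, 8.0]
        x, y = make_profile_arrays(centers, [500.0] * 3, [0.3] * 3, span=(0, 12.15))
        fit0 = fit_multipeak(_profile(x, y))
        delta = 3.24
        fit1 = fit_multipeak(_profile(x + delta, y))
        for p0, p1 in zip(fit0.peaks, fit1.peaks):
            assert p1.center - p0.center == pytest.approx(delta, abs=1e-6)
            assert p1.sigma == pytest.approx(p0.sigma, rel=1e-6)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_intensity_scaling_scales_amplitudes_only(self, scale):
        x, y = make_profile_arrays([4.0, 6.0, 8.0], [500.0] * 3, [0.3] * 3, span=(0, 12.15))
        fit0 = fit_multipeak(_profile(x, y))
        fit1 = fit_multipeak(_profile(x, y * scale))
        assert fit1.slope_a == pytest.approx(fit0.slope_a * scale, rel=1e-4, abs=1e-6)
        assert fit1.intercept_b == pytest.approx(fit0.intercept_b * scale, rel=1e-4)
        for p0, p1 in zip(fit0.peaks, fit1.peaks):
            assert p1.center == pytest.approx(p0.center, abs=1e-5)
            assert p1.amplitude == pytest.approx(p0.amplitude * scale, rel=1e-4)
            assert p1.sigma == pytest.approx(p0.sigma, rel=1e-4)

    def test_forced_two_peaks_on_single_gaussian_flags_collapse(self):
        x, y = make_profile_arrays([6.75], [600.0], [0.3], span=(0, 13.5))
        fit = fit_multipeak(_profile(x, y), n_peaks=2)
        assert fit.collapsed

    def test_n_peaks_below_two_rejected(self):
        x, y = make_profile_arrays([4.0, 6.0], [500.0] * 2, [0.3] * 2, span=(0, 10.8))
        with pytest.raises(InvalidInputError):
            fit_multipeak(_profile(x, y), n_peaks=1)

    def test_grid_search_oracle_equivalence(self):
        """LM solution matches an independent grid-search + polish oracle.

        The oracle never touches the package's optimizer: coarse center
        grid with linear solves for (a, b, A), then a bounded
        trust-region polish from the best grid node.
        """
        cases = [
            ([4.1, 7.3], [550.0, 830.0], [0.27, 0.36]),
            ([3.2, 6.1, 9.4], [700.0, 500.0, 900.0], [0.3, 0.25, 0.33]),
        ]
        for centers, amps, sigmas in cases:
            x, y = make_profile_arrays(centers, amps, sigmas, a=3.0, b=80.0, span=(0, 13.5))
            k = len(centers)
            fit = fit_multipeak(_profile(x, y), n_peaks=k)
            oracle = _grid_polish_oracle(x, y, k)
            got = np.sort([p.center for p in fit.peaks])
            assert np.allclose(got, np.sort(oracle["centers"]), atol=1e-4)
            assert np.allclose(
                sorted(p.amplitude for p in fit.peaks), np.sort(oracle["amps"]),
                rtol=1e-4,
            )
            assert np.allclose(
                sorted(p.sigma for p in fit.peaks), np.sort(oracle["sigmas"]), atol=1e-4
            )
            assert fit.slope_a == pytest.approx(oracle["a"], abs=1e-4)
            assert fit.intercept_b == pytest.approx(oracle["b"], abs=1e-3)


def _grid_polish_oracle(x, y, k, sigma0=0.3):
    """Dense center grid + linear least squares, then trust-region polish."""
    from itertools import combinations

    grid = np.linspace(x[0] + 0.5, x[-1] - 0.5, 40)
    best = None
    for cs in combinations(grid, k):
        basis = [np.ones_like(x), x] + [
            np.exp(-((x - c) ** 2) / (2 * sigma0**2)) for c in cs
        ]
        A = np.stack(basis, axis=1)
        coef, rss, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        score = float(resid @ resid)
        if best is None or score < best[0]:
            best = (score, cs, coef)
    _, cs, coef = best
    theta0 = np.concatenate([[coef[1], coef[0]], cs, np.maximum(coef[2:], 1.0), [sigma0] * k])

    def resid_fn(theta):
        a, b = theta[0], theta[1]
        cs_, as_, ss_ = theta[2 : 2 + k], theta[2 + k : 2 + 2 * k], theta[2 + 2 * k :]
        model = a * x + b
        for c, amp, s in zip(cs_, as_, ss_):
            model = model + amp * np.exp(-((x - c) ** 2) / (2 * s**2))
        return model - y

    lb = np.concatenate([[-np.inf, -np.inf], [x[0]] * k, [0.0] * k, [0.1] * k])
    ub = np.concatenate([[np.inf, np.inf], [x[-1]] * k, [np.inf] * k, [1.0] * k])
    sol = least_squares(resid_fn, theta0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14)
    t = sol.x
    return {
        "a": t[0], "b": t[1],
        "centers": t[2 : 2 + k], "amps": t[2 + k : 2 + 2 * k], "sigmas": t[2 + 2 * k :],
    }


class TestFilter:
    def _fit(self, amplitudes):
        peaks = tuple(
            GaussianPeak(2.0 * (i + 1), a, 0.3) for i, a in enumerate(amplitudes)
        )
        return MultiPeakFit(0.0, 100.0, peaks, 0.0, 1.0, True, 10)

    def test_equal_amplitudes_nothing_removed(self):
        fit = filter_peaks(self._fit([500.0] * 10))
        assert fit.n_peaks == 10
        assert fit.excluded == ()

    def test_dim_peak_removed(self):
        amps = [500.0] * 10
        amps[3] = 50.0  # 10% of median, below the 20% default
        fit = filter_peaks(self._fit(amps), FitConfig(min_amplitude_frac=0.2))
        assert fit.n_peaks == 9
        assert len(fit.excluded) == 1
        assert fit.excluded[0].center == pytest.approx(8.0)

    def test_interior_removal_drops_adjacent_distances_without_bridging(self):
        from sarcospace import compute_spacings

        amps = [500.0] * 10
        amps[4] = 50.0
        fit = filter_peaks(self._fit(amps))
        spacing = compute_spacings(fit)
        values = [d.value for d in spacing.distances]
        kept = [d.kept for d in spacing.distances]
        assert len(values) == 9  # no bridged ~4 μm distance appears
        assert all(v == pytest.approx(2.0) for v in values)
        assert kept == [True] * 3 + [False, False] + [True] * 4
        assert spacing.n == 7

    def test_fewer_than_two_survivors_is_an_error(self):
        # median amplitude 255 -> threshold 51 -> only one peak survives
        with pytest.raises(InsufficientStriationsError, match="after filtering"):
            filter_peaks(self._fit([500.0, 10.0]))

    def test_filter_requires_two_peaks(self):
        peaks = (GaussianPeak(2.0, 100.0, 0.3),)
        fit = MultiPeakFit(0.0, 0.0, peaks, 0.0, 1.0, True, 1)
        with pytest.raises(InvalidInputError):
            filter_peaks(fit)


def test_objective_never_increases_relative_to_initialization():
    """The converged RSS is no worse than the initialization's RSS."""
    rng = np.random.default_rng(12)
    centers = 2.5 + np.arange(8) * 2.0
    x, y = make_profile_arrays(centers, [800.0] * 8, [0.3] * 8, span=(0, 21.6))
    y = y + rng.normal(0, 60, y.shape)
    prof = IntensityProfile(x, y)
    init = initialize_peaks(prof)
    from sarcospace.fitting import multipeak_model

    rss_init = float(np.sum((multipeak_model(x, init.slope_a, init.intercept_b, init.peaks) - y) ** 2))
    fit = fit_multipeak(prof)
    assert fit.rss <= rss_init
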