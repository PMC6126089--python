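"""Multipeak Gaussian fitting of striation profiles.

The profile model is a sum of Gaussians on a linear offset,

    Y(X) = a·X + b + Σ_i A_i · exp(−(X − μ_i)² / (2σ_i²)),

fitted jointly by Levenberg–Marquardt damped least squares.  Each band
gets an independent σ_i (striation widths vary along real myocytes) and
all parameters are box-bounded: centers inside the profile span,
amplitudes non-negative, σ within ``sigma_bounds``.  The spacing of
interest is then the distance between the centers of adjacent peaks.

Initialization is deterministic: the baseline guess is a least-squares
line through the samples at or below the profile median (the lower
envelope), and peak candidates are prominent local maxima of the
smoothed, baseline-subtracted profile.

Peaks with insufficient fluorescence — fitted amplitude below a set
fraction of the median peak amplitude — are excluded afterwards; the
spacing stage drops the distances adjacent to an excluded peak rather
than bridging across it (a bridged distance would be ~2 periods and
corrupt the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
from scipy import ndimage, signal

from .errors import AnalysisError, InsufficientStriationsError, InvalidInputError
from .profiles import IntensityProfile

__all__ = [
    "GaussianPeak",
    "MultiPeakFit",
    "FitConfig",
    "initialize_peaks",
    "fit_multipeak",
    "filter_peaks",
    "multipeak_model",
]


@dataclass(frozen=True)
class GaussianPeak:
    center: float  # μm
    amplitude: float  # AU above baseline
    sigma: float  # μm

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise InvalidInputError(f"peak amplitude must be > 0, got {self.amplitude}")
        if not self.sigma > 0:
            raise InvalidInputError(f"peak sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class MultiPeakFit:
    """Fitted linear offset plus Gaussian peaks, with diagnostics.

    ``peaks`` holds the retained peaks ordered by center; ``excluded``
    holds peaks removed by the insufficient-intensity filter so the
    spacing stage can flag the distances that touch them.
    """

    slope_a: float  # AU/μm
    intercept_b: float  # AU
    peaks: tuple[GaussianPeak, ...]
    rss: float
    r_squared: float
    converged: bool
    n_iterations: int
    collapsed: bool = False  # any pair of centers closer than min_separation/2
    excluded: tuple[GaussianPeak, ...] = ()

    def __post_init__(self) -> None:
        centers = [p.center for p in self.peaks]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise InvalidInputError("peaks must be strictly ordered by center")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "excluded", tuple(self.excluded))

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def predict(self, positions: np.ndarray) -> np.ndarray:
        """Model evaluated at the given positions (kept peaks + excluded)."""
        x = np.asarray(positions, dtype=float)
        y = self.slope_a * x + self.intercept_b
        for p in (*self.peaks, *self.excluded):
            y = y + p.amplitude * np.exp(-((x - p.center) ** 2) / (2 * p.sigma**2))
        return y

    def to_dict(self) -> dict:
        return {
            "slope_a": self.slope_a,
            "intercept_b": self.intercept_b,
            "peaks": [
                {"center_um": p.center, "amplitude": p.amplitude, "sigma_um": p.sigma}
                for p in self.peaks
            ],
            "excluded_peaks": [
                {"center_um": p.center, "amplitude": p.amplitude, "sigma_um": p.sigma}
                for p in self.excluded
            ],
            "rss": self.rss,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "collapsed": self.collapsed,
        }


@dataclass(frozen=True)
class FitConfig:
    """Tunables for initialization, fitting and peak filtering.

    All lengths in μm.  ``min_prominence_frac`` is relative to the
    maximum of the baseline-subtracted signal; ``min_amplitude_frac``
    is the insufficient-fluorescence threshold relative to the median
    fitted amplitude.
    """

    smoothing_sigma: float = 0.15  # for initialization only
    min_prominence_frac: float = 0.1
    sigma_bounds: tuple[float, float] = (0.1, 1.0)
    min_separation: float = 0.8
    max_iterations: int = 200
    tolerance: float = 1e-8  # relative RSS / parameter change
    min_amplitude_frac: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.sigma_bounds
        if not (0 < lo < hi):
            raise InvalidInputError(f"sigma_bounds must be 0 < lo < hi, got {self.sigma_bounds}")
        for name in ("smoothing_sigma", "min_separation", "tolerance"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        for name in ("min_prominence_frac", "min_amplitude_frac"):
            if not 0 < getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be in (0, 1)")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")


def _baseline_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line through the profile's lower envelope.

    Fits the samples at or below the profile median, so the bright bands
    do not drag the baseline upward.
    """
    mask = y <= np.median(y)
    if mask.sum() < 2:
        mask = np.ones_like(y, dtype=bool)
    a, b = np.polyfit(x[mask], y[mask], 1)
    return float(a), float(b)


def _candidates(
    profile: IntensityProfile, cfg: FitConfig
) -> tuple[float, float, list[GaussianPeak]]:
    x, y = profile.positions, profile.intensities
    a, b = _baseline_guess(x, y)
    resid = y - (a * x + b)
    smoothed = ndimage.gaussian_filter1d(resid, cfg.smoothing_sigma / profile.step)
    # a signal indistinguishable from the baseline (numerically flat after
    # subtraction) has no striations, whatever the relative prominence says
    floor = 1e-9 * max(float(np.ptp(y)), 1.0)
    if smoothed.max() <= floor:
        return a, b, []
    prominence = cfg.min_prominence_frac * smoothed.max()
    distance = max(1, int(round(cfg.min_separation / profile.step)))
    idx, _ = signal.find_peaks(smoothed, prominence=prominence, distance=distance)
    init_sigma = np.clip(cfg.min_separation / 4, *cfg.sigma_bounds)
    peaks = [
        GaussianPeak(float(x[i]), float(max(resid[i], smoothed[i], 1e-12)), float(init_sigma))
        for i in idx
    ]
    return a, b, sorted(peaks, key=lambda p: p.center)


def initialize_peaks(profile: IntensityProfile, cfg: FitConfig | None = None) -> MultiPeakFit:
    """Deterministic initial guess for :func:`fit_multipeak`.

    Raises :class:`InsufficientStriationsError` when fewer than two
    candidate peaks are found.
    """
    cfg = cfg or FitConfig()
    a, b, peaks = _candidates(profile, cfg)
    if len(peaks) < 2:
        raise InsufficientStriationsError(
            f"insufficient striations: found {len(peaks)} candidate peak(s), need >= 2"
        )
    return MultiPeakFit(
        slope_a=a,
        intercept_b=b,
        peaks=tuple(peaks),
        rss=float("nan"),
        r_squared=float("nan"),
        converged=False,
        n_iterations=0,
    )


def multipeak_model(
    x: np.ndarray, a: float, b: float, peaks: Sequence[GaussianPeak]
) -> np.ndarray:
    """Sum-of-Gaussians-plus-line model, the fitted function."""
    y = a * np.asarray(x, dtype=float) + b
    for p in peaks:
        y = y + p.amplitude * np.exp(-((x - p.center) ** 2) / (2 * p.sigma**2))
    return y


def _adjust_candidate_count(
    peaks: list[GaussianPeak], n_peaks: int, cfg: FitConfig, span: tuple[float, float]
) -> list[GaussianPeak]:
    if len(peaks) > n_peaks:
        keep = sorted(peaks, key=lambda p: -p.amplitude)[:n_peaks]
        return sorted(keep, key=lambda p: p.center)
    lo, hi = span
    peaks = list(peaks)
    # seed extras next to the strongest candidates; the optimizer will
    # either separate them or collapse them (flagged in diagnostics)
    by_amp = sorted(peaks, key=lambda p: -p.amplitude)
    i = 0
    while len(peaks) < n_peaks:
        anchor = by_amp[i % len(by_amp)]
        offset = cfg.min_separation / 2 * (1 + i // len(by_amp))
        center = np.clip(anchor.center + offset, lo, hi)
        peaks.append(GaussianPeak(float(center), anchor.amplitude / 2, anchor.sigma))
        i += 1
    return sorted(peaks, key=lambda p: p.center)


def fit_multipeak(
    profile: IntensityProfile,
    cfg: FitConfig | None = None,
    n_peaks: int | None = None,
) -> MultiPeakFit:
    """Fit the multipeak Gaussian + linear-offset model by Levenberg–Marquardt.

    The peak count comes from :func:`initialize_peaks` unless ``n_peaks``
    forces it.  Non-convergence is reported via ``converged=False`` on
    the returned fit, never raised; peaks whose centers end up closer
    than ``min_separation/2`` set the ``collapsed`` flag.
    """
    cfg = cfg or FitConfig()
    x, y = profile.positions, profile.intensities
    span = (float(x[0]), float(x[-1]))

    a0, b0, candidates = _candidates(profile, cfg)
    if n_peaks is None:
        if len(candidates) < 2:
            raise InsufficientStriationsError(
                f"insufficient striations: found {len(candidates)} candidate peak(s), need >= 2"
            )
        init_peaks = candidates
    else:
        if n_peaks < 2:
            raise InvalidInputError(f"n_peaks must be >= 2, got {n_peaks}")
        if not candidates:
            raise InsufficientStriationsError(
                "insufficient striations: no candidate peaks to initialize from"
            )
        init_peaks = _adjust_candidate_count(candidates, n_peaks, cfg, span)

    params = lmfit.Parameters()
    params.add("a", value=a0)
    params.add("b", value=b0)
    sig_lo, sig_hi = cfg.sigma_bounds
    for i, p in enumerate(init_peaks):
        params.add(f"c{i}", value=p.center, min=span[0], max=span[1])
        params.add(f"A{i}", value=max(p.amplitude, 1e-9), min=0.0)
        params.add(f"s{i}", value=float(np.clip(p.sigma, sig_lo, sig_hi)),
                   min=sig_lo, max=sig_hi)

    n = len(init_peaks)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        v = pars.valuesdict()
        model = v["a"] * x + v["b"]
        for i in range(n):
            model = model + v[f"A{i}"] * np.exp(
                -((x - v[f"c{i}"]) ** 2) / (2 * v[f"s{i}"] ** 2)
            )
        return model - y

    result = lmfit.minimize(
        residual,
        params,
        method="leastsq",
        xtol=cfg.tolerance,
        ftol=cfg.tolerance,
        max_nfev=cfg.max_iterations * (2 + 3 * n),
    )

    v = result.params.valuesdict()
    fitted = sorted(
        (
            GaussianPeak(v[f"c{i}"], max(v[f"A{i}"], 1e-12), v[f"s{i}"])
            for i in range(n)
        ),
        key=lambda p: p.center,
    )
    # strict ordering required by the container; nudge exact ties apart
    for i in range(1, len(fitted)):
        if fitted[i].center <= fitted[i - 1].center:
            fitted[i] = replace(fitted[i], center=np.nextafter(fitted[i - 1].center, np.inf))

    rss = float(np.sum(np.asarray(result.residual) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else float("nan")
    centers = np.array([p.center for p in fitted])
    amplitudes = np.array([p.amplitude for p in fitted])
    # collapsed: two peaks landed on one band, or a forced peak vanished
    # (near-zero amplitude leaves its center meaningless)
    collapsed = bool(
        np.any(np.diff(centers) < cfg.min_separation / 2)
        or np.any(amplitudes < 1e-6 * amplitudes.max())
    )

    return MultiPeakFit(
        slope_a=float(v["a"]),
        intercept_b=float(v["b"]),
        peaks=tuple(fitted),
        rss=rss,
        r_squared=r_squared,
        converged=bool(result.success),
        n_iterations=int(result.nfev),
        collapsed=collapsed,
    )


def filter_peaks(fit: MultiPeakFit, cfg: FitConfig | None = None) -> MultiPeakFit:
    """Drop insufficient-fluorescence peaks.

    A peak is excluded when its fitted amplitude falls below
    ``min_amplitude_frac`` of the median fitted amplitude.  Excluded
    peaks move to ``fit.excluded`` (centers untouched) so the spacing
    stage can drop the adjacent distances.  Raises
    :class:`InsufficientStriationsError` when fewer than two peaks
    survive.
    """
    cfg = cfg or FitConfig()
    if fit.n_peaks < 2:
        raise InvalidInputError("filter_peaks requires a fit with >= 2 peaks")
    amplitudes = np.array([p.amplitude for p in fit.peaks])
    threshold = cfg.min_amplitude_frac * float(np.median(amplitudes))
    kept = tuple(p for p in fit.peaks if p.amplitude >= threshold)
    dropped = tuple(p for p in fit.peaks if p.amplitude < threshold)
    if len(kept) < 2:
        raise InsufficientStriationsError(
            f"insufficient striations after filtering: {len(kept)} peak(s) survive"
        )
    return replace(fit, peaks=kept, excluded=tuple((*fit.excluded, *dropped)))
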