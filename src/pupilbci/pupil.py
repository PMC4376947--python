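"""Task-evoked pupillometry: trial preparation, statistics, threshold rule.

Cognitive pupil responses are second-order effects (~0.1-0.5 mm) riding on
much larger light-driven changes, so every trial is normalized against its
own immediately preceding baseline: the mean diameter over the 2 s before
the go cue is subtracted from the whole epoch.  Left/right eyes are
averaged where both are valid; blink gaps are linearly interpolated up to a
configurable maximum, and trials below a completeness floor are flagged
unusable rather than silently filled.

The per-trial statistics (mean, derivative, max, min, range, variance,
skewness, kurtosis, low-frequency band amplitude) are computed over the
active window, by default 0.5-6 s after the cue.  Classification from a
single statistic uses the midpoint-threshold rule: the boundary is the
arithmetic mean of the two class averages, and a trial is called imagery
when its statistic exceeds the threshold (strictly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PupilTrialSeries",
    "PupilFeatures",
    "UnusableTrialError",
    "prepare_pupil",
    "pupil_statistics",
    "midpoint_threshold",
    "pupil_threshold_classify",
    "pupil_spectrum",
]


class UnusableTrialError(ValueError):
    """Pupil data too incomplete to yield a usable trial series."""


@dataclass
class PupilTrialSeries:
    """Baselined binocular-average pupil series for one trial."""

    t: np.ndarray  # cue-relative seconds
    d: np.ndarray  # baselined diameter, mm
    valid_mask: np.ndarray  # True where at least one eye was measured
    baseline_value: float  # mm subtracted from the raw average
    completeness: float  # fraction of samples valid before interpolation
    rate: float  # Hz


@dataclass
class PupilFeatures:
    """Per-trial pupil statistics over the active window.

    Units: mean/max/min/range/band_amplitude in mm, derivative in mm/s,
    variance in mm^2; skewness and kurtosis dimensionless (kurtosis is the
    non-excess, Pearson convention — a Gaussian scores 3).  Skewness and
    kurtosis are NaN when the series has zero variance.
    """

    mean: float
    derivative: float
    max: float
    min: float
    range: float
    variance: float
    skewness: float
    kurtosis: float
    band_amplitude: float


def _interpolate_gaps(t: np.ndarray, d: np.ndarray, max_gap_s: float) -> np.ndarray:
    """Linearly fill NaN runs no longer than max_gap_s; longer runs stay NaN."""
    out = d.copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    idx = np.arange(out.size)
    # locate NaN runs
    run_start = None
    for i in range(out.size + 1):
        if i < out.size and isnan[i]:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            run_end = i  # exclusive
            left, right = run_start - 1, run_end
            gap_s = t[min(run_end, out.size - 1)] - t[max(left, 0)]
            if left >= 0 and right < out.size and gap_s <= max_gap_s:
                out[run_start:run_end] = np.interp(
                    idx[run_start:run_end], [left, right], [out[left], out[right]]
                )
            run_start = None
    return out


def prepare_pupil(
    t: np.ndarray,
    pupil_left: np.ndarray,
    pupil_right: np.ndarray,
    baseline_window: tuple[float, float] = (-2.0, 0.0),
    max_gap_s: float = 0.5,
    min_completeness: float = 0.75,
) -> PupilTrialSeries:
    """Average the eyes, fill short gaps, and baseline one trial.

    Per sample, the diameters of the valid eyes are averaged (one-eye
    fallback when the other is missing).  Gaps up to ``max_gap_s`` present
    in the averaged series are linearly interpolated.  The mean over
    ``baseline_window`` (default the 2 s before the cue, half-open at 0)
    is subtracted from every sample.

    Raises
    ------
    UnusableTrialError
        If fewer than ``min_completeness`` of the samples are valid, or the
        baseline window contains no valid samples.
    """
    t = np.asarray(t, dtype=float)
    left = np.asarray(pupil_left, dtype=float)
    right = np.asarray(pupil_right, dtype=float)
    if not (t.shape == left.shape == right.shape):
        raise ValueError("t, pupil_left, pupil_right must have equal length")
    if t.size < 3:
        raise UnusableTrialError("fewer than 3 pupil samples in trial")

    both = np.stack([left, right])
    n_valid_eyes = (~np.isnan(both)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(both, axis=0)
    valid = n_valid_eyes > 0
    completeness = float(valid.mean())
    if completeness < min_completeness:
        raise UnusableTrialError(
            f"only {completeness:.0%} of pupil samples valid "
            f"(floor {min_completeness:.0%})"
        )
    filled = _interpolate_gaps(t, avg, max_gap_s)

    in_base = (t >= baseline_window[0]) & (t < baseline_window[1])
    base_vals = filled[in_base]
    base_vals = base_vals[~np.isnan(base_vals)]
    if base_vals.size == 0:
        raise UnusableTrialError("no valid samples in the baseline window")
    baseline = float(base_vals.mean())
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 0.0
    return PupilTrialSeries(
        t=t,
        d=filled - baseline,
        valid_mask=valid,
        baseline_value=baseline,
        completeness=completeness,
        rate=rate,
    )


def pupil_statistics(
    series: PupilTrialSeries,
    active_window: tuple[float, float] = (0.5, 6.0),
    band_edge_hz: float = 0.2,
) -> PupilFeatures:
    """Compute the per-trial statistics over the active window.

    derivative is the mean first difference scaled by the sampling rate
    (mm/s); variance is the population (two-pass) variance; skewness and
    kurtosis are the standardized third/fourth moments, kurtosis non-excess.
    """
    sel = (series.t >= active_window[0]) & (series.t < active_window[1])
    d = series.d[sel]
    d = d[~np.isnan(d)]
    if d.size < 3:
        raise ValueError("fewer than 3 valid samples in the active window")
    degenerate = np.ptp(d) == 0.0
    var = 0.0 if degenerate else float(np.var(d))
    if not degenerate:
        skew = float(sps.skew(d, bias=True))
        kurt = float(sps.kurtosis(d, fisher=False, bias=True))
    else:
        skew = float("nan")
        kurt = float("nan")
    spectrum_f, spectrum_a, band_amp = pupil_spectrum(
        d, series.rate, band_edge_hz=band_edge_hz
    )
    return PupilFeatures(
        mean=float(d.mean()),
        derivative=float(np.diff(d).mean() * series.rate),
        max=float(d.max()),
        min=float(d.min()),
        range=float(d.max() - d.min()),
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        band_amplitude=band_amp,
    )


def midpoint_threshold(class_a_average: float, class_b_average: float) -> float:
    """Classification threshold: midpoint of the two class averages."""
    a, b = float(class_a_average), float(class_b_average)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("class averages must be finite")
    return (a + b) / 2.0


def pupil_threshold_classify(trial_value: float, threshold: float = 0.05) -> str:
    """Fixed-threshold rule: imagery ("left") iff the trial statistic is
    strictly above the threshold, else rest ("nothing").

    The default 0.05 mm is the midpoint of the baselined trial-mean class
    averages; the boundary value itself is called rest, so ambiguity never
    fires the switch.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return "left" if trial_value > threshold else "nothing"


def pupil_spectrum(
    d: np.ndarray,
    rate: float,
    band_edge_hz: float = 0.2,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-sided amplitude spectrum of a within-trial series.

    The Fourier coefficients are divided by the number of samples (x2 for
    non-DC bins) so a sinusoid of amplitude *a* on an exact bin reads ~*a*;
    tapering gain is compensated by the window mean.  Returns
    (frequencies, amplitudes, band_amplitude) where band_amplitude is the
    mean amplitude over bins 0 < f <= band_edge_hz — the slow oscillations
    that carry the task-evoked response (DC is excluded: baselining removes
    it).
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 4:
        raise ValueError("series shorter than one analysis window")
    if window == "hann":
        w = np.hanning(n)
    elif window in ("boxcar", None, "none"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    # taper the demeaned series so the window cannot leak DC into the low
    # bins; the mean is reported as the DC amplitude directly
    mean = d.mean()
    coeffs = np.fft.rfft((d - mean) * w)
    amp = np.abs(coeffs) / (n * w.mean())
    amp[1:] *= 2.0
    if n % 2 == 0 and amp.size > 1:
        amp[-1] /= 2.0  # Nyquist bin is not duplicated
    amp[0] = abs(mean)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    in_band = (freqs > 0) & (freqs <= band_edge_hz)
    band_amp = float(amp[in_band].mean()) if in_band.any() else float("nan")
    return freqs, amp, band_amp
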