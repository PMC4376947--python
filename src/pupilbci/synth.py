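"""Synthetic hybrid BCI sessions with planted ERD and pupil dilation.

The generator emulates the statistical structure the pipeline assumes,
without any biophysical forward modelling:

* **EEG** is a linear mixture of sources plus white sensor noise.  Two
  narrowband Gaussian processes (band-pass-filtered white noise around the
  mu and beta frequencies) sit over the right motor cortex — contralateral
  to the imagined left hand — and their power is multiplied by
  ``1 - erd_depth`` during the active window of imagery trials: the planted
  event-related desynchronization.  A handful of 1/f background sources
  with smooth random scalp topographies supply realistic spatial clutter.
  Narrowband processes (not pure tones) keep trial covariances full of
  realistic variance, so CSP faces an honest estimation problem.
* **Pupil diameter** is a baseline plus a slow random-walk drift, white
  measurement noise per eye, blink gaps (NaN-masked), and a task-evoked
  dilation on imagery trials: a sigmoid ramp reaching plateau ~1.5 s after
  the cue and decaying exponentially in the micro-break, with trial
  amplitude drawn from N(pupil_effect_mm, pupil_effect_sd_mm).
* **Events** follow the block design: 25 trials per 5-minute block, 12 s
  apart, 6 s active window, balanced randomized class sequence, with a
  "stop" cue closing each active window.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .session import Session

__all__ = ["SynthConfig", "MONTAGE_32", "generate_session", "generate_cohort",
           "SubjectRecord", "CohortConfig"]

#: Approximate 2-D scalp coordinates (x: left->right, y: back->front) for the
#: 32-channel 10-20 montage, in BioSemi channel order.
MONTAGE_32: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "AF3": (-0.35, 0.78), "F7": (-0.81, 0.59),
    "F3": (-0.48, 0.59), "FC1": (-0.25, 0.30), "FC5": (-0.69, 0.30),
    "T7": (-1.00, 0.00), "C3": (-0.50, 0.00), "CP1": (-0.25, -0.30),
    "CP5": (-0.69, -0.30), "P7": (-0.81, -0.59), "P3": (-0.48, -0.59),
    "Pz": (0.00, -0.60), "PO3": (-0.35, -0.78), "O1": (-0.31, -0.95),
    "Oz": (0.00, -0.95), "O2": (0.31, -0.95), "PO4": (0.35, -0.78),
    "P4": (0.48, -0.59), "P8": (0.81, -0.59), "CP6": (0.69, -0.30),
    "CP2": (0.25, -0.30), "C4": (0.50, 0.00), "T8": (1.00, 0.00),
    "FC6": (0.69, 0.30), "FC2": (0.25, 0.30), "F4": (0.48, 0.59),
    "F8": (0.81, 0.59), "AF4": (0.35, 0.78), "Fp2": (0.31, 0.95),
    "Fz": (0.00, 0.60), "Cz": (0.00, 0.00),
}


@dataclass
class SynthConfig:
    """Study-design and effect-size parameters for one synthetic block.

    Trial schedule defaults mirror the block design (25 trials / 5 min,
    12 s apart, 6 s active).  ``erd_depth`` is the fractional power
    reduction of the motor rhythms during imagery; ``pupil_effect_mm`` the
    mean task-evoked dilation, chosen to mirror the ~0.16 mm class-mean gap
    of the baselined trial means.  ``pupil_drift_sd`` (mm per sample,
    random-walk step) is the calibration constant that places pupil-only
    threshold accuracy in the 65-85 % band at the default effect size.
    """

    n_channels: int = 32
    eeg_rate: float = 512.0
    pupil_rate: float = 30.0
    n_trials_per_block: int = 25
    block_seconds: float = 300.0
    trial_interval_s: float = 12.0
    active_window_s: float = 6.0
    first_cue_s: float = 4.0
    erd_depth: float = 0.5
    mu_freq: float = 10.0
    beta_freq: float = 22.0
    mu_amp_uv: float = 5.0
    beta_amp_uv: float = 3.0
    background_amp_uv: float = 8.0
    n_background: int = 6
    mixing_seed: int = 0
    inter_block_shift: float = 0.0
    sensor_noise_sd: float = 4.0
    pupil_baseline_mm: float = 3.5
    pupil_effect_mm: float = 0.16
    pupil_effect_sd_mm: float = 0.05
    pupil_noise_sd_mm: float = 0.03
    pupil_drift_sd: float = 0.01
    blink_rate_per_min: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.eeg_rate, self.pupil_rate, self.block_seconds,
               self.trial_interval_s, self.active_window_s) <= 0:
            raise ValueError("rates and durations must be positive")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        for name in ("sensor_noise_sd", "pupil_effect_sd_mm",
                     "pupil_noise_sd_mm", "pupil_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (2 <= self.n_channels <= len(MONTAGE_32)):
            raise ValueError(f"n_channels must be in [2, {len(MONTAGE_32)}]")
        last_active_end = (self.first_cue_s
                          + (self.n_trials_per_block - 1) * self.trial_interval_s
                          + self.active_window_s)
        if last_active_end > self.block_seconds:
            raise ValueError(
                f"trial schedule ends at {last_active_end:g} s, beyond the "
                f"{self.block_seconds:g} s block"
            )

    @property
    def channel_labels(self) -> list[str]:
        return list(MONTAGE_32)[: self.n_channels]


def _narrowband(rng: np.random.Generator, n: int, rate: float,
                center: float, halfwidth: float = 1.5) -> np.ndarray:
    """Unit-variance narrowband Gaussian process around ``center`` Hz."""
    taps = signal.firwin(257, [max(center - halfwidth, 0.1), center + halfwidth],
                         pass_zero=False, fs=rate)
    x = signal.lfilter(taps, [1.0], rng.standard_normal(n))
    return x / x.std()


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    x = np.fft.irfft(spec / np.sqrt(freqs), n=n)
    return x / x.std()


def _topography(positions: np.ndarray, center: np.ndarray,
                width: float = 0.45) -> np.ndarray:
    """Smooth Gaussian scalp topography over the montage."""
    d2 = ((positions - center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def _trial_schedule(config: SynthConfig, rng: np.random.Generator):
    """Balanced randomized class sequence and cue times."""
    n = config.n_trials_per_block
    n_left = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    labels = np.array(["left"] * n_left + ["nothing"] * (n - n_left))
    rng.shuffle(labels)
    cues = config.first_cue_s + np.arange(n) * config.trial_interval_s
    return cues, labels


def generate_session(config: SynthConfig | None = None,
                     seed: int | None = None,
                     block_id: str = "block-0") -> Session:
    """Generate one synthetic recording block.

    Reproducible: the same ``(config, seed)`` yields an identical Session.
    The mixing matrix depends only on ``config.mixing_seed`` (and, when
    ``inter_block_shift`` > 0, a deterministic jitter keyed on the session
    seed — the planted inter-block non-stationarity).
    """
    config = config or SynthConfig()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    labels = config.channel_labels
    positions = np.array([MONTAGE_32[c] for c in labels])

    n_eeg = int(round(config.block_seconds * config.eeg_rate))
    t_eeg = np.arange(n_eeg) / config.eeg_rate
    cues, classes = _trial_schedule(config, rng)

    # --- EEG ------------------------------------------------------------
    mix_rng = np.random.default_rng(config.mixing_seed)
    centers = [np.array([0.50, 0.00]),     # mu over right motor cortex (C4)
               np.array([0.45, 0.10])]     # beta, slightly anterior
    centers += [mix_rng.uniform(-0.9, 0.9, size=2) for _ in range(config.n_background)]
    if config.inter_block_shift > 0:
        jit = np.random.default_rng([config.mixing_seed, seed])
        centers = [c + config.inter_block_shift * jit.standard_normal(2)
                   for c in centers]

    # ERD gain: rhythm amplitude drops during imagery active windows
    gain = np.ones(n_eeg)
    amp_factor = np.sqrt(1.0 - config.erd_depth)
    for cue, lab in zip(cues, classes):
        if lab == "left":
            i0 = int(round(cue * config.eeg_rate))
            i1 = int(round((cue + config.active_window_s) * config.eeg_rate))
            gain[i0:i1] = amp_factor
    # soften the gain edges (~0.25 s) so the modulation is physiological
    smooth_n = max(int(0.25 * config.eeg_rate) | 1, 3)
    gain = np.convolve(gain, np.hanning(smooth_n) / np.hanning(smooth_n).sum(),
                       mode="same")

    eeg = np.zeros((config.n_channels, n_eeg))
    rhythm_amps = [config.mu_amp_uv, config.beta_amp_uv]
    rhythm_freqs = [config.mu_freq, config.beta_freq]
    for center, amp, freq in zip(centers[:2], rhythm_amps, rhythm_freqs):
        src = _narrowband(rng, n_eeg, config.eeg_rate, freq) * gain
        eeg += amp * np.outer(_topography(positions, center), src)
    for center in centers[2:]:
        src = _pink(rng, n_eeg)
        eeg += config.background_amp_uv * np.outer(_topography(positions, center), src)
    eeg += config.sensor_noise_sd * rng.standard_normal(eeg.shape)

    # --- pupil ----------------------------------------------------------
    n_pup = int(round(config.block_seconds * config.pupil_rate))
    t_pup = np.arange(n_pup) / config.pupil_rate
    common = np.full(n_pup, config.pupil_baseline_mm)
    common = common + np.cumsum(rng.normal(0.0, config.pupil_drift_sd, n_pup))
    for cue, lab in zip(cues, classes):
        if lab != "left":
            continue
        amp = rng.normal(config.pupil_effect_mm, config.pupil_effect_sd_mm)
        rel = t_pup - cue
        shape = 1.0 / (1.0 + np.exp(-np.clip((rel - 0.75) / 0.3, -60, 60)))
        decay = np.where(
            rel > config.active_window_s,
            np.exp(-np.clip(rel - config.active_window_s, 0, 120) / 2.0), 1.0)
        resp = np.where(rel > 0, shape * decay, 0.0)
        common = common + amp * resp
    left_eye = common + rng.normal(0.0, config.pupil_noise_sd_mm, n_pup)
    right_eye = common + rng.normal(0.0, config.pupil_noise_sd_mm, n_pup)

    # blink gaps: both eyes lost for 0.15-0.35 s
    n_blinks = rng.poisson(config.blink_rate_per_min * config.block_seconds / 60.0)
    for _ in range(n_blinks):
        b0 = rng.uniform(0.0, config.block_seconds)
        dur = rng.uniform(0.15, 0.35)
        mask = (t_pup >= b0) & (t_pup < b0 + dur)
        left_eye[mask] = np.nan
        right_eye[mask] = np.nan

    # --- events ---------------------------------------------------------
    events = []
    for cue, lab in zip(cues, classes):
        events.append((float(cue), str(lab)))
        stop_t = float(cue + config.active_window_s)
        if stop_t <= config.block_seconds:
            events.append((stop_t, "stop"))
    events.sort(key=lambda e: e[0])

    return Session(
        eeg=eeg,
        eeg_rate=config.eeg_rate,
        channel_labels=labels,
        pupil_left=left_eye,
        pupil_right=right_eye,
        pupil_rate=config.pupil_rate,
        pupil_t=t_pup,
        events=events,
        block_id=block_id,
    )


@dataclass
class CohortConfig:
    """Distributions of per-subject effect sizes for a synthetic cohort.

    A configurable fraction of subjects is "BCI illiterate": near-zero ERD
    (their motor rhythms barely modulate), mirroring the 20-30 % incidence
    reported for motor-imagery paradigms.  The pupil effect is drawn
    independently of the ERD, which is what lets the fused classifier help
    exactly where EEG alone fails.
    """

    base: SynthConfig = field(default_factory=SynthConfig)
    illiterate_fraction: float = 0.25
    erd_mean: float = 0.5
    erd_sd: float = 0.15
    illiterate_erd_max: float = 0.08
    pupil_effect_mean_mm: float = 0.16
    pupil_effect_sd_mm: float = 0.05
    inter_block_shift: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 <= self.illiterate_fraction <= 1.0):
            raise ValueError("illiterate_fraction must be in [0, 1]")
        if self.erd_sd < 0 or self.pupil_effect_sd_mm < 0:
            raise ValueError("distribution sds must be non-negative")


@dataclass
class SubjectRecord:
    """One synthetic participant: two blocks plus the planted parameters."""

    subject_id: str
    blocks: list
    erd_depth: float
    pupil_effect_mm: float
    illiterate: bool

    def ground_truth(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "erd_depth": self.erd_depth,
            "pupil_effect_mm": self.pupil_effect_mm,
            "illiterate": self.illiterate,
            "trials": [
                {"block_id": b.block_id,
                 "classes": [lab for _, lab in b.go_cues()]}
                for b in self.blocks
            ],
        }


def generate_cohort(n_subjects: int = 30,
                    cohort_config: CohortConfig | None = None,
                    seed: int = 0) -> list[SubjectRecord]:
    """Generate a cohort of subjects, two blocks each.

    Per subject, ``erd_depth`` and ``pupil_effect_mm`` are drawn from the
    cohort distributions; a planted inter-block covariance shift (jittered
    source topographies in block 2) reproduces the non-stationarity that
    makes cross-block generalization harder than within-block CV.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cc = cohort_config or CohortConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        illiterate = bool(rng.random() < cc.illiterate_fraction)
        if illiterate:
            erd = float(rng.uniform(0.0, cc.illiterate_erd_max))
        else:
            erd = float(np.clip(rng.normal(cc.erd_mean, cc.erd_sd), 0.1, 0.9))
        pupil = float(np.clip(
            rng.normal(cc.pupil_effect_mean_mm, cc.pupil_effect_sd_mm), 0.0, 0.5))
        base = asdict(cc.base)
        base.update(erd_depth=erd, pupil_effect_mm=pupil,
                    mixing_seed=int(rng.integers(2**31)))
        blocks = []
        for b in range(2):
            cfg = SynthConfig(**{**base,
                                 "inter_block_shift": cc.inter_block_shift * b})
            blocks.append(generate_session(cfg, seed=int(rng.integers(2**31)),
                                           block_id=f"s{i:02d}-block-{b}"))
        subjects.append(SubjectRecord(
            subject_id=f"s{i:02d}", blocks=blocks, erd_depth=erd,
            pupil_effect_mm=pupil, illiterate=illiterate))
    return subjects
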