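"""EEG preprocessing: resampling, common average reference, zero-phase FIR.

The processing chain mirrors standard motor-imagery practice: the raw signal
is resampled to 128 Hz, re-referenced to the common average (CAR), and
band-pass filtered to 8-30 Hz — the mu/beta range that carries the
event-related desynchronization used for imagery detection.  The band-pass
is a windowed-sinc (Hamming) FIR applied forward and backward, so the net
group delay is zero and the effective stopband attenuation is doubled.

The continuous block is filtered before epoching; 5-minute blocks make this
cheap and it avoids per-epoch edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .session import Session

__all__ = [
    "PreprocConfig",
    "common_average_reference",
    "resample_eeg",
    "bandpass_zero_phase",
    "fir_taps",
    "preprocess_session",
]


@dataclass
class PreprocConfig:
    """EEG preprocessing parameters.

    target_rate : Hz to resample to (default 128).
    band : (low, high) pass band in Hz (default (8, 30), mu + beta).
    reference : only "common_average" is supported.
    fir_transition : FIR transition width in Hz; sets the filter order via
        the Hamming-window design rule.
    filter_mode : only "zero_phase_forward_backward" (filtfilt) is supported.
    """

    target_rate: float = 128.0
    band: tuple[float, float] = (8.0, 30.0)
    reference: str = "common_average"
    fir_transition: float = 2.0
    filter_mode: str = "zero_phase_forward_backward"

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0.0 < low < high < self.target_rate / 2.0):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({self.target_rate / 2.0:g} Hz)"
            )
        if self.reference != "common_average":
            raise ValueError("only common_average reference is supported")
        if self.filter_mode != "zero_phase_forward_backward":
            raise ValueError("only zero_phase_forward_backward filtering is supported")


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every channel.

    CAR re-references each electrode against the mean of all electrodes; the
    output lies in the zero-channel-mean subspace (rank at most N-1, which
    downstream covariance estimation must regularize).
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def resample_eeg(eeg: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along the sample axis.

    Non-integer rate ratios are approximated by the closest small rational
    (never silently truncated).
    """
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("sampling rates must be positive")
    if to_rate > from_rate:
        raise ValueError("upsampling EEG is not supported (to_rate > from_rate)")
    if to_rate == from_rate:
        return np.asarray(eeg, dtype=float).copy()
    frac = Fraction(to_rate / from_rate).limit_denominator(1000)
    return signal.resample_poly(np.asarray(eeg, dtype=float), frac.numerator,
                                frac.denominator, axis=-1, padtype="line")


def fir_taps(rate: float, band: tuple[float, float], transition: float = 2.0) -> np.ndarray:
    """Hamming-window band-pass FIR taps for the given design.

    Order follows the standard Hamming rule numtaps ~ 3.3 * rate / transition,
    forced odd for a type-I (symmetric, integer-delay) filter.
    """
    low, high = band
    if not (0.0 < low < high < rate / 2.0):
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    numtaps = int(np.ceil(3.3 * rate / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [low, high], pass_zero=False,
                         window="hamming", fs=rate)


def bandpass_zero_phase(
    eeg: np.ndarray,
    rate: float,
    band: tuple[float, float] = (8.0, 30.0),
    transition: float = 2.0,
) -> np.ndarray:
    """Forward-backward (zero net phase) FIR band-pass along the sample axis.

    Raises if the segment is shorter than ~3 filter lengths, where edge
    effects would dominate; filter continuous blocks, not short epochs.
    """
    taps = fir_taps(rate, band, transition)
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[-1] < 3 * taps.size:
        raise ValueError(
            f"segment of {eeg.shape[-1]} samples is too short for a "
            f"{taps.size}-tap zero-phase filter (need >= {3 * taps.size})"
        )
    return signal.filtfilt(taps, [1.0], eeg, axis=-1)


def preprocess_session(session: Session, config: PreprocConfig | None = None) -> Session:
    """Apply the full chain (resample -> CAR -> band-pass) to a session's EEG.

    Returns a new Session with the processed EEG and updated rate; pupil
    streams and events are untouched (event times are in seconds and remain
    valid on the resampled axis).
    """
    config = config or PreprocConfig()
    eeg = resample_eeg(session.eeg, session.eeg_rate, config.target_rate)
    eeg = common_average_reference(eeg)
    eeg = bandpass_zero_phase(eeg, config.target_rate, config.band,
                              config.fir_transition)
    return Session(
        eeg=eeg,
        eeg_rate=config.target_rate,
        channel_labels=list(session.channel_labels),
        pupil_left=session.pupil_left,
        pupil_right=session.pupil_right,
        pupil_rate=session.pupil_rate,
        pupil_t=session.pupil_t,
        events=list(session.events),
        block_id=session.block_id,
    )
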