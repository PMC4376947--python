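"""Data model for hybrid EEG + pupillometry recording blocks.

A :class:`Session` holds one five-minute recording block: a multichannel EEG
matrix, binocular pupil-diameter time series (with missing-sample masks for
blinks and tracking loss), and the event stream of auditory trial cues.  All
streams share a common clock with t = 0 at the start of the EEG recording;
event times are expressed in seconds on that clock.

Sessions round-trip through a versioned HDF5 container
(:func:`write_session` / :func:`read_session`), so every downstream stage is
testable without hardware or vendor file formats.  Epoching
(:func:`epoch_session`) slices the continuous streams into cue-aligned
:class:`Trial` objects, one per "left"/"nothing" go cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "EVENT_LABELS",
    "GO_LABELS",
    "Session",
    "Trial",
    "FormatError",
    "ConsistencyError",
    "EmptySessionError",
    "read_session",
    "write_session",
    "epoch_session",
]

#: Labels allowed in the event stream: trial go cues and the stop cue.
EVENT_LABELS = frozenset({"left", "nothing", "stop"})

#: Event labels that start a trial ("left" = motor imagery, "nothing" = rest).
GO_LABELS = frozenset({"left", "nothing"})

_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A session container is missing a required section or is malformed."""


class ConsistencyError(ValueError):
    """Session fields are mutually inconsistent (rates, shapes, labels)."""


class EmptySessionError(ValueError):
    """A session contains no go cues to epoch."""


@dataclass
class Session:
    """One recording block.

    Parameters
    ----------
    eeg : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    eeg_rate : float
        EEG sampling rate in Hz.
    channel_labels : list of str
        10-20 montage names, one per EEG row.
    pupil_left, pupil_right : ndarray, shape (n_pupil,)
        Pupil diameter in mm; NaN marks missing samples (blinks, tracking
        loss).  Both eyes share the timestamp vector ``pupil_t``.
    pupil_rate : float
        Nominal pupil sampling rate in Hz.
    pupil_t : ndarray, shape (n_pupil,)
        Pupil sample times in seconds on the shared (EEG) clock.
    events : list of (float, str)
        Ordered (time_s, label) pairs; labels from :data:`EVENT_LABELS`.
    block_id : str
        Identifier of the block within a session/subject.
    """

    eeg: np.ndarray
    eeg_rate: float
    channel_labels: list[str]
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    pupil_rate: float
    events: list[tuple[float, str]]
    pupil_t: np.ndarray | None = None
    block_id: str = "block-0"

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.pupil_left = np.asarray(self.pupil_left, dtype=float)
        self.pupil_right = np.asarray(self.pupil_right, dtype=float)
        if self.pupil_t is None:
            self.pupil_t = np.arange(self.pupil_left.size) / float(self.pupil_rate)
        else:
            self.pupil_t = np.asarray(self.pupil_t, dtype=float)
        self.events = [(float(t), str(lab)) for t, lab in self.events]
        self.validate()

    # -- validation ------------------------------------------------------

    @property
    def duration(self) -> float:
        """Recording span in seconds (EEG clock)."""
        return self.eeg.shape[1] / float(self.eeg_rate)

    def validate(self) -> None:
        if self.eeg.ndim != 2:
            raise ConsistencyError("eeg must be a channels x samples matrix")
        if len(self.channel_labels) != self.eeg.shape[0]:
            raise ConsistencyError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.eeg.shape[0]} EEG rows"
            )
        if self.eeg_rate <= 0 or self.pupil_rate <= 0:
            raise ConsistencyError("sampling rates must be positive")
        if self.pupil_left.shape != self.pupil_right.shape:
            raise ConsistencyError("left/right pupil series differ in length")
        if self.pupil_t.shape != self.pupil_left.shape:
            raise ConsistencyError("pupil timestamps do not match series length")
        span = self.duration
        last = -np.inf
        for t, lab in self.events:
            if lab not in EVENT_LABELS:
                raise ConsistencyError(
                    f"unknown event label {lab!r}; allowed: {sorted(EVENT_LABELS)}"
                )
            if t <= last:
                raise ConsistencyError("event times must be strictly increasing")
            if not (0.0 <= t <= span):
                raise ConsistencyError(
                    f"event at {t:.3f} s outside recording span [0, {span:.3f}] s"
                )
            last = t

    def go_cues(self) -> list[tuple[float, str]]:
        """Return (time, label) for the left/nothing go cues, in order."""
        return [(t, lab) for t, lab in self.events if lab in GO_LABELS]


@dataclass
class Trial:
    """One cue-aligned epoch.

    ``eeg_epoch`` covers the configured analysis window relative to the go
    cue; the pupil slices cover the baseline + active window (default
    [-2 s, +6 s]) with cue-relative timestamps.  ``complete`` is False when
    the pupil slice does not span the full baseline window.
    """

    class_label: str
    eeg_epoch: np.ndarray  # (n_channels, T) µV
    pupil_t: np.ndarray  # cue-relative seconds
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    cue_time: float
    complete: bool = True
    block_id: str = "block-0"

    def __post_init__(self) -> None:
        if self.class_label not in GO_LABELS:
            raise ConsistencyError(f"trial class must be in {sorted(GO_LABELS)}")


# -- container I/O -------------------------------------------------------


def write_session(session: Session, path) -> None:
    """Write a session to the native HDF5 container.

    Datasets are written with HDF5 time tracking disabled so that writing
    the same session twice produces bit-identical payload sections.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["eeg_rate"] = float(session.eeg_rate)
        f.attrs["pupil_rate"] = float(session.pupil_rate)
        f.attrs["block_id"] = session.block_id
        f.attrs["channel_labels"] = [str(c) for c in session.channel_labels]
        kw = dict(track_times=False)
        f.create_dataset("eeg", data=session.eeg, **kw)
        f.create_dataset("pupil_left", data=session.pupil_left, **kw)
        f.create_dataset("pupil_right", data=session.pupil_right, **kw)
        f.create_dataset("pupil_t", data=session.pupil_t, **kw)
        ev = np.array(
            [(t, lab.encode()) for t, lab in session.events],
            dtype=[("time", "f8"), ("label", "S16")],
        )
        f.create_dataset("events", data=ev, **kw)


def read_session(path) -> Session:
    """Read and validate a session from the native container.

    Raises
    ------
    FormatError
        If a required dataset or attribute is absent.
    ConsistencyError
        If the stored fields violate the Session invariants (unknown event
        labels, rate/shape mismatches, ...).
    """
    required = ["eeg", "pupil_left", "pupil_right", "pupil_t", "events"]
    with h5py.File(path, "r") as f:
        for name in required:
            if name not in f:
                raise FormatError(f"container missing required section {name!r}")
        for attr in ("eeg_rate", "pupil_rate", "channel_labels"):
            if attr not in f.attrs:
                raise FormatError(f"container missing required attribute {attr!r}")
        ev = f["events"][()]
        events = [(float(r["time"]), r["label"].decode()) for r in ev]
        return Session(
            eeg=f["eeg"][()],
            eeg_rate=float(f.attrs["eeg_rate"]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            pupil_left=f["pupil_left"][()],
            pupil_right=f["pupil_right"][()],
            pupil_rate=float(f.attrs["pupil_rate"]),
            pupil_t=f["pupil_t"][()],
            events=events,
            block_id=str(f.attrs.get("block_id", "block-0")),
        )


# -- epoching ------------------------------------------------------------


def epoch_session(
    session: Session,
    eeg_window: tuple[float, float] = (0.5, 6.0),
    pupil_window: tuple[float, float] = (-2.0, 6.0),
) -> tuple[list[Trial], int]:
    """Slice a session into cue-aligned trials.

    Windows are half-open ``[start, end)`` in seconds relative to the go cue
    at t = 0.  One trial is produced per "left"/"nothing" event; stop cues
    and micro-breaks are excluded.  Trials whose EEG window falls outside the
    recording span are dropped and counted.

    Returns
    -------
    (trials, n_dropped)
        The retained trials in event order and the number dropped at the
        recording boundaries.
    """
    cues = session.go_cues()
    if not cues:
        raise EmptySessionError("session contains no left/nothing go cues")
    rate = float(session.eeg_rate)
    t_len = int(round((eeg_window[1] - eeg_window[0]) * rate))
    n_samples = session.eeg.shape[1]
    trials: list[Trial] = []
    dropped = 0
    for cue_t, label in cues:
        start = int(round((cue_t + eeg_window[0]) * rate))
        if start < 0 or start + t_len > n_samples:
            dropped += 1
            continue
        rel_t = session.pupil_t - cue_t
        sel = (rel_t >= pupil_window[0]) & (rel_t < pupil_window[1])
        # the pupil baseline must be fully covered, else the trial is flagged
        covers_baseline = sel.any() and rel_t[sel][0] <= pupil_window[0] + 1.5 / float(
            session.pupil_rate
        )
        covers_end = sel.any() and rel_t[sel][-1] >= pupil_window[1] - 1.5 / float(
            session.pupil_rate
        )
        trials.append(
            Trial(
                class_label=label,
                eeg_epoch=session.eeg[:, start : start + t_len],
                pupil_t=rel_t[sel],
                pupil_left=session.pupil_left[sel],
                pupil_right=session.pupil_right[sel],
                cue_time=cue_t,
                complete=bool(covers_baseline and covers_end),
                block_id=session.block_id,
            )
        )
    return trials, dropped


def sessions_equal(a: Session, b: Session) -> bool:
    """Exhaustive field comparison (NaNs compare equal), used by round-trip
    tests and the CLI's determinism checks."""
    if a.eeg_rate != b.eeg_rate or a.pupil_rate != b.pupil_rate:
        return False
    if a.channel_labels != b.channel_labels or a.block_id != b.block_id:
        return False
    if a.events != b.events:
        return False
    for x, y in ((a.eeg, b.eeg), (a.pupil_left, b.pupil_left),
                 (a.pupil_right, b.pupil_right), (a.pupil_t, b.pupil_t)):
        if x.shape != y.shape or not np.array_equal(x, y, equal_nan=True):
            return False
    return True
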