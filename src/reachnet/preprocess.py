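"""Pre-processing of continuous and epoched EEG-derived signals.

The pipeline's entry point is either a continuous multichannel recording
(sensor space) or an already epoched set of ROI-level source time courses.
This module implements the deterministic conditioning steps applied before
time-frequency and connectivity analysis:

* linear detrending and zero-phase band-pass/notch filtering of continuous
  recordings,
* epoching around cue events into fixed-length trials,
* per-trial baseline correction and common-average re-referencing,
* sign-flip aggregation of vertex-level source signals into one
  representative time course per cortical region of interest (ROI).

Artifact handling that requires human judgement or a head model (bad-channel
detection, ICA, source reconstruction) is deliberately outside this package;
signals are expected to enter it already cleaned, at sensor or ROI level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "VertexBundle",
    "read_continuous",
    "linear_detrend",
    "bandpass_notch",
    "epoch",
    "baseline_correct",
    "common_average_reference",
    "roi_aggregate",
]


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with event markers.

    Parameters
    ----------
    channels : list of str
        Channel (or ROI) labels, one per row of ``data``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
    events : list of (int, int)
        ``(sample_index, event_code)`` pairs. By convention codes 1..5 mark
        cue onsets for the five reaching targets.
    """

    channels: list
    fs: float
    data: np.ndarray
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels do not match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event sample {s} outside recording")


@dataclass
class EpochSet:
    """Epoched trials around cue onset: ``data`` is trials x channels x samples.

    ``time`` is seconds relative to the cue; the epoch convention is the
    half-open interval ``[tmin, tmax)`` sampled at ``fs`` so every trial has
    exactly the same number of samples, with the cue at ``time == 0``.
    ``targets`` holds one reaching-target id (1..5) per trial.
    """

    data: np.ndarray
    time: np.ndarray
    fs: float
    labels: list
    targets: np.ndarray
    n_skipped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.targets = np.asarray(self.targets, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[0] != self.targets.size:
            raise ValueError("one target label per trial required")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("one label per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_mask(self, window) -> np.ndarray:
        """Boolean sample mask for the half-open window ``[t0, t1)``."""
        t0, t1 = window
        return (self.time >= t0 - 1e-12) & (self.time < t1 - 1e-12)

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class VertexBundle:
    """Vertex-level source signals of one ROI plus their dipole orientations."""

    signals: np.ndarray       # vertices x samples
    orientations: np.ndarray  # vertices x 3, unit rows

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.signals.shape[0] != self.orientations.shape[0]:
            raise ValueError("one orientation per vertex required")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero orientation vector")
        self.orientations = self.orientations / norms[:, None]


def read_continuous(path, event_id=None) -> ContinuousRecording:
    """Adapter: load a continuous EDF/FIF recording via MNE.

    Events are taken from the stim channel if present, otherwise from
    annotations (``event_id`` maps annotation descriptions to integer
    codes). Requires the optional ``mne`` dependency; native I/O for this
    package is the array-container + JSON sidecar format of the synthetic
    module.
    """
    import mne

    path = str(path)
    if path.endswith(".fif"):
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    try:
        events = mne.find_events(raw, verbose="error")
    except ValueError:
        events, _ = mne.events_from_annotations(raw, event_id=event_id,
                                                verbose="error")
    picks = mne.pick_types(raw.info, eeg=True, meg=False, stim=False)
    data = raw.get_data(picks=picks)
    channels = [raw.ch_names[i] for i in picks]
    ev = [(int(s - raw.first_samp), int(code)) for s, _, code in events]
    return ContinuousRecording(channels=channels, fs=float(raw.info["sfreq"]),
                               data=data, events=ev)


def linear_detrend(recording: ContinuousRecording) -> ContinuousRecording:
    """Remove the least-squares line from every channel."""
    if recording.data.shape[1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = sps.detrend(recording.data, axis=1, type="linear")
    return replace(recording, data=out)


def bandpass_notch(
    recording: ContinuousRecording,
    low: float = 1.0,
    high: float = 60.0,
    notch: float = 50.0,
    notch_q: float = 30.0,
) -> ContinuousRecording:
    """Zero-phase band-pass plus power-line notch filtering.

    A 4th-order Butterworth band-pass (applied forward-backward with
    ``sosfiltfilt``, so the effective attenuation doubles and the phase is
    exactly zero) followed by a 2nd-order IIR notch at ``notch`` Hz with
    quality factor ``notch_q``. Zero-phase filtering is used so that
    time-frequency latencies downstream are not biased by filter delay.
    """
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={recording.fs}")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError(f"notch frequency {notch} outside (0, fs/2)")
        b, a = sps.iirnotch(notch, notch_q, fs=recording.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return replace(recording, data=out)


def epoch(
    recording: ContinuousRecording,
    tmin: float = -1.0,
    tmax: float = 3.0,
    cue_codes=(1, 2, 3, 4, 5),
) -> EpochSet:
    """Cut fixed-length trials around every cue event.

    Sample ranges are half-open ``[tmin, tmax)`` at the recording's sampling
    rate, so each trial has exactly ``round((tmax - tmin) * fs)`` samples.
    Cue events whose epoch would run outside the recording are skipped with a
    logged warning; the count is reported on the returned ``EpochSet``.
    """
    fs = recording.fs
    n_samp = int(round((tmax - tmin) * fs))
    offset = int(round(tmin * fs))
    n_total = recording.data.shape[1]
    trials, targets = [], []
    n_skipped = 0
    for s, code in recording.events:
        if code not in cue_codes:
            continue
        start = s + offset
        stop = start + n_samp
        if start < 0 or stop > n_total:
            n_skipped += 1
            logger.warning(
                "skipping cue event at sample %d: epoch [%d, %d) outside recording",
                s, start, stop,
            )
            continue
        trials.append(recording.data[:, start:stop])
        targets.append(code)
    if n_skipped:
        logger.warning("%d epoch(s) skipped as out of bounds", n_skipped)
    data = np.stack(trials) if trials else np.empty((0, len(recording.channels), n_samp))
    time = tmin + np.arange(n_samp) / fs
    return EpochSet(
        data=data, time=time, fs=fs, labels=list(recording.channels),
        targets=np.asarray(targets, dtype=int), n_skipped=n_skipped,
    )


def baseline_correct(epochs: EpochSet, window=(-1.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - mean)


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across channels."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    car = epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(epochs.data - car)


def roi_aggregate(bundle: VertexBundle) -> np.ndarray:
    """Collapse vertex signals of one ROI into a single representative trace.

    With dipole orientations constrained normal to the cortex, vertices on
    opposite walls of a sulcus carry near-opposite orientations and their raw
    average cancels. The dominant direction of the ROI is taken as the first
    principal direction of the orientations (leading eigenvector of their
    second-moment matrix); every vertex whose orientation points against it
    is sign-flipped before the plain average.

    The eigenvector sign is itself arbitrary; it is fixed so that the
    majority of vertices align positively with it (ties broken by the first
    vertex), which makes the output deterministic. A simultaneous global sign
    flip of all orientations and signals can therefore only flip the output's
    global sign, never change its magnitude.
    """
    ori = bundle.orientations
    second_moment = ori.T @ ori
    eigvals, eigvecs = np.linalg.eigh(second_moment)
    dominant = eigvecs[:, -1]
    dots = ori @ dominant
    n_pos = np.count_nonzero(dots > 0)
    n_neg = np.count_nonzero(dots < 0)
    if n_neg > n_pos or (n_neg == n_pos and dots[0] < 0):
        dominant = -dominant
        dots = -dots
    flip = np.where(dots < 0, -1.0, 1.0)
    return (flip[:, None] * bundle.signals).mean(axis=0)
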