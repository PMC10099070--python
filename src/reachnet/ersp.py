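"""Event-related spectral perturbation (ERSP) via complex Morlet wavelets.

Time-frequency power is obtained from the continuous wavelet transform with
the ``cmor1.5-1.0`` mother wavelet (bandwidth 1.5, normalized center
frequency 1.0, i.e. an effective mother-wavelet center frequency equal to
the sampling rate — 512 Hz at the native rate, so scale 64 maps to 8 Hz).
Squared coefficient moduli are averaged across trials (per reaching target),
and ERSP expresses power as percent change from the average baseline power
at the same frequency over the [-1, 0) s rest interval:

    ERSP(t, f) = 100 * (P(t, f) - B(f)) / B(f).

Band reductions use half-open band definitions, alpha = [8, 13) Hz and
beta = [13, 30] Hz, so the shared 13 Hz edge is never double-counted, and
window reductions are plain time means over half-open windows such as the
late post-cue interval [1, 2) s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.fft import next_fast_len

from .preprocess import EpochSet

__all__ = [
    "WaveletParams",
    "ScaleGrid",
    "TimeFreqPower",
    "ERSPMap",
    "scale_for_frequency",
    "morlet_cwt",
    "cwt_power",
    "mean_power_by_target",
    "coi_exclusion_samples",
    "baseline_validity_mask",
    "compute_ersp",
    "band_mask",
    "band_average",
    "window_average",
    "ALPHA_BAND",
    "BETA_BAND",
]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)


@dataclass(frozen=True)
class WaveletParams:
    """Complex Morlet parameters: ``cmor{bandwidth}-{center_freq_norm}``.

    ``center_freq_norm`` is in cycles per sample period, so the effective
    mother-wavelet center frequency in Hz is ``center_freq_norm * fs``.
    """

    bandwidth: float = 1.5
    center_freq_norm: float = 1.0
    fs: float = 512.0

    def __post_init__(self):
        if self.bandwidth <= 0 or self.center_freq_norm <= 0 or self.fs <= 0:
            raise ValueError("wavelet parameters must be positive")

    @property
    def name(self) -> str:
        return f"cmor{self.bandwidth}-{self.center_freq_norm}"


def scale_for_frequency(freq: float, params: WaveletParams) -> float:
    """Scale at which the wavelet's center frequency equals ``freq`` Hz:
    ``scale = fs * center_freq_norm / freq`` (e.g. 8 Hz at 512 Hz -> 64).

    Valid for any frequency down to scale 1 (the mother wavelet itself);
    analysis grids additionally enforce the Nyquist limit when the
    transform is applied to data.
    """
    if freq <= 0:
        raise ValueError("frequency must be positive")
    scale = params.fs * params.center_freq_norm / freq
    if scale < 1.0:
        raise ValueError(f"frequency {freq} Hz requires scale {scale:.3f} < 1")
    return scale


@dataclass(frozen=True)
class ScaleGrid:
    """Monotone grid of wavelet scales with their center frequencies in Hz."""

    scales: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        d = np.diff(self.scales)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scales must be strictly monotone")

    @classmethod
    def from_frequencies(cls, freqs, params: WaveletParams) -> "ScaleGrid":
        freqs = np.asarray(freqs, dtype=float)
        scales = np.array([scale_for_frequency(f, params) for f in freqs])
        return cls(scales=scales, freqs=freqs)

    @classmethod
    def default(cls, params: WaveletParams, fmin=4.0, fmax=32.0, df=1.0) -> "ScaleGrid":
        """1 Hz-spaced grid from 4 to 32 Hz, covering theta through beta."""
        return cls.from_frequencies(np.arange(fmin, fmax + df / 2, df), params)


@dataclass
class TimeFreqPower:
    """Nonnegative power values with axes metadata.

    ``values`` is (..., n_freqs, n_times): per-trial power is
    (trials, rois, f, t); trial-averaged power drops the leading axis.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    roi_labels: list = field(default_factory=list)


def _scaled_filters(scales, wavelet: str, precision: int):
    """The per-scale integrated-wavelet filters used by the CWT convolution."""
    w = pywt.ContinuousWavelet(wavelet)
    int_psi, x = pywt.integrate_wavelet(w, precision=precision)
    int_psi = np.conj(int_psi)
    step = x[1] - x[0]
    filts = []
    for s in scales:
        j = (np.arange(s * (x[-1] - x[0]) + 1) / (s * step)).astype(int)
        j = j[j < int_psi.size]
        filts.append(int_psi[j][::-1])
    return filts


def morlet_cwt(
    data: np.ndarray,
    scales,
    wavelet: str = "cmor1.5-1.0",
    precision: int = 12,
    single: bool = False,
) -> np.ndarray:
    """Batched continuous wavelet transform along the last axis.

    Algorithmically identical to ``pywt.cwt(..., method='fft')`` — the same
    integrated-wavelet filters, convolution, differentiation and cropping —
    but the signal FFT is computed once at a common padded length and reused
    across all scales, which makes large trial batches several times faster.
    ``single=True`` runs the FFTs in complex64 (ample for power maps that
    are reported on a percent scale).

    Returns complex coefficients of shape ``(n_scales,) + data.shape``.
    """
    data = np.asarray(data)
    scales = np.atleast_1d(scales)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    filts = _scaled_filters(scales, wavelet, precision)
    T = data.shape[-1]
    maxlen = max(f.size for f in filts)
    if maxlen - 1 > T:
        import warnings

        warnings.warn(
            "epoch shorter than the widest wavelet support; edge effects "
            "will dominate at the lowest frequencies",
            stacklevel=2,
        )
    N = next_fast_len(T + maxlen - 1)
    cdt = np.complex64 if single else np.complex128
    rdt = np.float32 if single else np.float64
    fd = np.fft.fft(data.astype(rdt), N, axis=-1).astype(cdt, copy=False)
    out = np.empty((len(scales),) + data.shape, dtype=cdt)
    for i, (s, filt) in enumerate(zip(scales, filts)):
        fw = np.fft.fft(filt.astype(cdt), N)
        conv = np.fft.ifft(fd * fw, axis=-1)[..., : T + filt.size - 1]
        coef = -np.sqrt(s) * np.diff(conv, axis=-1)
        d = (coef.shape[-1] - T) / 2.0
        out[i] = coef[..., int(np.floor(d)) : coef.shape[-1] - int(np.ceil(d))]
    return out


def cwt_power(
    epochs: EpochSet,
    grid: ScaleGrid,
    params: WaveletParams | None = None,
    single: bool = False,
) -> TimeFreqPower:
    """Per-trial time-frequency power: squared CWT moduli.

    Returns values of shape (trials, rois, freqs, times). Memory scales as
    trials x rois x freqs x times; for full-size cohorts prefer
    :func:`mean_power_by_target`, which streams per ROI.
    """
    if params is None:
        params = WaveletParams(fs=epochs.fs)
    if np.any(grid.freqs > epochs.fs / 2):
        raise ValueError("grid frequency above Nyquist")
    coefs = morlet_cwt(epochs.data, grid.scales, params.name, single=single)
    power = np.moveaxis((coefs.real ** 2 + coefs.imag ** 2), 0, 2).astype(float)
    return TimeFreqPower(values=power, freqs=grid.freqs.copy(),
                         times=epochs.time.copy(), roi_labels=list(epochs.labels))


def mean_power_by_target(
    epochs: EpochSet,
    grid: ScaleGrid,
    params: WaveletParams | None = None,
    single: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged power per reaching target, streamed one ROI at a time.

    Returns ``(target_ids, power)`` with power of shape
    (n_targets, n_rois, n_freqs, n_times). Equivalent to averaging
    :func:`cwt_power` values over trials within each target, but holds only
    one ROI's per-trial coefficients in memory at a time.
    """
    if params is None:
        params = WaveletParams(fs=epochs.fs)
    target_ids = np.unique(epochs.targets)
    n_t, n_r = target_ids.size, epochs.n_channels
    out = np.zeros((n_t, n_r, grid.freqs.size, epochs.n_samples))
    groups = [np.flatnonzero(epochs.targets == t) for t in target_ids]
    for r in range(n_r):
        coefs = morlet_cwt(epochs.data[:, r, :], grid.scales, params.name, single=single)
        power = coefs.real ** 2 + coefs.imag ** 2  # (freqs, trials, times)
        for gi, idx in enumerate(groups):
            out[gi, r] = power[:, idx, :].mean(axis=1)
    return target_ids, out


def coi_exclusion_samples(grid: ScaleGrid, params: WaveletParams,
                          n_std: float = 4.0) -> np.ndarray:
    """Per-frequency cone-of-influence width, in samples from an epoch edge.

    The complex Morlet envelope is a Gaussian with standard deviation
    ``scale * sqrt(bandwidth / 2)`` samples; within ``n_std`` standard
    deviations of an edge the convolution is visibly attenuated by the
    implicit zero padding. The default 4-sigma rule keeps the residual
    amplitude attenuation below 1e-4.
    """
    sd = np.sqrt(params.bandwidth / 2.0)
    return np.ceil(n_std * grid.scales * sd).astype(int)


def baseline_validity_mask(
    times: np.ndarray,
    grid: ScaleGrid,
    params: WaveletParams,
    baseline_window=(-1.0, 0.0),
    edge_n_std: float = 4.0,
    event_times=(0.0,),
    event_n_std: float = 3.0,
) -> np.ndarray:
    """Per-frequency boolean mask of baseline samples safe for the reference.

    Two contaminations of the baseline power estimate are excluded, both
    consequences of the wavelet's temporal support:

    * samples within ``edge_n_std`` Gaussian widths of an epoch edge, where
      zero padding biases power low;
    * samples within ``event_n_std`` widths *before* a stimulus onset,
      where the transform smears post-stimulus (e.g. evoked) energy
      backwards and biases the baseline high.

    If a frequency's mask would be empty the exclusion falls back to the
    edge rule alone, then to the plain window. Returns shape
    ``(n_freqs, n_times)``.
    """
    times = np.asarray(times)
    n = times.size
    idx = np.arange(n)
    t0, t1 = baseline_window
    window = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
    sd = np.sqrt(params.bandwidth / 2.0)
    k_edge = np.ceil(edge_n_std * grid.scales * sd).astype(int)
    k_ev = np.ceil(event_n_std * grid.scales * sd).astype(int)
    out = np.empty((grid.freqs.size, n), dtype=bool)
    for fi in range(grid.freqs.size):
        edge_ok = window & (idx >= k_edge[fi]) & (idx < n - k_edge[fi])
        valid = edge_ok.copy()
        for ev in event_times:
            i_ev = int(np.searchsorted(times, ev - 1e-12))
            valid &= ~((idx >= i_ev - k_ev[fi]) & (idx < i_ev))
        if not valid.any():
            valid = edge_ok if edge_ok.any() else window
        out[fi] = valid
    return out


@dataclass
class ERSPMap:
    """Percent-change-from-baseline power, per target and pooled.

    ``per_target`` is (n_targets, rois, freqs, times); ``values`` is the
    cross-target average (rois, freqs, times). By construction the mean over
    the baseline window is zero at every frequency.
    """

    values: np.ndarray
    per_target: np.ndarray
    target_ids: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_window: tuple
    roi_labels: list = field(default_factory=list)

    def time_mask(self, window):
        t0, t1 = window
        return (self.times >= t0 - 1e-12) & (self.times < t1 - 1e-12)

    def band_average(self, band, per_target: bool = False,
                     closed_upper: bool | None = None) -> np.ndarray:
        src = self.per_target if per_target else self.values
        return band_average(src, self.freqs, band, closed_upper=closed_upper)

    def window_average(self, band, window, per_target: bool = False,
                       closed_upper: bool | None = None) -> np.ndarray:
        return window_average(
            self.band_average(band, per_target=per_target, closed_upper=closed_upper),
            self.times, window,
        )


def compute_ersp(
    power: TimeFreqPower | np.ndarray,
    targets=None,
    baseline_window=(-1.0, 0.0),
    times=None,
    freqs=None,
    roi_labels=None,
    group_by_target: bool = True,
    baseline_exclude=None,
) -> ERSPMap:
    """Normalize trial-averaged power to percent change from baseline.

    Accepts per-trial power (a :class:`TimeFreqPower` plus per-trial
    ``targets``) or an already target-averaged array of shape
    (n_targets, rois, freqs, times). Averaging runs trials-first within each
    target, then per frequency the baseline power ``B(f)`` is the mean over
    the baseline window and ``ERSP = 100 * (P - B) / B``. The cross-target
    ``values`` average the per-target ERSP maps (normalize per target, then
    pool), mirroring an analysis that first checks for target differences
    and pools only after finding none.
    """
    if isinstance(power, TimeFreqPower):
        if targets is None:
            raise ValueError("per-trial power requires per-trial targets")
        times, freqs = power.times, power.freqs
        roi_labels = power.roi_labels
        targets = np.asarray(targets)
        if group_by_target:
            target_ids = np.unique(targets)
        else:
            target_ids = np.array([0])
            targets = np.zeros(power.values.shape[0], dtype=int)
        mean_power = np.stack(
            [power.values[targets == t].mean(axis=0) for t in target_ids]
        )
    else:
        mean_power = np.asarray(power, dtype=float)
        if mean_power.ndim != 4:
            raise ValueError("target-averaged power must be 4-D")
        if times is None or freqs is None:
            raise ValueError("times and freqs required with array input")
        target_ids = np.arange(1, mean_power.shape[0] + 1)
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)

    t0, t1 = baseline_window
    mask = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} contains no samples")
    if baseline_exclude is None:
        base = mean_power[..., mask].mean(axis=-1, keepdims=True)  # (targets, R, F, 1)
    else:
        # per frequency, restrict the baseline reference to uncontaminated
        # samples; accepts a (F, T) validity mask (baseline_validity_mask)
        # or per-frequency edge-exclusion sample counts
        baseline_exclude = np.asarray(baseline_exclude)
        n_samp = times.size
        idx = np.arange(n_samp)
        base_cols = []
        for fi in range(freqs.size):
            if baseline_exclude.ndim == 2:
                fmask = mask & baseline_exclude[fi]
            else:
                k = int(baseline_exclude[fi])
                fmask = mask & (idx >= k) & (idx < n_samp - k)
            if not fmask.any():
                fmask = mask  # whole baseline contaminated: fall back
            base_cols.append(mean_power[..., fi, fmask].mean(axis=-1))
        base = np.stack(base_cols, axis=-1)[..., None]
    bad = np.flatnonzero((base <= 0).any(axis=(0, 1, 3)))
    if bad.size:
        raise ValueError(f"zero baseline power at frequency {freqs[bad[0]]} Hz")
    per_target = 100.0 * (mean_power - base) / base
    return ERSPMap(
        values=per_target.mean(axis=0),
        per_target=per_target,
        target_ids=np.asarray(target_ids),
        freqs=freqs,
        times=times,
        baseline_window=tuple(baseline_window),
        roi_labels=list(roi_labels) if roi_labels else [],
    )


def band_mask(freqs: np.ndarray, band, closed_upper: bool | None = None) -> np.ndarray:
    """Grid-frequency mask for a band.

    Bands are half-open ``[low, high)`` so the 13 Hz edge shared by alpha
    [8, 13) and beta [13, 30] is never double-counted; beta's upper edge is
    closed. ``closed_upper=None`` applies exactly that convention (closed
    iff the band's upper edge is 30 Hz); pass True/False to override.
    """
    low, high = band
    if closed_upper is None:
        closed_upper = np.isclose(high, BETA_BAND[1])
    freqs = np.asarray(freqs)
    mask = (freqs >= low - 1e-9) & (freqs < high - 1e-9)
    if closed_upper:
        mask |= np.isclose(freqs, high)
    return mask


def band_average(values: np.ndarray, freqs: np.ndarray, band,
                 closed_upper: bool | None = None) -> np.ndarray:
    """Unweighted mean over the grid frequencies inside the band (see
    :func:`band_mask` for the edge convention)."""
    mask = band_mask(freqs, band, closed_upper)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    axis = -2  # frequency axis of (..., F, T)
    return np.take(values, np.flatnonzero(mask), axis=axis).mean(axis=axis)


def window_average(band_values: np.ndarray, times: np.ndarray, window=(1.0, 2.0)) -> np.ndarray:
    """Time mean over the half-open window ``[t0, t1)`` (last axis)."""
    t0, t1 = window
    times = np.asarray(times)
    mask = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return band_values[..., mask].mean(axis=-1)
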