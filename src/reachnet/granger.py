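"""Pairwise spectral Granger causality (GC) between ROI time courses.

For every ordered ROI pair the two signals are modelled as a bivariate
autoregressive (VAR) process of order ``p`` (default 30), fitted by ordinary
least squares on lagged design rows accumulated *within* each 1-s trial
window only — concatenation across trials never lets a lag span a trial
boundary. From the fitted coefficients ``A_k`` and residual covariance
``Sigma`` the transfer function and spectral matrix are

    H(f) = (I - sum_k A_k exp(-2 pi i f k / fs))^{-1},
    S(f) = H(f) Sigma H(f)*,

and Geweke's decomposition gives the causal power of source ``j`` onto
target ``i`` as ``(Sigma_jj - Sigma_ij**2 / Sigma_ii) |H_ij(f)|**2``, so

    GC_{j->i}(f) = ln[ S_ii(f) / (S_ii(f) - causal power) ].

The GC ratio is invariant to the one- vs two-sided spectral convention
(the convention factor cancels), so the internal two-sided convention is
immaterial. Band averages over alpha [8, 13) and beta [13, 30] Hz in the
baseline [-1, 0) s and late post-cue [1, 2) s windows yield four directed
connectivity matrices per subject, optionally normalized so the
off-diagonal entries sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .ersp import ALPHA_BAND, BETA_BAND, band_mask
from .preprocess import EpochSet

__all__ = [
    "BivariateVARFit",
    "GCSpectrum",
    "GCMatrix",
    "remove_evoked",
    "extract_windows",
    "fit_bivariate_var",
    "gc_spectrum",
    "build_gc_matrices",
    "normalize_matrix",
    "default_gc_freqs",
    "DEFAULT_BANDS",
    "DEFAULT_WINDOWS",
]

DEFAULT_ORDER = 30
DEFAULT_BANDS = {"alpha": ALPHA_BAND, "beta": BETA_BAND}
DEFAULT_WINDOWS = {"baseline": (-1.0, 0.0), "post_cue_late": (1.0, 2.0)}
_COND_THRESHOLD = 1e10


def default_gc_freqs(fmin: float = 1.0, fmax: float = 45.0, df: float = 0.5) -> np.ndarray:
    """0.5 Hz-spaced spectral grid from 1 to 45 Hz for GC band averaging."""
    return np.arange(fmin, fmax + df / 2, df)


@dataclass
class BivariateVARFit:
    """OLS fit of a bivariate VAR: ``coeffs`` (p, 2, 2), residual covariance
    ``resid_cov`` and the number of regression rows used."""

    order: int
    coeffs: np.ndarray
    resid_cov: np.ndarray
    n_effective: int
    fs: float
    stable: bool = True

    def companion_spectral_radius(self) -> float:
        p = self.order
        comp = np.zeros((2 * p, 2 * p))
        comp[:2, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            comp[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass
class GCSpectrum:
    """GC_{source -> target}(f) on a frequency grid, nonnegative after
    clamping tiny negative round-off; ``n_clamped`` counts clamp events."""

    pair: tuple
    freqs: np.ndarray
    values: np.ndarray
    n_clamped: int = 0

    def band_average(self, band, closed_upper=None) -> float:
        mask = band_mask(self.freqs, band, closed_upper)
        if not mask.any():
            raise ValueError(f"band {band} does not intersect the GC grid")
        return float(self.values[mask].mean())


@dataclass
class GCMatrix:
    """Directed band-averaged connectivity: ``values[j, i]`` = GC j -> i
    (rows are sources, columns targets); the diagonal is fixed at zero."""

    values: np.ndarray
    band: str
    condition: str
    roi_labels: list
    order: int
    normalized: bool = False
    n_clamped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GC matrix must be square")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("GC matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("GC values must be nonnegative")

    def offdiag_sum(self) -> float:
        return float(self.values.sum() - np.trace(self.values))

    def to_digraph(self):
        """Weighted directed graph view (networkx) of the matrix."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.roi_labels)
        n = len(self.roi_labels)
        for j in range(n):
            for i in range(n):
                if i != j and self.values[j, i] > 0:
                    g.add_edge(self.roi_labels[j], self.roi_labels[i],
                               weight=float(self.values[j, i]))
        return g


def remove_evoked(epochs: EpochSet, group_by_target: bool = True) -> EpochSet:
    """Subtract the across-trial mean waveform (the evoked potential).

    Grouped per reaching target by default, since different targets can
    elicit different evoked responses; each group needs at least 2 trials.
    """
    data = epochs.data.copy()
    groups = (
        [np.flatnonzero(epochs.targets == t) for t in np.unique(epochs.targets)]
        if group_by_target
        else [np.arange(epochs.n_trials)]
    )
    for idx in groups:
        if idx.size < 2:
            raise ValueError("evoked removal needs at least 2 trials per group")
        data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return epochs.copy_with(data)


def extract_windows(epochs: EpochSet, window) -> np.ndarray:
    """Per-trial segments (trials x rois x samples) of one analysis window,
    demeaned per trial and ROI. The window must lie within the epoch."""
    t0, t1 = window
    if t0 < epochs.time[0] - 1e-9 or t1 > epochs.time[-1] + 1.0 / epochs.fs + 1e-9:
        raise ValueError(f"window {window} outside epoch "
                         f"[{epochs.time[0]}, {epochs.time[-1] + 1 / epochs.fs})")
    mask = epochs.time_mask(window)
    seg = epochs.data[:, :, mask]
    return seg - seg.mean(axis=2, keepdims=True)


def _lag_design(x: np.ndarray, order: int):
    """Within-segment lagged design: rows ``[x[t-1], ..., x[t-p]]`` and
    targets ``x[t]`` for one node, stacked over segments.

    ``x`` is (n_segments, L); returns (rows, p) and (rows,) with
    rows = n_segments * (L - p).
    """
    n_seg, L = x.shape
    rows = L - order
    lag = np.empty((n_seg, rows, order))
    for k in range(1, order + 1):
        lag[:, :, k - 1] = x[:, order - k : L - k]
    return lag.reshape(n_seg * rows, order), x[:, order:].reshape(-1)


def fit_bivariate_var(
    x_segments: np.ndarray,
    y_segments: np.ndarray,
    order: int = DEFAULT_ORDER,
    fs: float = 1.0,
) -> BivariateVARFit:
    """OLS fit of the bivariate VAR on concatenated trial segments.

    ``x_segments`` and ``y_segments`` are aligned (n_segments, L) arrays from
    the same trials; no intercept is fitted (segments enter demeaned).
    Residual covariance uses the maximum-likelihood 1/n scaling. Raises if
    the normal matrix is ill-conditioned or the system underdetermined.
    """
    x_segments = np.atleast_2d(np.asarray(x_segments, dtype=float))
    y_segments = np.atleast_2d(np.asarray(y_segments, dtype=float))
    if x_segments.shape != y_segments.shape:
        raise ValueError("x and y segments must be aligned with equal shapes")
    L = x_segments.shape[1]
    if L <= order:
        raise ValueError(f"segment length {L} must exceed order {order}")
    Lx, tx = _lag_design(x_segments, order)
    Ly, ty = _lag_design(y_segments, order)
    n_rows = Lx.shape[0]
    if n_rows < 4 * order:
        raise ValueError(
            f"{n_rows} regression rows for {4 * order} unknowns; "
            "use more data or a lower order"
        )
    X = np.concatenate([Lx, Ly], axis=1)          # (rows, 2p)
    Y = np.stack([tx, ty], axis=1)                # (rows, 2)
    XtX = X.T @ X
    XtY = X.T @ Y
    return _fit_from_normal(XtX, XtY, Y.T @ Y, n_rows, order, fs=fs)


def _fit_from_normal(XtX, XtY, YtY, n_rows, order, fs) -> BivariateVARFit:
    cond = np.linalg.cond(XtX)
    if cond > _COND_THRESHOLD:
        raise ValueError(
            f"ill-conditioned VAR normal matrix (cond {cond:.2e}); "
            "use more data or a lower model order"
        )
    B = np.linalg.solve(XtX, XtY)                 # (2p, 2)
    resid_scatter = YtY - XtY.T @ B
    resid_cov = (resid_scatter + resid_scatter.T) / (2.0 * n_rows)
    # B rows: [x lags 1..p, y lags 1..p]; coeffs[k] = [[a_xx, a_xy], [a_yx, a_yy]]
    p = order
    coeffs = np.empty((p, 2, 2))
    coeffs[:, 0, 0] = B[:p, 0]
    coeffs[:, 0, 1] = B[p:, 0]
    coeffs[:, 1, 0] = B[:p, 1]
    coeffs[:, 1, 1] = B[p:, 1]
    fit = BivariateVARFit(order=p, coeffs=coeffs, resid_cov=resid_cov,
                          n_effective=n_rows, fs=fs)
    rho = fit.companion_spectral_radius()
    if rho >= 1.0:
        warnings.warn(f"fitted VAR is unstable (companion radius {rho:.4f}); "
                      "spectra may be unreliable", stacklevel=3)
        fit.stable = False
    return fit


def _transfer_and_spectrum(coeffs: np.ndarray, sigma: np.ndarray,
                           freqs: np.ndarray, fs: float):
    """Vectorized H(f) and S(f) over the whole grid for a 2x2 VAR."""
    p = coeffs.shape[0]
    k = np.arange(1, p + 1)
    # phase[k, f] = exp(-2 pi i f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(k, freqs) / fs)       # (p, F)
    Az = np.tensordot(coeffs, phase, axes=(0, 0))               # (2, 2, F)
    A = np.moveaxis(Az, -1, 0)                                  # (F, 2, 2)
    ImA = np.eye(2)[None] - A
    det = ImA[:, 0, 0] * ImA[:, 1, 1] - ImA[:, 0, 1] * ImA[:, 1, 0]
    H = np.empty_like(ImA)
    H[:, 0, 0] = ImA[:, 1, 1]
    H[:, 1, 1] = ImA[:, 0, 0]
    H[:, 0, 1] = -ImA[:, 0, 1]
    H[:, 1, 0] = -ImA[:, 1, 0]
    H /= det[:, None, None]
    S = H @ sigma[None] @ np.conj(np.swapaxes(H, 1, 2))
    return H, S


def gc_spectrum(
    fit: BivariateVARFit,
    freqs,
    fs: float | None = None,
) -> tuple[GCSpectrum, GCSpectrum]:
    """Geweke spectral GC in both directions from a bivariate VAR fit.

    Returns ``(x -> y, y -> x)`` spectra on ``freqs``. Negative values from
    floating-point round-off are clamped to zero and counted; a denominator
    driven non-positive is floored at ``1e-12 * S_ii`` and flagged the same
    way.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if fs is None:
        fs = fit.fs
    if np.any(freqs > fs / 2 + 1e-9):
        raise ValueError("frequency above Nyquist")
    sig = fit.resid_cov
    H, S = _transfer_and_spectrum(fit.coeffs, sig, freqs, fs)
    out = []
    for tgt, src in ((1, 0), (0, 1)):  # x->y then y->x
        s_ii = S[:, tgt, tgt].real
        causal_var = sig[src, src] - sig[tgt, src] ** 2 / sig[tgt, tgt]
        causal = causal_var * np.abs(H[:, tgt, src]) ** 2
        denom = s_ii - causal
        floor = 1e-12 * s_ii
        n_floored = int(np.count_nonzero(denom < floor))
        denom = np.maximum(denom, floor)
        vals = np.log(s_ii / denom)
        n_clamped = n_floored + int(np.count_nonzero(vals < 0))
        vals = np.maximum(vals, 0.0)
        out.append(GCSpectrum(pair=(src, tgt), freqs=freqs, values=vals,
                              n_clamped=n_clamped))
    return out[0], out[1]


def _roi_lag_blocks(segments: np.ndarray, order: int):
    """Normal-equation building blocks shared by all ROI pairs.

    For segments (trials, R, L) returns the stacked lag matrices' Gram
    blocks ``G[(r1, r2)]`` = L_r1^T L_r2 (p x p), cross vectors
    ``c[(r1, r2)]`` = L_r1^T y_r2, target scatters ``s[(r1, r2)]`` and the
    row count. Computing them once makes the 240-pair battery a sequence of
    small (2p x 2p) solves.
    """
    n_seg, R, L = segments.shape
    p = order
    rows = n_seg * (L - p)
    lag_all = np.empty((R, rows, p))
    y_all = np.empty((R, rows))
    for r in range(R):
        lag_all[r], y_all[r] = _lag_design(segments[:, r, :], p)
    big = lag_all.transpose(1, 0, 2).reshape(rows, R * p)
    G = big.T @ big                                  # (R*p, R*p)
    C = big.T @ y_all.T                              # (R*p, R)
    Syy = y_all @ y_all.T                            # (R, R)
    return G, C, Syy, rows


def build_gc_matrices(
    epochs: EpochSet,
    bands: dict | None = None,
    windows: dict | None = None,
    order: int = DEFAULT_ORDER,
    freqs=None,
) -> dict:
    """Band-averaged GC matrices for every band x condition combination.

    ``epochs`` must already be evoked-removed. For each condition window the
    trial segments are extracted and demeaned, the lagged Gram blocks are
    computed once, and each of the R*(R-1)/2 unordered ROI pairs is fitted
    and reduced to its two directed band averages. Returns
    ``{(band, condition): GCMatrix}`` (unnormalized).
    """
    bands = DEFAULT_BANDS if bands is None else bands
    windows = DEFAULT_WINDOWS if windows is None else windows
    if freqs is None:
        freqs = default_gc_freqs()
    freqs = np.asarray(freqs, dtype=float)
    R = epochs.n_channels
    p = order
    band_masks = {b: band_mask(freqs, rng) for b, rng in bands.items()}
    for b, m in band_masks.items():
        if not m.any():
            raise ValueError(f"band {b} does not intersect the GC frequency grid")

    out = {}
    for cond, window in windows.items():
        segments = extract_windows(epochs, window)
        G, C, Syy, rows = _roi_lag_blocks(segments, order)
        mats = {b: np.zeros((R, R)) for b in bands}
        clamps = {b: 0 for b in bands}
        for i in range(R):
            for j in range(i + 1, R):
                sl_i = slice(i * p, (i + 1) * p)
                sl_j = slice(j * p, (j + 1) * p)
                XtX = np.block([[G[sl_i, sl_i], G[sl_i, sl_j]],
                                [G[sl_j, sl_i], G[sl_j, sl_j]]])
                XtY = np.concatenate([C[sl_i][:, [i, j]], C[sl_j][:, [i, j]]])
                YtY = Syy[np.ix_([i, j], [i, j])]
                try:
                    fit = _fit_from_normal(XtX, XtY, YtY, rows, p, fs=epochs.fs)
                except ValueError as err:
                    raise ValueError(
                        f"GC fit failed for pair ({epochs.labels[i]}, "
                        f"{epochs.labels[j]}) in condition {cond!r}: {err}"
                    ) from err
                sp_ij, sp_ji = gc_spectrum(fit, freqs, fs=epochs.fs)
                for b in bands:
                    m = band_masks[b]
                    mats[b][i, j] = sp_ij.values[m].mean()
                    mats[b][j, i] = sp_ji.values[m].mean()
                    clamps[b] += sp_ij.n_clamped + sp_ji.n_clamped
        for b in bands:
            out[(b, cond)] = GCMatrix(
                values=mats[b], band=b, condition=cond,
                roi_labels=list(epochs.labels), order=p, n_clamped=clamps[b],
            )
    return out


def normalize_matrix(matrix: GCMatrix) -> GCMatrix:
    """Divide every off-diagonal entry by the off-diagonal total, so the
    normalized entries sum to 1 (idempotent, scale invariant)."""
    total = matrix.offdiag_sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero GC matrix")
    return replace(matrix, values=matrix.values / total, normalized=True)
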