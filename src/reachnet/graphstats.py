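"""Degree centralities and the group-level statistical battery.

A normalized GC matrix is a weighted directed graph over the 16 ROIs; the
*in degree* of an ROI is the summed weight of entering connections (total
causal inflow) and the *out degree* the summed weight of exiting
connections (outflow). Because normalization fixes the off-diagonal sum to
1, both degree vectors sum to exactly 1.

Group inference uses:

* Wilcoxon signed-rank tests (exact null by enumeration up to n = 15
  non-zero differences, normal approximation with tie and continuity
  correction beyond) for ERSP-vs-0, left-right lateralization and degree
  contrasts,
* Benjamini-Hochberg FDR control across each test battery,
* paired sign-flip permutation tests (mean paired difference statistic,
  5000 permutations) for the per-connection GC contrasts, and
* a one-dimensional cluster permutation test (point-wise paired t, summed-t
  cluster mass, max-mass null) for time-resolved band ERSP comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .granger import GCMatrix

__all__ = [
    "DegreeProfile",
    "PairedStatResult",
    "Cluster",
    "in_degree",
    "out_degree",
    "degree_profile",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "paired_permutation_test",
    "paired_permutation_battery",
    "cluster_permutation_test_1d",
]


@dataclass
class DegreeProfile:
    """Per-ROI causal inflow (in degree) and outflow (out degree)."""

    roi_labels: list
    in_degree: np.ndarray
    out_degree: np.ndarray
    band: str = ""
    condition: str = ""


@dataclass
class PairedStatResult:
    """One battery of paired tests with multiplicity control."""

    labels: list
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float
    method: str


def _as_matrix(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, GCMatrix) else np.asarray(matrix, float)


def in_degree(matrix) -> np.ndarray:
    """Column sums of the (rows = source) GC matrix: causal inflow per ROI."""
    m = _as_matrix(matrix)
    return m.sum(axis=0) - np.diag(m)


def out_degree(matrix) -> np.ndarray:
    """Row sums of the (rows = source) GC matrix: causal outflow per ROI."""
    m = _as_matrix(matrix)
    return m.sum(axis=1) - np.diag(m)


def degree_profile(matrix: GCMatrix) -> DegreeProfile:
    return DegreeProfile(
        roi_labels=list(matrix.roi_labels),
        in_degree=in_degree(matrix),
        out_degree=out_degree(matrix),
        band=matrix.band,
        condition=matrix.condition,
    )


def _exact_wilcoxon_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of the 2^n sign assignments.

    Works with tied (midrank) ranks: ranks are doubled to integers and the
    distribution of W+ is built by subset-sum dynamic programming, which is
    equivalent to enumerating every sign pattern.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b=0.0) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired samples (or vs 0).

    Zero differences are dropped (the classic rule). With n <= 15 non-zero
    differences the null distribution is enumerated exactly (ties included);
    beyond that a normal approximation with tie correction and a 0.5
    continuity correction is used. Returns ``(W+, p)``; if every difference
    is zero the test is degenerate and p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p = 1", stacklevel=2)
        return 0.0, 1.0
    if n < 5:
        warnings.warn(f"only {n} non-zero differences; Wilcoxon test has "
                      "essentially no power", stacklevel=2)
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 15:
        return w_plus, _exact_wilcoxon_p(w_plus, ranks)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (abs(w_plus - mu) - 0.5) / sigma
    return w_plus, float(min(1.0, 2.0 * sstats.norm.sf(max(z, 0.0))))


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected flags, adjusted p-values)``; adjusted p-values are
    monotone non-decreasing in the raw ranks.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


def paired_permutation_test(a, b, n_perm: int = 5000, seed=None) -> float:
    """Paired sign-flip permutation test on the mean difference.

    The observed statistic is ``mean(a - b)``; the null is built by random
    independent sign flips of the per-subject differences, and the two-sided
    p-value is ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)``.
    """
    stat, p = paired_permutation_battery(
        np.asarray(a, float)[:, None], np.asarray(b, float)[:, None],
        n_perm=n_perm, seed=seed,
    )
    return float(p[0])


def paired_permutation_battery(
    a: np.ndarray, b: np.ndarray, n_perm: int = 5000, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized battery of paired sign-flip permutation tests.

    ``a`` and ``b`` are (n_subjects, n_tests); one common set of sign-flip
    assignments is shared across the battery (the exchangeability argument
    is per subject, not per test), which keeps large batteries — e.g. the
    240 ordered ROI pairs — inside one matrix product. Returns
    ``(mean differences, p-values)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shapes")
    n = a.shape[0]
    if n < 6:
        warnings.warn(f"only {n} subjects; the permutation null has at most "
                      f"2^{n} distinct values", stacklevel=2)
    d = a - b
    obs = d.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = (signs @ d) / n                          # (n_perm, n_tests)
    exceed = (np.abs(perm) >= np.abs(obs)[None, :] - 1e-15).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    degenerate = np.all(d == 0, axis=0)
    p[degenerate] = 1.0
    return obs, p


@dataclass
class Cluster:
    """A contiguous supra-threshold segment with its summed-t mass."""

    start: int
    stop: int          # half-open sample range
    mass: float
    p: float


def _cluster_masses_1d(t_row: np.ndarray, threshold: float):
    """Signed cluster masses (summed t) of one t-statistic series."""
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * t_row > threshold
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            clusters.append((int(s), int(e), float(t_row[s:e].sum())))
    return clusters


def _max_cluster_mass_2d(tmat: np.ndarray, threshold: float) -> np.ndarray:
    """Per-row maximum |cluster mass| for a (n_perm, T) t array, vectorized."""
    n_perm, T = tmat.shape
    out = np.zeros(n_perm)
    for sign in (1.0, -1.0):
        mask = sign * tmat > threshold
        if not mask.any():
            continue
        padded = np.zeros((n_perm, T + 2), dtype=bool)
        padded[:, 1:-1] = mask
        d = np.diff(padded.astype(np.int8), axis=1)
        rows, starts = np.nonzero(d == 1)
        _, stops = np.nonzero(d == -1)
        csum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(tmat, axis=1)], axis=1)
        masses = sign * (csum[rows, stops] - csum[rows, starts])
        np.maximum.at(out, rows, masses)
    return out


def cluster_permutation_test_1d(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    cluster_threshold: float | None = None,
    alpha_point: float = 0.05,
    seed=None,
) -> list:
    """Paired cluster permutation test on aligned per-subject time series.

    Point-wise paired t statistics are thresholded (default: the two-sided
    ``alpha_point`` critical t with n-1 degrees of freedom); contiguous
    supra-threshold samples form clusters scored by their summed t, and the
    null distribution is the maximum |cluster mass| under subject-level sign
    flips. Returns a list of :class:`Cluster`; an empty list is the valid
    non-significant outcome.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be (n_subjects, n_times) with equal shapes")
    n, T = a.shape
    if n < 6:
        warnings.warn(f"only {n} subjects in cluster test", stacklevel=2)
    d = a - b
    if cluster_threshold is None:
        cluster_threshold = float(sstats.t.ppf(1 - alpha_point / 2, n - 1))

    ss = (d ** 2).sum(axis=0)  # invariant under sign flips

    def t_series(means):
        var = (ss[None, :] - n * means ** 2) / (n - 1)
        var = np.maximum(var, 1e-300)
        return means / np.sqrt(var / n)

    t_obs = t_series(d.mean(axis=0)[None, :])[0]
    clusters = _cluster_masses_1d(t_obs, cluster_threshold)
    if not clusters:
        return []

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_perm = t_series((signs @ d) / n)
    null_max = _max_cluster_mass_2d(t_perm, cluster_threshold)
    out = []
    for s, e, mass in clusters:
        p = (1.0 + np.count_nonzero(null_max >= abs(mass) - 1e-12)) / (n_perm + 1.0)
        out.append(Cluster(start=s, stop=e, mass=mass, p=float(p)))
    return sorted(out, key=lambda c: c.p)
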