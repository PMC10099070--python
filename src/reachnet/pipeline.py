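"""End-to-end orchestration of the two analysis arms.

The full analysis mirrors a source-level study of reaching-movement
preparation: a cohort of epoched ROI time courses (synthetic, or loaded
from disk) is baseline-corrected, then

* the **ERSP arm** computes Morlet time-frequency power per trial, averages
  per reaching target, normalizes to percent change from the [-1, 0) s
  baseline, reduces to alpha/beta band time courses and to scalar
  late-post-cue ([1, 2) s) window averages per ROI;
* the **connectivity arm** removes the per-target evoked potential, fits
  pairwise bivariate VAR models in the baseline and late post-cue windows,
  band-averages the Geweke GC spectra into four directed matrices per
  subject, normalizes them, and derives in/out degree centralities;
* the **statistical layer** runs the four test batteries (ERSP vs 0,
  left-right lateralization, per-connection GC contrasts, degree
  contrasts) plus the across-target cluster permutation checks.

Everything stochastic is driven by one master seed through documented
stream splitting, so a configuration determines every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import graphstats
from .ersp import (ScaleGrid, WaveletParams, baseline_validity_mask, compute_ersp,
                   mean_power_by_target)
from .granger import build_gc_matrices, normalize_matrix, remove_evoked
from .preprocess import EpochSet, baseline_correct
from .synthetic import SyntheticDataset, generate_reaching_dataset, load_dataset, preset_config

__all__ = ["RunConfig", "ResultBundle", "run_full_analysis",
           "stage_ersp", "stage_connectivity", "stage_stats", "prepare_dataset"]


@dataclass
class RunConfig:
    """Flat, JSON-serializable run configuration.

    Defaults encode the study conditions: 20 subjects with 60 trials per
    target over 5 targets, alpha [8, 13) / beta [13, 30] Hz bands, baseline
    [-1, 0) and late post-cue [1, 2) s windows, VAR order 30, 5000
    permutations, alpha level 0.05. ``ersp_decimate`` downsamples the
    signals (512 -> 128 Hz by default) before the wavelet transform only;
    all analysis bands lie well below the decimated Nyquist.
    """

    preset: str = "paper-default"
    dataset_path: str | None = None
    n_subjects: int = 20
    trials_per_target: int = 60
    bands: dict = field(default_factory=lambda: {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)})
    windows: dict = field(default_factory=lambda: {"baseline": (-1.0, 0.0),
                                                   "post_cue_late": (1.0, 2.0)})
    wavelet_bandwidth: float = 1.5
    wavelet_center: float = 1.0
    ersp_freqs: tuple = (4.0, 32.0, 1.0)
    ersp_decimate: int = 4
    ersp_coi_baseline: bool = True
    gc_freqs: tuple = (1.0, 45.0, 0.5)
    var_order: int = 30
    n_perm: int = 5000
    cluster_n_perm: int = 1000
    run_cluster_tests: bool = True
    gc_correction: str = "raw"        # "raw" or "fdr" for the 240-pair battery
    gc_contrast_on: str = "raw"       # contrast raw or normalized matrices
    degree_contrast_on: str = "raw"   # contrast degrees of raw or normalized matrices
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.bands = {k: tuple(v) for k, v in self.bands.items()}
        self.windows = {k: tuple(v) for k, v in self.windows.items()}
        self.ersp_freqs = tuple(self.ersp_freqs)
        self.gc_freqs = tuple(self.gc_freqs)
        if "baseline" not in self.windows:
            raise ValueError("a 'baseline' window is required")
        if self.gc_correction not in ("raw", "fdr"):
            raise ValueError("gc_correction must be 'raw' or 'fdr'")
        for f in (self.gc_contrast_on, self.degree_contrast_on):
            if f not in ("raw", "normalized"):
                raise ValueError("contrast matrices must be 'raw' or 'normalized'")
        edges = sorted(self.bands.values())
        for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1 - 1e-9:
                raise ValueError("bands must not overlap (half-open convention)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def contrast_window(self) -> str:
        names = [k for k in self.windows if k != "baseline"]
        if len(names) != 1:
            raise ValueError("exactly one non-baseline window is required")
        return names[0]


@dataclass
class ErspResults:
    summary: pd.DataFrame                  # subject, roi, band, value (%)
    band_timeseries: dict                  # band -> (subjects, targets, rois, times)
    times: np.ndarray
    roi_labels: list


@dataclass
class GcResults:
    raw: np.ndarray                        # (subjects, bands, conds, R, R)
    normalized: np.ndarray
    degrees: pd.DataFrame                  # subject, roi, band, condition, in_degree, out_degree
    band_names: list
    cond_names: list
    roi_labels: list
    n_clamped: int = 0


@dataclass
class ResultBundle:
    """All per-subject summaries, statistical tables and the run manifest."""

    config: RunConfig
    ersp: ErspResults
    gc: GcResults
    stats: dict                            # name -> DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ersp.summary.to_csv(outdir / "ersp_summary.csv", index=False)
        np.savez(outdir / "ersp_band_timeseries.npz",
                 times=self.ersp.times,
                 **{b: v for b, v in self.ersp.band_timeseries.items()})
        np.savez(outdir / "gc_matrices.npz", raw=self.gc.raw, normalized=self.gc.normalized,
                 band_names=np.array(self.gc.band_names),
                 cond_names=np.array(self.gc.cond_names),
                 roi_labels=np.array(self.gc.roi_labels))
        for b, bn in enumerate(self.gc.band_names):
            for c, cn in enumerate(self.gc.cond_names):
                mean_mat = self.gc.normalized[:, b, c].mean(axis=0)
                pd.DataFrame(mean_mat, index=self.gc.roi_labels,
                             columns=self.gc.roi_labels).to_csv(
                    outdir / f"gc_mean_{bn}_{cn}.csv")
        self.gc.degrees.to_csv(outdir / "degrees.csv", index=False)
        for name, df in self.stats.items():
            df.to_csv(outdir / f"stats_{name}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def prepare_dataset(config: RunConfig) -> SyntheticDataset:
    """Load the dataset from disk, or generate the configured preset."""
    if config.dataset_path is not None:
        return load_dataset(config.dataset_path)
    kw = preset_config(config.preset, seed=config.seed,
                       n_subjects=config.n_subjects,
                       trials_per_target=config.trials_per_target)
    return generate_reaching_dataset(**kw)


def _decimated(epochs: EpochSet, q: int) -> EpochSet:
    if q <= 1:
        return epochs
    data = sps.decimate(epochs.data, q, ftype="fir", zero_phase=True, axis=-1)
    return EpochSet(data=data, time=epochs.time[::q], fs=epochs.fs / q,
                    labels=list(epochs.labels), targets=epochs.targets)


def stage_ersp(dataset: SyntheticDataset, config: RunConfig) -> ErspResults:
    """Per-subject ERSP maps, band time courses, and window summaries."""
    rows = []
    band_ts = {b: [] for b in config.bands}
    times = None
    contrast = config.windows[config.contrast_window]
    baseline = config.windows["baseline"]
    fmin, fmax, df = config.ersp_freqs
    for s_idx, sub in enumerate(dataset.subjects):
        ep = baseline_correct(_decimated(sub, config.ersp_decimate), baseline)
        params = WaveletParams(config.wavelet_bandwidth, config.wavelet_center, ep.fs)
        grid = ScaleGrid.default(params, fmin, fmax, df)
        _, mean_power = mean_power_by_target(ep, grid, params)
        excl = (baseline_validity_mask(ep.time, grid, params, baseline)
                if config.ersp_coi_baseline else None)
        ersp = compute_ersp(mean_power, baseline_window=baseline, times=ep.time,
                            freqs=grid.freqs, roi_labels=ep.labels,
                            baseline_exclude=excl)
        times = ersp.times
        for b, rng in config.bands.items():
            band_ts[b].append(ersp.band_average(rng, per_target=True))
            vals = ersp.window_average(rng, contrast)      # (rois,)
            rows += [
                {"subject": s_idx, "roi": lab, "band": b, "value": float(v)}
                for lab, v in zip(ep.labels, vals)
            ]
    return ErspResults(
        summary=pd.DataFrame(rows),
        band_timeseries={b: np.stack(v) for b, v in band_ts.items()},
        times=times,
        roi_labels=list(dataset.roi_labels),
    )


def stage_connectivity(dataset: SyntheticDataset, config: RunConfig) -> GcResults:
    """Per-subject GC matrices (raw + normalized) and degree centralities."""
    band_names = list(config.bands)
    cond_names = list(config.windows)
    R = len(dataset.roi_labels)
    S = len(dataset.subjects)
    freqs = np.arange(config.gc_freqs[0], config.gc_freqs[1] + config.gc_freqs[2] / 2,
                      config.gc_freqs[2])
    raw = np.zeros((S, len(band_names), len(cond_names), R, R))
    norm = np.zeros_like(raw)
    deg_rows = []
    n_clamped = 0
    for s_idx, sub in enumerate(dataset.subjects):
        ep = remove_evoked(baseline_correct(sub, config.windows["baseline"]))
        mats = build_gc_matrices(ep, bands=config.bands, windows=config.windows,
                                 order=config.var_order, freqs=freqs)
        for b, bn in enumerate(band_names):
            for c, cn in enumerate(cond_names):
                m = mats[(bn, cn)]
                n_clamped += m.n_clamped
                nm = normalize_matrix(m)
                raw[s_idx, b, c] = m.values
                norm[s_idx, b, c] = nm.values
                for kind, mat in (("raw", m), ("normalized", nm)):
                    prof = graphstats.degree_profile(mat)
                    deg_rows += [
                        {"subject": s_idx, "roi": lab, "band": bn, "condition": cn,
                         "normalization": kind,
                         "in_degree": float(i), "out_degree": float(o)}
                        for lab, i, o in zip(prof.roi_labels, prof.in_degree,
                                             prof.out_degree)
                    ]
    return GcResults(raw=raw, normalized=norm, degrees=pd.DataFrame(deg_rows),
                     band_names=band_names, cond_names=cond_names,
                     roi_labels=list(dataset.roi_labels), n_clamped=n_clamped)


def _homologous_pairs(labels):
    pairs = []
    for lab in labels:
        if lab.startswith("L."):
            right = "R." + lab[2:]
            if right in labels:
                pairs.append((lab, right))
    return pairs


def stage_stats(ersp_res: ErspResults, gc_res: GcResults, config: RunConfig) -> dict:
    """The group statistical battery; returns a dict of result tables."""
    labels = ersp_res.roi_labels
    seed_root = np.random.SeedSequence([config.seed, 104729])
    seeds = seed_root.spawn(2 * len(config.bands))
    contrast = config.contrast_window
    out = {}

    # 1: window-averaged band ERSP vs 0, per ROI, BH per band battery
    rows = []
    piv = ersp_res.summary.pivot_table(index="subject", columns=["band", "roi"],
                                       values="value")
    for b in config.bands:
        stats_p = [graphstats.wilcoxon_signed_rank(piv[(b, lab)].to_numpy())
                   for lab in labels]
        pvals = [p for _, p in stats_p]
        rej, padj = graphstats.bh_fdr(pvals, config.alpha)
        for lab, (w, p), pa, rj in zip(labels, stats_p, padj, rej):
            rows.append({"band": b, "roi": lab, "statistic": w, "p_raw": p,
                         "p_adjusted": pa, "rejected": bool(rj)})
    out["ersp_vs_zero"] = pd.DataFrame(rows)

    # 2: left vs right homologous ROIs, BH per band battery
    rows = []
    for b in config.bands:
        pairs = _homologous_pairs(labels)
        if not pairs:
            break
        stats_p = [graphstats.wilcoxon_signed_rank(piv[(b, l)].to_numpy(),
                                                   piv[(b, r)].to_numpy())
                   for l, r in pairs]
        rej, padj = graphstats.bh_fdr([p for _, p in stats_p], config.alpha)
        for (l, r), (w, p), pa, rj in zip(pairs, stats_p, padj, rej):
            rows.append({"band": b, "pair": f"{l}|{r}", "statistic": w, "p_raw": p,
                         "p_adjusted": pa, "rejected": bool(rj)})
    out["ersp_lateralization"] = pd.DataFrame(rows)

    # 3: per-connection GC contrast (post-cue vs baseline), sign-flip permutations
    rows = []
    cond_idx = {c: k for k, c in enumerate(gc_res.cond_names)}
    R = len(labels)
    offdiag = [(j, i) for j in range(R) for i in range(R) if i != j]
    gc_source = (gc_res.normalized if config.gc_contrast_on == "normalized"
                 else gc_res.raw)
    for b_i, b in enumerate(gc_res.band_names):
        post = gc_source[:, b_i, cond_idx[contrast]]
        base = gc_source[:, b_i, cond_idx["baseline"]]
        a_mat = np.stack([post[:, j, i] for j, i in offdiag], axis=1)
        b_mat = np.stack([base[:, j, i] for j, i in offdiag], axis=1)
        stat, p = graphstats.paired_permutation_battery(
            a_mat, b_mat, n_perm=config.n_perm, seed=seeds[b_i])
        rej_fdr, padj = graphstats.bh_fdr(p, config.alpha)
        rej = rej_fdr if config.gc_correction == "fdr" else (p < config.alpha)
        for k, (j, i) in enumerate(offdiag):
            rows.append({"band": b, "source": labels[j], "target": labels[i],
                         "statistic": stat[k], "p_raw": p[k], "p_adjusted": padj[k],
                         "rejected": bool(rej[k])})
    out["gc_edges"] = pd.DataFrame(rows)

    # 4: in/out degree contrasts, Wilcoxon + BH per band x direction battery
    rows = []
    deg = gc_res.degrees
    if "normalization" in deg.columns:
        deg = deg[deg["normalization"] == config.degree_contrast_on]
    for b in gc_res.band_names:
        for direction in ("in_degree", "out_degree"):
            dpiv = deg[deg["band"] == b].pivot_table(
                index="subject", columns=["condition", "roi"], values=direction)
            stats_p = [graphstats.wilcoxon_signed_rank(
                dpiv[(contrast, lab)].to_numpy(),
                dpiv[("baseline", lab)].to_numpy()) for lab in labels]
            rej, padj = graphstats.bh_fdr([p for _, p in stats_p], config.alpha)
            for lab, (w, p), pa, rj in zip(labels, stats_p, padj, rej):
                rows.append({"band": b, "roi": lab, "direction": direction,
                             "statistic": w, "p_raw": p, "p_adjusted": pa,
                             "rejected": bool(rj)})
    out["degree_contrast"] = pd.DataFrame(rows)

    # preliminary check: band ERSP differences across targets (cluster tests)
    if config.run_cluster_tests:
        rows = []
        for b_i, b in enumerate(config.bands):
            ts = ersp_res.band_timeseries[b]          # (S, targets, R, T)
            n_targets = ts.shape[1]
            cl_seed = seeds[len(config.bands) + b_i]
            sub_seeds = iter(cl_seed.spawn(n_targets * n_targets * R))
            pvals, keys = [], []
            for t1 in range(n_targets):
                for t2 in range(t1 + 1, n_targets):
                    for r in range(R):
                        clusters = graphstats.cluster_permutation_test_1d(
                            ts[:, t1, r], ts[:, t2, r],
                            n_perm=config.cluster_n_perm, seed=next(sub_seeds))
                        pvals.append(min((c.p for c in clusters), default=1.0))
                        keys.append((t1 + 1, t2 + 1, labels[r], len(clusters)))
            rej, padj = graphstats.bh_fdr(pvals, config.alpha)
            for (t1, t2, lab, ncl), p, pa, rj in zip(keys, pvals, padj, rej):
                rows.append({"band": b, "target_a": t1, "target_b": t2, "roi": lab,
                             "n_clusters": ncl, "min_cluster_p": p,
                             "p_adjusted": pa, "rejected": bool(rj)})
        out["ersp_target_clusters"] = pd.DataFrame(rows)

    return out


def run_full_analysis(config: RunConfig, dataset: SyntheticDataset | None = None,
                      outdir=None) -> ResultBundle:
    """Execute simulate/load -> ERSP arm -> connectivity arm -> statistics.

    Idempotent under identical configuration and seed; pass ``outdir`` to
    also write every table plus the run manifest to disk.
    """
    t0 = _time.time()
    timing = {}
    if dataset is None:
        dataset = prepare_dataset(config)
    timing["simulate_or_load"] = _time.time() - t0

    t1 = _time.time()
    try:
        ersp_res = stage_ersp(dataset, config)
    except Exception as err:
        raise RuntimeError(f"ERSP stage failed ({type(err).__name__}): {err}") from err
    timing["ersp"] = _time.time() - t1

    t1 = _time.time()
    try:
        gc_res = stage_connectivity(dataset, config)
    except Exception as err:
        raise RuntimeError(f"connectivity stage failed ({type(err).__name__}): {err}") from err
    timing["connectivity"] = _time.time() - t1

    t1 = _time.time()
    stats = stage_stats(ersp_res, gc_res, config)
    timing["stats"] = _time.time() - t1

    import reachnet

    manifest = {
        "config": json.loads(config.to_json()),
        "package_version": reachnet.__version__,
        "numpy_version": np.__version__,
        "n_subjects": len(dataset.subjects),
        "roi_labels": list(dataset.roi_labels),
        "gc_values_clamped": int(gc_res.n_clamped),
        "timing_s": {k: round(v, 3) for k, v in timing.items()},
    }
    bundle = ResultBundle(config=config, ersp=ersp_res, gc=gc_res, stats=stats,
                          manifest=manifest)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
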