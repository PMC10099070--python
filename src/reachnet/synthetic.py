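"""Synthetic multi-subject reaching datasets with known ground truth.

The generator emulates the structure of a delayed center-out reaching
experiment recorded at source level: 16 cortical ROIs (8 per hemisphere),
epochs from -1 to +3 s around the cue at 512 Hz, 5 reaching targets with a
fixed number of trials per target, and 20 subjects by default.

Each trial is the sum of

* a stable vector-autoregressive (VAR) background whose coefficients switch
  from a baseline system to a post-cue system shortly after the cue (the
  directed-coupling ground truth for Granger-causality estimation),
* amplitude-modulated alpha/beta sinusoids with random per-trial phase,
  whose post-cue amplitude gain programs event-related
  desynchronization/synchronization (ERD/ERS) with an exactly known
  spectral-perturbation value of ``100 * (gain**2 - 1)`` percent,
* a damped 5 Hz cue-evoked burst on designated (visual) ROIs, and
* optional 1/f-shaped background noise.

The module also provides :func:`analytic_spectral_gc`, a closed-form Geweke
spectral Granger-causality evaluation on the *true* VAR coefficients, used
as the independent oracle against which the estimator is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import EpochSet

__all__ = [
    "VARModel",
    "EnvelopeSpec",
    "SyntheticDataset",
    "build_var_model",
    "simulate_var",
    "analytic_spectral_gc",
    "generate_reaching_dataset",
    "make_evoked_template",
    "default_roi_labels",
    "preset_config",
    "save_dataset",
    "load_dataset",
]

DEFAULT_FS = 512.0

_ROI_NAMES = ("CU", "LO", "PCU", "SP", "PoC", "PrC", "PaC", "SF")


def _companion_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stability iff < 1)."""
    p, n = coeffs.shape[0], coeffs.shape[1]
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(coeffs, axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def default_roi_labels():
    """The 16 ROI labels: 8 regions per hemisphere, prefixed ``L.``/``R.``.

    Regions: cuneus (CU), lateral occipital (LO), precuneus (PCU), superior
    parietal (SP), post-central (PoC), precentral (PrC), paracentral (PaC),
    superior frontal (SF).
    """
    return [f"L.{r}" for r in _ROI_NAMES] + [f"R.{r}" for r in _ROI_NAMES]


@dataclass
class VARModel:
    """A stable vector-autoregressive system ``x[t] = sum_k A_k x[t-k] + e[t]``.

    ``coeffs`` has shape (order, n_nodes, n_nodes) with ``coeffs[k][i][j]``
    the influence of node ``j``'s value ``k+1`` samples ago on node ``i``
    now.  ``noise_cov`` is the innovation covariance. Construction validates
    symmetry/positive-definiteness of the covariance and stability of the
    companion matrix (spectral radius < 1).
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (order, n, n)")
        n = self.coeffs.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov shape does not match n_nodes")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be positive definite") from None
        rho = self.companion_spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR model: companion spectral radius {rho:.4f} >= 1"
            )

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion_spectral_radius(self) -> float:
        return _companion_radius(self.coeffs)


def build_var_model(
    n_nodes: int,
    order: int,
    edges=(),
    self_decay=0.5,
    noise_cov=None,
    fs: float = DEFAULT_FS,
) -> VARModel:
    """Construct a VAR model from self-decay terms plus explicit directed edges.

    ``edges`` is a list of ``(source, target, lag, weight)`` tuples placed at
    ``coeffs[lag-1][target][source]``; ``self_decay`` may be a scalar (lag-1
    diagonal) or a sequence of per-lag diagonal coefficients. Construction
    fails with an explicit error if the companion spectral radius is >= 1.
    """
    coeffs = np.zeros((order, n_nodes, n_nodes))
    decay = np.atleast_1d(np.asarray(self_decay, dtype=float))
    if decay.size > order:
        raise ValueError("more self_decay terms than lags")
    for k, d in enumerate(decay):
        coeffs[k] += d * np.eye(n_nodes)
    for src, dst, lag, w in edges:
        if not (1 <= lag <= order):
            raise ValueError(f"edge lag {lag} outside 1..{order}")
        if not (0 <= src < n_nodes and 0 <= dst < n_nodes):
            raise ValueError(f"edge ({src}, {dst}) outside node range")
        coeffs[lag - 1, dst, src] = w
    if noise_cov is None:
        noise_cov = np.eye(n_nodes)
    return VARModel(coeffs=coeffs, noise_cov=np.asarray(noise_cov, float), fs=fs)


def _simulate(coeff_seq, chol, n_pre, n_samples, n_trials, rng):
    """Drive the (possibly time-varying) VAR with Gaussian innovations.

    ``coeff_seq`` maps step index (0-based over pre+epoch samples) to a
    (p, n, n) coefficient array; constant models pass a single array.
    """
    if callable(coeff_seq):
        get_A = coeff_seq
    else:
        A_const = coeff_seq

        def get_A(step):
            return A_const

    p, n = get_A(0).shape[0], get_A(0).shape[1]
    total = n_pre + n_samples
    out = np.zeros((n_trials, total, n))
    innov = rng.standard_normal((n_trials, total, n)) @ chol.T
    lag_flat = np.zeros((n_trials, p * n))  # [x[t-1], ..., x[t-p]] flattened
    for t in range(total):
        A = get_A(t)
        A_flat = np.moveaxis(A, 0, 1).reshape(n, p * n)  # (n, p*n)
        x = lag_flat @ A_flat.T + innov[:, t]
        out[:, t] = x
        if p > 0:
            lag_flat[:, n:] = lag_flat[:, :-n]
            lag_flat[:, :n] = x
    return np.swapaxes(out[:, n_pre:], 1, 2)  # trials x nodes x samples


def simulate_var(
    model: VARModel,
    n_samples: int,
    n_trials: int = 1,
    burn_in: int | None = None,
    seed=None,
) -> np.ndarray:
    """Simulate independent realizations of a stationary VAR model.

    Returns ``(n_trials, n_nodes, n_samples)`` after discarding ``burn_in``
    initial samples (default ``10 * order``, the minimum allowed).
    Reproducible under a fixed seed.
    """
    if burn_in is None:
        burn_in = 10 * model.order
    if burn_in < 10 * model.order:
        raise ValueError("burn_in must be at least 10 * order")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.noise_cov)
    return _simulate(model.coeffs, chol, burn_in, n_samples, n_trials, rng)


def analytic_spectral_gc(model: VARModel, freqs) -> np.ndarray:
    """Closed-form Geweke spectral Granger causality on true VAR coefficients.

    For each frequency the transfer function ``H(f) = (I - sum_k A_k
    e^{-2 pi i f k / fs})^{-1}`` and spectral matrix ``S = H Sigma H*`` are
    evaluated directly; the causal power of node ``j`` onto node ``i`` is
    ``(Sigma_jj - Sigma_ij**2 / Sigma_ii) |H_ij(f)|**2`` and

        GC_{j->i}(f) = ln[ S_ii / (S_ii - causal power) ].

    Returns an array of shape ``(n, n, len(freqs))`` with entry ``[j, i]``
    the spectrum of the ordered pair ``j -> i``; the diagonal is zero. This
    is a deliberately simple per-frequency loop kept independent of the
    estimator's vectorized code path, so the two can cross-check each other.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs > model.fs / 2 + 1e-9):
        raise ValueError("frequency above Nyquist")
    n, p = model.n_nodes, model.order
    Sig = model.noise_cov
    out = np.zeros((n, n, freqs.size))
    eye = np.eye(n)
    for fi, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / model.fs)
        Az = np.zeros((n, n), dtype=complex)
        for k in range(p):
            Az += model.coeffs[k] * z ** (k + 1)
        H = np.linalg.inv(eye - Az)
        S = H @ Sig @ H.conj().T
        for i in range(n):
            s_ii = S[i, i].real
            for j in range(n):
                if i == j:
                    continue
                cv = Sig[j, j] - Sig[i, j] ** 2 / Sig[i, i]
                denom = s_ii - cv * abs(H[i, j]) ** 2
                denom = max(denom, 1e-300)
                out[j, i, fi] = max(np.log(s_ii / denom), 0.0)
    return out


@dataclass
class EnvelopeSpec:
    """Amplitude program for one band-limited oscillation on one ROI.

    ``postcue_gain`` multiplies the amplitude after the cue: gain < 1
    programs ERD, gain > 1 programs ERS, and the induced spectral
    perturbation at full gain equals ``100 * (gain**2 - 1)`` percent.
    ``ramp`` is ``("step", t0)`` or ``("linear", t_on, t_off)`` in seconds
    relative to the cue; the default linear ramp from 0.5 to 1.0 s makes the
    gain fully expressed throughout the late post-cue window [1, 2) s.
    """

    roi: str
    band_center_hz: float
    baseline_amp: float = 1.0
    postcue_gain: float = 1.0
    ramp: tuple = ("linear", 0.5, 1.0)

    def __post_init__(self):
        if self.baseline_amp <= 0:
            raise ValueError("baseline_amp must be > 0")
        if self.postcue_gain < 0:
            raise ValueError("postcue_gain must be >= 0")

    def amplitude(self, time: np.ndarray) -> np.ndarray:
        a0 = self.baseline_amp
        a1 = self.baseline_amp * self.postcue_gain
        if self.ramp[0] == "step":
            t0 = self.ramp[1]
            return np.where(time < t0, a0, a1)
        if self.ramp[0] == "linear":
            _, t_on, t_off = self.ramp
            w = np.clip((time - t_on) / max(t_off - t_on, 1e-12), 0.0, 1.0)
            return a0 + (a1 - a0) * w
        raise ValueError(f"unknown ramp kind {self.ramp[0]!r}")


def make_evoked_template(
    fs: float = DEFAULT_FS,
    amp: float = 1.0,
    freq: float = 5.0,
    duration: float = 0.5,
    decay: float = 8.0,
) -> np.ndarray:
    """Damped 5 Hz burst of 0.5 s, the stereotyped cue-evoked transient.

    The exponential decay constant is chosen so the burst has essentially
    extinguished (< 5 % of peak) by 500 ms after stimulus onset.
    """
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t) * np.exp(-decay * t)


@dataclass
class SyntheticDataset:
    """A simulated cohort: one :class:`EpochSet` per subject plus the truth block."""

    subjects: list
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.subjects:
            ref = self.subjects[0]
            for s in self.subjects:
                if s.fs != ref.fs or s.labels != ref.labels or s.time.size != ref.time.size:
                    raise ValueError("subjects must share fs, labels and epoch limits")

    @property
    def roi_labels(self):
        return self.subjects[0].labels

    @property
    def fs(self):
        return self.subjects[0].fs


def _pink_noise(rng, shape, n_samples, fs):
    """1/f-amplitude noise via spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.maximum(sd, 1e-30)


def generate_reaching_dataset(
    base_model: VARModel,
    post_model: VARModel,
    envelopes,
    *,
    n_subjects: int = 20,
    trials_per_target: int = 60,
    n_targets: int = 5,
    roi_labels=None,
    evoked_rois=(),
    evoked_template=None,
    evoked_jitter: float = 0.1,
    pink_level: float = 0.05,
    tmin: float = -1.0,
    tmax: float = 3.0,
    switch_time: float = 0.5,
    crossfade: float = 0.05,
    subject_jitter: float = 0.1,
    coupling_jitter: float = 0.15,
    seed=0,
) -> SyntheticDataset:
    """Generate the full multi-subject cohort with a populated truth block.

    Each trial is a VAR background whose coefficients cross-fade from
    ``base_model`` to ``post_model`` over ``crossfade`` seconds starting at
    ``switch_time`` after the cue, plus the enveloped oscillations, the
    cue-evoked transient on ``evoked_rois``, and 1/f noise scaled by
    ``pink_level``. Subject-level realism comes from log-normal jitter of
    oscillation amplitudes, innovation scale, and every coupling
    coefficient (``coupling_jitter``, applied identically to the baseline
    and post-cue systems so the condition contrast itself stays the
    programmed one); ERD/ERS gains are identical across subjects.
    """
    if base_model.n_nodes != post_model.n_nodes:
        raise ValueError("baseline and post-cue models must share n_nodes")
    fs = base_model.fs
    n_rois = base_model.n_nodes
    if roi_labels is None:
        roi_labels = default_roi_labels() if n_rois == 16 else [f"ROI{i}" for i in range(n_rois)]
    if len(roi_labels) != n_rois:
        raise ValueError("roi_labels length must match model n_nodes")
    label_idx = {lab: i for i, lab in enumerate(roi_labels)}
    for spec in envelopes:
        if spec.roi not in label_idx:
            raise ValueError(f"envelope ROI {spec.roi!r} not in roi_labels")
    if evoked_template is None:
        evoked_template = make_evoked_template(fs, amp=1.5)

    n_samples = int(round((tmax - tmin) * fs))
    time = tmin + np.arange(n_samples) / fs
    n_trials = trials_per_target * n_targets
    burn_in = max(10 * max(base_model.order, post_model.order), 100)

    # cross-fade weight from baseline to post-cue coefficients
    w = np.clip((time - switch_time) / max(crossfade, 1.0 / fs), 0.0, 1.0)
    pad_p = max(base_model.order, post_model.order)
    A_base = np.zeros((pad_p, n_rois, n_rois))
    A_base[: base_model.order] = base_model.coeffs
    A_post = np.zeros((pad_p, n_rois, n_rois))
    A_post[: post_model.order] = post_model.coeffs

    offdiag_mask = ~np.eye(n_rois, dtype=bool)
    chol = np.linalg.cholesky(base_model.noise_cov)
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)

    ev = np.zeros(n_samples)
    cue_idx = int(round(-tmin * fs))
    ev_len = min(evoked_template.size, n_samples - cue_idx)
    ev[cue_idx : cue_idx + ev_len] = evoked_template[:ev_len]

    subjects = []
    for s_idx in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[s_idx])
        noise_factor = float(np.exp(subject_jitter * rng.standard_normal()))

        # per-subject coupling strengths: the same log-normal factors scale
        # both systems, so only the programmed edges differ between windows
        jit = np.exp(coupling_jitter * rng.standard_normal((pad_p, n_rois, n_rois)))
        A_base_s, A_post_s = A_base.copy(), A_post.copy()
        for k in range(pad_p):
            A_base_s[k][offdiag_mask] *= jit[k][offdiag_mask]
            A_post_s[k][offdiag_mask] *= jit[k][offdiag_mask]
        for name, arr in (("baseline", A_base_s), ("post-cue", A_post_s)):
            if _companion_radius(arr) >= 1.0:
                raise ValueError(
                    f"subject {s_idx}: jittered {name} system became unstable")

        def coeff_at(step, _b=A_base_s, _p=A_post_s):
            if step < burn_in:
                return _b
            wt = w[step - burn_in]
            if wt == 0.0:
                return _b
            if wt == 1.0:
                return _p
            return (1 - wt) * _b + wt * _p

        data = _simulate(coeff_at, chol * noise_factor, burn_in, n_samples, n_trials, rng)

        for spec in envelopes:
            r = label_idx[spec.roi]
            # independent per-subject, per-oscillation amplitude factor:
            # between-subject variation in band power (and hence in how much
            # the oscillation dilutes band-limited GC) is a cohort property
            amp_factor = float(np.exp(subject_jitter * rng.standard_normal()))
            env = spec.amplitude(time) * amp_factor
            phases = rng.uniform(0, 2 * np.pi, size=n_trials)
            osc = np.sin(
                2 * np.pi * spec.band_center_hz * time[None, :] + phases[:, None]
            )
            data[:, r, :] += env[None, :] * osc

        if evoked_rois:
            gains = 1.0 + evoked_jitter * rng.standard_normal((n_trials, len(evoked_rois)))
            for k, roi in enumerate(evoked_rois):
                data[:, label_idx[roi], :] += gains[:, k : k + 1] * ev[None, :]

        if pink_level > 0:
            data += pink_level * _pink_noise(rng, (n_trials, n_rois), n_samples, fs)

        targets = np.repeat(np.arange(1, n_targets + 1), trials_per_target)
        rng.shuffle(targets)
        subjects.append(
            EpochSet(data=data, time=time, fs=fs, labels=list(roi_labels), targets=targets)
        )

    truth = {
        "seed": seed,
        "envelopes": [vars(e).copy() for e in envelopes],
        "base_model": base_model,
        "post_model": post_model,
        "evoked_template": evoked_template,
        "evoked_rois": list(evoked_rois),
        "switch_time": switch_time,
        "crossfade": crossfade,
        "pink_level": pink_level,
    }
    return SyntheticDataset(subjects=subjects, truth=truth)


def _default_models(n_rois=16, fs=DEFAULT_FS, planted_edge=("L.SP", "L.PrC"),
                    planted_weight=0.1, noise_sd=0.25):
    """Baseline/post-cue VAR pair for the default cohort.

    The baseline coupling web is anatomically ordered: a posterior-to-
    anterior chain within each hemisphere (visual -> parietal ->
    sensorimotor -> frontal, lag-1 weight 0.12) plus left-to-right
    homologous links (lag-2 weight 0.08). The post-cue system adds one
    directed skip edge (default parietal L.SP -> motor L.PrC), the planted
    connectivity change whose recovery the downstream battery is judged on.
    """
    labels = default_roi_labels() if n_rois == 16 else [f"ROI{i}" for i in range(n_rois)]
    idx = {lab: i for i, lab in enumerate(labels)}
    half = n_rois // 2
    edges = [(i, i + 1, 1, 0.12) for i in range(half - 1)]
    edges += [(half + i, half + i + 1, 1, 0.12) for i in range(half - 1)]
    edges += [(i, i + half, 2, 0.08) for i in range(half)]
    cov = (noise_sd ** 2) * np.eye(n_rois)
    base = build_var_model(n_rois, 2, edges, self_decay=(0.5, -0.2), noise_cov=cov, fs=fs)
    post_edges = list(edges)
    if planted_edge is not None:
        post_edges.append((idx[planted_edge[0]], idx[planted_edge[1]], 1, planted_weight))
    post = build_var_model(n_rois, 2, post_edges, self_decay=(0.5, -0.2), noise_cov=cov, fs=fs)
    return labels, base, post


def preset_config(name: str, seed=0, **overrides) -> dict:
    """Keyword presets for :func:`generate_reaching_dataset`.

    ``"paper-default"``: 20 subjects, 60 trials/target, 16 ROIs; alpha
    (10 Hz) and beta (20 Hz) oscillations on every ROI; ERD programmed on
    L.PoC (alpha gain 0.5, beta gain 0.7); one post-cue directed edge
    L.SP -> L.PrC added to the coupling web; evoked transient on the visual
    and visuomotor ROIs.

    ``"null"``: identical baseline/post-cue systems and all gains 1 — every
    downstream condition contrast is truly null.
    """
    if name not in ("paper-default", "null"):
        raise ValueError(f"unknown preset {name!r}")
    null = name == "null"
    labels, base, post = _default_models(
        planted_edge=None if null else ("L.SP", "L.PrC")
    )
    envelopes = []
    for lab in labels:
        erd = (not null) and lab == "L.PoC"
        envelopes.append(EnvelopeSpec(lab, 10.0, baseline_amp=1.0,
                                      postcue_gain=0.5 if erd else 1.0))
        envelopes.append(EnvelopeSpec(lab, 20.0, baseline_amp=0.6,
                                      postcue_gain=0.7 if erd else 1.0))
    visual = [l for l in labels if l.split(".")[-1] in ("CU", "LO", "PCU", "SP")]
    cfg = dict(
        base_model=base,
        post_model=base if null else post,
        envelopes=envelopes,
        roi_labels=labels,
        evoked_rois=visual,
        seed=seed,
    )
    cfg.update(overrides)
    return cfg


# ---------------------------------------------------------------------------
# serialization: one array file per subject + one JSON sidecar


def _model_to_json(m: VARModel):
    return {"coeffs": m.coeffs.tolist(), "noise_cov": m.noise_cov.tolist(), "fs": m.fs}


def _model_from_json(d):
    return VARModel(np.asarray(d["coeffs"]), np.asarray(d["noise_cov"]), d["fs"])


def save_dataset(dataset: SyntheticDataset, path) -> None:
    """Write ``subject_XX.npy`` arrays plus a ``meta.json`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(dataset.subjects):
        np.save(path / f"subject_{i:02d}.npy", sub.data)
    ref = dataset.subjects[0]
    truth = dict(dataset.truth)
    meta = {
        "fs": ref.fs,
        "time": [float(ref.time[0]), float(ref.time[-1]), ref.time.size],
        "roi_labels": ref.labels,
        "n_subjects": len(dataset.subjects),
        "targets": [s.targets.tolist() for s in dataset.subjects],
        "truth": {
            **{k: v for k, v in truth.items()
               if k not in ("base_model", "post_model", "evoked_template")},
            "base_model": _model_to_json(truth["base_model"]) if "base_model" in truth else None,
            "post_model": _model_to_json(truth["post_model"]) if "post_model" in truth else None,
            "evoked_template": np.asarray(truth["evoked_template"]).tolist()
            if "evoked_template" in truth else None,
        },
    }
    (path / "meta.json").write_text(json.dumps(meta))


def load_dataset(path) -> SyntheticDataset:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    t0, _, n = meta["time"]
    time = t0 + np.arange(int(n)) / meta["fs"]
    subjects = []
    for i in range(meta["n_subjects"]):
        data = np.load(path / f"subject_{i:02d}.npy")
        subjects.append(
            EpochSet(data=data, time=time, fs=meta["fs"], labels=meta["roi_labels"],
                     targets=np.asarray(meta["targets"][i]))
        )
    truth = dict(meta["truth"])
    for key in ("base_model", "post_model"):
        if truth.get(key) is not None:
            truth[key] = _model_from_json(truth[key])
    if truth.get("evoked_template") is not None:
        truth["evoked_template"] = np.asarray(truth["evoked_template"])
    return SyntheticDataset(subjects=subjects, truth=truth)
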