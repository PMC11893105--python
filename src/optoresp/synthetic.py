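"""Ground-truth synthetic data for every pipeline input class.

Four generators emulate the study's recordings: whole-cell membrane
potential trials around a 100 ms optogenetic pulse, GCaMP-style calcium
traces or movie stacks, connectome synapse edge tables, and single-nucleus
count matrices. Each returns the generated object together with a
:class:`~optoresp.types.GroundTruth` record of the true labels, latencies,
amplitudes and spike times, so recovery can be tested exactly.

All randomness flows from a single seed per session; per-entity
sub-streams are spawned from it, so equal seeds give bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    ConfigurationError,
    EphysTrialSet,
    GroundTruth,
    MovieStack,
    RoiTraceSet,
    synapse_table,
)

LABELS = ("excited", "inhibited", "unaffected")


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

@dataclass
class EphysSimConfig:
    """Parameters of a simulated patch-clamp activation experiment.

    Defaults mirror the recording conditions the pipeline was designed
    for: 10 trials of a 100 ms stimulus at 20 kHz, a ~−40 mV resting
    potential and ~0.8 Hz spontaneous firing. ``trial_length`` is the
    extracted stimulus-aligned window (the 10 s inter-stimulus interval
    is not materialized; ``isi`` is kept for provenance).
    """

    n_cells: int = 1
    n_trials: int = 10
    sampling_rate: float = 20_000.0
    stim_duration: float = 0.1
    isi: float = 10.0
    trial_length: float = 2.5
    stim_onset: float = 1.0
    baseline_vm: float = -40.0
    spont_rate: float = 0.8
    response_labels: Optional[Sequence[str]] = None  # per cell; default all "excited"
    response_amplitude: float = 8.0  # mV, sign taken from the label
    response_latency: float = 0.03  # s after stimulus onset
    response_tau_rise: float = 0.02  # s
    response_tau_decay: float = 0.25  # s
    spike_amplitude: float = 30.0  # mV above baseline
    spike_width: float = 0.002  # s
    noise_sd: float = 0.5  # mV
    drift_sd: float = 0.0  # mV, slow Ornstein–Uhlenbeck drift
    drift_tau: float = 1.0  # s
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("n_cells", self.n_cells >= 1),
            ("n_trials", self.n_trials >= 1),
            ("sampling_rate", self.sampling_rate > 0),
            ("stim_duration", self.stim_duration >= 0),
            ("trial_length", self.trial_length > 0),
            ("stim_onset", 0 <= self.stim_onset
             and self.stim_onset + self.stim_duration <= self.trial_length),
            ("response_latency", self.response_latency >= 0),
            ("noise_sd", self.noise_sd >= 0),
            ("drift_sd", self.drift_sd >= 0),
            ("spont_rate", self.spont_rate >= 0),
            ("response_tau_rise", self.response_tau_rise > 0),
            ("response_tau_decay", self.response_tau_decay > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid EphysSimConfig field: {name}")
        if self.response_labels is not None:
            if len(self.response_labels) != self.n_cells:
                raise ConfigurationError("invalid EphysSimConfig field: response_labels")
            for lab in self.response_labels:
                if lab not in LABELS:
                    raise ConfigurationError("invalid EphysSimConfig field: response_labels")


def spike_template(sampling_rate: float, width: float = 0.002, amplitude: float = 30.0) -> np.ndarray:
    """Biexponential action-potential waveform (~2 ms, peak ``amplitude`` mV)."""
    tau_r = width / 8.0
    tau_d = width / 3.0
    t = np.arange(0, width * 3, 1.0 / sampling_rate)
    w = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return amplitude * w / w.max()


def response_kernel(t: np.ndarray, latency: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials PSP shape, unit peak, zero before ``latency``."""
    s = t - latency
    out = np.zeros_like(t)
    m = s > 0
    out[m] = np.exp(-s[m] / tau_decay) - np.exp(-s[m] / tau_rise)
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def _ou_drift(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1 - a * a)
    eps = rng.normal(size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i - 1]
    return x


def gen_ephys_session(config: EphysSimConfig):
    """Simulate one session of stimulus-aligned membrane-potential trials.

    Returns ``(trial_sets, ground_truth)`` where ``trial_sets`` is a list of
    :class:`EphysTrialSet`, one per cell. Each trial is baseline + Gaussian
    noise (+ optional OU drift) + Poisson spontaneous spikes + a
    stimulus-locked difference-of-exponentials de/hyperpolarization
    according to the cell's true label.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    n_samples = int(round(config.trial_length * config.sampling_rate))
    t = np.arange(n_samples) / config.sampling_rate
    labels = list(config.response_labels) if config.response_labels is not None \
        else ["excited"] * config.n_cells

    template = spike_template(config.sampling_rate, config.spike_width, config.spike_amplitude)
    gt = GroundTruth()
    sets = []
    for c in range(config.n_cells):
        rng = np.random.default_rng(root.integers(0, 2**31))
        cell_id = f"cell{c:03d}"
        label = labels[c]
        sign = {"excited": 1.0, "inhibited": -1.0, "unaffected": 0.0}[label]
        amp = sign * abs(config.response_amplitude)
        resp = amp * response_kernel(t - config.stim_onset, config.response_latency,
                                     config.response_tau_rise, config.response_tau_decay)
        vm = np.empty((config.n_trials, n_samples))
        trial_spikes = []
        for tr in range(config.n_trials):
            trace = config.baseline_vm + resp.copy()
            if config.noise_sd > 0:
                trace = trace + rng.normal(0, config.noise_sd, n_samples)
            if config.drift_sd > 0:
                trace = trace + _ou_drift(rng, n_samples, 1.0 / config.sampling_rate,
                                          config.drift_sd, config.drift_tau)
            n_sp = rng.poisson(config.spont_rate * config.trial_length)
            times = np.sort(rng.uniform(0, config.trial_length, n_sp))
            # enforce a refractory separation so the template insertions stay distinct
            if times.size > 1:
                keep = np.concatenate([[True], np.diff(times) > 0.005])
                times = times[keep]
            for ts in times:
                i0 = int(round(ts * config.sampling_rate))
                seg = template[: n_samples - i0]
                trace[i0: i0 + seg.size] += seg
            vm[tr] = trace
            trial_spikes.append(times)
        sets.append(EphysTrialSet(cell_id=cell_id, vm=vm,
                                  sampling_rate=config.sampling_rate,
                                  stim_onset=config.stim_onset,
                                  stim_duration=config.stim_duration))
        gt.labels[cell_id] = label
        gt.latencies[cell_id] = None if label == "unaffected" else config.response_latency
        gt.amplitudes[cell_id] = amp
        gt.spike_times[cell_id] = trial_spikes
    return sets, gt


# ---------------------------------------------------------------------------
# calcium imaging
# ---------------------------------------------------------------------------

@dataclass
class CalciumSimConfig:
    """Parameters of a simulated calcium-imaging session.

    Defaults emulate single-plane imaging at 10 Hz for 2 min trials with
    two 5 s stimulus pulses per trial. The spike-to-fluorescence transform
    is a phenomenological double-exponential kernel with literature-typical
    GCaMP6m kinetics (rise 0.08 s, decay 0.6 s); these are free parameters.
    """

    n_rois: int = 13
    frame_rate: float = 10.0
    trial_duration: float = 120.0
    n_trials: int = 4
    stim_schedule: Optional[list] = None  # per-trial (onset_s, duration_s); default 2×5 s
    kernel_rise: float = 0.08
    kernel_decay: float = 0.6
    baseline_f: float = 100.0
    spike_dff_amp: float = 0.1  # ΔF/F contribution of a single spike, × baseline_f
    response_labels: Optional[Sequence[str]] = None
    response_amplitude: float = 0.5  # peak ΔF/F of the stimulus response, × baseline_f
    spont_rate: float = 0.8  # Hz, spontaneous spiking (matches baseline firing rate)
    photon_noise_sd: float = 1.0  # a.u.
    background_f: float = 20.0  # a.u., additive offset in stack mode (keeps F0 > 0)
    motion_shifts: Optional[np.ndarray] = None  # (n_frames, 2) integer (dy, dx)
    roi_geometry: Optional[list] = None  # [(cy, cx, radius_px), ...]
    frame_shape: tuple = (64, 64)
    seed: int = 0

    def schedule(self) -> list:
        if self.stim_schedule is not None:
            return list(self.stim_schedule)
        return [(30.0, 5.0), (80.0, 5.0)]

    def validate(self) -> None:
        if self.n_rois < 1:
            raise ConfigurationError("invalid CalciumSimConfig field: n_rois")
        if self.frame_rate <= 0:
            raise ConfigurationError("invalid CalciumSimConfig field: frame_rate")
        if self.n_trials < 1:
            raise ConfigurationError("invalid CalciumSimConfig field: n_trials")
        if not self.kernel_rise < self.kernel_decay:
            raise ConfigurationError("invalid CalciumSimConfig field: kernel_rise")
        for onset, dur in self.schedule():
            if onset < 0 or onset + dur > self.trial_duration:
                raise ConfigurationError(
                    "invalid CalciumSimConfig field: stim_schedule (window outside trial)")
        if self.response_labels is not None and len(self.response_labels) != self.n_rois:
            raise ConfigurationError("invalid CalciumSimConfig field: response_labels")


def gcamp_kernel(frame_rate: float, rise: float = 0.08, decay: float = 0.6) -> np.ndarray:
    """Unit-peak double-exponential calcium-indicator impulse response."""
    t = np.arange(0, decay * 8, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_calcium_session(config: CalciumSimConfig, mode: str = "traces"):
    """Simulate a calcium-imaging session as ROI traces or a movie stack.

    In ``traces`` mode returns ``(RoiTraceSet, GroundTruth)`` with raw
    fluorescence traces (``kind="f"``); ΔF/F is left to the analysis
    pipeline. In ``stack`` mode renders Gaussian-blob ROIs into frames,
    applies configured integer motion shifts and returns
    ``(MovieStack, label_mask, GroundTruth)``.
    """
    config.validate()
    if mode not in ("traces", "stack"):
        raise ConfigurationError(f"unknown calcium simulation mode {mode!r}")
    if mode == "stack" and config.roi_geometry is None:
        raise ConfigurationError("stack mode requires roi_geometry")

    root = np.random.default_rng(config.seed)
    frames_per_trial = int(round(config.trial_duration * config.frame_rate))
    n_frames = frames_per_trial * config.n_trials
    labels = list(config.response_labels) if config.response_labels is not None \
        else ["excited"] * config.n_rois
    kernel = gcamp_kernel(config.frame_rate, config.kernel_rise, config.kernel_decay)

    # absolute stimulus schedule across concatenated trials
    schedule = []
    for tr in range(config.n_trials):
        for onset, dur in config.schedule():
            schedule.append((tr * config.trial_duration + onset, dur))
    trial_boundaries = [tr * frames_per_trial for tr in range(config.n_trials)]

    t = np.arange(n_frames) / config.frame_rate
    gt = GroundTruth()
    traces = np.empty((config.n_rois, n_frames))
    for r in range(config.n_rois):
        rng = np.random.default_rng(root.integers(0, 2**31))
        roi_id = f"roi{r + 1:02d}"
        label = labels[r]
        sign = {"excited": 1.0, "inhibited": -1.0, "unaffected": 0.0}[label]
        amp = sign * abs(config.response_amplitude) * config.baseline_f

        # spontaneous calcium events convolved with the indicator kernel
        n_sp = rng.poisson(config.spont_rate * config.n_trials * config.trial_duration)
        sp_times = np.sort(rng.uniform(0, config.n_trials * config.trial_duration, n_sp))
        impulses = np.zeros(n_frames)
        idx = np.minimum((sp_times * config.frame_rate).round().astype(int), n_frames - 1)
        np.add.at(impulses, idx, 1.0)
        spike_component = np.convolve(impulses, kernel)[:n_frames] \
            * config.spike_dff_amp * config.baseline_f

        # stimulus-locked sustained response shaped by the indicator kinetics
        stim_component = np.zeros(n_frames)
        if sign != 0:
            drive = np.zeros(n_frames)
            for onset, dur in schedule:
                drive[(t >= onset) & (t < onset + dur)] = 1.0
            shaped = np.convolve(drive, kernel)[:n_frames]
            peak = shaped.max()
            if peak > 0:
                stim_component = amp * shaped / peak

        trace = config.baseline_f + spike_component + stim_component
        if config.photon_noise_sd > 0:
            trace = trace + rng.normal(0, config.photon_noise_sd, n_frames)
        traces[r] = trace
        gt.labels[roi_id] = label
        gt.amplitudes[roi_id] = amp
        gt.spike_times[roi_id] = sp_times
        gt.latencies[roi_id] = None if label == "unaffected" else 0.0
    gt.extras["kernel"] = kernel
    gt.extras["baseline_f"] = config.baseline_f

    trace_set = RoiTraceSet(
        roi_ids=[f"roi{r + 1:02d}" for r in range(config.n_rois)],
        values=traces, frame_rate=config.frame_rate,
        stim_schedule=schedule, trial_boundaries=trial_boundaries, kind="f")
    if mode == "traces":
        return trace_set, gt

    h, w = config.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    geometry = config.roi_geometry
    if len(geometry) != config.n_rois:
        raise ConfigurationError("roi_geometry length must equal n_rois")
    mask = np.zeros((h, w), dtype=int)
    footprints = []
    for i, (cy, cx, rad) in enumerate(geometry, start=1):
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (rad / 2.0) ** 2)))
        footprints.append(blob)
        mask[((yy - cy) ** 2 + (xx - cx) ** 2) <= rad ** 2] = i

    shifts = config.motion_shifts
    if shifts is None:
        shifts = np.zeros((n_frames, 2), dtype=int)
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (n_frames, 2):
        raise ConfigurationError("motion_shifts must have shape (n_frames, 2)")

    noise_rng = np.random.default_rng(root.integers(0, 2**31))
    stack = np.zeros((n_frames, h, w))
    for f in range(n_frames):
        frame = np.full((h, w), float(config.background_f))
        for r in range(config.n_rois):
            frame += traces[r, f] * footprints[r]
        dy, dx = shifts[f]
        frame = np.roll(np.roll(frame, dy, axis=0), dx, axis=1)
        if config.photon_noise_sd > 0:
            frame = frame + noise_rng.normal(0, config.photon_noise_sd, (h, w))
        stack[f] = frame
    gt.shifts = shifts
    movie = MovieStack(frames=stack, frame_rate=config.frame_rate,
                       stim_schedule=schedule, trial_boundaries=trial_boundaries)
    return movie, mask, gt


# ---------------------------------------------------------------------------
# connectome edge tables
# ---------------------------------------------------------------------------

_TRANSMITTERS = ("ACh", "Glu", "GABA", "DA", "OA", "5-HT")


def gen_synapse_table(n_pre: int, n_post: int,
                      count_law: Optional[dict] = None,
                      score_law: Optional[dict] = None,
                      transmitters: Sequence[str] = _TRANSMITTERS,
                      seed: int = 0):
    """Simulate a connectome export: one edge per (pre, post) pair.

    ``count_law`` supports ``{"name": "poisson", "mean": m}`` (shifted by 1
    so counts are ≥ 1) and ``{"name": "geometric", "mean": m}``;
    ``score_law`` supports ``{"name": "beta", "a": ..., "b": ...}`` and
    ``{"name": "uniform"}``. Returns ``(table, ground_truth)``.
    """
    if n_pre < 1 or n_post < 1:
        raise ConfigurationError("n_pre and n_post must be ≥ 1")
    count_law = count_law or {"name": "poisson", "mean": 8.0}
    score_law = score_law or {"name": "beta", "a": 5.0, "b": 2.0}
    rng = np.random.default_rng(seed)
    n_edges = n_pre * n_post
    pre = np.repeat([f"pre{i:05d}" for i in range(n_pre)], n_post)
    post = np.tile([f"ipc{i:03d}" for i in range(n_post)], n_pre)

    name = count_law["name"]
    if name == "poisson":
        mean = float(count_law["mean"])
        if mean < 1:
            raise ConfigurationError("poisson count law needs mean ≥ 1")
        counts = 1 + rng.poisson(mean - 1.0, n_edges)
    elif name == "geometric":
        mean = float(count_law["mean"])
        if mean < 1:
            raise ConfigurationError("geometric count law needs mean ≥ 1")
        counts = rng.geometric(1.0 / mean, n_edges)
    else:
        raise ConfigurationError(f"unknown count law {name!r}")

    sname = score_law["name"]
    if sname == "beta":
        scores = rng.beta(float(score_law["a"]), float(score_law["b"]), n_edges)
    elif sname == "uniform":
        scores = rng.uniform(0, 1, n_edges)
    else:
        raise ConfigurationError(f"unknown score law {sname!r}")

    true_tx = rng.choice(list(transmitters), size=n_pre)
    tx_per_edge = np.repeat(true_tx, n_post)
    table = synapse_table({
        "pre_id": pre, "post_id": post, "syn_count": counts.astype(int),
        "transmitter": tx_per_edge, "score": scores})
    gt = GroundTruth(transmitters={f"pre{i:05d}": true_tx[i] for i in range(n_pre)})
    gt.extras["count_law"] = dict(count_law)
    gt.extras["score_law"] = dict(score_law)
    return table, gt


# ---------------------------------------------------------------------------
# expression count matrices
# ---------------------------------------------------------------------------

def gen_expression_matrix(n_cells: int, genes: Sequence[str],
                          expr_prob, mean_count: float = 5.0, seed: int = 0):
    """Simulate a cells × genes integer count matrix with Bernoulli gating.

    Each cell expresses gene g with probability ``expr_prob[g]``; expressed
    entries get ``1 + Poisson(mean_count − 1)`` counts, silent entries 0.
    ``expr_prob`` may be a scalar or a per-gene mapping/sequence. Returns
    ``(DataFrame cells × genes, ground_truth)``.
    """
    import pandas as pd

    if n_cells < 1:
        raise ConfigurationError("n_cells must be ≥ 1")
    genes = list(genes)
    if np.isscalar(expr_prob):
        probs = {g: float(expr_prob) for g in genes}
    elif isinstance(expr_prob, dict):
        probs = {g: float(expr_prob[g]) for g in genes}
    else:
        probs = {g: float(p) for g, p in zip(genes, expr_prob)}
    for g, p in probs.items():
        if not 0 <= p <= 1:
            raise ConfigurationError(f"expression probability out of range for gene {g}")
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_cells, len(genes)), dtype=int)
    for j, g in enumerate(genes):
        gate = rng.random(n_cells) < probs[g]
        counts = 1 + rng.poisson(max(mean_count - 1.0, 0.0), n_cells)
        mat[:, j] = np.where(gate, counts, 0)
    df = pd.DataFrame(mat, index=[f"cell{i:04d}" for i in range(n_cells)], columns=genes)
    gt = GroundTruth(expr_prob=probs)
    return df, gt
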