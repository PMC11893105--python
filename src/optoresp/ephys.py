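"""Patch-clamp analysis chain for optogenetic activation experiments.

The pipeline mirrors the standard workflow for whole-cell recordings of
insulin-producing cells during repeated 100 ms optogenetic pulses:

1. median-filter each trial (250 ms window) to suppress spikes,
2. center each trial by subtracting its median,
3. take the pointwise median across the 10 trials as the global response,
4. derive baseline-variability thresholds as the 10th/90th percentiles of
   the pooled filtered traces in a 900 ms window starting 100 ms after
   trace onset,
5. classify the median trace as excited / inhibited / unaffected by a
   50 ms consecutive-crossing criterion in the 1 s post-onset window,
6. quantify by trapezoidal AUC (±1 s around onset) and, for responders,
   onset latency from Savitzky–Golay-filtered traces at four window
   lengths (400/200/100/50 ms) averaged.

Population-level helpers compute the per-driver-line effect coefficient
(mean post-stimulus AUC normalized to the maximum AUC among excited
cells) and paired Wilcoxon signed-rank statistics.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import wilcoxon

from .types import (
    EphysTrialSet,
    InputError,
    PopulationSummary,
    ResponseResult,
    SpikeTrain,
    ThresholdPair,
)

__all__ = [
    "median_filter_trace", "center_trace", "trial_median", "baseline_thresholds",
    "classify_vm_response", "detect_spikes", "bin_firing_rate", "response_auc",
    "estimate_latency", "paired_wilcoxon", "population_effect_coefficient",
    "classify_cell", "analyze_session", "summarize_population",
]


def _window_samples(window: float, sampling_rate: float, odd: bool = False) -> int:
    n = int(round(window * sampling_rate))
    if odd and n % 2 == 0:
        n += 1
    return max(n, 1)


def median_filter_trace(trace: np.ndarray, window: float = 0.25,
                        sampling_rate: float = 20_000.0) -> np.ndarray:
    """Sliding-window median filter (default 250 ms).

    The window shrinks at the trace edges (no padding), so the first and
    last samples are medians over the in-bounds part of the window only.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InputError("cannot median-filter an empty trace")
    w = _window_samples(window, sampling_rate)
    if w < 1:
        raise InputError("median filter window must cover at least one sample")
    if w == 1:
        return trace.copy()
    return (
        pd.Series(trace)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def center_trace(trace: np.ndarray) -> np.ndarray:
    """Center a trace around zero by subtracting its median."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InputError("cannot center an empty trace")
    return trace - np.median(trace)


def trial_median(trials: np.ndarray) -> np.ndarray:
    """Pointwise median across trials — the cell's global response estimate."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim == 1:
        trials = trials[None, :]
    if trials.ndim != 2 or trials.shape[0] < 1:
        raise InputError("trials must be a non-empty (trials, samples) matrix")
    return np.median(trials, axis=0)


def baseline_thresholds(trials: np.ndarray, sampling_rate: float,
                        window_start: float = 0.1, window_len: float = 0.9,
                        percentiles: Tuple[float, float] = (10.0, 90.0),
                        pooled: bool = True) -> ThresholdPair:
    """Baseline variability thresholds from the pre-stimulus window.

    Percentiles (default 10th/90th) are taken over the pooled samples of
    all filtered, centered trials inside ``[window_start, window_start +
    window_len]`` seconds from trace start. ``pooled=False`` computes
    per-trial percentiles and averages them instead.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    i0 = int(round(window_start * sampling_rate))
    i1 = int(round((window_start + window_len) * sampling_rate))
    if i0 < 0 or i1 > trials.shape[1] or i1 <= i0:
        raise InputError("baseline window lies outside the trace")
    seg = trials[:, i0:i1]
    if pooled:
        lo, hi = np.percentile(seg.ravel(), percentiles)
    else:
        per = np.percentile(seg, percentiles, axis=1)
        lo, hi = per[0].mean(), per[1].mean()
    return ThresholdPair(lower=float(lo), upper=float(hi),
                         baseline_window=(window_start, window_start + window_len))


def _first_qualifying_run(mask: np.ndarray, min_len: int) -> Optional[int]:
    """Start index of the first run of True of length ≥ min_len, else None."""
    if mask.size == 0:
        return None
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return int(s)
    return None


def classify_vm_response(median_trace: np.ndarray, thresholds: ThresholdPair,
                         stim_onset: float, sampling_rate: float,
                         eval_window: float = 1.0,
                         min_duration: float = 0.05) -> str:
    """Three-way response label from threshold crossings of the median trace.

    Excited: the trace stays above the upper threshold for at least
    ``min_duration`` consecutive seconds within ``eval_window`` after
    stimulus onset; inhibited: the mirror criterion on the lower
    threshold; otherwise unaffected. If both criteria are met, the label
    whose qualifying run starts earlier wins (tie → excited).
    """
    median_trace = np.asarray(median_trace, dtype=float)
    i0 = int(round(stim_onset * sampling_rate))
    i1 = int(round((stim_onset + eval_window) * sampling_rate))
    if i0 < 0 or i1 > median_trace.size:
        raise InputError("evaluation window lies outside the trace")
    seg = median_trace[i0:i1]
    min_len = _window_samples(min_duration, sampling_rate)
    up = _first_qualifying_run(seg > thresholds.upper, min_len)
    down = _first_qualifying_run(seg < thresholds.lower, min_len)
    if up is None and down is None:
        return "unaffected"
    if down is None or (up is not None and up <= down):
        return "excited"
    return "inhibited"


def detect_spikes(trace: np.ndarray, sampling_rate: float,
                  threshold_sd: float = 6.0, refractory: float = 0.002,
                  filter_window: float = 0.25) -> np.ndarray:
    """Detect spike peak times (s) on the high-pass residual of one trace.

    The slow component (sliding median, ``filter_window``) is subtracted;
    peaks must rise at least ``threshold_sd`` robust standard deviations
    (1.4826 × MAD) above the residual baseline and are de-duplicated by a
    ``refractory`` minimum separation.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InputError("cannot detect spikes in an empty trace")
    residual = trace - median_filter_trace(trace, filter_window, sampling_rate)
    sigma = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    if sigma == 0:
        sigma = np.std(residual)
    if sigma == 0:
        return np.array([])
    distance = max(_window_samples(refractory, sampling_rate), 1)
    peaks, _ = find_peaks(residual, height=threshold_sd * sigma,
                          prominence=threshold_sd * sigma / 2, distance=distance)
    return peaks / sampling_rate


def detect_spikes_trials(trial_set: EphysTrialSet, **kwargs) -> SpikeTrain:
    """Run :func:`detect_spikes` on every trial of a trial set."""
    return SpikeTrain([detect_spikes(tr, trial_set.sampling_rate, **kwargs)
                       for tr in trial_set.vm])


def bin_firing_rate(spikes: SpikeTrain, duration: float, bin_width: float = 0.25) -> np.ndarray:
    """Firing rate (spk/s) in non-overlapping bins, averaged across trials."""
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    edges = np.arange(0.0, duration + bin_width / 2, bin_width)
    if edges[-1] < duration:
        edges = np.append(edges, duration)
    rates = []
    for times in spikes.spike_times:
        counts, _ = np.histogram(times, bins=edges)
        rates.append(counts / np.diff(edges))
    return np.mean(rates, axis=0) if rates else np.zeros(len(edges) - 1)


def response_auc(median_trace: np.ndarray, sampling_rate: float,
                 stim_onset: float, horizon: float = 1.0) -> Tuple[float, float, float]:
    """Trapezoidal AUC (mV·s) post vs pre stimulus.

    ``auc_post`` integrates from onset to ``horizon`` s after onset,
    ``auc_base`` from ``horizon`` s before onset to onset;
    ``delta_auc = auc_post − auc_base``.
    """
    median_trace = np.asarray(median_trace, dtype=float)
    i_on = int(round(stim_onset * sampling_rate))
    i_pre = int(round((stim_onset - horizon) * sampling_rate))
    i_post = int(round((stim_onset + horizon) * sampling_rate))
    if i_pre < 0 or i_post >= median_trace.size:
        raise InputError("AUC windows lie outside the trace")
    dx = 1.0 / sampling_rate
    # inclusive right endpoint so an n-second window integrates n seconds
    auc_post = float(np.trapezoid(median_trace[i_on:i_post + 1], dx=dx))
    auc_base = float(np.trapezoid(median_trace[i_pre:i_on + 1], dx=dx))
    return auc_post, auc_base, auc_post - auc_base


def estimate_latency(trials: np.ndarray, sampling_rate: float, stim_onset: float,
                     label: str,
                     sg_windows: Sequence[float] = (0.4, 0.2, 0.1, 0.05),
                     sg_order: int = 4,
                     baseline_start: float = 0.1, baseline_len: float = 0.9,
                     eval_window: float = 1.0,
                     percentiles: Tuple[float, float] = (10.0, 90.0)):
    """Onset latency of a classified response, in seconds after onset.

    Per Savitzky–Golay window length: each raw trial is SG-filtered
    (odd sample window, 4th-order polynomial), centered by its median,
    the pointwise median is taken across trials, 10th/90th baseline
    percentiles are recomputed on the filtered traces, and the latency is
    the first post-onset crossing of the upper (excited) or lower
    (inhibited) threshold. The final estimate averages the per-window
    latencies; windows without a crossing are flagged and excluded. If no
    window yields a crossing the latency is undefined (``None``).

    Returns ``(latency, flags)`` where ``flags`` maps each window length
    to its per-window latency or ``None``.
    """
    if label not in ("excited", "inhibited"):
        raise InputError("latency is only defined for excited or inhibited cells")
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    n = trials.shape[1]
    i_on = int(round(stim_onset * sampling_rate))
    i_end = min(int(round((stim_onset + eval_window) * sampling_rate)), n)
    per_window = {}
    for w in sg_windows:
        wl = _window_samples(w, sampling_rate, odd=True)
        wl = max(wl, sg_order + 2 + ((sg_order + 2) % 2 == 0))  # odd, > polyorder
        if wl % 2 == 0:
            wl += 1
        if wl > n:
            per_window[w] = None
            continue
        filt = savgol_filter(trials, window_length=wl, polyorder=sg_order, axis=1)
        filt = filt - np.median(filt, axis=1, keepdims=True)
        med = np.median(filt, axis=0)
        thr = baseline_thresholds(filt, sampling_rate, baseline_start, baseline_len,
                                  percentiles)
        seg = med[i_on:i_end]
        if label == "excited":
            crossings = np.flatnonzero(seg > thr.upper)
        else:
            crossings = np.flatnonzero(seg < thr.lower)
        per_window[w] = float(crossings[0] / sampling_rate) if crossings.size else None
    found = [v for v in per_window.values() if v is not None]
    latency = float(np.mean(found)) if found else None
    return latency, per_window


def paired_wilcoxon(pre_values: np.ndarray, post_values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (Wilcoxon's original treatment); if
    every difference is zero the comparison is degenerate and p = 1.
    The exact null distribution is used whenever scipy can (small n, no
    ties), otherwise the normal approximation.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise InputError("pre and post value vectors must have equal length")
    if pre.size == 0:
        raise InputError("empty sample")
    d = post - pre
    if np.all(d == 0):
        return 1.0
    res = wilcoxon(pre, post, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def population_effect_coefficient(aucs: Sequence[float], labels: Sequence[str]):
    """Effect coefficient: mean post-stimulus AUC over max excited-cell AUC.

    The per-cell post-stimulus AUCs (from median-centered median traces)
    are averaged across all cells of a driver line and normalized so that
    the maximum AUC among excited cells maps to 1. When no cell is
    excited the normalizer falls back to the maximum |AUC| over all cells
    and the result is flagged.

    Returns ``(coefficient, normalizer, fallback_used)``.
    """
    aucs = np.asarray(aucs, dtype=float)
    labels = list(labels)
    if aucs.size == 0:
        raise InputError("effect coefficient needs at least one cell")
    if len(labels) != aucs.size:
        raise InputError("labels and AUCs must align")
    excited = aucs[[lab == "excited" for lab in labels]]
    fallback = excited.size == 0
    normalizer = float(np.max(np.abs(aucs))) if fallback else float(np.max(excited))
    if normalizer == 0:
        return 0.0, normalizer, fallback
    return float(np.mean(aucs) / normalizer), normalizer, fallback


# ---------------------------------------------------------------------------
# convenience chains
# ---------------------------------------------------------------------------

def classify_cell(trial_set: EphysTrialSet,
                  filter_window: float = 0.25,
                  baseline_start: float = 0.1, baseline_len: float = 0.9,
                  percentiles: Tuple[float, float] = (10.0, 90.0),
                  eval_window: float = 1.0, min_duration: float = 0.05,
                  auc_horizon: float = 1.0,
                  with_latency: bool = True,
                  pooled: bool = True) -> ResponseResult:
    """Full single-cell chain: filter → center → median → classify → AUC → latency."""
    rate = trial_set.sampling_rate
    filtered = np.stack([
        center_trace(median_filter_trace(tr, filter_window, rate))
        for tr in trial_set.vm
    ])
    med = trial_median(filtered)
    thr = baseline_thresholds(filtered, rate, baseline_start, baseline_len,
                              percentiles, pooled=pooled)
    label = classify_vm_response(med, thr, trial_set.stim_onset, rate,
                                 eval_window, min_duration)
    auc_post, auc_base, delta = response_auc(med, rate, trial_set.stim_onset, auc_horizon)
    latency, flags = (None, {})
    if with_latency and label != "unaffected":
        latency, flags = estimate_latency(
            trial_set.vm, rate, trial_set.stim_onset, label,
            baseline_start=baseline_start, baseline_len=baseline_len,
            eval_window=eval_window, percentiles=percentiles)
    return ResponseResult(label=label, auc_post=auc_post, auc_base=auc_base,
                          delta_auc=delta, latency=latency, thresholds=thr,
                          cell_id=trial_set.cell_id, latency_flags=flags)


def analyze_session(trial_sets, **kwargs):
    """Classify every cell of a session; returns a list of ResponseResult."""
    return [classify_cell(ts, **kwargs) for ts in trial_sets]


def summarize_population(results, driver_line: str = "",
                         min_cluster_n: int = 5) -> PopulationSummary:
    """Population summary: effect coefficient, cluster counts, Wilcoxon tests.

    The pre-vs-post AUC comparison runs over all cells and, separately,
    per cluster for clusters with at least ``min_cluster_n`` cells.
    """
    if not results:
        raise InputError("population summary needs at least one result")
    labels = [r.label for r in results]
    aucs = [r.auc_post for r in results]
    coeff, norm, fallback = population_effect_coefficient(aucs, labels)
    counts = {lab: labels.count(lab) for lab in ("excited", "inhibited", "unaffected")}
    pvals = {"all": paired_wilcoxon([r.auc_base for r in results],
                                    [r.auc_post for r in results])}
    for lab in ("excited", "inhibited", "unaffected"):
        members = [r for r in results if r.label == lab]
        if len(members) >= min_cluster_n:
            pvals[lab] = paired_wilcoxon([r.auc_base for r in members],
                                         [r.auc_post for r in members])
    return PopulationSummary(driver_line=driver_line, effect_coefficient=coeff,
                             cluster_counts=counts, p_values=pvals,
                             normalizer=norm, normalizer_fallback=fallback)
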