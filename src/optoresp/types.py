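"""Shared data containers for the response-analysis pipelines.

Everything is a plain dataclass wrapping numpy arrays or pandas frames;
units are documented per field (mV, s, Hz, dimensionless ΔF/F).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LABELS = ("excited", "inhibited", "unaffected")


class ConfigurationError(ValueError):
    """A simulation or analysis configuration field is invalid."""


class InputError(ValueError):
    """An input array/table violates a precondition of an operation."""


@dataclass
class EphysTrialSet:
    """Stimulus-aligned whole-cell membrane-potential trials for one cell.

    ``vm`` is a (n_trials, n_samples) matrix in mV sampled at
    ``sampling_rate`` Hz; ``stim_onset``/``stim_duration`` are seconds
    relative to trace start.
    """

    cell_id: str
    vm: np.ndarray
    sampling_rate: float
    stim_onset: float
    stim_duration: float
    driver_line: str = ""

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        if self.vm.ndim != 2:
            raise InputError("vm must be a (trials, samples) matrix")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        dur = self.vm.shape[1] / self.sampling_rate
        if not (0 <= self.stim_onset and self.stim_onset + self.stim_duration <= dur):
            raise InputError("stimulus window must lie within the trial")

    @property
    def n_trials(self) -> int:
        return self.vm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.vm.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds from trace start."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class SpikeTrain:
    """Detected spike peak times, one list of seconds per trial."""

    spike_times: list  # list of 1-D float arrays, seconds

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for t in self.spike_times:
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise InputError("spike times must be strictly increasing per trial")

    @property
    def n_trials(self) -> int:
        return len(self.spike_times)

    def total_count(self) -> int:
        return int(sum(t.size for t in self.spike_times))


@dataclass
class ThresholdPair:
    """Baseline-variability thresholds (percentiles of pooled baseline)."""

    lower: float
    upper: float
    baseline_window: tuple = (0.1, 1.0)

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InputError("lower threshold exceeds upper threshold")


@dataclass
class ResponseResult:
    """Classification and quantification for one recorded cell or ROI."""

    label: str
    auc_post: float
    auc_base: float
    delta_auc: float
    latency: Optional[float]
    thresholds: ThresholdPair
    cell_id: str = ""
    latency_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InputError(f"unknown label {self.label!r}")


@dataclass
class PopulationSummary:
    """Per-driver-line population statistics."""

    driver_line: str
    effect_coefficient: float
    cluster_counts: dict
    p_values: dict = field(default_factory=dict)
    normalizer: float = float("nan")
    normalizer_fallback: bool = False


@dataclass
class MovieStack:
    """Single-plane imaging movie: (time, height, width) intensities."""

    frames: np.ndarray
    frame_rate: float
    stim_schedule: list  # list of (onset_s, duration_s)
    trial_boundaries: Optional[list] = None  # frame indices starting each trial

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("frames must be (time, height, width)")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence time series at frame rate.

    ``values`` is (n_rois, n_frames); ``kind`` records whether the values
    are raw fluorescence ("f") or ΔF/F ("dff").
    """

    roi_ids: list
    values: np.ndarray
    frame_rate: float
    stim_schedule: list
    trial_boundaries: Optional[list] = None
    animal_id: str = ""
    kind: str = "dff"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.roi_ids) != self.values.shape[0]:
            raise InputError("roi_ids length must match number of trace rows")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InputError("trace values must be finite")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class RoiClassification:
    """Threshold classification outcome for one ROI."""

    roi_id: str
    label: str
    lower: float
    upper: float
    run_frames: int
    required_run: int
    auc_pre: float
    auc_post: float
    delta_auc: float


@dataclass
class GroundTruth:
    """Generation metadata keyed by entity id, enabling recovery tests."""

    labels: dict = field(default_factory=dict)
    latencies: dict = field(default_factory=dict)
    amplitudes: dict = field(default_factory=dict)
    spike_times: dict = field(default_factory=dict)
    shifts: Optional[np.ndarray] = None  # per-frame (dy, dx) integer shifts
    expr_prob: dict = field(default_factory=dict)
    transmitters: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return {
            "labels": conv(self.labels),
            "latencies": conv(self.latencies),
            "amplitudes": conv(self.amplitudes),
            "spike_times": conv(self.spike_times),
            "shifts": conv(self.shifts),
            "expr_prob": conv(self.expr_prob),
            "transmitters": conv(self.transmitters),
            "extras": conv(self.extras),
        }


def synapse_table(rows) -> pd.DataFrame:
    """Build a validated connectome edge table.

    Columns: pre_id, post_id, syn_count (int ≥ 1), transmitter, score in [0, 1].
    """
    df = pd.DataFrame(rows, columns=["pre_id", "post_id", "syn_count", "transmitter", "score"])
    if len(df) and (df["syn_count"] < 1).any():
        raise InputError("syn_count must be ≥ 1")
    if len(df) and ((df["score"] < 0) | (df["score"] > 1)).any():
        raise InputError("score must lie in [0, 1]")
    return df
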