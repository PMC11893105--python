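"""Readers and writers for the pipeline's on-disk formats.

Trial-set tables and ROI traces travel as CSV (one row per sample with a
trigger column mirroring TTL storage), movies as multi-frame TIFF with
integer label-mask TIFFs for ROIs, connectome edge tables and expression
matrices as CSV (expression alternatively MTX + name files), and
ground-truth / summary metadata as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EphysTrialSet, GroundTruth, InputError, MovieStack, RoiTraceSet


class ParseError(ValueError):
    """A file violates the expected schema."""


# ---------------------------------------------------------------------------
# ephys trial tables
# ---------------------------------------------------------------------------

EPHYS_COLUMNS = ["time_s", "trial", "vm_mv", "trigger"]


def write_trial_table(trial_set: EphysTrialSet, path) -> Path:
    """Serialize a trial set as long-form CSV with a TTL trigger column."""
    path = Path(path)
    t = trial_set.time()
    trig = ((t >= trial_set.stim_onset)
            & (t < trial_set.stim_onset + trial_set.stim_duration)).astype(int)
    frames = []
    for i, trial in enumerate(trial_set.vm):
        frames.append(pd.DataFrame({"time_s": t, "trial": i, "vm_mv": trial,
                                    "trigger": trig}))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    meta = {"cell_id": trial_set.cell_id, "sampling_rate": trial_set.sampling_rate,
            "driver_line": trial_set.driver_line}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_trial_table(path) -> EphysTrialSet:
    """Read a long-form trial CSV back into an :class:`EphysTrialSet`.

    The trigger column is parsed into the stimulus onset/duration; a
    missing required column raises a :class:`ParseError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in EPHYS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    trials = sorted(df["trial"].unique())
    mats, lengths = [], set()
    for tr in trials:
        sub = df[df["trial"] == tr]
        mats.append(sub["vm_mv"].to_numpy())
        lengths.add(len(sub))
    if len(lengths) != 1:
        raise ParseError(f"{path.name}: trials have unequal lengths {sorted(lengths)}")
    sub0 = df[df["trial"] == trials[0]]
    t = sub0["time_s"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path.name}: need at least two samples per trial")
    rate = 1.0 / np.median(np.diff(t))
    trig = sub0["trigger"].to_numpy()
    on = np.flatnonzero(trig > 0)
    if on.size == 0:
        raise ParseError(f"{path.name}: trigger column contains no stimulus")
    stim_onset = float(t[on[0]])
    stim_duration = float((on[-1] - on[0] + 1) / rate)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EphysTrialSet(cell_id=meta.get("cell_id", path.stem),
                         vm=np.stack(mats),
                         sampling_rate=float(meta.get("sampling_rate", rate)),
                         stim_onset=stim_onset, stim_duration=stim_duration,
                         driver_line=meta.get("driver_line", ""))


# ---------------------------------------------------------------------------
# ROI traces and trigger tables
# ---------------------------------------------------------------------------

def write_roi_traces(traces: RoiTraceSet, path) -> Path:
    """Wide-form CSV: time_s column plus one column per ROI."""
    path = Path(path)
    df = pd.DataFrame({"time_s": traces.time()})
    for i, roi in enumerate(traces.roi_ids):
        df[roi] = traces.values[i]
    df.to_csv(path, index=False)
    meta = {"frame_rate": traces.frame_rate, "stim_schedule": traces.stim_schedule,
            "trial_boundaries": traces.trial_boundaries, "animal_id": traces.animal_id,
            "kind": traces.kind}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_roi_traces(path) -> RoiTraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path.name}: missing time_s column")
    roi_cols = [c for c in df.columns if c != "time_s"]
    if not roi_cols:
        raise ParseError(f"{path.name}: no ROI columns")
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    schedule = [tuple(x) for x in meta.get("stim_schedule", [])]
    return RoiTraceSet(roi_ids=roi_cols,
                       values=df[roi_cols].to_numpy().T,
                       frame_rate=float(meta.get("frame_rate", rate)),
                       stim_schedule=schedule,
                       trial_boundaries=meta.get("trial_boundaries"),
                       animal_id=meta.get("animal_id", ""),
                       kind=meta.get("kind", "dff"))


def read_trigger_table(path) -> list:
    """Stimulus schedule CSV (onset_s, duration_s) → list of tuples."""
    df = pd.read_csv(path)
    for c in ("onset_s", "duration_s"):
        if c not in df.columns:
            raise ParseError(f"{Path(path).name}: missing column {c}")
    return [(float(r.onset_s), float(r.duration_s)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# TIFF stacks and masks
# ---------------------------------------------------------------------------

def write_stack(frames: np.ndarray, path) -> Path:
    import tifffile
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames), photometric="minisblack")
    return path


def read_stack(path, frame_rate: float = 10.0, stim_schedule=None) -> MovieStack:
    """Read a multi-frame TIFF into a :class:`MovieStack`."""
    import tifffile
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise ParseError(f"{path.name}: not a readable TIFF ({exc})") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(frames=frames.astype(float), frame_rate=frame_rate,
                      stim_schedule=stim_schedule or [])


def read_label_mask(path) -> np.ndarray:
    import tifffile
    mask = np.asarray(tifffile.imread(Path(path)))
    if mask.ndim != 2:
        raise ParseError("label mask must be a single 2-D image")
    return mask.astype(int)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Cells × genes integer counts from CSV (indexed) or MTX + name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense())
        genes = Path(genes_path).read_text().split() if genes_path else \
            [f"g{i}" for i in range(mat.shape[1])]
        cells = Path(cells_path).read_text().split() if cells_path else \
            [f"c{i}" for i in range(mat.shape[0])]
        return pd.DataFrame(mat.astype(int), index=cells, columns=genes)
    return pd.read_csv(path, index_col=0)


def write_count_matrix(matrix: pd.DataFrame, path) -> Path:
    path = Path(path)
    matrix.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(gt.to_jsonable(), indent=1))
    return path


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    gt = GroundTruth(labels=d.get("labels", {}), latencies=d.get("latencies", {}),
                     amplitudes=d.get("amplitudes", {}),
                     spike_times={k: [np.asarray(t) for t in v] if v and isinstance(v[0], list)
                                  else np.asarray(v)
                                  for k, v in d.get("spike_times", {}).items()},
                     expr_prob=d.get("expr_prob", {}),
                     transmitters=d.get("transmitters", {}),
                     extras=d.get("extras", {}))
    if d.get("shifts") is not None:
        gt.shifts = np.asarray(d["shifts"], dtype=int)
    return gt
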