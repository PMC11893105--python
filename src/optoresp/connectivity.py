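"""Connectome input profiles for insulin-producing cells.

Operates on whole-brain connectome edge exports (pre_id, post_id,
syn_count, transmitter, score): confidence-thresholded transmitter
assignment, minimum-synapse filtering, and per-target aggregation of
synaptic input pooled by predicted transmitter.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .types import InputError

COLUMNS = ["pre_id", "post_id", "syn_count", "transmitter", "score"]


def _check(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"synapse table missing columns: {missing}")
    if len(table) and ((table["score"] < 0) | (table["score"] > 1)).any():
        raise InputError("transmitter prediction scores must lie in [0, 1]")
    return table


def collapse_duplicate_edges(table: pd.DataFrame) -> pd.DataFrame:
    """Sum syn_count over duplicate (pre, post) rows (e.g. per-neuropil splits).

    Transmitter and score are taken from the highest-count contributing row.
    """
    _check(table)
    if table.duplicated(["pre_id", "post_id"]).sum() == 0:
        return table.copy()
    idx = table.groupby(["pre_id", "post_id"])["syn_count"].idxmax()
    rep = table.loc[idx].set_index(["pre_id", "post_id"])
    sums = table.groupby(["pre_id", "post_id"])["syn_count"].sum()
    rep["syn_count"] = sums
    return rep.reset_index()[COLUMNS]


def assign_transmitters(table: pd.DataFrame, score_threshold: float = 0.62) -> pd.DataFrame:
    """Relabel low-confidence transmitter predictions as "unknown".

    Rows with score strictly below ``score_threshold`` lose their
    predicted transmitter; a score exactly at the threshold keeps it.
    """
    _check(table)
    out = table.copy()
    out.loc[out["score"] < score_threshold, "transmitter"] = "unknown"
    return out


def filter_by_synapse_count(table: pd.DataFrame, min_syn: int = 5) -> pd.DataFrame:
    """Keep only edges with at least ``min_syn`` synapses."""
    _check(table)
    return table[table["syn_count"] >= min_syn].reset_index(drop=True)


def aggregate_inputs(table: pd.DataFrame, targets: Sequence[str]) -> pd.DataFrame:
    """Per-target, per-transmitter input profile.

    For every requested postsynaptic target the summed synapse count and
    the number of distinct presynaptic partners are accumulated per
    transmitter. Targets absent from the table get an all-zero profile.
    Returns a tidy frame (post_id, transmitter, syn_total, n_partners).
    """
    _check(table)
    rows = []
    grouped = table.groupby(["post_id", "transmitter"]).agg(
        syn_total=("syn_count", "sum"), n_partners=("pre_id", "nunique"))
    for target in targets:
        if target in grouped.index.get_level_values(0):
            sub = grouped.loc[target]
            for tx, rec in sub.iterrows():
                rows.append({"post_id": target, "transmitter": tx,
                             "syn_total": int(rec["syn_total"]),
                             "n_partners": int(rec["n_partners"])})
        else:
            rows.append({"post_id": target, "transmitter": "none",
                         "syn_total": 0, "n_partners": 0})
    return pd.DataFrame(rows, columns=["post_id", "transmitter", "syn_total", "n_partners"])


def input_profile_pipeline(table: pd.DataFrame, targets: Sequence[str],
                           min_syn: int = 5, score_threshold: float = 0.62) -> pd.DataFrame:
    """Full chain: collapse duplicates → assign transmitters → filter → aggregate."""
    t = collapse_duplicate_edges(table)
    t = assign_transmitters(t, score_threshold)
    t = filter_by_synapse_count(t, min_syn)
    return aggregate_inputs(t, targets)


def export_connectivity_map(profiles: pd.DataFrame, path, fmt: str = "csv") -> Path:
    """Write the aggregated input profile as a weighted bipartite edge list.

    ``csv`` writes (source=transmitter group, target=post_id,
    weight=syn_total, n_partners); ``graphml`` writes the same bipartite
    graph via networkx-compatible XML.
    """
    if profiles.empty:
        raise InputError("cannot export an empty profile set")
    path = Path(path)
    edges = profiles[profiles["syn_total"] > 0]
    if fmt == "csv":
        out = edges.rename(columns={"transmitter": "source", "post_id": "target",
                                    "syn_total": "weight"})
        out[["source", "target", "weight", "n_partners"]].to_csv(path, index=False)
    elif fmt == "graphml":
        import networkx as nx
        g = nx.DiGraph()
        for _, r in edges.iterrows():
            g.add_edge(r["transmitter"], r["post_id"], weight=int(r["syn_total"]),
                       n_partners=int(r["n_partners"]))
        nx.write_graphml(g, path)
    else:
        raise InputError(f"unknown export format {fmt!r}")
    return path
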