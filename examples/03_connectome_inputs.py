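"""Connectome input profiles: synapse table → per-target transmitter mix.

Simulates a connectome export (one edge per pre/post pair with a synapse
count, a predicted transmitter and a confidence score) and applies the
standard filtering: scores below 0.62 are relabeled "unknown", edges
with fewer than 5 synapses are dropped, duplicate edges are collapsed,
and the remainder is aggregated into a per-target, per-transmitter
input profile.

Run:  python examples/03_connectome_inputs.py
"""
from optoresp import connectivity
from optoresp.synthetic import gen_synapse_table

table, truth = gen_synapse_table(n_pre=40, n_post=4, seed=11)
print(f"raw edges: {len(table)}")

labeled = connectivity.assign_transmitters(table, score_threshold=0.62)
print(f"low-confidence transmitters set to unknown: "
      f"{(labeled['transmitter'] == 'unknown').sum()}")

kept = connectivity.filter_by_synapse_count(labeled, min_syn=5)
print(f"edges with ≥ 5 synapses: {len(kept)}")

targets = sorted(table["post_id"].unique())
profile = connectivity.aggregate_inputs(kept, targets)
print("\nper-target input profile:")
print(profile.to_string(index=False))

# the same chain in one call, then exported for downstream tools
profile2 = connectivity.input_profile_pipeline(table, targets)
out = connectivity.export_connectivity_map(profile2, "results/inputs.csv")
print(f"\nwritten to {out}")
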