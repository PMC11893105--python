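"""Receptor-expression cutoffs on a simulated single-nucleus count matrix.

Insulin-producing cells are selected as transcriptomes co-expressing
Ilp2, Ilp3 and Ilp5; per-gene percent-expressing values are then called
against 5 % and 10 % cutoffs. The 5 % cutoff guards against false
positives: over 16 IPCs it corresponds to 0.8 expected cells — less
than one cell per animal — and over 392 transcriptomes any gene seen in
fewer than 20 cells is treated as noise.

Run:  python examples/04_expression_cutoffs.py
"""
from optoresp import expression
from optoresp.synthetic import gen_expression_matrix

genes = ["Ilp2", "Ilp3", "Ilp5", "Dop1R1", "Dop2R", "OambX"]
probs = {"Ilp2": 0.95, "Ilp3": 0.95, "Ilp5": 0.95,
         "Dop1R1": 0.55, "Dop2R": 0.12, "OambX": 0.02}
matrix, truth = gen_expression_matrix(n_cells=392, genes=genes,
                                      expr_prob=probs, seed=2)

ipcs = expression.select_ipc_transcriptomes(matrix)
print(f"IPC transcriptomes (Ilp2 ∧ Ilp3 ∧ Ilp5 > 0): {len(ipcs)} of {len(matrix)}")

table = expression.expression_table(matrix, ["Dop1R1", "Dop2R", "OambX"])
print("\n" + table.to_string(index=False))

for n in (16, 392):
    expected, min_int = expression.expected_positive_cells(0.05, n)
    print(f"\n5 % of {n} cells → {expected:.1f} expected positives "
          f"(minimum integer count {min_int})")
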