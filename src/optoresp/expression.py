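"""Receptor-expression cutoff logic for single-nucleus count matrices.

Cells are accepted as insulin-producing-cell (IPC) transcriptomes when
all three insulin-like-peptide markers (Ilp2, Ilp3, Ilp5) have strictly
positive counts. A receptor gene is called expressed when the percentage
of selected cells with a nonzero count reaches a cutoff (5 % for the
conservative screen, 10 % for the stricter one). Expression is defined on
the raw zero/nonzero pattern; no normalization is applied.
"""
from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .types import InputError

DEFAULT_MARKERS = ("Ilp2", "Ilp3", "Ilp5")


def _check_genes(matrix: pd.DataFrame, genes) -> None:
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise InputError(f"gene(s) not present in matrix: {missing}")


def select_ipc_transcriptomes(matrix: pd.DataFrame,
                              markers: Sequence[str] = DEFAULT_MARKERS) -> list:
    """Cell ids with strictly positive counts for every marker gene."""
    _check_genes(matrix, markers)
    mask = (matrix[list(markers)] > 0).all(axis=1)
    return list(matrix.index[mask])


def fraction_expressing(matrix: pd.DataFrame, gene: str, cells: Sequence[str]) -> float:
    """Percentage of ``cells`` with a nonzero count for ``gene``."""
    _check_genes(matrix, [gene])
    cells = list(cells)
    if not cells:
        raise InputError("empty cell set")
    col = matrix.loc[cells, gene]
    return 100.0 * float((col > 0).sum()) / len(cells)


def apply_cutoff(fraction: float, cutoff: float = 5.0, inclusive: bool = True) -> bool:
    """Expressed-gene call from a percent-expressing value.

    A fraction exactly at the cutoff counts as expressed by default
    (``inclusive=False`` switches to a strict inequality).
    """
    if not 0 <= fraction <= 100:
        raise InputError("fraction must be a percentage in [0, 100]")
    return fraction >= cutoff if inclusive else fraction > cutoff


def expected_positive_cells(cutoff: float, n_cells: int):
    """Expected positives under a cutoff: ``cutoff × n`` and its ceiling.

    A 5 % cutoff over 16 IPCs corresponds to 0.8 cells on average —
    less than one cell per animal — and over 392 transcriptomes any gene
    detected in fewer than ceil(0.05 × 392) = 20 cells is treated as a
    false positive. Returns ``(expected, min_integer)``.
    """
    if not 0 <= cutoff <= 1:
        raise InputError("cutoff must be a fraction in [0, 1]")
    if n_cells < 0:
        raise InputError("n_cells must be nonnegative")
    expected = cutoff * n_cells
    return expected, int(math.ceil(expected))


def expression_table(matrix: pd.DataFrame, genes: Sequence[str],
                     markers: Sequence[str] = DEFAULT_MARKERS,
                     cutoffs: Sequence[float] = (5.0, 10.0)) -> pd.DataFrame:
    """Per-gene percent-expressing table over the selected IPC transcriptomes.

    Columns: gene, percent, and one boolean ``expressed_at_<c>`` per cutoff.
    """
    cells = select_ipc_transcriptomes(matrix, markers)
    if not cells:
        raise InputError("marker selection retained no cells")
    rows = []
    for g in genes:
        pct = fraction_expressing(matrix, g, cells)
        row = {"gene": g, "percent": pct}
        for c in cutoffs:
            row[f"expressed_at_{c:g}"] = apply_cutoff(pct, c)
        rows.append(row)
    return pd.DataFrame(rows)
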