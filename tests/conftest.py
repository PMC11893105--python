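"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive each quantity with the
most naive correct algorithm (per-sample window scans, sort-and-pick
percentiles, exhaustive enumeration) so the vectorized implementations
are checked against something that cannot share their bugs.
"""
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sliding_median_oracle(x, w):
    """O(n·w) shrinking-window sliding median."""
    n = len(x)
    out = np.empty(n)
    half_lo = w // 2
    half_hi = w - half_lo  # centered window [i-half_lo, i+half_hi); even w leans left
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi)
        out[i] = np.median(x[lo:hi])
    return out


def percentile_oracle(samples, q):
    """Sort-based percentile with linear interpolation between order stats."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    pos = (q / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def run_length_oracle(mask, min_len):
    """Exhaustive scan for the first run of True of length ≥ min_len."""
    count, start = 0, None
    for i, v in enumerate(mask):
        if v:
            if count == 0:
                start = i
            count += 1
            if count >= min_len:
                return start
        else:
            count = 0
    return None


def classify_oracle(trace, lower, upper, min_len):
    """Run-length three-way classification with earliest-run precedence."""
    up = run_length_oracle(trace > upper, min_len)
    down = run_length_oracle(trace < lower, min_len)
    if up is None and down is None:
        return "unaffected"
    if down is None:
        return "excited"
    if up is None:
        return "inhibited"
    return "excited" if up <= down else "inhibited"


def trapezoid_oracle(y, dx):
    """Explicit trapezoid sum."""
    y = np.asarray(y, dtype=float)
    return float(sum((y[i] + y[i + 1]) * dx / 2 for i in range(len(y) - 1)))


def wilcoxon_exact_oracle(pre, post):
    """Two-sided signed-rank p-value by enumerating all 2^n sign patterns.

    Zero differences are dropped first (Wilcoxon's treatment); ranks of
    |d| use midranks for ties.
    """
    from itertools import product
    from scipy.stats import rankdata

    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def masked_mean_oracle(stack, mask, label):
    """Per-frame mean over pixels of one ROI label, via explicit loops."""
    coords = [(y, x) for y in range(mask.shape[0]) for x in range(mask.shape[1])
              if mask[y, x] == label]
    return np.array([np.mean([stack[t, y, x] for (y, x) in coords])
                     for t in range(stack.shape[0])])
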