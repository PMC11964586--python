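"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive results from first principles (per-base
walks, order-statistic formulas) rather than calling the package's own
segment/percentile code paths.
"""

from __future__ import annotations

import math

import numpy as np


def merge_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class BruteForceMap:
    """Per-base genomic→display map.

    Walks the locus base by base: each covered base advances the display
    axis by 1; each base of an uncovered gap of length L advances it by
    min(L, cap)/L, so the gap's total display length is min(L, cap).
    """

    def __init__(self, exon_intervals, cap: float):
        union = merge_intervals(exon_intervals)
        self.lo = union[0][0]
        self.hi = union[-1][1]
        n = self.hi - self.lo + 1
        covered = np.zeros(n, dtype=bool)
        for s, e in union:
            covered[s - self.lo : e - self.lo + 1] = True
        # cumulative display length through each base
        cum = np.empty(n, dtype=float)
        disp = 0.0
        i = 0
        while i < n:
            j = i
            while j < n and covered[j] == covered[i]:
                j += 1
            run = j - i
            if covered[i]:
                cum[i:j] = disp + np.arange(1, run + 1)
                disp += run
            else:
                total = min(float(run), float(cap))
                cum[i:j] = disp + np.arange(1, run + 1) * total / run
                disp += total
            i = j
        self.cum = cum

    def display_end_of(self, pos: int) -> float:
        return float(self.cum[pos - self.lo])

    def display_start_of(self, pos: int) -> float:
        if pos == self.lo:
            return 1.0
        return float(self.cum[pos - self.lo - 1]) + 1.0


def quantile_type7(values, q: float) -> float:
    """Linear-interpolation quantile from the order statistics."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q
    f = math.floor(h)
    c = min(f + 1, n - 1)
    return v[f] + (h - f) * (v[c] - v[f])


def tukey_box(values):
    """Brute-force five-number summary + fences + whiskers + outliers."""
    q1 = quantile_type7(values, 0.25)
    med = quantile_type7(values, 0.50)
    q3 = quantile_type7(values, 0.75)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [v for v in values if lo_fence <= v <= hi_fence]
    outliers = sorted(v for v in values if v < lo_fence or v > hi_fence)
    return {
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": min(inside) if inside else q1,
        "whisker_high": max(inside) if inside else q3,
        "outliers": outliers,
    }


def random_locus(rng: np.random.Generator, max_span: int = 50_000):
    """Random non-overlapping exon set for gap-map stress tests."""
    n_exons = int(rng.integers(1, 12))
    starts = []
    pos = int(rng.integers(1, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(1, 400))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(1, 5000))
        if pos > max_span:
            break
    return exons
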