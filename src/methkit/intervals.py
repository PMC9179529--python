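"""Closed-interval arithmetic on 1-based inclusive coordinates.

Every coordinate in the package is 1-based and inclusive on both ends
(matching printed genome-browser coordinates); conversion to 0-based
half-open BED happens only at the I/O boundary.
"""

from __future__ import annotations

import numpy as np


def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended closed intervals into a sorted disjoint set."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        if s > e:
            raise ValueError(f"invalid interval: start {s} > end {e}")
        ps, pe = out[-1]
        if s <= pe + 1:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def subtract(universe: list[tuple[int, int]], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Closed-interval set difference universe \\ holes; both merged internally."""
    uni = merge(universe)
    rem = merge(holes)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in uni:
        cur = s
        while j < len(rem) and rem[j][1] < cur:
            j += 1
        k = j
        while k < len(rem) and rem[k][0] <= e:
            hs, he = rem[k]
            if hs > cur:
                out.append((cur, hs - 1))
            cur = max(cur, he + 1)
            k += 1
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


def member_mask(pos: np.ndarray, merged: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of positions falling inside any interval of a merged set."""
    if not merged:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] = pos[ok] <= ends[idx[ok]]
    return ok


def total_length(merged: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merged)
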