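"""Genomic interval tracks and the small set of interval operations the
pipeline needs (merge, coverage thresholding, overlap, per-bin coverage).

Coordinates are 0-based half-open throughout, matching BED on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntervalTrack",
    "merge_intervals",
    "coverage_regions",
    "overlaps_any",
    "bases_per_bin",
]


def _as_array(ivs) -> np.ndarray:
    a = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
    if a.size and np.any(a[:, 1] <= a[:, 0]):
        raise ValueError("intervals must be non-empty half-open [start, end)")
    return a


@dataclass
class IntervalTrack:
    """Per-chromosome interval set with a role tag (gene, HMR, PMD,
    5hmC_peak, H3K27ac_peak, mutation, enhancer, gap)."""

    intervals: dict[str, np.ndarray]
    role: str = ""
    sample_id: str | None = None
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {c: _as_array(v) for c, v in self.intervals.items()}

    def merged(self) -> "IntervalTrack":
        return IntervalTrack({c: merge_intervals(v) for c, v in self.intervals.items()},
                             self.role, self.sample_id)

    def total_bases(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self.intervals.values()))

    def n_intervals(self) -> int:
        return int(sum(v.shape[0] for v in self.intervals.values()))


def merge_intervals(ivs: np.ndarray) -> np.ndarray:
    """Union of intervals as maximal disjoint sorted intervals."""
    a = _as_array(ivs)
    if a.shape[0] == 0:
        return a
    a = a[np.argsort(a[:, 0], kind="stable")]
    out = [list(a[0])]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def coverage_regions(tracks: list[np.ndarray], min_count: int) -> np.ndarray:
    """Maximal regions covered by at least ``min_count`` of the given
    per-sample interval sets (each set counted at most once per base)."""
    events: list[tuple[int, int]] = []
    for ivs in tracks:
        for s, e in merge_intervals(ivs):
            events.append((int(s), 1))
            events.append((int(e), -1))
    if not events:
        return np.zeros((0, 2), dtype=np.int64)
    events.sort()
    out: list[list[int]] = []
    depth = 0
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_count and open_start is None:
            open_start = pos
        elif depth < min_count and open_start is not None:
            if pos > open_start:
                out.append([open_start, pos])
            open_start = None
    return np.array(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)


def overlaps_any(queries: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Boolean per query: does it overlap any target interval?"""
    q = _as_array(queries)
    t = merge_intervals(targets)
    if q.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    if t.shape[0] == 0:
        return np.zeros(q.shape[0], dtype=bool)
    # a query [s,e) overlaps some merged target iff the first target with
    # end > s starts before e
    idx = np.searchsorted(t[:, 1], q[:, 0], side="right")
    ok = idx < t.shape[0]
    res = np.zeros(q.shape[0], dtype=bool)
    res[ok] = t[idx[ok], 0] < q[ok, 1]
    return res


def bases_per_bin(ivs: np.ndarray, n_bins: int, bin_width: int) -> np.ndarray:
    """Bp of interval coverage falling in each fixed-width bin (intervals are
    merged first so overlapping inputs are not double-counted)."""
    cov = np.zeros(n_bins)
    for s, e in merge_intervals(ivs):
        b0 = s // bin_width
        b1 = (e - 1) // bin_width
        if b0 == b1:
            cov[b0] += e - s
            continue
        cov[b0] += (b0 + 1) * bin_width - s
        if b1 > b0 + 1:
            cov[b0 + 1:b1] += bin_width
        cov[b1] += e - b1 * bin_width
    return cov
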