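"""Quantifying introgression-derived ancestry.

Two estimators are provided: the exact one, from the ancestry segments each
haplotype carries (donor/recipient labels assigned at the population
split), and the marker-based one, from neutral marker mutations placed at a
fixed spacing on every donor haplotype immediately before the admixture
pulse.  The segment method is exact by construction; the marker method
differs from it only through tract-boundary effects at the marker spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ancestry segment origin labels
RECIPIENT = 0
DONOR = 1

_MARKER_CLASS = 3  # selection.MARKER; duplicated to avoid an import cycle


def segment_donor_bp(anc_ends: np.ndarray, anc_orig: np.ndarray) -> int:
    """Donor-labeled base pairs on one haplotype's segment encoding."""
    if anc_ends.size == 1:
        return int(anc_ends[0]) if anc_orig[0] == DONOR else 0
    starts = np.concatenate(([0], anc_ends[:-1]))
    mask = anc_orig == DONOR
    return int((anc_ends[mask] - starts[mask]).sum())


def donor_intervals(hap) -> np.ndarray:
    """(k, 2) array of donor-ancestry intervals on one haplotype."""
    ends = hap.anc_ends
    starts = np.concatenate(([0], ends[:-1]))
    mask = hap.anc_orig == DONOR
    return np.column_stack([starts[mask], ends[mask]])


@dataclass
class AncestryReport:
    """Global and per-window introgressed-ancestry fractions."""

    p_I_global: float
    p_I_by_window: np.ndarray
    method: str


@dataclass
class DesertSet:
    """Maximal intervals devoid of donor ancestry across sampled haplotypes."""

    intervals: np.ndarray  # (k, 2)
    lengths: np.ndarray


def _interval_overlap(intervals: np.ndarray, start: int, end: int) -> int:
    if intervals.size == 0:
        return 0
    lo = np.clip(intervals[:, 0], start, end)
    hi = np.clip(intervals[:, 1], start, end)
    return int(np.maximum(hi - lo, 0).sum())


def p_i_from_segments(haps, windows) -> AncestryReport:
    """Exact introgressed-ancestry fractions from segment tracking.

    Per window: donor-labeled bp / (window bp * number of haplotypes).  The
    global value is the base-pair-weighted mean over windows, identically
    equal to total donor bp / (L * number of haplotypes).
    """
    haps = list(haps)
    if not haps:
        raise ValueError("no haplotypes supplied")
    n = len(haps)
    length = int(haps[0].anc_ends[-1])
    per_hap = [donor_intervals(h) for h in haps]
    window_vals = np.array([
        sum(_interval_overlap(iv, w.start, w.end) for iv in per_hap)
        / (w.length * n)
        for w in windows
    ])
    total = sum(iv[:, 1].sum() - iv[:, 0].sum() for iv in per_hap if iv.size)
    return AncestryReport(p_I_global=float(total) / (length * n),
                          p_I_by_window=window_vals, method="segment")


def p_i_from_markers(haps, table, windows) -> AncestryReport:
    """Marker-based introgressed-ancestry estimate.

    Per window: mean marker-mutation frequency over the markers inside the
    window (NaN when a window contains no marker); global value: mean
    frequency over all markers.
    """
    haps = list(haps)
    n = len(haps)
    marker_ids = np.flatnonzero(table.func_class[: table.n] == _MARKER_CLASS)
    if marker_ids.size == 0:
        raise ValueError("no marker mutations have been placed")
    counts = np.zeros(table.n, dtype=np.int64)
    for h in haps:
        if h.ids.size:
            counts += np.bincount(h.ids, minlength=table.n)
    freq = counts[marker_ids] / n
    pos = table.position[marker_ids]
    window_vals = np.full(len(windows), np.nan)
    for k, w in enumerate(windows):
        inside = (pos >= w.start) & (pos < w.end)
        if inside.any():
            window_vals[k] = freq[inside].mean()
    return AncestryReport(p_I_global=float(freq.mean()),
                          p_I_by_window=window_vals, method="marker")


def desert_lengths(haps, length: int | None = None) -> DesertSet:
    """Maximal intervals with zero donor ancestry on every sampled haplotype."""
    haps = list(haps)
    if not haps:
        raise ValueError("no haplotypes supplied")
    if length is None:
        length = int(haps[0].anc_ends[-1])
    ivs = [donor_intervals(h) for h in haps]
    ivs = [iv for iv in ivs if iv.size]
    if not ivs:
        intervals = np.array([[0, length]], dtype=np.int64)
        return DesertSet(intervals, intervals[:, 1] - intervals[:, 0])
    allints = np.concatenate(ivs)
    order = np.argsort(allints[:, 0], kind="stable")
    merged: list[list[int]] = []
    for s, e in allints[order]:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    deserts = []
    pos = 0
    for s, e in merged:
        if s > pos:
            deserts.append([pos, s])
        pos = max(pos, e)
    if pos < length:
        deserts.append([pos, length])
    intervals = (np.asarray(deserts, dtype=np.int64)
                 if deserts else np.empty((0, 2), dtype=np.int64))
    return DesertSet(intervals, intervals[:, 1] - intervals[:, 0]
                     if intervals.size else np.empty(0, dtype=np.int64))
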