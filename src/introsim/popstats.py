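"""Summary statistics: load, Hudson/Bhatia F_ST, SFS, variant sharing,
and window-level rank correlations with randomized tie-breaking.

All statistics consume either simulated populations (lists of haplotype id
arrays against a mutation table) or plain frequency arrays.  Marker
mutations are always excluded, and globally fixed variants are assumed to
have been pruned by the engine (they carry no between-population signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .selection import MARKER


@dataclass
class LoadSummary:
    """Per-population fitness and deleterious-variant counts.

    ``mean_w`` is the arithmetic mean fitness over segregating selected
    sites only; ``w_ratio`` is recipient over donor.
    """

    mean_w: dict
    w_ratio: float
    del_per_hap: dict
    hom_del_per_ind: dict


@dataclass
class FstResult:
    per_site_num: np.ndarray
    per_site_den: np.ndarray
    combined: float


@dataclass
class SfsTable:
    """Derived-allele-count spectrum; the last bin pools counts >= the
    fold threshold."""

    bins: np.ndarray
    fold_threshold: int
    sample_size: int


def hap_counts(hap_ids: Sequence[np.ndarray], table) -> np.ndarray:
    """Occurrences of each mutation id across a list of haplotypes."""
    counts = np.zeros(table.n, dtype=np.int64)
    for ids in hap_ids:
        if len(ids):
            counts += np.bincount(ids, minlength=table.n)
    return counts


def _ids_of(pop_or_ids):
    """Accept a population (list of Individuals) or a list of id arrays."""
    out = []
    for item in pop_or_ids:
        if isinstance(item, np.ndarray):
            out.append(item)
        else:
            for h in item.haplotypes():
                out.append(h.ids)
    return out


def load_summary(recipient, donor, table) -> LoadSummary:
    """Population mean fitness ratio and deleterious-site counts.

    ``recipient``/``donor`` are lists of Individuals.  Fitness means use the
    cached (segregating-sites-only) individual fitnesses; counts use the
    selected-mutation flags of the table.
    """
    if not recipient or not donor:
        raise ValueError("empty population")
    out_w, out_del, out_hom = {}, {}, {}
    for name, pop in (("recipient", recipient), ("donor", donor)):
        out_w[name] = float(np.mean([ind.w for ind in pop]))
        sel_counts = []
        hom = []
        for ind in pop:
            haps = ind.haplotypes()
            per = [table.selected[h.ids].sum() for h in haps]
            sel_counts.extend(per)
            if len(haps) == 2:
                s1 = set(ind.h1.ids[table.selected[ind.h1.ids]].tolist())
                s2 = set(ind.h2.ids[table.selected[ind.h2.ids]].tolist())
                hom.append(len(s1 & s2))
        out_del[name] = float(np.mean(sel_counts))
        out_hom[name] = float(np.mean(hom)) if hom else 0.0
    return LoadSummary(mean_w=out_w,
                       w_ratio=out_w["recipient"] / out_w["donor"],
                       del_per_hap=out_del, hom_del_per_ind=out_hom)


def hudson_fst_site(p1, p2, n1: int, n2: int):
    """Per-site Hudson estimator components.

    numerator = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("sample sizes must be >= 2")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def combine_fst(num, den) -> float:
    """Ratio-of-averages combination across sites (never average of ratios).

    Sites monomorphic in both samples contribute (0, 0) and must be
    excluded by the caller; an all-zero denominator is undefined.
    """
    den_sum = float(np.sum(den))
    if den_sum == 0:
        raise ValueError("F_ST undefined: all sites monomorphic")
    return float(np.sum(num)) / den_sum


def fst_between(hap_ids1, hap_ids2, table, classes=None) -> FstResult:
    """Combined Hudson/Bhatia F_ST between two haplotype samples.

    Marker mutations and sites monomorphic in both samples are excluded;
    ``classes`` optionally restricts to a set of functional classes.
    """
    ids1 = _ids_of(hap_ids1)
    ids2 = _ids_of(hap_ids2)
    n1, n2 = len(ids1), len(ids2)
    c1 = hap_counts(ids1, table)
    c2 = hap_counts(ids2, table)
    keep = table.func_class[: table.n] != MARKER
    if classes is not None:
        keep &= np.isin(table.func_class[: table.n], list(classes))
    # polymorphic somewhere: present at least once, absent at least once
    seg = ((c1 + c2) > 0) & ((c1 < n1) | (c2 < n2))
    keep &= seg
    p1 = c1[keep] / n1
    p2 = c2[keep] / n2
    num, den = hudson_fst_site(p1, p2, n1, n2)
    return FstResult(per_site_num=num, per_site_den=den,
                     combined=combine_fst(num, den))


def fst_for_split_sweep(snapshot, table) -> float:
    """Combined F_ST over all segregating non-marker variants at the
    pre-pulse snapshot (the amount of differentiation at admixture)."""
    return fst_between(snapshot.hap_ids["recipient"],
                       snapshot.hap_ids["donor"], table).combined


def sfs(hap_ids, table, classes=None, fold_threshold: int = 25) -> SfsTable:
    """Derived-allele-count spectrum of a haplotype sample.

    Bins 1 .. fold_threshold-1 count sites at that derived-allele count;
    the final bin pools everything at count >= fold_threshold.  Marker
    mutations are excluded.
    """
    ids = _ids_of(hap_ids)
    k = len(ids)
    if k < 2:
        raise ValueError("need at least two chromosomes")
    counts = hap_counts(ids, table)
    keep = table.func_class[: table.n] != MARKER
    if classes is not None:
        keep &= np.isin(table.func_class[: table.n], list(classes))
    keep &= (counts > 0) & (counts < k)
    c = counts[keep]
    nbins = min(fold_threshold, k - 1)
    bins = np.zeros(nbins, dtype=np.int64)
    for ct in c:
        bins[min(ct, nbins) - 1] += 1
    return SfsTable(bins=bins, fold_threshold=fold_threshold, sample_size=k)


def private_shared(hap_ids1, hap_ids2, table) -> tuple[int, int, int]:
    """Counts of segregating variants private to each sample or shared.

    Returns (private to first, private to second, shared); the three are
    disjoint and sum to the total segregating variant count.
    """
    ids1 = _ids_of(hap_ids1)
    ids2 = _ids_of(hap_ids2)
    c1 = hap_counts(ids1, table)
    c2 = hap_counts(ids2, table)
    keep = table.func_class[: table.n] != MARKER
    seg = ((c1 + c2) > 0) & ((c1 < len(ids1)) | (c2 < len(ids2))) & keep
    both = seg & (c1 > 0) & (c2 > 0)
    only1 = seg & (c1 > 0) & (c2 == 0)
    only2 = seg & (c2 > 0) & (c1 == 0)
    return int(only1.sum()), int(only2.sum()), int(both.sum())


def spearman_random_ties(x, y, rng: np.random.Generator):
    """Spearman rank correlation with ties broken by a random permutation.

    Ranks are assigned by sorting with a seeded random tie-break (instead of
    midranks); the statistic is the Pearson correlation of the ranks, with a
    two-sided large-sample t-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = _random_tie_ranks(x, rng)
    ry = _random_tie_ranks(y, rng)
    res = sps.pearsonr(rx, ry)
    return float(res.statistic), float(res.pvalue)


def _random_tie_ranks(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    order = np.lexsort((rng.random(len(v)), v))
    ranks = np.empty(len(v), dtype=float)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks
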