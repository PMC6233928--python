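"""Discrete-generation Wright-Fisher forward simulator with exact ancestry
tracking.

The life cycle is: an ancestral population at mutation-drift-selection
balance (forward burn-in from a mutation-free state), a split into donor
and recipient subpopulations, ``t_s`` generations of independent evolution,
a single one-generation admixture pulse in which each parent of a recipient
offspring is drawn from the donor pool with probability ``f``, and a
post-admixture phase.  Parents are sampled with probability proportional to
fitness within their pool (soft selection at fixed census size).

Haplotypes are immutable, shared-by-reference objects; a gamete with no
crossover and no new mutation is a reference to one parental haplotype, so
most of the per-generation cost is fitness bookkeeping.  Every haplotype
carries exact ancestry segments (donor / recipient labels assigned at the
split), which is what the introgressed-ancestry statistics are computed
from.  Mutations fixed in every extant population are pruned periodically;
pruning rescales every cached fitness by the same constant, leaving
relative fitness untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ancestry
from .ancestry import DONOR, RECIPIENT
from .genome import GenomeStructure
from .selection import (
    ADDITIVE,
    ADDITIVE_TEXTBOOK,
    HS_FUNCTION,
    MARKER,
    NEUTRAL,
    NONSYNONYMOUS,
    RECESSIVE,
    SYNONYMOUS,
    DFEParams,
    DominanceModel,
    assign_dominance,
)

_EMPTY_I8 = np.empty(0, dtype=np.int64)
_EMPTY_SET: frozenset = frozenset()

# mutation origin-population codes
POP_ANCESTRAL = 0
POP_RECIPIENT = 1
POP_DONOR = 2


class MutationTable:
    """Append-only registry of every mutation created during a run.

    Row index is the mutation id.  ``het_factor`` / ``hom_factor`` are the
    precomputed single-locus fitness factors (1 for neutral classes), and
    ``hom_ratio`` = hom / het^2 is the correction a homozygous site applies
    on top of the two per-copy heterozygote factors.
    """

    def __init__(self, capacity: int = 1024):
        self.n = 0
        #: count of draws whose |s| exceeded 1 (fitness factor clipped at 0)
        self.n_clipped = 0
        self._cap = capacity
        self.position = np.zeros(capacity, dtype=np.int64)
        self.s = np.zeros(capacity)
        self.h = np.full(capacity, 0.5)
        self.func_class = np.zeros(capacity, dtype=np.int8)
        self.origin_pop = np.zeros(capacity, dtype=np.int8)
        self.origin_gen = np.zeros(capacity, dtype=np.int32)
        self.het_factor = np.ones(capacity)
        self.hom_factor = np.ones(capacity)
        self.hom_ratio = np.ones(capacity)
        self.selected = np.zeros(capacity, dtype=bool)

    #: count of draws whose |s| exceeded 1 (fitness factor clipped at 0)
    n_clipped = 0

    def _grow(self, need: int) -> None:
        if self.n + need <= self._cap:
            return
        new_cap = max(self._cap * 2, self.n + need)
        for name in ("position", "s", "h", "func_class", "origin_pop",
                     "origin_gen", "het_factor", "hom_factor", "hom_ratio",
                     "selected"):
            old = getattr(self, name)
            arr = np.zeros(new_cap, dtype=old.dtype)
            if name in ("het_factor", "hom_factor", "hom_ratio"):
                arr[:] = 1.0
            elif name == "h":
                arr[:] = 0.5
            arr[: self.n] = old[: self.n]
            setattr(self, name, arr)
        self._cap = new_cap

    def add_many(self, positions, s, h, func_class, origin_pop,
                 origin_gen: int, model: DominanceModel) -> np.ndarray:
        """Vectorized append; returns the new mutation ids."""
        positions = np.asarray(positions, dtype=np.int64)
        k = len(positions)
        self._grow(k)
        i0, i1 = self.n, self.n + k
        self.position[i0:i1] = positions
        self.s[i0:i1] = s
        self.h[i0:i1] = h
        self.func_class[i0:i1] = func_class
        self.origin_pop[i0:i1] = origin_pop
        self.origin_gen[i0:i1] = origin_gen
        a = np.abs(np.asarray(s, dtype=float))
        if a.ndim == 0:
            a = np.full(k, float(a))
        clipped = int((a > 1).sum())
        if clipped:
            self.n_clipped += clipped
        het = np.clip(1.0 - np.asarray(h, dtype=float) * a, 0.0, None)
        if model.mode in (RECESSIVE, ADDITIVE_TEXTBOOK):
            hom = np.clip(1.0 - a, 0.0, None)
        else:
            hom = np.clip(1.0 - 0.5 * a, 0.0, None) ** 2
        sel = a > 0
        het = np.where(sel, het, 1.0)
        hom = np.where(sel, hom, 1.0)
        ratio = np.ones(k)
        np.divide(hom, het * het, out=ratio, where=sel & (het > 0))
        self.het_factor[i0:i1] = het
        self.hom_factor[i0:i1] = hom
        self.hom_ratio[i0:i1] = ratio
        self.selected[i0:i1] = sel
        self.n = i1
        return np.arange(i0, i1, dtype=np.int64)

    def add(self, position: int, s: float, h: float, func_class: int,
            origin_pop: int, origin_gen: int, model: DominanceModel) -> int:
        if abs(s) > 1:
            warnings.warn("|s| exceeds 1; fitness factor clipped at 0",
                          stacklevel=2)
        return int(self.add_many([position], [s], [h], [func_class],
                                 [origin_pop], origin_gen, model)[0])


class Haplotype:
    """One chromosome copy: sorted mutation ids plus ancestry segments.

    ``pos``/``ids`` are parallel arrays sorted by position.  Ancestry
    segments are run-length encoded as ascending segment ``anc_ends``
    (last equals the chromosome length) with origin labels ``anc_orig``.
    ``het_score`` caches the product of per-copy heterozygote factors and
    ``sel`` the frozenset of selected mutation ids (populated only when the
    dominance mode needs homozygote corrections).
    """

    __slots__ = ("pos", "ids", "het_score", "sel", "anc_ends", "anc_orig",
                 "hemi_score")

    def __init__(self, pos, ids, het_score, sel, anc_ends, anc_orig):
        self.pos = pos
        self.ids = ids
        self.het_score = het_score
        self.sel = sel
        self.anc_ends = anc_ends
        self.anc_orig = anc_orig
        self.hemi_score: Optional[float] = None

    @classmethod
    def empty(cls, length: int, label: int = RECIPIENT) -> "Haplotype":
        return cls(_EMPTY_I8, _EMPTY_I8, 1.0, _EMPTY_SET,
                   np.array([length], dtype=np.int64),
                   np.array([label], dtype=np.int8))

    def donor_fraction(self) -> float:
        return ancestry.segment_donor_bp(self.anc_ends, self.anc_orig) / self.anc_ends[-1]


class Individual:
    """A diploid (or, for X-linked males, hemizygous) individual."""

    __slots__ = ("h1", "h2", "w", "sex")

    def __init__(self, h1: Haplotype, h2: Optional[Haplotype], w: float,
                 sex: Optional[str] = None):
        self.h1 = h1
        self.h2 = h2
        self.w = w
        self.sex = sex

    def haplotypes(self):
        return (self.h1,) if self.h2 is None else (self.h1, self.h2)


Schedule = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class DemographicModel:
    """Two-population split / admixture-pulse demography.

    Times are in generations; ``t_s`` is the interval between the split and
    the pulse, and the pulse is a single generation in which a fraction
    ``admixture_fraction`` of each recipient parent draw comes from the
    donor.  Size schedules are piecewise-constant lists of
    (generations-since-split, diploid size).
    """

    N_A: int
    burn_in: int
    t_s: int
    post_admixture: int
    admixture_fraction: float = 0.05
    donor_schedule: Schedule = ()
    recipient_schedule: Schedule = ()

    def __post_init__(self) -> None:
        if self.N_A < 2:
            raise ValueError("ancestral size must be >= 2")
        if not (0 < self.admixture_fraction < 1):
            raise ValueError("admixture fraction must lie in (0, 1)")

    @staticmethod
    def _size_at(schedule: Schedule, g: int, default: int) -> int:
        size = default
        for start, n in schedule:
            if g >= start:
                size = n
        return size

    def donor_size(self, g: int) -> int:
        return self._size_at(self.donor_schedule, g, self.N_A)

    def recipient_size(self, g: int) -> int:
        return self._size_at(self.recipient_schedule, g, self.N_A)

    @classmethod
    def preset(cls, model: int, N_A: int, *, burn_in: int | None = None,
               t_s: int | None = None, post_admixture: int | None = None,
               admixture_fraction: float = 0.05) -> "DemographicModel":
        """The five study demographies.

        Model 0: equal constant sizes.  Model 1: recipient bottleneck to
        N_A/10 for the last 0.1*N_A generations before the pulse, recovery
        at the pulse.  Model 2: donor at N_A/10 from the split onward.
        Model 3: recipient at N_A/10 from the split onward.  Model 4:
        recipient at N_A/10 from the split, restored to N_A at the pulse.
        """
        burn_in = 10 * N_A if burn_in is None else burn_in
        t_s = 2 * N_A if t_s is None else t_s
        post = N_A if post_admixture is None else post_admixture
        small = max(2, N_A // 10)
        donor: Schedule = ()
        recip: Schedule = ()
        if model == 1:
            start = max(0, t_s - max(1, N_A // 10))
            recip = ((start, small), (t_s, N_A))
        elif model == 2:
            donor = ((0, small),)
        elif model == 3:
            recip = ((0, small),)
        elif model == 4:
            recip = ((0, small), (t_s, N_A))
        elif model != 0:
            raise ValueError("model must be one of 0..4")
        return cls(N_A=N_A, burn_in=burn_in, t_s=t_s, post_admixture=post,
                   admixture_fraction=admixture_fraction,
                   donor_schedule=donor, recipient_schedule=recip)


@dataclass(frozen=True)
class MatingConfig:
    """Mating system: per-population selfing probabilities or X inheritance."""

    selfing_donor: float = 0.0
    selfing_recipient: float = 0.0
    selfing_ancestral: float = 0.0
    x_mode: bool = False

    def __post_init__(self) -> None:
        for p in (self.selfing_donor, self.selfing_recipient, self.selfing_ancestral):
            if not (0 <= p <= 1):
                raise ValueError("selfing probabilities must lie in [0, 1]")
        if self.x_mode and (self.selfing_donor or self.selfing_recipient):
            raise ValueError("selfing and X-linked inheritance cannot be combined")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed for one run; ``c`` is the rescaling constant."""

    structure: GenomeStructure
    demography: DemographicModel
    dfe: DFEParams
    dominance: DominanceModel
    mu: float = 1.5e-8
    ns_syn_ratio: float = 2.31
    c: float = 1.0
    seed: int = 0
    neutral: bool = False
    #: when False, only the selected mutational target (exonic
    #: nonsynonymous sites) is simulated; neutral classes have no feedback
    #: on the dynamics and can be omitted when no neutral-site statistic
    #: (F_ST, full SFS) is required
    track_neutral: bool = True
    mating: MatingConfig = MatingConfig()
    markers: bool = False
    marker_spacing: int = 500
    record_every: int = 50
    prune_every: int = 100

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.ns_syn_ratio <= 0:
            raise ValueError("nonsynonymous:synonymous ratio must be positive")
        if self.c < 1:
            raise ValueError("scaling constant must be >= 1")


def rescale(config: SimulationConfig) -> SimulationConfig:
    """Apply the rescaling N/c, t/c, s*c, mu*c, r -> 0.5*(1-(1-2r)^c).

    Sequence length is unchanged.  Returns ``config`` itself when c = 1.
    """
    c = config.c
    if c == 1:
        return config
    d = config.demography

    def t(x: int) -> int:
        return max(0, round(x / c))

    def n(x: int) -> int:
        size = round(x / c)
        if size < 2:
            raise ValueError(f"scaled population size {size} < 2 (N={x}, c={c})")
        return size

    def sched(s: Schedule) -> Schedule:
        return tuple((t(g), n(size)) for g, size in s)

    demog = DemographicModel(
        N_A=n(d.N_A), burn_in=t(d.burn_in), t_s=t(d.t_s),
        post_admixture=t(d.post_admixture),
        admixture_fraction=d.admixture_fraction,
        donor_schedule=sched(d.donor_schedule),
        recipient_schedule=sched(d.recipient_schedule),
    )
    structure = config.structure.with_map(config.structure.recomb_map.rescaled(c))
    return replace(config, demography=demog, structure=structure,
                   dfe=config.dfe.scaled(c), mu=config.mu * c, c=1.0)


@dataclass
class PopulationSnapshot:
    """Light-weight copy of per-haplotype mutation ids at one time point."""

    gen_rel: int
    hap_ids: dict
    n_haps: dict
    mean_w: dict


@dataclass
class SimulationResult:
    config: SimulationConfig
    scaled_config: SimulationConfig
    table: MutationTable
    timeseries: pd.DataFrame
    populations: dict
    pre_pulse: Optional[PopulationSnapshot]
    substitutions: list


def _weighted_choice(rng: np.random.Generator, w: np.ndarray, size: int) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        raise RuntimeError("all-zero fitness pool: no viable parents")
    if np.ptp(w) == 0:
        return rng.integers(0, len(w), size)
    return rng.choice(len(w), size=size, p=w / total)


def _splice_muts(posA, idsA, posB, idsB, bps):
    """Alternate [0,b0) from A, [b0,b1) from B, ... for sorted breakpoints.

    Implemented by piece-parity masks: a position in piece k (k = number of
    breakpoints at or before it) comes from A when k is even.
    """
    if len(bps) == 1:
        b = bps[0]
        i = posA.searchsorted(b)
        j = posB.searchsorted(b)
        return (np.concatenate([posA[:i], posB[j:]]),
                np.concatenate([idsA[:i], idsB[j:]]))
    keepA = (np.searchsorted(bps, posA, side="right") % 2) == 0
    keepB = (np.searchsorted(bps, posB, side="right") % 2) == 1
    pos = np.concatenate([posA[keepA], posB[keepB]])
    ids = np.concatenate([idsA[keepA], idsB[keepB]])
    if len(pos) == 0:
        return _EMPTY_I8, _EMPTY_I8
    order = np.argsort(pos, kind="stable")
    return pos[order], ids[order]


def _merge_sorted(pos, ids, new_pos, new_ids):
    """Merge sorted (new_pos, new_ids) into sorted (pos, ids)."""
    k = len(new_pos)
    idx = np.searchsorted(pos, new_pos)
    out_pos = np.empty(len(pos) + k, dtype=np.int64)
    out_ids = np.empty(len(pos) + k, dtype=np.int64)
    tgt = idx + np.arange(k)
    mask = np.ones(len(out_pos), dtype=bool)
    mask[tgt] = False
    out_pos[tgt] = new_pos
    out_ids[tgt] = new_ids
    out_pos[mask] = pos
    out_ids[mask] = ids
    return out_pos, out_ids


def _splice_segments(endsA, origA, endsB, origB, bps, length):
    """Splice run-length-encoded ancestry segments at the breakpoints.

    Segments are encoded as ascending ``ends`` (the last equals the
    chromosome length) with per-run origin labels; adjacent same-origin
    runs in the output are merged.
    """
    if len(endsA) == 1 and len(endsB) == 1:
        if origA[0] == origB[0]:
            return endsA, origA
        # single-run parents with different labels: strict alternation
        ends = np.append(bps, length)
        orig = np.empty(len(ends), dtype=np.int8)
        orig[0::2] = origA[0]
        orig[1::2] = origB[0]
        return ends, orig
    if len(bps) + len(endsA) + len(endsB) < 40:
        return _splice_segments_small(endsA, origA, endsB, origB, bps, length)
    bounds = np.empty(len(bps) + 2, dtype=np.int64)
    bounds[0] = 0
    bounds[1:-1] = bps
    bounds[-1] = length
    npieces = len(bounds) - 1
    los = bounds[:-1]
    his = bounds[1:]
    # per-piece source-segment index ranges [i0, i1] (inclusive), gathered
    # with one searchsorted pair per parent
    i0 = np.empty(npieces, dtype=np.int64)
    i1 = np.empty(npieces, dtype=np.int64)
    for off, (ends, orig) in ((0, (endsA, origA)), (1, (endsB, origB))):
        i0[off::2] = ends.searchsorted(los[off::2], side="right")
        i1[off::2] = ends.searchsorted(his[off::2], side="left")
    cnt = i1 - i0 + 1
    total = int(cnt.sum())
    offsets = np.concatenate(([0], np.cumsum(cnt)))
    within = np.arange(total, dtype=np.int64) - np.repeat(offsets[:-1], cnt)
    idx = np.repeat(i0, cnt) + within
    out_e = np.empty(total, dtype=np.int64)
    out_o = np.empty(total, dtype=np.int8)
    piece_of = np.repeat(np.arange(npieces), cnt)
    for off, (ends, orig) in ((0, (endsA, origA)), (1, (endsB, origB))):
        m = (piece_of % 2) == off
        out_e[m] = ends[idx[m]]
        out_o[m] = orig[idx[m]]
    out_e[offsets[1:] - 1] = his  # clip each piece's last segment
    keep = np.empty(total, dtype=bool)
    keep[-1] = True
    np.not_equal(out_o[:-1], out_o[1:], out=keep[:-1])
    return out_e[keep], out_o[keep]


def _splice_segments_small(endsA, origA, endsB, origB, bps, length):
    """Plain-loop segment splice; faster than the vectorized form for the
    few-breakpoint, few-segment case and the reference for both."""
    sources = ((endsA, origA), (endsB, origB))
    out_ends: list[int] = []
    out_orig: list[int] = []
    lo = 0
    take = 0
    for b in list(bps) + [length]:
        hi = int(b)
        if hi > lo:
            ends, orig = sources[take]
            i = int(ends.searchsorted(lo, side="right"))
            while lo < hi:
                seg_end = min(int(ends[i]), hi)
                o = int(orig[i])
                if out_orig and out_orig[-1] == o:
                    out_ends[-1] = seg_end
                else:
                    out_ends.append(seg_end)
                    out_orig.append(o)
                lo = seg_end
                i += 1
        take ^= 1
    return (np.asarray(out_ends, dtype=np.int64),
            np.asarray(out_orig, dtype=np.int8))


class Engine:
    """Stateful driver for one simulation replicate (scaled units)."""

    def __init__(self, config: SimulationConfig):
        self.user_config = config
        cfg = rescale(config)
        self.cfg = cfg
        self.structure = cfg.structure
        self.recmap = cfg.structure.recomb_map
        self.L = cfg.structure.length
        self.tbl = MutationTable()
        self.rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.mode = cfg.dominance.mode
        self.need_shared = self.mode in (RECESSIVE, HS_FUNCTION, ADDITIVE_TEXTBOOK)
        self.morgans = self.recmap.total_morgans
        self.p_ns = cfg.ns_syn_ratio / (cfg.ns_syn_ratio + 1.0)
        self._exon_only = not cfg.track_neutral
        if self._exon_only:
            iv = cfg.structure.exon_intervals
            lens = (iv[:, 1] - iv[:, 0]) if iv.size else np.empty(0, np.int64)
            self._exon_starts = iv[:, 0] if iv.size else np.empty(0, np.int64)
            self._exon_cum = np.concatenate(([0], np.cumsum(lens)))
            self.mu_total = cfg.mu * float(self._exon_cum[-1]) * self.p_ns
        else:
            self.mu_total = cfg.mu * self.L
        self._markers_placed = False
        self.substitutions: list[tuple[int, int]] = []
        self._records: list[dict] = []
        self.pre_pulse: Optional[PopulationSnapshot] = None

    # -- fitness -----------------------------------------------------------
    def _fitness(self, h1: Haplotype, h2: Haplotype) -> float:
        w = h1.het_score * h2.het_score
        if self.need_shared and h1.sel and h2.sel:
            shared = h1.sel & h2.sel
            if shared:
                w *= float(self.tbl.hom_ratio[np.fromiter(shared, dtype=np.int64,
                                                          count=len(shared))].prod())
        return w

    def _hemi_fitness(self, h: Haplotype) -> float:
        if h.hemi_score is None:
            h.hemi_score = float(self.tbl.hom_factor[h.ids].prod())
        return h.hemi_score

    # -- mutation ----------------------------------------------------------
    def _draw_positions(self, k: int) -> np.ndarray:
        if self._exon_only:
            u = self.rng.integers(0, self._exon_cum[-1], k)
            j = np.searchsorted(self._exon_cum, u, side="right") - 1
            return self._exon_starts[j] + (u - self._exon_cum[j])
        return self.rng.integers(0, self.L, k)

    def _spawn_mutations(self, k: int, pos, ids, anc_ends, anc_orig, gen: int,
                         pop_code: int):
        """Add k new mutations to (pos, ids); returns new arrays and the
        freshly added ids (sorted by position)."""
        cfg = self.cfg
        rng = self.rng
        p = np.sort(self._draw_positions(k))
        # infinite sites within the gamete: re-draw collisions (rare)
        for _ in range(16):
            dup = np.zeros(k, dtype=bool)
            if k > 1:
                dup[1:] = np.diff(p) == 0
            if len(pos):
                j = np.searchsorted(pos, p)
                hit = (j < len(pos)) & (pos[np.minimum(j, len(pos) - 1)] == p)
            else:
                hit = np.zeros(k, dtype=bool)
            bad = dup | hit
            if not bad.any():
                break
            p[bad] = self._draw_positions(int(bad.sum()))
            p.sort()
        if self._exon_only:
            classes = np.full(k, NONSYNONYMOUS, dtype=np.int8)
            ns_mask = np.ones(k, dtype=bool)
        else:
            exonic = self.structure.in_exon(p)
            ns_mask = exonic & (rng.random(k) < self.p_ns)
            classes = np.where(ns_mask, NONSYNONYMOUS,
                               np.where(exonic, SYNONYMOUS, NEUTRAL)).astype(np.int8)
        s = np.zeros(k)
        h = np.full(k, 0.5)
        if not cfg.neutral and ns_mask.any():
            s[ns_mask] = -rng.gamma(cfg.dfe.shape, cfg.dfe.scale,
                                    int(ns_mask.sum()))
            h[ns_mask] = assign_dominance(s[ns_mask], cfg.dominance)
        seg = np.searchsorted(anc_ends, p, side="right")
        origin = np.where(anc_orig[seg] == DONOR, POP_DONOR, pop_code)
        new_ids = self.tbl.add_many(p, s, h, classes, origin, gen,
                                    cfg.dominance)
        pos, ids = _merge_sorted(pos, ids, p, new_ids)
        return pos, ids, new_ids

    # -- gametes -----------------------------------------------------------
    def _gamete(self, parent: Individual, start: int, n_cross: int,
                n_mut: int, gen: int, pop_code: int) -> Haplotype:
        h1, h2 = parent.h1, parent.h2
        if h2 is None:
            base = h1
            n_cross = 0
        else:
            base = h1 if start == 0 else h2
        if n_cross == 0 and n_mut == 0:
            return base
        if n_cross == 0:
            pos, ids = base.pos, base.ids
            anc_ends, anc_orig = base.anc_ends, base.anc_orig
            het = base.het_score
            sel = base.sel
        else:
            bps = self.recmap.sample_positions(self.rng, n_cross)
            if n_cross > 1:
                bps = bps[np.concatenate(([True], np.diff(bps) > 0))]
            bps = bps[bps > 0]
            a, b = (h1, h2) if start == 0 else (h2, h1)
            pos, ids = _splice_muts(a.pos, a.ids, b.pos, b.ids, bps)
            anc_ends, anc_orig = _splice_segments(a.anc_ends, a.anc_orig,
                                                  b.anc_ends, b.anc_orig,
                                                  bps, self.L)
            het = None
            sel = None
        new_ids = _EMPTY_I8
        if n_mut:
            pos, ids, new_ids = self._spawn_mutations(n_mut, pos, ids,
                                                      anc_ends, anc_orig,
                                                      gen, pop_code)
        if het is None:
            het = float(self.tbl.het_factor[ids].prod())
            if self.need_shared:
                sel = frozenset(ids[self.tbl.selected[ids]].tolist())
        elif len(new_ids):
            het = het * float(self.tbl.het_factor[new_ids].prod())
            if self.need_shared:
                extra = new_ids[self.tbl.selected[new_ids]]
                sel = sel | frozenset(extra.tolist()) if len(extra) else sel
        if not self.need_shared:
            sel = _EMPTY_SET
        return Haplotype(pos, ids, het, sel, anc_ends, anc_orig)

    def mutate_gamete(self, hap: Haplotype, gen: int = 0,
                      pop_code: int = POP_RECIPIENT,
                      n_mut: int | None = None) -> Haplotype:
        """Return ``hap`` with Poisson(mu*target) new mutations added.

        Within exons a new mutation is nonsynonymous with probability
        ns_ratio/(ns_ratio+1), else synonymous; outside exons neutral.
        """
        if n_mut is None:
            n_mut = int(self.rng.poisson(self.mu_total)) if self.mu_total > 0 else 0
        if n_mut == 0:
            return hap
        pos, ids, new_ids = self._spawn_mutations(
            n_mut, hap.pos, hap.ids, hap.anc_ends, hap.anc_orig, gen, pop_code)
        het = hap.het_score * float(self.tbl.het_factor[new_ids].prod())
        sel = hap.sel
        if self.need_shared:
            extra = new_ids[self.tbl.selected[new_ids]]
            if len(extra):
                sel = sel | frozenset(extra.tolist())
        return Haplotype(pos, ids, het, sel, hap.anc_ends, hap.anc_orig)

    def recombine(self, parent: Individual,
                  n_cross: int | None = None) -> Haplotype:
        """Produce one recombinant (but unmutated) gamete from ``parent``."""
        if n_cross is None:
            n_cross = int(self.rng.poisson(self.morgans)) if self.morgans > 0 else 0
        start = int(self.rng.integers(0, 2))
        return self._gamete(parent, start, n_cross, 0, 0, POP_RECIPIENT)

    # -- one generation of offspring --------------------------------------
    def _offspring_auto(self, n: int, main: list, donor: Optional[list],
                        f: float, selfing: float, gen: int,
                        pop_code: int) -> list:
        rng = self.rng
        w_main = np.fromiter((ind.w for ind in main), dtype=float, count=len(main))
        pa = _weighted_choice(rng, w_main, n)
        pb = _weighted_choice(rng, w_main, n)
        use_donor_a = use_donor_b = None
        if f > 0 and donor is not None:
            w_don = np.fromiter((ind.w for ind in donor), dtype=float, count=len(donor))
            da = _weighted_choice(rng, w_don, n)
            db = _weighted_choice(rng, w_don, n)
            use_donor_a = rng.random(n) < f
            use_donor_b = rng.random(n) < f
        selfed = rng.random(n) < selfing if selfing > 0 else None
        n_cross = rng.poisson(self.morgans, 2 * n) if self.morgans > 0 else np.zeros(2 * n, dtype=np.int64)
        n_mut = rng.poisson(self.mu_total, 2 * n) if self.mu_total > 0 else np.zeros(2 * n, dtype=np.int64)
        start = rng.integers(0, 2, 2 * n)
        out = []
        for i in range(n):
            if use_donor_a is not None and use_donor_a[i]:
                parent_a = donor[da[i]]
            else:
                parent_a = main[pa[i]]
            if selfed is not None and selfed[i]:
                parent_b = parent_a
            elif use_donor_b is not None and use_donor_b[i]:
                parent_b = donor[db[i]]
            else:
                parent_b = main[pb[i]]
            ha = self._gamete(parent_a, start[2 * i], n_cross[2 * i],
                              n_mut[2 * i], gen, pop_code)
            hb = self._gamete(parent_b, start[2 * i + 1], n_cross[2 * i + 1],
                              n_mut[2 * i + 1], gen, pop_code)
            out.append(Individual(ha, hb, self._fitness(ha, hb)))
        return out

    def _offspring_x(self, n: int, main: list, donor: Optional[list],
                     f: float, gen: int, pop_code: int) -> list:
        rng = self.rng
        females = [ind for ind in main if ind.sex == "female"]
        males = [ind for ind in main if ind.sex == "male"]
        if not females or not males:
            raise RuntimeError("X-mode population lost one sex entirely")
        w_f = np.fromiter((ind.w for ind in females), dtype=float, count=len(females))
        w_m = np.fromiter((ind.w for ind in males), dtype=float, count=len(males))
        mi = _weighted_choice(rng, w_f, n)
        fi = _weighted_choice(rng, w_m, n)
        use_donor_m = use_donor_f = None
        if f > 0 and donor is not None:
            d_fem = [ind for ind in donor if ind.sex == "female"]
            d_mal = [ind for ind in donor if ind.sex == "male"]
            dw_f = np.fromiter((ind.w for ind in d_fem), dtype=float, count=len(d_fem))
            dw_m = np.fromiter((ind.w for ind in d_mal), dtype=float, count=len(d_mal))
            dmi = _weighted_choice(rng, dw_f, n)
            dfi = _weighted_choice(rng, dw_m, n)
            use_donor_m = rng.random(n) < f
            use_donor_f = rng.random(n) < f
        n_cross = rng.poisson(self.morgans, n) if self.morgans > 0 else np.zeros(n, dtype=np.int64)
        n_mut_m = rng.poisson(self.mu_total, n) if self.mu_total > 0 else np.zeros(n, dtype=np.int64)
        n_mut_p = rng.poisson(self.mu_total, n) if self.mu_total > 0 else np.zeros(n, dtype=np.int64)
        start = rng.integers(0, 2, n)
        out = []
        for i in range(n):
            sex = "female" if i % 2 == 0 else "male"
            if use_donor_m is not None and use_donor_m[i]:
                mother = d_fem[dmi[i]]
            else:
                mother = females[mi[i]]
            h_mat = self._gamete(mother, start[i], n_cross[i], n_mut_m[i],
                                 gen, pop_code)
            if sex == "male":
                out.append(Individual(h_mat, None, self._hemi_fitness(h_mat),
                                      sex="male"))
            else:
                if use_donor_f is not None and use_donor_f[i]:
                    father = d_mal[dfi[i]]
                else:
                    father = males[fi[i]]
                # the paternal X is transmitted without recombination
                h_pat = self._gamete(father, 0, 0, n_mut_p[i], gen, pop_code)
                out.append(Individual(h_mat, h_pat,
                                      self._fitness(h_mat, h_pat),
                                      sex="female"))
        return out

    def _next(self, n: int, main: list, donor: Optional[list], f: float,
              selfing: float, gen: int, pop_code: int) -> list:
        if self.cfg.mating.x_mode:
            return self._offspring_x(n, main, donor, f, gen, pop_code)
        return self._offspring_auto(n, main, donor, f, selfing, gen, pop_code)

    # -- bookkeeping -------------------------------------------------------
    def _hap_slots(self, pop: list) -> int:
        return sum(1 if ind.h2 is None else 2 for ind in pop)

    def _pop_counts(self, pop: list) -> np.ndarray:
        all_ids = [h.ids for ind in pop for h in ind.haplotypes()]
        if not all_ids:
            return np.zeros(self.tbl.n, dtype=np.int64)
        return np.bincount(np.concatenate(all_ids), minlength=self.tbl.n)

    def prune_fixed(self, pops: dict, gen: int) -> list:
        """Remove mutations fixed in every extant population.

        Marker mutations are never pruned (they carry the ancestry signal).
        Every individual's cached fitness is divided by the same constant,
        so relative fitness is invariant.
        """
        if self.tbl.n == 0:
            return []
        fixed_mask = np.ones(self.tbl.n, dtype=bool)
        for pop in pops.values():
            counts = self._pop_counts(pop)
            fixed_mask &= counts == self._hap_slots(pop)
        fixed_mask &= self.tbl.func_class[: self.tbl.n] != MARKER
        fixed = np.flatnonzero(fixed_mask)
        if fixed.size == 0:
            return []
        rm = np.zeros(self.tbl.n, dtype=bool)
        rm[fixed] = True
        seen: set[int] = set()
        for pop in pops.values():
            for ind in pop:
                for h in ind.haplotypes():
                    if id(h) in seen:
                        continue
                    seen.add(id(h))
                    keep = ~rm[h.ids]
                    if keep.all():
                        continue
                    h.pos = h.pos[keep]
                    h.ids = h.ids[keep]
                    h.het_score = float(self.tbl.het_factor[h.ids].prod())
                    if self.need_shared:
                        h.sel = frozenset(h.ids[self.tbl.selected[h.ids]].tolist())
                    h.hemi_score = None
        factor = float(self.tbl.hom_factor[fixed].prod())
        if factor > 0:
            for pop in pops.values():
                for ind in pop:
                    ind.w /= factor
        self.substitutions.extend((int(m), gen) for m in fixed)
        return fixed.tolist()

    def _record(self, gen_abs: int, gen_rel: int, pops: dict) -> None:
        for name, pop in pops.items():
            haps = [h for ind in pop for h in ind.haplotypes()]
            n_haps = len(haps)
            donor_bp = sum(ancestry.segment_donor_bp(h.anc_ends, h.anc_orig)
                           for h in haps)
            p_i = donor_bp / (self.L * n_haps)
            sel_counts = [int(self.tbl.selected[h.ids].sum()) for h in haps]
            hom = 0
            for ind in pop:
                if ind.h2 is None:
                    continue
                s1 = frozenset(ind.h1.ids[self.tbl.selected[ind.h1.ids]].tolist())
                s2 = frozenset(ind.h2.ids[self.tbl.selected[ind.h2.ids]].tolist())
                hom += len(s1 & s2)
            n_dip = sum(1 for ind in pop if ind.h2 is not None)
            self._records.append(dict(
                gen=gen_abs, gen_rel=gen_rel, pop=name, size=len(pop),
                mean_w=float(np.mean([ind.w for ind in pop])),
                p_I=p_i,
                del_per_hap=float(np.mean(sel_counts)) if sel_counts else 0.0,
                hom_del_per_ind=hom / n_dip if n_dip else 0.0,
            ))

    def _snapshot(self, gen_rel: int, pops: dict) -> PopulationSnapshot:
        return PopulationSnapshot(
            gen_rel=gen_rel,
            hap_ids={name: [h.ids.copy() for ind in pop
                            for h in ind.haplotypes()]
                     for name, pop in pops.items()},
            n_haps={name: self._hap_slots(pop) for name, pop in pops.items()},
            mean_w={name: float(np.mean([ind.w for ind in pop]))
                    for name, pop in pops.items()},
        )

    def place_markers(self, donor_pop: list, gen: int) -> None:
        """Add neutral marker mutations at fixed spacing to every donor
        haplotype (once, immediately before the pulse)."""
        if self._markers_placed:
            raise RuntimeError("markers have already been placed")
        self._markers_placed = True
        spacing = self.cfg.marker_spacing
        positions = np.arange(0, self.L, spacing, dtype=np.int64)
        ids = self.tbl.add_many(positions, 0.0, 0.5, MARKER, POP_DONOR, gen,
                                self.cfg.dominance)
        seen: set[int] = set()
        for ind in donor_pop:
            for h in ind.haplotypes():
                if id(h) in seen:
                    continue
                seen.add(id(h))
                pos = np.concatenate([h.pos, positions])
                allids = np.concatenate([h.ids, ids])
                order = np.argsort(pos, kind="stable")
                h.pos = pos[order]
                h.ids = allids[order]
                # markers are neutral: cached scores unchanged

    # -- phases ------------------------------------------------------------
    def _init_pop(self, n: int) -> list:
        length = self.L
        if self.cfg.mating.x_mode:
            out = []
            shared_f = Haplotype.empty(length)
            for i in range(n):
                if i % 2 == 0:
                    out.append(Individual(shared_f, shared_f, 1.0, sex="female"))
                else:
                    out.append(Individual(shared_f, None, 1.0, sex="male"))
            return out
        shared = Haplotype.empty(length)
        return [Individual(shared, shared, 1.0) for _ in range(n)]

    def _relabel(self, pop: list, label: int) -> None:
        cache: dict[int, Haplotype] = {}
        length = self.L
        for ind in pop:
            new_haps = []
            for h in ind.haplotypes():
                key = id(h)
                if key not in cache:
                    nh = Haplotype(h.pos, h.ids, h.het_score, h.sel,
                                   np.array([length], dtype=np.int64),
                                   np.array([label], dtype=np.int8))
                    nh.hemi_score = h.hemi_score
                    cache[key] = nh
                new_haps.append(cache[key])
            ind.h1 = new_haps[0]
            if ind.h2 is not None:
                ind.h2 = new_haps[1]

    def run(self) -> SimulationResult:
        cfg = self.cfg
        d = cfg.demography
        mating = cfg.mating
        anc = self._init_pop(d.N_A)
        pops = {"ancestral": anc}
        for g in range(d.burn_in):
            anc = self._next(d.N_A, anc, None, 0.0, mating.selfing_ancestral,
                             g + 1, POP_ANCESTRAL)
            pops = {"ancestral": anc}
            if cfg.prune_every and (g + 1) % cfg.prune_every == 0:
                self.prune_fixed(pops, g + 1)
        # split: both subpopulations draw their parents from the ancestral pool
        g_split = d.burn_in
        donor = self._next(d.donor_size(0), anc, None, 0.0,
                           mating.selfing_donor, g_split, POP_DONOR)
        recip = self._next(d.recipient_size(0), anc, None, 0.0,
                           mating.selfing_recipient, g_split, POP_RECIPIENT)
        self._relabel(donor, DONOR)
        self._relabel(recip, RECIPIENT)
        pops = {"donor": donor, "recipient": recip}
        self.prune_fixed(pops, g_split)
        self._record(g_split, 0, pops)
        # a split time of 0 collapses to a pulse in the first post-split
        # generation (one generation is the minimum resolvable divergence)
        pulse_gen = max(1, d.t_s)
        total = pulse_gen + d.post_admixture
        for g_rel in range(1, total + 1):
            gen = g_split + g_rel
            pulse = g_rel == pulse_gen
            if pulse:
                self.prune_fixed(pops, gen)
                self.pre_pulse = self._snapshot(g_rel - 1, pops)
                if cfg.markers:
                    self.place_markers(pops["donor"], gen)
            f = d.admixture_fraction if pulse else 0.0
            new_donor = self._next(d.donor_size(g_rel), pops["donor"], None,
                                   0.0, mating.selfing_donor, gen, POP_DONOR)
            new_recip = self._next(d.recipient_size(g_rel), pops["recipient"],
                                   pops["donor"] if pulse else None, f,
                                   mating.selfing_recipient, gen, POP_RECIPIENT)
            pops = {"donor": new_donor, "recipient": new_recip}
            due = (cfg.prune_every and g_rel % cfg.prune_every == 0)
            rec = (g_rel % cfg.record_every == 0 or pulse or g_rel == total
                   or g_rel == pulse_gen - 1)
            if due or rec:
                self.prune_fixed(pops, gen)
            if rec:
                self._record(gen, g_rel, pops)
        ts = pd.DataFrame(self._records)
        return SimulationResult(
            config=self.user_config, scaled_config=cfg, table=self.tbl,
            timeseries=ts, populations=pops, pre_pulse=self.pre_pulse,
            substitutions=self.substitutions,
        )


def run(config: SimulationConfig) -> SimulationResult:
    """Run one replicate of the configured simulation."""
    return Engine(config).run()


def run_equilibrium(config: SimulationConfig, generations: int | None = None):
    """Evolve a single population for ``generations`` (default: the
    configured burn-in) and return (engine, population).

    Used for equilibrium-population checks such as comparing site-frequency
    spectra between fitness formulations.
    """
    eng = Engine(config)
    cfg = eng.cfg
    gens = cfg.demography.burn_in if generations is None else generations
    pop = eng._init_pop(cfg.demography.N_A)
    for g in range(gens):
        pop = eng._next(cfg.demography.N_A, pop, None, 0.0,
                        cfg.mating.selfing_ancestral, g + 1, POP_ANCESTRAL)
        if cfg.prune_every and (g + 1) % cfg.prune_every == 0:
            eng.prune_fixed({"ancestral": pop}, g + 1)
    eng.prune_fixed({"ancestral": pop}, gens)
    return eng, pop
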