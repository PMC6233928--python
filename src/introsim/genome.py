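"""Chromosome structure: genic elements, recombination maps, analysis windows.

A simulated chromosome is a gapless tiling of exon / intron / intergenic
elements plus a piecewise-constant recombination map.  Structures are either
generated at random (lognormal exon and intron lengths, uniform intergenic
lengths, genes built as exon-(intron-exon)* runs) or loaded from a BED exon
annotation and a two-column position/rate map file.  All coordinates are
0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"

_KINDS = (EXON, INTRON, INTERGENIC)


@dataclass(frozen=True)
class GenomicElement:
    """One element of the chromosome tiling (0-based, half-open)."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid element interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class RecombinationMap:
    """Piecewise-constant per-bp crossover rates covering [0, L).

    ``starts`` are the ascending left edges of the constant pieces (the first
    must be 0) and ``rates`` the per-bp per-generation crossover
    probabilities.
    """

    def __init__(self, starts: Sequence[int], rates: Sequence[float], length: int):
        starts = np.asarray(starts, dtype=np.int64)
        rates = np.asarray(rates, dtype=float)
        if starts.ndim != 1 or starts.shape != rates.shape or starts.size == 0:
            raise ValueError("starts and rates must be equal-length 1-D sequences")
        if starts[0] != 0:
            raise ValueError("recombination map must start at position 0")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("recombination map positions must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("recombination rates must be non-negative")
        if length <= starts[-1]:
            raise ValueError("map length must exceed the last breakpoint")
        self.starts = starts
        self.rates = rates
        self.length = int(length)
        self._ends = np.append(starts[1:], length)
        self._seg_lens = (self._ends - starts).astype(float)
        self._morgans = self.rates * self._seg_lens
        #: total genetic length in Morgans (expected crossovers per gamete)
        self.total_morgans = float(self._morgans.sum())
        cum = np.cumsum(self._morgans)
        self._cum_morgans = cum / cum[-1] if cum[-1] > 0 else cum

    @classmethod
    def uniform(cls, rate: float, length: int) -> "RecombinationMap":
        return cls([0], [rate], length)

    @property
    def mean_rate(self) -> float:
        """Base-pair-weighted mean per-bp rate."""
        return self.total_morgans / self.length

    def rate_in(self, start: int, end: int) -> float:
        """Base-pair-weighted mean rate over [start, end)."""
        lo = np.clip(self.starts, start, end)
        hi = np.clip(self._ends, start, end)
        overlap = (hi - lo).astype(float)
        if end <= start:
            raise ValueError("empty interval")
        return float((overlap * self.rates).sum() / (end - start))

    def sample_positions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` crossover positions with density proportional to rate."""
        if n == 0 or self.total_morgans == 0:
            return np.empty(0, dtype=np.int64)
        if len(self.rates) == 1:
            pos = (rng.random(n) * self.length).astype(np.int64)
        else:
            u = rng.random(n)
            seg = np.searchsorted(self._cum_morgans, u, side="left")
            within = rng.random(n)
            pos = np.minimum((self.starts[seg] + within * self._seg_lens[seg])
                             .astype(np.int64), self.length - 1)
        pos.sort()
        return pos

    def rescaled(self, c: float) -> "RecombinationMap":
        """Return the map with each rate r mapped to 0.5*(1 - (1 - 2r)^c)."""
        new = 0.5 * (1.0 - (1.0 - 2.0 * self.rates) ** c)
        return RecombinationMap(self.starts.copy(), new, self.length)


@dataclass(frozen=True)
class StructureParams:
    """Element-length distributions for random chromosome generation.

    Exon and intron lengths are lognormal (``meanlog``/``sdlog`` on the log
    scale), intergenic lengths uniform on [min, max].  After the first exon
    of a gene, an (intron, exon) pair is appended with probability
    ``intron_continue_prob``, so genes always start and end with an exon.
    """

    exon_meanlog: float = math.log(50)
    exon_sdlog: float = math.log(2)
    intron_meanlog: float = math.log(100)
    intron_sdlog: float = math.log(1.5)
    intergenic_min: int = 100
    intergenic_max: int = 5000
    intron_continue_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.exon_sdlog < 0 or self.intron_sdlog < 0:
            raise ValueError("lognormal sdlog parameters must be >= 0")
        if not (0 < self.intergenic_min <= self.intergenic_max):
            raise ValueError("intergenic length bounds must satisfy 0 < min <= max")
        if not (0 <= self.intron_continue_prob < 1):
            raise ValueError("intron_continue_prob must lie in [0, 1)")


class GenomeStructure:
    """A chromosome: length, element tiling, and recombination map."""

    def __init__(self, length: int, elements: Sequence[GenomicElement],
                 recomb_map: RecombinationMap):
        if length <= 0:
            raise ValueError("chromosome length must be positive")
        if recomb_map.length != length:
            raise ValueError("recombination map length does not match chromosome")
        pos = 0
        for el in elements:
            if el.start != pos:
                raise ValueError("elements must tile the chromosome without gaps")
            pos = el.end
        if pos != length:
            raise ValueError("elements must cover the full chromosome length")
        self.length = int(length)
        self.elements = list(elements)
        self.recomb_map = recomb_map
        exons = [(e.start, e.end) for e in elements if e.kind == EXON]
        self.exon_intervals = _merge_intervals(exons)
        # flattened [s0, e0, s1, e1, ...]; searchsorted parity tests membership
        self._exon_flat = self.exon_intervals.reshape(-1)

    @property
    def exonic_bp(self) -> int:
        if self.exon_intervals.size == 0:
            return 0
        return int((self.exon_intervals[:, 1] - self.exon_intervals[:, 0]).sum())

    def in_exon(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: is each position inside an exon?"""
        if self._exon_flat.size == 0:
            return np.zeros(np.shape(positions), dtype=bool)
        idx = np.searchsorted(self._exon_flat, positions, side="right")
        return (idx % 2) == 1

    def exonic_overlap(self, start: int, end: int) -> int:
        """Exonic base pairs overlapping [start, end)."""
        if self.exon_intervals.size == 0:
            return 0
        lo = np.clip(self.exon_intervals[:, 0], start, end)
        hi = np.clip(self.exon_intervals[:, 1], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def with_uniform_rate(self, rate: float) -> "GenomeStructure":
        """Same tiling with a uniform recombination map."""
        return GenomeStructure(self.length, self.elements,
                               RecombinationMap.uniform(rate, self.length))

    def with_map(self, recomb_map: RecombinationMap) -> "GenomeStructure":
        return GenomeStructure(self.length, self.elements, recomb_map)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tstart\tend\n")
            for el in self.elements:
                fh.write(f"{el.kind}\t{el.start}\t{el.end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, recomb_map: RecombinationMap) -> "GenomeStructure":
        elements = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                kind, start, end = line.split()
                elements.append(GenomicElement(kind, int(start), int(end)))
        return cls(elements[-1].end, elements, recomb_map)


@dataclass(frozen=True)
class Window:
    """A fixed-size analysis window with its genomic covariates."""

    start: int
    end: int
    exon_density: float
    mean_r: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    ivals = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(merged, dtype=np.int64)


def generate_random_structure(length: int, seed: int,
                              params: StructureParams | None = None,
                              r: float = 1e-8) -> GenomeStructure:
    """Generate a random chromosome tiling, reproducible from ``seed``.

    Alternates intergenic blocks with genes (exon, then (intron, exon) pairs
    with continuation probability ``params.intron_continue_prob``) until
    ``length`` is reached; the final element is truncated at the chromosome
    end, keeping its kind.  The recombination map is uniform at rate ``r``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    params = params or StructureParams()
    rng = np.random.default_rng(seed)
    elements: list[GenomicElement] = []
    pos = 0

    def draw_lognormal(meanlog: float, sdlog: float) -> int:
        if sdlog == 0:
            return max(1, int(round(math.exp(meanlog))))
        return max(1, int(round(rng.lognormal(meanlog, sdlog))))

    def push(kind: str, ln: int) -> bool:
        nonlocal pos
        ln = min(ln, length - pos)
        if ln <= 0:
            return False
        elements.append(GenomicElement(kind, pos, pos + ln))
        pos += ln
        return pos < length

    going = True
    while going:
        inter = int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
        if not push(INTERGENIC, inter):
            break
        if not push(EXON, draw_lognormal(params.exon_meanlog, params.exon_sdlog)):
            break
        while rng.random() < params.intron_continue_prob:
            if not push(INTRON, draw_lognormal(params.intron_meanlog, params.intron_sdlog)):
                going = False
                break
            if not push(EXON, draw_lognormal(params.exon_meanlog, params.exon_sdlog)):
                going = False
                break
    return GenomeStructure(length, elements, RecombinationMap.uniform(r, length))


def read_annotation(path: str | Path, chrom_length: int) -> GenomeStructure:
    """Load exon intervals from a BED file (0-based, half-open).

    Overlapping exon records are merged; every non-exonic gap is labeled
    intergenic (loaded annotations do not distinguish introns, since only
    the exon/non-exon split matters for mutation targeting).  The returned
    structure carries a uniform placeholder map; attach a real one with
    :meth:`GenomeStructure.with_map`.
    """
    exons: list[tuple[int, int]] = []
    chroms = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED record at line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinates at line {lineno}") from exc
            if start < 0 or end > chrom_length or start >= end:
                raise ValueError(f"{path}: out-of-range interval at line {lineno}")
            chroms.add(parts[0])
            exons.append((start, end))
    if len(chroms) > 1:
        raise ValueError(f"{path}: BED spans multiple chromosomes: {sorted(chroms)}")
    merged = _merge_intervals(exons)
    elements: list[GenomicElement] = []
    pos = 0
    for s, e in merged:
        if s > pos:
            elements.append(GenomicElement(INTERGENIC, pos, int(s)))
        elements.append(GenomicElement(EXON, int(s), int(e)))
        pos = int(e)
    if pos < chrom_length:
        elements.append(GenomicElement(INTERGENIC, pos, chrom_length))
    return GenomeStructure(chrom_length, elements,
                           RecombinationMap.uniform(1e-8, chrom_length))


def read_recomb_map(path: str | Path, length: int) -> RecombinationMap:
    """Load a whitespace-delimited position / per-bp-rate text file.

    Rates apply from each listed position to the next (piecewise constant);
    a single ``0 <rate>`` row yields a uniform map.
    """
    starts: list[int] = []
    rates: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed map record at line {lineno}")
            pos, rate = int(parts[0]), float(parts[1])
            if rate < 0:
                raise ValueError(f"{path}: negative rate at line {lineno}")
            if starts and pos <= starts[-1]:
                raise ValueError(f"{path}: non-ascending position at line {lineno}")
            starts.append(pos)
            rates.append(rate)
    if not starts:
        raise ValueError(f"{path}: empty recombination map")
    if starts[0] != 0:
        starts.insert(0, 0)
        rates.insert(0, rates[0])
    return RecombinationMap(starts, rates, length)


def make_windows(structure: GenomeStructure, size: int = 100_000) -> list[Window]:
    """Tile the chromosome into non-overlapping windows of ``size`` bp.

    Exon density and mean recombination rate are base-pair-weighted; the
    terminal window may be shorter than ``size``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows = []
    for start in range(0, structure.length, size):
        end = min(start + size, structure.length)
        exonic = structure.exonic_overlap(start, end)
        windows.append(Window(
            start=start, end=end,
            exon_density=exonic / (end - start),
            mean_r=structure.recomb_map.rate_in(start, end),
        ))
    return windows
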