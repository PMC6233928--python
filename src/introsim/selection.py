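"""Fitness effects: the gamma DFE, dominance models, and locus fitness.

Selection coefficients are stored signed (s <= 0, 0 for neutral classes);
fitness formulas consume |s|.  Under the default within-locus scheme a
heterozygote has fitness factor 1 - h|s| and a homozygote (1 - 0.5|s|)^2,
multiplied across loci.  With h = 0.5 this makes individual fitness a
function of the total number of deleterious allele copies alone, removing
the spurious heterozygote advantage of the textbook additive scheme (whose
two-heterozygote configuration exceeds the one-homozygote configuration by
exactly 0.25 s^2).  Fully recessive fitness (h = 0) uses the standard
1 - |s| homozygote factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

ADDITIVE = "additive"
RECESSIVE = "recessive"
HS_FUNCTION = "hs_function"
# textbook additive scheme (het 1-0.5|s|, hom 1-|s|); used as the comparison
# arm for the site-frequency-spectrum equivalence check
ADDITIVE_TEXTBOOK = "additive_textbook"

_MODES = (ADDITIVE, RECESSIVE, HS_FUNCTION, ADDITIVE_TEXTBOOK)

# functional classes of new mutations
NEUTRAL = 0
SYNONYMOUS = 1
NONSYNONYMOUS = 2
MARKER = 3


@dataclass(frozen=True)
class DFEParams:
    """Gamma distribution of (negative) selection coefficients.

    ``mean_s`` is the expected selection coefficient (< 0); the gamma scale
    is |mean_s| / shape.
    """

    shape: float
    mean_s: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("DFE shape must be positive")
        if self.mean_s >= 0:
            raise ValueError("DFE mean selection coefficient must be negative")

    @property
    def scale(self) -> float:
        return -self.mean_s / self.shape

    def scaled(self, c: float) -> "DFEParams":
        return DFEParams(self.shape, self.mean_s * c)


@dataclass(frozen=True)
class DominanceModel:
    """Dominance of deleterious mutations.

    ``hs_function`` uses the hyperbola h(s) = h0 / (1 - B s) with intercept
    h0 = h(0) and denominator coefficient B; for s <= 0 this decreases
    monotonically from h0 toward 0.  The human estimate prints as
    0.5 / (1 - 7071.07 s), i.e. (h0, B) = (0.5, 7071.07).  The Arabidopsis
    estimate prints as 1 / ((1/0.987) - 39547 s), which is the same
    hyperbola with (h0, B) = (0.987, 0.987 * 39547).
    """

    mode: str = ADDITIVE
    hs_intercept: float = 0.5
    hs_coef: float = 7071.07

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown dominance mode {self.mode!r}")
        if self.mode == HS_FUNCTION and not (0 < self.hs_intercept <= 1):
            raise ValueError("hs intercept must lie in (0, 1]")


@dataclass(frozen=True)
class SpeciesPreset:
    """Literature-estimated DFE, dominance, and mutation-rate parameter set."""

    dfe: DFEParams
    dominance: DominanceModel
    mu: float


HUMAN = SpeciesPreset(
    dfe=DFEParams(shape=0.186, mean_s=-0.01314833),
    dominance=DominanceModel(HS_FUNCTION, hs_intercept=0.5, hs_coef=7071.07),
    mu=1.5e-8,
)

ARABIDOPSIS = SpeciesPreset(
    dfe=DFEParams(shape=0.185, mean_s=-0.00048655),
    dominance=DominanceModel(HS_FUNCTION, hs_intercept=0.987,
                             hs_coef=0.987 * 39547.0),
    mu=7e-9,
)

PRESETS = {"human": HUMAN, "arabidopsis": ARABIDOPSIS}


def sample_selection_coefficient(dfe: DFEParams, rng: np.random.Generator,
                                 size: int | None = None):
    """Draw s = -Gamma(shape, scale=|mean_s|/shape); strictly negative."""
    return -rng.gamma(dfe.shape, dfe.scale, size=size)


def assign_dominance(s, model: DominanceModel):
    """Dominance coefficient h for selection coefficient(s) s <= 0."""
    s = np.asarray(s, dtype=float)
    if np.any(s > 0):
        raise ValueError("positive selection coefficients are out of scope")
    if model.mode in (ADDITIVE, ADDITIVE_TEXTBOOK):
        h = np.full_like(s, 0.5)
    elif model.mode == RECESSIVE:
        h = np.zeros_like(s)
    else:
        h = model.hs_intercept / (1.0 - model.hs_coef * s)
    return h if h.ndim else float(h)


def _abs_s(s: float) -> float:
    a = abs(s)
    if a > 1:
        warnings.warn("|s| exceeds 1; fitness factor clipped at 0",
                      stacklevel=3)
    return a


def heterozygote_factor(s: float, h: float) -> float:
    """Fitness factor of a single heterozygous copy: max(0, 1 - h|s|)."""
    return max(0.0, 1.0 - h * _abs_s(s))


def homozygote_factor(s: float, model: DominanceModel) -> float:
    """Fitness factor of a homozygous site.

    (1 - 0.5|s|)^2 for the multiplicative-within-locus additive and h(s)
    schemes; 1 - |s| for fully recessive (and for the textbook additive
    comparison scheme).
    """
    a = _abs_s(s)
    if model.mode in (RECESSIVE, ADDITIVE_TEXTBOOK):
        return max(0.0, 1.0 - a)
    return max(0.0, 1.0 - 0.5 * a) ** 2


def locus_fitness_factor(s: float, h: float, copies: int,
                         model: DominanceModel) -> float:
    """Multiplicative fitness factor of one locus given 0, 1 or 2 copies."""
    if copies == 0:
        return 1.0
    if copies == 1:
        return heterozygote_factor(s, h)
    if copies == 2:
        return homozygote_factor(s, model)
    raise ValueError("copies must be 0, 1, or 2")


def individual_fitness(genotype: Iterable[tuple[float, float, int]],
                       model: DominanceModel) -> float:
    """Multiplicative fitness over (s, h, copies) records of selected loci.

    The caller must already have pruned globally fixed mutations; neutral
    classes (s = 0) contribute factor 1 and may simply be omitted.
    """
    w = 1.0
    for s, h, copies in genotype:
        w *= locus_fitness_factor(s, h, copies, model)
    return w


def x_fitness(genotype: Iterable[tuple[float, float, int]], sex: str,
              model: DominanceModel) -> float:
    """X-linked fitness with dosage compensation.

    Females use the autosomal factors.  Hemizygous males carrying the
    allele get the female homozygote factor, so homozygous females and
    carrier males have equal fitness; in the additive model heterozygous
    females are intermediate.
    """
    if sex == "female":
        return individual_fitness(genotype, model)
    if sex != "male":
        raise ValueError(f"unknown sex {sex!r}")
    w = 1.0
    for s, h, copies in genotype:
        if copies == 0:
            continue
        if copies != 1:
            raise ValueError("males are hemizygous: X loci carry 0 or 1 copies")
        w *= homozygote_factor(s, model)
    return w
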