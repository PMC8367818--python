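"""Dating LTR retrotransposon insertions from terminal-repeat divergence.

The two long terminal repeats of a retrotransposon are identical at the
moment of insertion and diverge afterwards, so their pairwise distance D
dates the insertion through the molecular clock T = D / (2 mu).  Distances
use the Kimura two-parameter (K2P) model, separating transition and
transversion rates; a Jukes–Cantor fallback is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codon_evol import ClockParams

__all__ = [
    "LTRElement",
    "AgeEstimate",
    "AgeHistogram",
    "SaturationError",
    "k2p_distance",
    "insertion_time",
    "age_histogram",
]

_VALID = frozenset("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """Divergence too high for the distance correction to be defined."""


@dataclass(frozen=True)
class LTRElement:
    """An LTR retrotransposon's aligned 5'/3' terminal repeats.

    Sequences must be equal length (gap columns already removed); ambiguity
    characters are tolerated and excluded pairwise during distance
    computation.
    """

    element_id: str
    ltr5: str
    ltr3: str
    source: str | None = None

    def __post_init__(self):
        if len(self.ltr5) != len(self.ltr3):
            raise ValueError(f"{self.element_id}: LTR lengths differ")
        if len(self.ltr5) < 100:
            raise ValueError(f"{self.element_id}: aligned LTRs shorter than 100 bp")


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    P: float  # transition proportion
    Q: float  # transversion proportion
    D: float  # distance (substitutions/site)
    T: float  # years
    n_sites: int
    saturated: bool = False


def k2p_distance(ltr5: str, ltr3: str, model: str = "k2p") -> tuple[float, float, float]:
    """Kimura two-parameter distance between two aligned sequences.

    Returns (P, Q, D) where P and Q are the transition and transversion
    proportions over comparable (both-ACGT) sites and
    D = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).  With ``model="jc"`` the
    Jukes–Cantor distance of the total mismatch proportion is returned in D
    instead (P and Q still reported).
    """
    a = ltr5.upper()
    b = ltr3.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n < 100:
        raise ValueError(f"only {n} comparable sites (< 100)")
    P, Q = ts / n, tv / n
    if model == "jc":
        p = P + Q
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError("JC distance undefined: p >= 3/4")
        return P, Q, -0.75 * math.log(arg)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2P distance undefined: divergence saturated")
    return P, Q, -0.5 * math.log(w1) - 0.25 * math.log(w2)


def insertion_time(
    element: LTRElement,
    clock: ClockParams = ClockParams(),
    model: str = "k2p",
) -> AgeEstimate:
    """Date one element: T = D / (2 mu)."""
    P, Q, D = k2p_distance(element.ltr5, element.ltr3, model=model)
    n = sum(
        1
        for x, y in zip(element.ltr5.upper(), element.ltr3.upper())
        if x in _VALID and y in _VALID
    )
    return AgeEstimate(
        element_id=element.element_id,
        P=P,
        Q=Q,
        D=D,
        T=D / (2.0 * clock.mu),
        n_sites=n,
    )


@dataclass
class AgeHistogram:
    """Binned insertion-age distribution plus the undateable remainder."""

    bin_edges: np.ndarray  # years, length n_bins + 1
    counts: np.ndarray  # dateable elements per bin
    n_older: int  # dateable but beyond the last edge
    n_saturated: int  # distance correction undefined
    ages: np.ndarray  # all dateable ages, years

    @property
    def n_total(self) -> int:
        return int(self.counts.sum()) + self.n_older + self.n_saturated

    @property
    def fractions(self) -> np.ndarray:
        """Per-bin fraction of all elements (bins + older + saturated sum to 1)."""
        return self.counts / self.n_total

    def window_fraction(self, lo_years: float, hi_years: float) -> float:
        """Fraction of dateable elements with lo <= age < hi."""
        if len(self.ages) == 0:
            return math.nan
        return float(np.mean((self.ages >= lo_years) & (self.ages < hi_years)))


def age_histogram(
    elements,
    bin_width: float = 4e6,
    max_age: float = 60e6,
    clock: ClockParams = ClockParams(),
    model: str = "k2p",
) -> AgeHistogram:
    """Insertion-age histogram over a cohort of elements.

    Elements whose distance correction is saturated are tallied separately;
    dateable ages beyond ``max_age`` land in the ``n_older`` class.
    """
    elements = list(elements)
    if not elements:
        raise ValueError("no elements supplied")
    ages = []
    n_sat = 0
    for el in elements:
        try:
            ages.append(insertion_time(el, clock=clock, model=model).T)
        except SaturationError:
            n_sat += 1
    ages = np.asarray(ages, dtype=float)
    edges = np.arange(0.0, max_age + bin_width, bin_width)
    in_range = ages[ages < edges[-1]]
    counts, _ = np.histogram(in_range, bins=edges)
    return AgeHistogram(
        bin_edges=edges,
        counts=counts,
        n_older=int((ages >= edges[-1]).sum()),
        n_saturated=n_sat,
        ages=ages,
    )
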