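"""Pairwise codon-level substitution statistics.

Implements the Nei–Gojobori (1986) counting approach to Ka/Ks estimation:
fractional synonymous/nonsynonymous site counting per codon, equal-weight
averaging over all mutational pathways between differing codons, and the
Jukes–Cantor multiple-hit correction.  Also computes the transversion
proportion at fourfold-degenerate third positions (4DTv), a complementary
divergence signal used to place whole-genome duplication events, and the
molecular-clock conversion from synonymous divergence to absolute time.

All per-codon quantities are precomputed as 64-entry (or 64x64) lookup
tables under the universal genetic code, so estimation over long alignments
reduces to vectorized table sums.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonPairAlignment",
    "SubstitutionEstimate",
    "ClockParams",
    "CodonPathwayError",
    "count_sites",
    "count_differences",
    "ng86",
    "fourdtv",
    "ks_to_age",
    "jc_correct",
    "jc_uncorrect",
    "synonymous_third_choices",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PURINES = frozenset("AG")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
_AA = dict(_STANDARD.forward_table)  # sense codons only


class CodonPathwayError(ValueError):
    """Raised when every mutational pathway between two codons crosses a stop."""


def _codon_index(codon: str) -> int:
    return (
        16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
    )


def _syn_site_count(codon: str) -> float:
    """Fractional synonymous sites of one codon.

    At each position the synonymous fraction is the number of single-base
    changes preserving the amino acid divided by the number of changes not
    producing a stop codon (mutations to stops are dropped from the
    denominator, the standard NG86 convention).
    """
    aa = _AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two codons.

    Enumerates all orderings of the differing positions, discards pathways
    whose intermediates are stop codons, classifies each single-base step as
    synonymous or not, and averages with equal weight.  Returns NaNs when no
    pathway avoids stops.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_totals = []
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA[current] == _AA[nxt]:
                syn += 1
            current = nxt
        if ok:
            syn_totals.append(syn)
    if not syn_totals:
        return math.nan, math.nan
    k = len(diff_pos)
    sd = sum(syn_totals) / len(syn_totals)
    return sd, k - sd


def _build_tables():
    syn_sites = np.full(64, np.nan)
    for codon in SENSE_CODONS:
        syn_sites[_codon_index(codon)] = _syn_site_count(codon)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            s, n = _pathway_counts(c1, c2)
            sd[_codon_index(c1), _codon_index(c2)] = s
            nd[_codon_index(c1), _codon_index(c2)] = n
    return syn_sites, sd, nd


_SYN_SITES, _PAIR_SD, _PAIR_ND = _build_tables()

# prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = frozenset(
    p
    for p in {c[:2] for c in SENSE_CODONS}
    if all(p + b in _AA for b in BASES)
    and len({_AA[p + b] for b in BASES}) == 1
)


def synonymous_third_choices(codon: str) -> str:
    """Third-position bases encoding the same amino acid as ``codon``.

    Includes the current base; used by the synthetic codon-pair generator to
    restrict evolution to synonymous third-position states.
    """
    aa = _AA[codon]
    prefix = codon[:2]
    return "".join(
        b for b in BASES if prefix + b in _AA and _AA[prefix + b] == aa
    )


@dataclass(frozen=True)
class CodonPairAlignment:
    """A gapless pair of coding sequences partitioned into codons."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    name_a: str = "seq_a"
    name_b: str = "seq_b"

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")
        for codons in (self.codons_a, self.codons_b):
            for i, c in enumerate(codons):
                if len(c) != 3 or any(b not in _BASE_INDEX for b in c):
                    raise ValueError(f"invalid codon {c!r} at position {i}")
                if c in STOP_CODONS:
                    raise ValueError(f"stop codon {c} at codon position {i + 1}")

    def __len__(self) -> int:
        return len(self.codons_a)

    @classmethod
    def from_sequences(cls, seq_a: str, seq_b: str, **kw) -> "CodonPairAlignment":
        seq_a, seq_b = seq_a.upper(), seq_b.upper()
        if len(seq_a) != len(seq_b):
            raise ValueError("sequences differ in length")
        if len(seq_a) % 3:
            raise ValueError("not codon-multiple: length % 3 != 0")
        split = lambda s: tuple(s[i : i + 3] for i in range(0, len(s), 3))
        return cls(split(seq_a), split(seq_b), **kw)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        ia = np.array([_codon_index(c) for c in self.codons_a], dtype=np.intp)
        ib = np.array([_codon_index(c) for c in self.codons_b], dtype=np.intp)
        return ia, ib


@dataclass
class SubstitutionEstimate:
    """NG86 site/difference counts and corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    fourdtv: float = math.nan
    n_4d_sites: int = 0
    ks_saturated: bool = False
    ka_saturated: bool = False

    @property
    def ka_ks(self) -> float:
        if not self.Ks or math.isnan(self.Ks) or math.isnan(self.Ka):
            return math.nan
        return self.Ka / self.Ks


@dataclass(frozen=True)
class ClockParams:
    """Neutral molecular-clock rate in substitutions per site per year.

    The default is the slow gymnosperm rate used for Taxus; rice-like
    angiosperm analyses use ~1.8e-8.
    """

    mu: float = 7.34573e-10

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")


def count_sites(pair: CodonPairAlignment) -> tuple[float, float]:
    """Synonymous (S) and nonsynonymous (N) site counts, S averaged over
    the two sequences and N = 3L - S."""
    ia, ib = pair.indices()
    S = float((_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum()) / 2.0)
    return S, 3.0 * len(pair) - S


def count_differences(
    pair: CodonPairAlignment, on_invalid: str = "raise"
) -> tuple[float, float]:
    """Synonymous (Sd) and nonsynonymous (Nd) differences, pathway-averaged.

    ``on_invalid`` controls codons for which every pathway crosses a stop:
    "raise" (default) or "skip" (drop the codon from both counts).
    """
    ia, ib = pair.indices()
    sd = _PAIR_SD[ia, ib]
    nd = _PAIR_ND[ia, ib]
    bad = np.isnan(sd)
    if bad.any():
        if on_invalid == "raise":
            idx = np.flatnonzero(bad)
            raise CodonPathwayError(
                "no stop-free mutational pathway for codon position(s) "
                + ", ".join(str(i + 1) for i in idx)
            )
        sd, nd = sd[~bad], nd[~bad]
    return float(np.nansum(sd)), float(np.nansum(nd))


def jc_correct(p: float) -> float:
    """Jukes–Cantor correction d = -3/4 ln(1 - 4p/3); NaN at saturation."""
    if math.isnan(p):
        return math.nan
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg) + 0.0  # avoid -0.0 at p == 0


def jc_uncorrect(d: float) -> float:
    """Expected proportion of differing sites at JC distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def fourdtv(pair: CodonPairAlignment) -> tuple[float, int]:
    """Transversion proportion at shared fourfold-degenerate third positions.

    A site qualifies when both codons have identical first two bases and that
    prefix is fourfold degenerate.  Returns (NaN, 0) when no site qualifies.
    The proportion is reported uncorrected.
    """
    n_sites = 0
    n_tv = 0
    for ca, cb in zip(pair.codons_a, pair.codons_b):
        if ca[:2] != cb[:2] or ca[:2] not in FOURFOLD_PREFIXES:
            continue
        n_sites += 1
        a3, b3 = ca[2], cb[2]
        if a3 != b3 and (a3 in PURINES) != (b3 in PURINES):
            n_tv += 1
    if n_sites == 0:
        return math.nan, 0
    return n_tv / n_sites, n_sites


def ng86(pair: CodonPairAlignment, on_invalid: str = "raise") -> SubstitutionEstimate:
    """Full NG86 estimate (with 4DTv) for one codon pair alignment."""
    S, N = count_sites(pair)
    Sd, Nd = count_differences(pair, on_invalid=on_invalid)
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    Ks = jc_correct(pS)
    Ka = jc_correct(pN)
    tv, n4 = fourdtv(pair)
    return SubstitutionEstimate(
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        fourdtv=tv,
        n_4d_sites=n4,
        ks_saturated=bool(not math.isnan(pS) and pS >= 0.75),
        ka_saturated=bool(not math.isnan(pN) and pN >= 0.75),
    )


def ks_to_age(ks: float, clock: ClockParams = ClockParams()) -> float:
    """Convert synonymous divergence to an age in years via T = Ks / (2 mu)."""
    if ks is None or math.isnan(ks):
        raise ValueError("Ks is saturated or undefined; cannot date")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * clock.mu)
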