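"""Whole-genome duplication signatures from paralog divergence distributions.

Builds a paralogous gene-pair set by reciprocal-best-hit filtering of an
all-vs-all protein similarity table (E-value <= 1e-5, c-score >= 0.3,
alignment length >= 100 aa), computes per-pair synonymous divergence (Ks)
and 4DTv from codon alignments, and locates density peaks: a shared peak
(e.g. near Ks ~ 2.1 / 4DTv ~ 0.7 in Taxus paralogues) marks an ancient WGD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import codon_evol
from .codon_evol import CodonPairAlignment

__all__ = [
    "ParalogPair",
    "PeakReport",
    "rbh_pairs",
    "kde_peaks",
    "ks_distribution",
    "fourdtv_distribution",
]

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_C_MIN = 0.3
DEFAULT_ALN_MIN = 100
MIN_VALUES_FOR_PEAKS = 10


@dataclass(frozen=True)
class ParalogPair:
    """An unordered paralogous gene pair surviving the RBH filters."""

    gene_a: str
    gene_b: str
    bitscore: float
    evalue: float
    aln_length: float
    c_score: float
    source: str = "rbh"

    def __post_init__(self):
        if not (0.0 <= self.c_score <= 1.0 + 1e-12):
            raise ValueError(f"c_score {self.c_score} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class PeakReport:
    """Density-estimate peaks of a divergence value distribution."""

    values: np.ndarray
    kde_bandwidth: float
    peaks: list[tuple[float, float]]  # (location, density), descending density
    bin_width: float = 0.05
    n_excluded: int = 0  # saturated / undefined values left out

    @property
    def top_peak(self) -> float:
        return self.peaks[0][0]

    def peak_near(self, location: float, tol: float | None = None) -> bool:
        """True when some detected peak lies within ``tol`` of ``location``
        (default tolerance: the KDE bandwidth)."""
        tol = self.kde_bandwidth if tol is None else tol
        return any(abs(loc - location) <= tol for loc, _ in self.peaks)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best non-self hit per query: highest bitscore, ties by lower evalue
    then lexicographic subject id."""
    nonself = hits[hits["query"] != hits["subject"]]
    ranked = nonself.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ranked.groupby("query", sort=False).first().reset_index()


def rbh_pairs(
    hits: pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    c_min: float = DEFAULT_C_MIN,
    aln_min: float = DEFAULT_ALN_MIN,
) -> list[ParalogPair]:
    """Reciprocal-best-hit paralog pairs under the three similarity filters.

    Self-hits are removed before ranking; the c-score denominator is the
    query's best non-self bitscore.  A pair is kept iff each gene is the
    other's best hit and the connecting hit passes E-value, c-score and
    alignment-length thresholds.
    """
    if hits.empty:
        return []
    best = _best_hits(hits)
    best_of = dict(zip(best["query"], best["subject"]))
    best_score = dict(zip(best["query"], best["bitscore"]))
    pairs: dict[tuple[str, str], ParalogPair] = {}
    for row in best.itertuples(index=False):
        q, s = row.query, row.subject
        if best_of.get(s) != q:
            continue
        c_score = row.bitscore / best_score[q] if best_score[q] > 0 else 0.0
        if row.evalue > evalue_max or c_score < c_min or row.aln_length < aln_min:
            continue
        key = tuple(sorted((q, s)))
        if key not in pairs:
            pairs[key] = ParalogPair(
                gene_a=key[0],
                gene_b=key[1],
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
                aln_length=float(row.aln_length),
                c_score=min(float(c_score), 1.0),
            )
    return [pairs[k] for k in sorted(pairs)]


def kde_peaks(
    values: Sequence[float],
    bin_width: float = 0.05,
    grid_size: int = 512,
    n_excluded: int = 0,
) -> PeakReport:
    """Gaussian-KDE peak report for a divergence value sample.

    Uses Silverman's bandwidth; peaks are local maxima of the density on a
    regular grid spanning the data (endpoints included so a boundary mode,
    e.g. a pile-up at 0, is still reported), ordered by descending density.
    """
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size < MIN_VALUES_FOR_PEAKS:
        raise ValueError(
            f"peak detection refused: {arr.size} finite values "
            f"(< {MIN_VALUES_FOR_PEAKS})"
        )
    if np.ptp(arr) == 0.0:
        # degenerate sample: a single atom is its own peak
        return PeakReport(
            values=arr,
            kde_bandwidth=0.0,
            peaks=[(float(arr[0]), math.inf)],
            bin_width=bin_width,
            n_excluded=n_excluded,
        )
    kde = gaussian_kde(arr, bw_method="silverman")
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    lo, hi = arr.min(), arr.max()
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    idx = list(np.flatnonzero(interior) + 1)
    if dens[0] > dens[1]:
        idx.append(0)
    if dens[-1] > dens[-2]:
        idx.append(grid_size - 1)
    peaks = sorted(
        ((float(grid[i]), float(dens[i])) for i in idx),
        key=lambda t: -t[1],
    )
    return PeakReport(
        values=arr,
        kde_bandwidth=bandwidth,
        peaks=peaks,
        bin_width=bin_width,
        n_excluded=n_excluded,
    )


def _divergence_distribution(pairs, alignments, metric: str, bin_width: float):
    if not pairs:
        raise ValueError("empty pair set: nothing to estimate")
    values = []
    n_excluded = 0
    for pair in pairs:
        aln = alignments[pair.key] if pair.key in alignments else alignments[
            (pair.gene_a, pair.gene_b)
        ]
        est = codon_evol.ng86(aln)
        v = est.Ks if metric == "ks" else est.fourdtv
        if v is None or math.isnan(v):
            n_excluded += 1
        else:
            values.append(v)
    return kde_peaks(values, bin_width=bin_width, n_excluded=n_excluded)


def ks_distribution(
    pairs: Sequence[ParalogPair],
    alignments: Mapping[tuple[str, str], CodonPairAlignment],
    bin_width: float = 0.05,
) -> PeakReport:
    """Per-pair NG86 Ks distribution with KDE peaks; saturated pairs are
    excluded and counted in ``n_excluded``."""
    return _divergence_distribution(pairs, alignments, "ks", bin_width)


def fourdtv_distribution(
    pairs: Sequence[ParalogPair],
    alignments: Mapping[tuple[str, str], CodonPairAlignment],
    bin_width: float = 0.05,
) -> PeakReport:
    """Per-pair 4DTv distribution with KDE peaks; pairs without qualifying
    fourfold-degenerate sites are excluded."""
    return _divergence_distribution(pairs, alignments, "4dtv", bin_width)
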