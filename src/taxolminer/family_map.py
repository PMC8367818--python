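"""CYP450-style family classification and physical gene grouping.

Classification follows the standard cytochrome-P450 identity ladder (97% /
55% / 40% for allelic, subfamily and family variants).  Physical grouping
chains family-filtered genes along each chromosome while the intergenic gap
stays within a threshold (default 5.26 Mb) and keeps chains with at least a
minimum number of members (default 7) — the criteria used to call the 25
CYP450 groups on the Taxus pseudochromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GeneLocus, get_logger

__all__ = [
    "ClassificationRule",
    "Assignment",
    "GeneGroup",
    "classify_by_identity",
    "detect_groups",
    "chromosome_distribution",
    "family_aggregation",
]

_LOG = get_logger(__name__)

DEFAULT_MAX_GAP = 5_260_000  # bp
DEFAULT_MIN_SIZE = 7


@dataclass(frozen=True)
class ClassificationRule:
    """Percent-identity cutoffs for allele / subfamily / family assignment."""

    allele_min: float = 97.0
    subfamily_min: float = 55.0
    family_min: float = 40.0

    def __post_init__(self):
        if not (self.allele_min > self.subfamily_min > self.family_min):
            raise ValueError("cutoffs must satisfy allele > subfamily > family")


@dataclass(frozen=True)
class Assignment:
    query_id: str
    level: str  # allele-of | subfamily-of | family-of | unclassified
    reference: str | None
    identity: float


@dataclass(frozen=True)
class GeneGroup:
    """A physically chained run of same-set genes on one chromosome."""

    label: str  # "<chrom>.<k>" in coordinate order
    chrom: str
    members: tuple[GeneLocus, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, max(m.end for m in self.members)

    @property
    def n_families(self) -> int:
        return len({m.family for m in self.members})


def classify_by_identity(
    query_id: str,
    identities: Sequence[tuple[str, float]],
    rule: ClassificationRule = ClassificationRule(),
) -> Assignment:
    """Assign a query to the best reference by the identity ladder.

    ``identities`` lists (reference name, % identity).  The best-identity
    reference wins (ties broken by reference name); >= 97% makes the query an
    allelic variant, >= 55% the same subfamily, >= 40% the same family, and
    anything lower is unclassified — a candidate new family.
    """
    if not identities:
        _LOG.warning("%s: empty identity table -> unclassified", query_id)
        return Assignment(query_id, "unclassified", None, float("nan"))
    ref, ident = min(identities, key=lambda t: (-t[1], t[0]))
    if ident >= rule.allele_min:
        level = "allele-of"
    elif ident >= rule.subfamily_min:
        level = "subfamily-of"
    elif ident >= rule.family_min:
        level = "family-of"
    else:
        return Assignment(query_id, "unclassified", None, ident)
    return Assignment(query_id, level, ref, ident)


def detect_groups(
    loci: Iterable[GeneLocus],
    family_filter: Iterable[str] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[GeneGroup]:
    """Detect physical gene groups by single-linkage gap chaining.

    Per chromosome, the family-filtered genes sorted by start are chained
    while the intergenic gap (next.start - current.end, floored at 0 for
    overlaps) is <= ``max_gap``; chains with >= ``min_size`` members become
    groups labelled "<chrom>.<k>" in coordinate order.  Strand is ignored.
    """
    fam = set(family_filter) if family_filter is not None else None
    selected = [g for g in loci if fam is None or g.family in fam]
    groups: list[GeneGroup] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in selected:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        chains: list[list[GeneLocus]] = []
        current = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            gap = max(0, nxt.start - prev.end)
            if gap <= max_gap:
                current.append(nxt)
            else:
                chains.append(current)
                current = [nxt]
        chains.append(current)
        k = 0
        for chain in chains:
            if len(chain) >= min_size:
                k += 1
                groups.append(GeneGroup(f"{chrom}.{k}", chrom, tuple(chain)))
    return groups


def chromosome_distribution(
    loci: Iterable[GeneLocus], family: str
) -> pd.DataFrame:
    """Per-chromosome counts and percentages for one family label.

    Percentages are 100 * count / family total, rounded to 2 decimals.
    Returns an empty table if the family is absent.
    """
    members = [g for g in loci if g.family == family]
    if not members:
        return pd.DataFrame(columns=["chrom", "count", "percent"])
    counts = pd.Series([g.chrom for g in members]).value_counts().sort_index()
    total = counts.sum()
    return pd.DataFrame(
        {
            "chrom": counts.index,
            "count": counts.values,
            "percent": (100.0 * counts.values / total).round(2),
        }
    ).reset_index(drop=True)


def family_aggregation(groups: Sequence[GeneGroup]) -> dict:
    """Distinct-family counts per group plus aggregation summary.

    Returns per-group counts and how many groups contain exactly one family
    and at most three families.
    """
    per_group = {g.label: g.n_families for g in groups}
    return {
        "per_group": per_group,
        "n_groups": len(groups),
        "n_single_family": sum(1 for v in per_group.values() if v == 1),
        "n_at_most_three": sum(1 for v in per_group.values() if v <= 3),
    }
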