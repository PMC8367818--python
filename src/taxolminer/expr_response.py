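"""Expression-level summaries: RPKM, up/down calls, group response scores.

A gene group's jasmonate response is summarised two ways, following the
group-level profiling of the CYP450 groups: the sum of member RPKM values,
and a response score adding +1 for each upregulated and -1 for each
downregulated member.  Also provides the qPCR 2^(-ddCt) fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DirectionCall",
    "GroupProfile",
    "rpkm",
    "rpkm_matrix",
    "mean_rpkm",
    "call_direction",
    "group_profile",
    "ddct_fold_change",
]

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class DirectionCall:
    gene_id: str
    log2fc: float
    call: int  # +1 up, -1 down, 0 unchanged


@dataclass(frozen=True)
class GroupProfile:
    label: str
    sum_expression: float  # sum of member RPKM (treated condition)
    response_score: int  # sum of member +-1 calls
    n_members: int


def rpkm(
    counts: pd.Series, gene_lengths: pd.Series, library_size: float | None = None
) -> pd.Series:
    """Reads per kilobase per million mapped reads for one sample.

    RPKM = 1e9 * count / (length_bp * total_mapped_reads).  When
    ``library_size`` is omitted the column sum of ``counts`` is used.
    """
    if library_size is None:
        library_size = float(counts.sum())
    if library_size <= 0:
        raise ValueError("library size must be positive")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"genes without lengths: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return 1e9 * counts / (lengths * library_size)


def rpkm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Per-column RPKM with per-sample library size = column sum."""
    return counts.apply(lambda col: rpkm(col, gene_lengths))


def mean_rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, columns: Sequence[str]
) -> pd.Series:
    """Replicate-mean RPKM over the given sample columns."""
    if not len(columns):
        raise ValueError("no sample columns given")
    return rpkm_matrix(counts[list(columns)], gene_lengths).mean(axis=1)


def call_direction(
    gene_id: str,
    rpkm_treated: float,
    rpkm_control: float,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DirectionCall:
    """+-1 direction call from pseudocounted RPKM fold change.

    log2fc = log2((treated + pc) / (control + pc)); the call is +1 when
    log2fc exceeds log2(fc_threshold), -1 below the negative threshold,
    else 0.
    """
    if rpkm_treated < 0 or rpkm_control < 0:
        raise ValueError("RPKM must be non-negative")
    log2fc = math.log2((rpkm_treated + pseudocount) / (rpkm_control + pseudocount))
    cut = math.log2(fc_threshold)
    call = 1 if log2fc > cut else (-1 if log2fc < -cut else 0)
    return DirectionCall(gene_id, log2fc, call)


def call_directions(
    rpkm_treated: pd.Series,
    rpkm_control: pd.Series,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, DirectionCall]:
    """Vector version of :func:`call_direction` over a shared gene index."""
    return {
        g: call_direction(
            g, rpkm_treated[g], rpkm_control[g], fc_threshold, pseudocount
        )
        for g in rpkm_treated.index
    }


def group_profile(
    group,
    calls: Mapping[str, DirectionCall],
    rpkm_treated: pd.Series,
) -> GroupProfile:
    """Group response score (sum of calls) and expression sum (sum of RPKM).

    ``group`` is a :class:`~taxolminer.family_map.GeneGroup`; every member
    must appear in both tables.
    """
    ids = [m.gene_id for m in group.members]
    missing = [g for g in ids if g not in calls or g not in rpkm_treated.index]
    if missing:
        raise KeyError(f"group {group.label}: members missing from expression: {missing}")
    score = int(sum(calls[g].call for g in ids))
    total = float(rpkm_treated[ids].sum())
    return GroupProfile(
        label=group.label,
        sum_expression=total,
        response_score=score,
        n_members=len(ids),
    )


def ddct_fold_change(delta_delta_ct: float) -> float:
    """qPCR relative expression: fold change = 2^(-ddCt)."""
    if not math.isfinite(delta_delta_ct):
        raise ValueError("ddCt must be finite")
    return 2.0 ** (-delta_delta_ct)
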