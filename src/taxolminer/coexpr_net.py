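"""Three-round subtraction screening and anchor-gene coexpression network.

The screen that surfaced the candidate paclitaxel-pathway genes:

1. keep genes more highly expressed in root or bark than in leaf;
2. keep genes significantly higher in the high-yield (HC) than the low-yield
   (LC) cell line (log2FC > 1, Benjamini-Hochberg FDR < 0.05);
3. keep candidates whose expression over the 5-point methyl-jasmonate time
   course (0, 2, 4, 8, 24 h) correlates with a known pathway anchor gene
   (two-sided Pearson t-test, P < 0.05).

The round-2 differential test is a negative-binomial Wald test on
library-size-normalised counts with a method-of-moments common dispersion
(exact conditional binomial when the data look Poisson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionStudy, get_logger
from .expr_response import mean_rpkm

__all__ = [
    "DEResult",
    "CorrEdge",
    "round1_tissue_filter",
    "round2_hc_lc_de",
    "round3_anchor_correlation",
    "build_network",
    "bh_adjust",
    "pearson_pvalue",
]

_LOG = get_logger(__name__)

MEJA_TIMEPOINTS = (0.0, 2.0, 4.0, 8.0, 24.0)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float  # HC over LC
    pvalue: float
    fdr: float


@dataclass(frozen=True)
class CorrEdge:
    anchor_id: str
    candidate_id: str
    r: float
    pvalue: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def round1_tissue_filter(
    study: ExpressionStudy,
    floor: float = 1.0,
) -> set[str]:
    """Round 1: genes higher in root or bark than in leaf.

    Uses replicate-mean RPKM per tissue; a gene passes when
    mean(root) > mean(leaf) or mean(bark) > mean(leaf) and its best tissue
    mean reaches the expression floor (default RPKM >= 1).
    """
    means = {}
    for tissue in ("root", "bark", "leaf"):
        cols = study.columns_for(tissue=tissue)
        if not cols:
            raise ValueError(f"no samples for tissue {tissue!r}")
        means[tissue] = mean_rpkm(study.counts, study.gene_lengths, cols)
    best = pd.concat(means.values(), axis=1).max(axis=1)
    keep = (
        ((means["root"] > means["leaf"]) | (means["bark"] > means["leaf"]))
        & (best >= floor)
    )
    return set(keep.index[keep])


def _common_dispersion(scaled: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Method-of-moments NB dispersion pooled across genes.

    On counts scaled to a common library size the Poisson variance is ~mean,
    so phi_g = (pooled within-group variance - mean) / mean^2; the common
    value is the median over genes with adequate counts, floored at 0.
    """
    phis = []
    for row in scaled:
        num = 0.0
        den = 0
        mean_all = []
        for idx in groups:
            y = row[idx]
            if len(y) < 2:
                continue
            num += ((y - y.mean()) ** 2).sum()
            den += len(y) - 1
            mean_all.append(y.mean())
        if den == 0 or not mean_all:
            continue
        m = float(np.mean(mean_all))
        if m < 5.0:
            continue
        s2 = num / den
        phis.append(max(0.0, (s2 - m) / m**2))
    if not phis:
        return 0.0
    return float(np.median(phis))


def round2_hc_lc_de(
    study: ExpressionStudy,
    logfc_min: float = 1.0,
    fdr_max: float = 0.05,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Round 2: HC-vs-LC differential expression on raw counts.

    Counts are scaled to the geometric-mean library size; per gene a Wald
    test on the log mean ratio uses NB variance (1/(n*m) + phi/n per group)
    with the pooled method-of-moments dispersion.  When the pooled
    dispersion is ~0, an exact conditional binomial test on the summed
    counts replaces the Wald test.  P-values are BH-adjusted across tested
    genes; survivors satisfy log2fc > ``logfc_min`` (HC over LC) and
    fdr < ``fdr_max``.

    Returns a DataFrame (gene_id, log2fc, pvalue, fdr, survivor); all-zero
    genes are excluded from testing and reported with NaN p-values.
    """
    hc_cols = study.columns_for(line="HC")
    lc_cols = study.columns_for(line="LC", treatment="control")
    if not lc_cols:
        lc_cols = study.columns_for(line="LC")
    if len(hc_cols) < 2 or len(lc_cols) < 2:
        raise ValueError("need >= 2 replicates per cell line")

    counts = study.counts
    if genes is not None:
        counts = counts.loc[[g for g in genes if g in counts.index]]
    cols = list(hc_cols) + list(lc_cols)
    sub = counts[cols].to_numpy(dtype=float)
    lib = study.counts[cols].sum(axis=0).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(lib))))
    scaled = sub * (common / lib)

    idx_hc = np.arange(len(hc_cols))
    idx_lc = np.arange(len(hc_cols), len(cols))
    nonzero = sub.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        _LOG.info("round 2: %d all-zero gene(s) excluded from testing", n_dropped)

    phi = _common_dispersion(scaled[nonzero], [idx_hc, idx_lc])
    pc = 0.5  # pseudo-count on the common-library scale
    m_hc = scaled[:, idx_hc].mean(axis=1)
    m_lc = scaled[:, idx_lc].mean(axis=1)
    log2fc = np.log2((m_hc + pc) / (m_lc + pc))

    pvals = np.full(scaled.shape[0], np.nan)
    if phi < 1e-8:
        # Poisson-like: exact conditional binomial on summed counts
        frac_hc = len(hc_cols) / len(cols)
        for i in np.flatnonzero(nonzero):
            total = int(round(sub[i].sum()))
            hc_total_scaled = scaled[i, idx_hc].sum()
            all_scaled = scaled[i].sum()
            k = int(round(total * hc_total_scaled / all_scaled)) if all_scaled else 0
            pvals[i] = stats.binomtest(k, total, frac_hc).pvalue
    else:
        lnfc = np.log(m_hc + pc) - np.log(m_lc + pc)
        var = (
            1.0 / (len(hc_cols) * (m_hc + pc))
            + phi / len(hc_cols)
            + 1.0 / (len(lc_cols) * (m_lc + pc))
            + phi / len(lc_cols)
        )
        z = lnfc / np.sqrt(var)
        pvals = np.where(nonzero, 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    fdr = np.full_like(pvals, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        fdr[tested] = bh_adjust(pvals[tested])

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
        }
    )
    out["survivor"] = (out["log2fc"] > logfc_min) & (out["fdr"] < fdr_max)
    return out


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation: t = r sqrt(n-2)/sqrt(1-r^2),
    df = n - 2."""
    if n < 3:
        raise ValueError("need at least 3 points")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def _timecourse_matrix(study: ExpressionStudy) -> pd.DataFrame:
    """Replicate-mean RPKM per MeJA time point (genes x 5 columns)."""
    cols_by_time = {}
    for t in MEJA_TIMEPOINTS:
        cols = study.columns_for(treatment="MeJA", time_h=t)
        if not cols:
            raise ValueError(f"no MeJA samples at {t} h")
        cols_by_time[t] = cols
    return pd.DataFrame(
        {
            t: mean_rpkm(study.counts, study.gene_lengths, cols)
            for t, cols in cols_by_time.items()
        }
    )


def round3_anchor_correlation(
    timecourse: pd.DataFrame | ExpressionStudy,
    anchors: Sequence[str],
    candidates: Sequence[str],
    p_max: float = 0.05,
) -> list[CorrEdge]:
    """Round 3: anchor-candidate Pearson correlation over the time course.

    ``timecourse`` is a genes x time-points matrix of replicate-mean
    expression (an :class:`ExpressionStudy` is reduced to one automatically).
    Pairs with a two-sided P < ``p_max`` survive.  Zero-variance series are
    skipped with a log message.
    """
    if isinstance(timecourse, ExpressionStudy):
        timecourse = _timecourse_matrix(timecourse)
    n = timecourse.shape[1]
    edges = []
    for anchor in anchors:
        if anchor not in timecourse.index:
            raise KeyError(f"anchor {anchor} absent from time-course matrix")
        x = timecourse.loc[anchor].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            _LOG.info("anchor %s has zero-variance series; skipped", anchor)
            continue
        for cand in candidates:
            if cand == anchor or cand not in timecourse.index:
                continue
            y = timecourse.loc[cand].to_numpy(dtype=float)
            if np.ptp(y) == 0.0:
                _LOG.info("candidate %s has zero-variance series; skipped", cand)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            p = pearson_pvalue(r, n)
            if p < p_max:
                edges.append(CorrEdge(anchor, cand, r, p))
    return edges


def build_network(
    edges: Sequence[CorrEdge],
    de_survivors: Sequence[str] | None = None,
    annotations: Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Assemble the coregulation network from round-3 edges.

    Nodes are anchors plus surviving candidates (optionally intersected with
    the round-2 survivor set); node attributes carry any annotation fields
    supplied (family, TF flag, transferase flag, ...).  Parallel anchor
    correlations become distinct edges of a simple graph.
    """
    survivors = set(de_survivors) if de_survivors is not None else None
    g = nx.Graph()
    for e in edges:
        if survivors is not None and e.candidate_id not in survivors:
            continue
        g.add_node(e.anchor_id, role="anchor")
        if "role" not in g.nodes.get(e.candidate_id, {}):
            g.add_node(e.candidate_id, role="candidate")
        g.add_edge(e.anchor_id, e.candidate_id, r=e.r, pvalue=e.pvalue)
    if annotations:
        for node in g.nodes:
            for key, value in annotations.get(node, {}).items():
                g.nodes[node][key] = value
    return g
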