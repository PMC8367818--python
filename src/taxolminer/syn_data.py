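"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators make the whole pipeline testable without any downloads:

* gene layouts with physically clustered family members planted among
  uniformly placed background genes (group detection truth);
* codon pair alignments whose expected NG86 synonymous divergence equals a
  requested Ks, with true Ka = 0 by construction (only synonymous
  third-position states evolve, under a symmetric Jukes-Cantor-style
  within-set exchange);
* LTR pairs of known insertion age evolved independently under the Kimura
  two-parameter model at a specified clock rate;
* negative-binomial RNA-seq counts over the study design — three tissues
  (root/leaf/bark), two half-sib cell lines (HC/LC) and a 5-point methyl
  jasmonate time course, three replicates throughout — with planted tissue
  and line effects and a shared latent MeJA trajectory linking anchor genes
  to their true coregulation partners.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .codon_evol import (
    CodonPairAlignment,
    SENSE_CODONS,
    count_sites,
    jc_uncorrect,
    synonymous_third_choices,
)
from .formats_io import ExpressionStudy, GeneLocus
from .ltr_clock import LTRElement

__all__ = [
    "LayoutSpec",
    "PlantedGroup",
    "ExprDesign",
    "simulate_layout",
    "simulate_codon_pair",
    "simulate_ltr_pair",
    "simulate_expression",
]

_BASES = "ACGT"
_PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transitions


# ---------------------------------------------------------------------------
# gene layouts


@dataclass(frozen=True)
class PlantedGroup:
    chrom: str
    n_members: int
    max_internal_gap: int  # bp
    family: str | tuple[str, ...] = "CYP725A"

    def families(self) -> tuple[str, ...]:
        fams = self.family if isinstance(self.family, tuple) else (self.family,)
        return fams


@dataclass(frozen=True)
class LayoutSpec:
    chrom_lengths: dict[str, int]
    n_background_genes: int = 100
    planted_groups: tuple[PlantedGroup, ...] = ()
    background_family: str = "CYP_other"
    gene_length: int = 3000
    seed: int = 0


def _place_group(
    rng: np.random.Generator, spec: LayoutSpec, planted: PlantedGroup, k: int
) -> list[GeneLocus]:
    chrom_len = spec.chrom_lengths[planted.chrom]
    gaps = rng.integers(
        low=planted.max_internal_gap // 5,
        high=planted.max_internal_gap + 1,
        size=max(planted.n_members - 1, 0),
    )
    span = planted.n_members * spec.gene_length + int(gaps.sum())
    if span >= chrom_len:
        raise ValueError(
            f"planted group of {planted.n_members} does not fit on "
            f"{planted.chrom} ({span} bp needed, {chrom_len} available)"
        )
    start = int(rng.integers(1, chrom_len - span))
    fams = planted.families()
    loci = []
    pos = start
    for m in range(planted.n_members):
        loci.append(
            GeneLocus(
                gene_id=f"planted_{k}_{m}",
                chrom=planted.chrom,
                start=pos,
                end=pos + spec.gene_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                family=fams[m % len(fams)],
            )
        )
        if m < planted.n_members - 1:
            pos += spec.gene_length + int(gaps[m])
    return loci


def simulate_layout(spec: LayoutSpec) -> list[GeneLocus]:
    """Gene layout with planted physical groups among background genes.

    Background genes are placed uniformly without overlap (rejection
    sampling, proportional to chromosome length); each planted group's
    internal gaps are drawn within its ``max_internal_gap`` so the group
    satisfies the chaining criterion by construction.  Planted regions are
    kept disjoint; background genes may fall anywhere (they carry a
    different family label, so family-filtered grouping is unaffected).
    """
    rng = np.random.default_rng(spec.seed)
    loci: list[GeneLocus] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}

    for k, planted in enumerate(spec.planted_groups, start=1):
        if planted.chrom not in spec.chrom_lengths:
            raise ValueError(f"unknown chromosome {planted.chrom}")
        for _ in range(200):
            group = _place_group(rng, spec, planted, k)
            lo, hi = group[0].start, group[-1].end
            if all(hi < a or lo > b for a, b in occupied[planted.chrom]):
                occupied[planted.chrom].append((lo, hi))
                loci.extend(group)
                break
        else:
            raise ValueError(f"could not place planted group {k} without overlap")

    chroms = list(spec.chrom_lengths)
    weights = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for c in chroms:
        taken[c] = [(g.start, g.end) for g in loci if g.chrom == c]
    for i in range(spec.n_background_genes):
        for attempt in range(1000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            chrom_len = spec.chrom_lengths[chrom]
            if chrom_len <= spec.gene_length + 2:
                continue
            start = int(rng.integers(1, chrom_len - spec.gene_length))
            end = start + spec.gene_length - 1
            if all(end < a or start > b for a, b in taken[chrom]):
                taken[chrom].append((start, end))
                loci.append(
                    GeneLocus(
                        gene_id=f"bg_{i}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                        family=spec.background_family,
                    )
                )
                break
        else:
            raise ValueError("infeasible packing: could not place background genes")
    return sorted(loci, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# codon pairs at a target Ks


def _syn_category_sizes(codons: Sequence[str]) -> np.ndarray:
    """Size of the synonymous third-position state set per codon (1, 2, 3 or 4)."""
    return np.array([len(synonymous_third_choices(c)) for c in codons])


def _p_diff(m: np.ndarray, theta: float) -> np.ndarray:
    """P(two states differ) for a symmetric m-state exchange after 'time'
    theta (expected number of each specific substitution)."""
    return (m - 1) / m * (1.0 - np.exp(-m * theta))


def simulate_codon_pair(
    n_codons: int,
    target_ks: float,
    seed: int,
    rng: np.random.Generator | None = None,
) -> CodonPairAlignment:
    """Codon pair whose expected NG86 Ks equals ``target_ks``.

    The ancestor is drawn uniformly over sense codons.  Only synonymous
    third-position states evolve: at each site the base moves within its
    synonymous state set (fourfold, threefold, twofold or fixed) under a
    symmetric exchange process whose intensity theta is solved so that the
    expected synonymous difference count over the expected synonymous sites
    matches the Jukes-Cantor-uncorrected target.  Nonsynonymous positions
    never change, so the true Ka is exactly 0.

    Raises ValueError when ``target_ks`` exceeds what the alignment's
    synonymous-site composition can express before saturation.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if not math.isfinite(target_ks):
        raise ValueError("target_ks beyond JC saturation: corrected distance undefined")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    if target_ks == 0:
        return CodonPairAlignment(tuple(ancestor), tuple(ancestor))

    pair0 = CodonPairAlignment(tuple(ancestor), tuple(ancestor))
    s_sites, _ = count_sites(pair0)
    m = _syn_category_sizes(ancestor)
    p_target = jc_uncorrect(target_ks)  # expected Sd / S
    p_max = float(_p_diff(m.astype(float), np.inf).sum() / s_sites)
    expected_sd = lambda theta: float(_p_diff(m.astype(float), theta).sum())
    if p_target >= p_max:
        raise ValueError(
            f"target_ks {target_ks} beyond saturation for this alignment "
            f"(max expected pS {p_max:.3f})"
        )
    theta = brentq(lambda t: expected_sd(t) / s_sites - p_target, 0.0, 200.0)

    derived = []
    p_site = _p_diff(m.astype(float), theta)
    u = rng.random(n_codons)
    for i, codon in enumerate(ancestor):
        choices = synonymous_third_choices(codon)
        if len(choices) > 1 and u[i] < p_site[i]:
            others = [b for b in choices if b != codon[2]]
            new_base = others[rng.integers(0, len(others))]
            derived.append(codon[:2] + new_base)
        else:
            derived.append(codon)
    return CodonPairAlignment(tuple(ancestor), tuple(derived))


# ---------------------------------------------------------------------------
# LTR pairs of known age


def _k2p_transition_probs(t_years: float, mu: float, kappa: float):
    """K2P substitution probabilities after ``t_years`` at total rate ``mu``.

    ``kappa`` is the transition:transversion *rate* ratio alpha/beta; the
    total rate alpha + 2 beta equals mu so that divergence accumulates at
    mu substitutions per site per year.
    """
    beta = mu / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t_years)
    e2 = math.exp(-2.0 * (alpha + beta) * t_years)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def _evolve_k2p(
    seq: np.ndarray, t_years: float, mu: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an A/C/G/T integer sequence (A=0,G=1,C=2,T=3) for t_years."""
    p_same, p_ts, p_tv = _k2p_transition_probs(t_years, mu, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    transition = (u >= p_same) & (u < p_same + p_ts)
    out[transition] ^= 1  # A<->G, C<->T within the (0,1)/(2,3) encoding
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2 = u >= p_same + p_ts + p_tv
    out[tv1] = (seq[tv1] + 2) % 4  # cross purine/pyrimidine
    out[tv2] = ((seq[tv2] ^ 1) + 2) % 4
    return out


_INT_TO_BASE = np.array(list("AGCT"))


def simulate_ltr_pair(
    length: int,
    age: float,
    mu: float = 7.34573e-10,
    seed: int = 0,
    kappa: float = 2.0,
    element_id: str = "ltr",
    rng: np.random.Generator | None = None,
) -> LTRElement:
    """Two LTR copies of known insertion age.

    A random ancestral repeat is copied and each copy evolved independently
    for ``age`` years under K2P (transition:transversion rate ratio
    ``kappa``), so the expected pairwise divergence is D = 2 * mu * age.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if age < 0:
        raise ValueError("age must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length)
    ltr5 = _evolve_k2p(ancestor, age, mu, kappa, rng)
    ltr3 = _evolve_k2p(ancestor, age, mu, kappa, rng)
    return LTRElement(
        element_id=element_id,
        ltr5="".join(_INT_TO_BASE[ltr5]),
        ltr3="".join(_INT_TO_BASE[ltr3]),
    )


# ---------------------------------------------------------------------------
# RNA-seq counts over the study design


@dataclass(frozen=True)
class ExprDesign:
    """Parameters of the synthetic RNA-seq study.

    Effects are log2 fold changes applied multiplicatively to the
    negative-binomial mean.  ``tissue_log2_effects`` raises root and bark
    over leaf for the listed genes; ``hc_lc_log2_effect`` raises HC over LC;
    ``meja_profile`` is the shared latent log2 trajectory (5 time points)
    followed by every anchor gene and every designated true partner, each
    with independent per-gene noise of sd ``profile_noise_sd``.
    """

    n_genes: int = 2000
    library_size: float = 2e6
    dispersion: float = 0.1
    tissue_log2_effects: dict[str, float] = field(default_factory=dict)
    hc_lc_log2_effect: dict[str, float] = field(default_factory=dict)
    anchor_ids: tuple[str, ...] = ()
    partner_ids: tuple[str, ...] = ()
    meja_profile: tuple[float, ...] = (0.0, 1.5, 2.5, 2.0, 0.5)
    profile_noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.meja_profile) != 5:
            raise ValueError("meja_profile must have 5 time points")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


_MEJA_TIMES = (0.0, 2.0, 4.0, 8.0, 24.0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(design: ExprDesign) -> ExpressionStudy:
    """Negative-binomial counts over tissues, cell lines and the MeJA course.

    Sample layout (``n_replicates`` each): root/leaf/bark tissue panels,
    HC and LC cell lines, and MeJA-treated LC at 0, 2, 4, 8 and 24 h.
    Counts are NB(mean = library_size * relative abundance * 2^effects,
    dispersion); baseline relative abundances are log-normal.  Anchors and
    their true partners follow the latent MeJA trajectory; all other genes
    stay flat over the time course apart from sampling noise.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    for gid in (*design.anchor_ids, *design.partner_ids):
        if gid not in genes:
            raise ValueError(f"anchor/partner {gid} outside the gene universe")
    gene_index = pd.Index(genes, name="gene_id")
    lengths = pd.Series(
        rng.integers(500, 5001, size=design.n_genes), index=gene_index, name="length"
    )
    base = rng.lognormal(mean=0.0, sigma=1.0, size=design.n_genes)
    base /= base.sum()

    records = []  # (sample, tissue, line, treatment, time_h, replicate)
    for tissue in ("root", "leaf", "bark"):
        for rep in range(1, design.n_replicates + 1):
            records.append((f"{tissue}_{rep}", tissue, "none", "control", 0.0, rep))
    for line in ("HC", "LC"):
        for rep in range(1, design.n_replicates + 1):
            records.append((f"{line}_{rep}", "culture", line, "control", 0.0, rep))
    for t in _MEJA_TIMES:
        for rep in range(1, design.n_replicates + 1):
            records.append(
                (f"meja_{t:g}h_{rep}", "culture", "LC", "MeJA", t, rep)
            )
    samples = pd.DataFrame(
        records,
        columns=["sample", "tissue", "line", "treatment", "time_h", "replicate"],
    ).set_index("sample")

    tissue_fx = pd.Series(0.0, index=gene_index)
    for gid, fx in design.tissue_log2_effects.items():
        tissue_fx[gid] = fx
    line_fx = pd.Series(0.0, index=gene_index)
    for gid, fx in design.hc_lc_log2_effect.items():
        line_fx[gid] = fx

    followers = set(design.anchor_ids) | set(design.partner_ids)
    follower_mask = np.array([g in followers for g in genes])
    profile = np.asarray(design.meja_profile, dtype=float)
    # per-gene noise around the shared trajectory, fixed across replicates
    gene_noise = rng.normal(0.0, design.profile_noise_sd, size=(design.n_genes, 5))

    counts = {}
    time_idx = {t: i for i, t in enumerate(_MEJA_TIMES)}
    for sample, row in samples.iterrows():
        log2_effect = np.zeros(design.n_genes)
        if row["tissue"] in ("root", "bark"):
            log2_effect += tissue_fx.to_numpy()
        if row["line"] == "HC":
            log2_effect += line_fx.to_numpy()
        if row["treatment"] == "MeJA":
            i = time_idx[row["time_h"]]
            log2_effect = log2_effect + follower_mask * (
                profile[i] + gene_noise[:, i]
            )
        mean = design.library_size * base * np.exp2(log2_effect)
        counts[sample] = _nb_draw(rng, mean, design.dispersion)

    counts_df = pd.DataFrame(counts, index=gene_index)
    return ExpressionStudy(counts=counts_df, gene_lengths=lengths, samples=samples)
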