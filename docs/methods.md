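# Methods

This note documents the models, estimators and design choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the numerical conventions that make results deterministic.

## Codon-level divergence (NG86)

Ka/Ks is estimated by Nei–Gojobori (1986) counting. Per codon, the
synonymous site count at each position is the fraction of the three
single-base changes that preserve the amino acid, with changes to stop
codons removed from the denominator; S is averaged over the two sequences
and N = 3L − S, so S + N = 3L holds exactly. Codons differing at k
positions are scored by averaging synonymous/nonsynonymous step counts over
all k! orderings of single-base steps, excluding pathways that pass through
a stop codon (if no pathway survives, the codon is flagged as an error or
optionally skipped). Proportions pS = Sd/S and pN = Nd/N are corrected with
the Jukes–Cantor formula d = −3/4·ln(1 − 4p/3); p ≥ 3/4 is reported as
saturated (NaN plus a flag), never as a silent zero. All per-codon
quantities are precomputed as 64-entry and 64×64 lookup tables under the
universal genetic code (no alternative codes), so estimation is a table sum.

Large-genome pipelines often compute Ks with the YN00 model via
KaKs_Calculator. NG86 is used here
because it is fully specified and checkable against an exhaustive
pathway-enumeration oracle; the test suite exploits exactly that property.
Ks values from the two estimators differ modestly at high divergence, which
is acceptable because every quantitative claim exercised here is validated
against synthetic truth generated under the same counting conventions.

4DTv is the transversion proportion among third positions whose two codons
share an identical, fourfold-degenerate first-two-base prefix. It is
reported uncorrected; no correction is applied by default because none is
standard for this statistic in WGD scans.

## Molecular clocks

Synonymous divergence converts to time as T = Ks/(2µ) and LTR terminal-
repeat divergence as T = D/(2µ), with µ = 7.34573 × 10⁻¹⁰
substitutions/site/year by default (a slow gymnosperm rate; the fast
angiosperm alternative 1.8 × 10⁻⁸ is available per call). D is the Kimura
two-parameter distance D = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) over comparable
(both-ACGT) sites, chosen because the LTR-dating convention this mirrors
uses K2P; a Jukes–Cantor fallback sits behind a `model="jc"` flag.
Saturated distances raise a typed error and are tallied separately by the
age histogram, whose per-bin fractions together with the beyond-range and
saturated classes sum to one.

## WGD peak detection

Reciprocal-best-hit paralog pairs are built per query from the best
non-self hit by bitscore (ties broken by lower E-value, then lexicographic
subject id). The c-score denominator is the query's best non-self bitscore,
so a self-hit row never defines "best". A pair is retained when the two
genes are mutually best and a connecting direction passes all three filters
(E ≤ 1e-5, c ≥ 0.3, alignment ≥ 100 aa). Ks/4DTv distributions use a
Gaussian KDE with Silverman bandwidth evaluated on a 512-point grid
spanning the data; peaks are local density maxima (grid endpoints included
so a pile-up at zero is reported), returned in descending density order.
Peak detection refuses samples with fewer than 10 finite values. Histogram
display uses 0.05-wide bins; bin width is a configuration knob, not an
inference. Syntenic pair generation (collinearity chaining) is out of
scope; externally supplied syntenic pairs are accepted through the same
interfaces.

## Physical gene grouping

Within one chromosome, family-filtered genes sorted by start are chained
while the intergenic distance (next start − current end, floored at zero
for overlapping genes) is ≤ 5.26 Mb; chains of ≥ 7 genes become groups
labelled `<chrom>.<k>` in coordinate order. The comparator is "≤" (the
inclusive form), visible in the defaults rather than hidden in code. Strand is carried but
ignored. Internal coordinates are 1-based inclusive (GFF3 native); BED-like
output is 0-based half-open, so output end − start equals the span length.
Classification by the 97/55/40 identity ladder is independent of grouping.

## Expression summaries and the subtraction screen

RPKM = 10⁹·count/(length·library size), with library size taken as the
column sum of the count table (total mapped reads are not available from a
count matrix). Direction calls use log2((t + 0.1)/(c + 0.1)) against a
1.5-fold threshold; the pseudocount (0.1 RPKM) prevents near-zero noise
from producing confident calls and the threshold is configurable — there
is no field-standard cutoff for ±1 calls. Replicates are averaged
before calling. A group's response score is the sum of member calls, its
expression the sum of member RPKM.

Round 1 keeps genes whose replicate-mean RPKM is strictly higher in root or
bark than in leaf, with a floor of RPKM ≥ 1 in the best tissue so that
never-expressed genes cannot pass on noise. Round 2 is an in-house
negative-binomial test rather than an edgeR call: counts are scaled to the
geometric-mean library size, a common dispersion is estimated by pooled
method of moments (median over genes with mean ≥ 5 of
(within-group variance − mean)/mean²), and a Wald statistic on the log mean
ratio uses variance 1/(n·m) + φ/n per group; when the pooled dispersion is
~0 the test falls back to an exact conditional binomial on summed counts.
P-values are Benjamini–Hochberg adjusted; survivors need log2FC > 1 (HC
over LC) and FDR < 0.05. This Wald test is approximate at n = 3, but the
null simulations in the test suite confirm that the BH-controlled
false-positive fraction stays at or below the nominal level under the
simulated conditions. Round 3 averages replicates per MeJA time point
(n = 5 points), computes Pearson r between each anchor and candidate, and
keeps pairs with two-sided P < 0.05 from t = r·√(n−2)/√(1−r²) at df = 3
(survival boundary |r| ≈ 0.878). Zero-variance series are skipped with a
log message. The network is a simple graph of anchors and surviving
candidates with annotation attributes on nodes.

## Neighbour joining

p-distances use pairwise deletion of gap/ambiguous columns and the same
formula for nucleotide and protein alignments. Neighbour joining follows
Saitou–Nei with the standard branch-length formulas; among equal-Q pairs
the lexicographically smallest pair of working-node labels is merged
(internal nodes inherit their smallest leaf label), making the output
deterministic including on ultrametric ties. Negative branch-length
estimates are clamped to zero and counted on the returned tree
(`tree.n_clamped`), mirroring common tree-viewer behaviour. Trees are
scikit-bio `TreeNode`s; the NJ agglomeration itself is implemented here and
cross-checked against scikit-bio's independent implementation on additive
matrices in the tests.

## Michaelis–Menten fitting

Plain (unweighted) least squares of v = Vmax·S/(Km + S), initialised
deterministically at Vmax₀ = max(v) and Km₀ = the substrate level at
half-maximal velocity by linear interpolation; relative parameter tolerance
1e-10, at most 500 iterations, both parameters bounded positive. On
noiseless data from the standard 8-point GGPP assay grid (0.2–50 µM) the fit
recovers Km to better than 1e-6 relative error across the 0.5–50 µM range.
kcat = Vmax/[E] is computed only when an enzyme concentration is supplied
(converting an assay's enzyme mass to molarity requires a molecular
weight, which stays in user configuration). Velocity series that decrease
monotonically with substrate trigger a warning rather than an error.

## Synthetic data: what it does and does not emulate

*Layouts* place background genes uniformly without overlap and plant groups
whose internal gaps are drawn within the chaining threshold, so the planted
group is detectable by construction; planted regions are disjoint.

*Codon pairs* draw a uniform sense-codon ancestor and evolve only
synonymous third-position states: each site moves within its synonymous
state set (fourfold, threefold, twofold or fixed) under a symmetric
exchange whose intensity θ solves E[Sd]/S = 3/4·(1 − e^(−4·Ks/3)), so the
expected NG86 Ks equals the target exactly and true Ka = 0. This reaches
targets up to the composition's achievable pS (≈ 0.86 for random ancestors,
comfortably covering the Ks ≈ 2.1 WGD signature); non-finite or
unreachable targets raise a typed error. The generator does not model
nonsynonymous change, rate variation among sites, or indels.

*LTR pairs* copy a uniform random ancestor and evolve each copy
independently for the requested age under K2P with a
transition:transversion rate ratio of 2.0 by default (a typical plant
value; configurable) and total rate µ, giving expected divergence
D = 2µ·age. No indels, nested insertions or gene conversion between
repeats — the known failure modes of real LTR dating are deliberately
absent, so recovery tests certify the estimator, not the biology.

*Expression* draws NB(mean, dispersion 0.1) counts with log-normal baseline
abundances at library size 2 × 10⁶ over the full design — root/leaf/bark,
HC/LC, and a MeJA course at 0/2/4/8/24 h with three replicates everywhere,
matching the study's n = 3. Planted log2 effects act multiplicatively;
anchors and designated partners share a latent MeJA trajectory
(default log2 deviations (0, 1.5, 2.5, 2, 0.5)) plus per-gene noise
(sd 0.1). Library-size variation, batch effects, gene-length bias and
isoform structure are not modelled; passing recovery tests therefore shows
the estimators work under idealised NB sampling, not that the screen's
yields on real tissue data would match.

Problem sizes in the test suite (e.g. 200 pairs × 2,000 codons for the Ks
peak, 200 LTR elements, 2,000-gene expression studies, 500 random layouts)
were chosen as the smallest cohorts at which the sampling error of each
recovered quantity is well inside its acceptance tolerance.

## Known limitations

* NG86, not a maximum-likelihood codon model; at Ks ≳ 2 the estimator is
  noisy and its JC correction is convex, so single-pair values scatter
  widely even though cohort peaks are stable.
* The round-2 count test is a Wald approximation with a single pooled
  dispersion; it is calibrated in simulation but is not edgeR, and per-gene
  dispersion shrinkage is not implemented.
* 4DTv is uncorrected; comparisons across very different divergences should
  rely on Ks as the primary signal.
* The LTR helper assumes pre-aligned terminal repeats; the package does not
  discover LTR elements from genomic sequence.
* Group detection is single-linkage chaining on one family set at a time;
  it does not attempt multi-class biosynthetic cluster typing.
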