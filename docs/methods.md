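# Methods

This note documents the models and procedures implemented in `coldscan`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Study design and data model

The scan contrasts a focal population sampled at a cold range margin with a
reference population from the warm source range, with an outgroup panel of
sister species for allele polarization and divergence. Default sample sizes
(15 / 21 / 15 diploids) follow that design. Inputs are phased biallelic SNPs
(VCF v4.2), a sample→group→role map (TSV) and gene intervals (BED). Internally
haplotypes are a 2N×V matrix of {0, 1, missing}; coordinates are 0-based
half-open except VCF `pos` (1-based). A SNP is assigned to an interval iff
`start ≤ pos < end`; this single rule is used for windows, genes and the
site-level HKA scan, so a SNP exactly at an interval's `end` belongs to the
next tile.

## Filtering and polarization

Sites are retained at MAF ≥ 0.05 (computed over non-outgroup samples, called
alleles only) and missingness ≤ 0.2. One deliberate exception: the HKA
polymorphism/divergence counts are taken from the missingness-filtered but
*not* MAF-filtered site set, because interspecies fixed differences are by
definition monomorphic within the study populations and a within-population
MAF filter would delete the divergence signal wholesale.

A site is polarized iff at least `min_outgroup = 2` outgroup samples are
fully called and every called outgroup haplotype carries the same allele
(that allele is ancestral). A single outgroup genotype cannot distinguish a
lineage-specific substitution from a genotyping error, hence the default of
2. Polarization never inspects focal or reference genotypes.

## The four statistics

**Hudson Fst, ratio of sums.** Per site, numerator
`(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)` and denominator
`p₁(1−p₂) + p₂(1−p₁)` with n the called allele counts; windowed values are
`ΣN/ΣD` over usable sites (n ≥ 2 in both populations, D > 0). Ratio of sums
is the standard for two-population scans and is robust in low-diversity
windows; small negative values under frequency equality are the unbiasedness
correction at work, not a bug.

**π and the log₂ ratio.** π = `Σ_sites 2pq·n/(n−1)` per window, normalized by
window length in bp (not by segregating sites), missing-aware. The ratio
`log₂(π_ref/π_focal)` maps a zero-diversity focal window to +∞, deliberately
ranked above all finite values: a fully swept window is exactly the signal
sought, and a pseudocount would shrink it. 0/0 is missing. Default windows
are 50 kb with 25 kb step; both are configurable and carry no claim of
matching any particular published scan.

**XP-CLR.** The drift variance ω is estimated genome-wide by method of
moments, `Var(p_focal − p_ref) = ω · mean[p̄(1−p̄)]` with p̄ the reference
frequency, clamped to (1e−6, 1). The neutral marginal likelihood of a focal
derived count x of k integrates a Binomial(k, p₂) against a Normal(p₁,
ω·p₁(1−p₁)) truncated to [0, 1], the escaped tail mass placed as point
masses at 0 and 1. Numerics: 64-point Gauss–Legendre quadrature over
p₁ ± 8 sd clipped to [0, 1] (a fixed grid over the whole unit interval
cannot resolve the near-degenerate densities at small ω; the windowed grid
keeps total mass within 1e−6 of 1 across the tested (p₁, ω) lattice).
Reference frequencies are clamped away from {0, 1} by one pseudo-allele.
The selection model at position τ mixes the neutral density (weight
`c = 1 − exp(−ρd/s)`, the escape probability at distance d) with fixation
point masses (weight p₁ at p₂ = 1, 1−p₁ at p₂ = 0). CLR(τ) =
`2·max_s Σ w_j (ℓ_sel − ℓ_neut)`, floored at 0 — the neutral point is always
in the maximization, so CLR ≥ 0 by construction. LD down-weighting uses
`w_j = 1/#{SNPs in window with r² > 0.95 to j}`. Defaults: constant
ρ = 1e−8/bp, logarithmic s-grid over [1e−5, 0.5] (20 points), 10 kb grid
spacing, 250 kb window radius, ≤ 200 nearest SNPs. Because the hitchhiked
component is a fixation point mass, the statistic responds most strongly to
boundary focal frequencies (completed or near-complete local sweeps); under
neutrality on ascertained data the CLR null collapses toward 0, which is
conservative for outlier calling.

**EHH and iHH12.** EHH(x) = `Σ C(n_h,2)/C(n,2)` over distinct extended
haplotypes among core-allele carriers, computed outward site by site. EHH12
is defined over all haplotypes at a biallelic core with the two most frequent
extended classes pooled; iHH12 is its trapezoidal integral over physical
distance (no recombination map is assumed; a map hook would slot in at the
integration step). Each side truncates at the contig end, at a gap > 200 kb,
when the value drops below 0.05 (that point is recorded and included in the
integral), or when fewer than two haplotypes survive. A haplotype is dropped
from a side at its first missing call and the denominator is recomputed over
the survivors — conservative, and it keeps the statistic well-defined; note
that with missing data EHH is then not guaranteed monotone (dropping a
singleton can raise homozygosity), which is why the monotonicity property is
asserted on complete data only. z-standardization of iHH12 is genome-wide by
default; standardization within 10 derived-frequency bins is available since
published scans differ on this point.

**HKA-like test.** Per unit (gene): P = sites polymorphic among focal
haplotypes, D = sites with the focal population fixed (≥ 2 called alleles)
for one allele and all called outgroup haplotypes fixed for the other. Units
need D > 60 to be ranked ("usable"), read as a strict per-unit threshold on
divergence informativeness. Each usable unit's [[P, D], [P_tot−P, D_tot−D]]
table is tested by Pearson chi-square without continuity correction against
the totals over usable units; the signed score is +√χ² for polymorphism
deficiency. This per-unit contrast replaces the classical multi-locus HKA
likelihood: the goal is ranking departures, not parameter estimation. The
site-level variant scans sliding sub-windows (50 kb / 10 kb) around a focal
variant using polarized sites only (derived-polymorphic vs fixed-derived),
scored against the totals of the scanned region.

## Gene-level calling

Gene raw values aggregate by **max** over overlapping windows / grid points /
sites (sweep signals are local; a mean dilutes sub-gene peaks — this is the
main sensitivity knob and is deliberately not configurable per method).
Percentiles are empirical with average ranks for ties over genes with data;
a gene is an outlier when its percentile strictly exceeds 1−q. The paired
methods (Fst + π-ratio, XP-CLR + π-ratio) require *both* components in their
top q_pair = 5% (a rank-sum mode is available); iHH12 and HKA use
q_site = 1%. Candidates need ≥ 3 of 4 methods, strict calls need all 4.
ΔdAF leaders are ranked among polarized sites in strict genes by default
(configurable down to ≥ 3; the completed-sweep acceptance experiment uses 3,
see below), with ties broken toward the smaller coordinate and reported.

## IBS distances and the NJ tree

Distances follow the PLINK `1-ibs` dosage convention,
`d(i,j) = mean |dos_i − dos_j| / 2` over pairwise-complete sites, after
optional uniform thinning (seeded, order-preserving). The tree is canonical
Saitou–Nei neighbor joining; a negative branch length is clamped to 0 with
the excess moved to the sister branch, so path lengths between joined taxa
are preserved. Tests cross-check the topology against scikit-bio's NJ and
invert additive matrices exactly.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every end-to-end claim is made.

Neutral background: S segregating sites uniform on [0, L), with S chosen so
expected within-population heterozygosity per bp equals `theta_site`
(ancestral derived frequencies are U(0.05, 0.95), E[2pq] = 0.365). Population
frequencies are independent Balding–Nichols draws,
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with F the target background Fst — the null
calibration of a two-population scan needs differentiated-but-neutral data,
which this gives with one knob. Haplotype alleles are Bernoulli per
population; which of REF/ALT is ancestral is randomized. The outgroup is
fixed ancestral at pig-polymorphic sites (clean polarization; polarization
edge cases live in dedicated unit fixtures instead), and fixed for a non-pig
allele at Binomial(L, d_og) additional divergent sites. Defaults: L = 2 Mb,
theta_site = 1e−3, d_og = 5e−3, F = 0.05, 10 gene tiles of 200 kb.

One ascertainment condition is imposed: every background site must segregate
within *each* population sample (columns failing this are redrawn). This
emulates a jointly called SNP panel and, importantly, guarantees that no
background site carries the planted sweep variant's exact signature
(fixed-in-focal, absent-in-reference) by chance — without it, roughly one to
four such sites arise per 2 Mb replicate and the planted variant is not
identifiable as the ΔdAF maximum even in principle. Measured side effects of
the conditioning at the defaults: realized genome-wide Hudson Fst ≈ 0.047
against the 0.05 target, per-bp π ≈ 6% above `theta_site`.

The hard sweep is injected by haplotype replacement, not forward simulation:
a donor focal haplotype is copied over `round(f·2N)` focal haplotypes across
the sweep interval (so the realized sweep frequency is exact, quantized to
1/(2N)), and two new linked derived variants carried by exactly the swept
haplotypes are added — one regulatory at the center, one missense 1 kb
downstream — so that the per-class ΔdAF leader check has a truth site in
both classes. This produces the four signatures the scan consumes
(diversity loss, differentiation, extended haplotypes, frequency shift)
deterministically and fast. Default sweep: width 200 kb equal to one gene
tile and centered within it, so "the gene containing the sweep" is
unambiguous; f = 0.9 emulates the near-fixation regime.

What the generator does *not* emulate: recombination (haplotype structure
arises only from the replacement operation, so neutral EHH decays faster
than coalescent expectation and all EHH-based checks are relative contrasts,
never absolute decay rates), demographic history (growth, migration), soft
sweeps, and linkage disequilibrium in the neutral background (sites are
independent). Passing tests therefore demonstrate correctness of the
statistics and the calling logic under controlled signatures — not power or
calibration on real demography.

## Problem sizes and experiment design in the test suite

End-to-end experiments run on the default 2 Mb / 15+21+15-diploid
configuration (~16k sites before filtering, ~5.5k after). Sweep-recovery
experiments (20 seeds) use f = 1.0, the canonical completed hard sweep: at
partial f the unswept focal haplotypes add derived copies at dragged linked
sites, so a linked background variant can legitimately tie or exceed the
planted variant's ΔdAF and the leader is not identifiable at a fixed rate —
at f = 1 with the ascertained background the planted variants are the strict
unique maxima. A completed sweep leaves no polymorphic core sites inside the
swept gene, so iHH12 (which needs a biallelic core) contributes no score
there and recovery comes from the other three methods; iHH12's sweep
response is exercised at f = 0.9, where all four methods support the truth
gene. Null-calibration experiments (10 seeds) use 100 gene tiles because a
1%-tail count bound is not meaningful with fewer than 100 ranked units; at
100 genes each single-statistic method flags exactly the top gene (1%).

## Known limitations

* The XP-CLR implementation is the model described above, not a numeric
  reimplementation of any particular tool; equivalence claims are at the
  level of the model definition.
* Gene-level values for the paired methods take each component's max over
  windows independently, so the Fst and π-ratio maxima may come from
  different windows of the same gene.
* The HKA unit mode is interval-based (genes or windows); the classical
  multi-locus likelihood test and the MK test are out of scope.
* Unphased input is accepted only behind a flag, and haplotype-based
  statistics refuse to run on it.
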