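# Methods

## Input representation

Each individual is a set of scaffold-length diploid consensus sequences
over the 11-letter alphabet {A, C, G, T, R, Y, S, W, K, M, N}:
homozygous sites as plain bases, heterozygous biallelic sites as the
two-base IUPAC code, uncallable sites as N. Three- and four-base
ambiguity codes are rejected, mirroring a biallelic-SNP filter upstream.
Coordinates are 0-based half-open everywhere internally; genotype tables
accept 1-based (VCF-convention) positions and convert on load, because
the BED/VCF dialect mismatch is the classic off-by-one source and is
best fixed at the boundary. Soft-masked (lowercase) input is uppercased,
not masked: masking is expressed through N only.

## Windowed heterozygosity

Scaffolds are tiled with fixed non-overlapping windows (default 100 kb;
the last window of a scaffold may be short). Per window we record the
heterozygote count *k* and the callable-site count *n*. Non-overlapping
windows keep the HMM's observations conditionally independent given the
hidden state; 100 kb gives on the order of a hundred observations per
multi-megabase tract, ample for segmentation, while keeping per-window
counts large enough (~100 hets at 10⁻³ heterozygosity) that the two
states separate sharply. Windows with *n*/width < 0.2 are flagged
missing — masked deserts would otherwise mimic homozygosity — and
contribute likelihood one in every HMM state. Genome-wide
heterozygosity is Σk/Σn over all windows, which is exactly the
callable-weighted mean of window rates and therefore invariant to the
window size.

## The ROH HMM

Two hidden states per scaffold, inbred and outbred, with emissions

    k_t | s  ~  Poisson(lambda_s · n_t)

The Poisson-with-exposure family is the natural count model when the
number of callable sites varies per window. Parameters (two rates, the
2×2 transition matrix, the initial distribution) are estimated by
Baum–Welch; the M-step for the rates is the exposure-weighted ratio
Σγk/Σγn. Numerical choices:

- Initialization: lambda_out at the genome-wide heterozygosity,
  lambda_in a tenth of it, transition diagonal 0.999 (tracts are
  Mb-scale, windows 100 kb).
- Label switching is resolved by sorting states after convergence so
  lambda_in < lambda_out.
- Rates are floored at 10⁻¹² per bp. Fully autozygous windows can be
  literally het-free (the simulator adds no new mutation), and an
  unfloored EM would drive lambda_in to exactly zero, making the
  log-pmf −∞ at the first stray heterozygote. The floor is ~7 orders of
  magnitude below any realistic rate and does not measurably perturb
  the fit.
- Convergence: relative log-likelihood improvement < 1e-6 or 100
  iterations; the log-likelihood is non-decreasing (standard EM
  guarantee, preserved in practice by the floor).
- Input with no heterozygotes anywhere is degenerate: the fit returns a
  flat zero-rate model, flagged, with a warning, rather than
  meaningless estimates.

Decoding uses Viterbi with ties broken toward the outbred state, so
borderline windows do not inflate inbreeding estimates; forward–backward
posteriors accompany every window. Consecutive inbred windows merge
into tracts (missing windows inherit their Viterbi state, so an isolated
masked window between inbred flanks does not split a tract), and tracts
shorter than 2 Mb are discarded: shorter tracts cannot be called with
high confidence from 100 kb windows, and tracts above 2 Mb are the ones
that require actual inbreeding rather than background LD.

## Dating and summaries

A tract at which the maternal and paternal lineages coalesce g
generations back has survived 2g meioses; with crossovers a Poisson
process at r cM/Mb the surviving tract length is exponential with mean
100/(2rg) Mb, giving g = 100/(2rL) as the point estimate for an
observed length L. The default r = 1.1 cM/Mb is the domestic-cat
genome average, the standard proxy for felids. Histogram classes
derive from generation thresholds {8, 5, 3} plus the 2 Mb call floor:
{2, 5.7, 9.1, 15.2, ∞} Mb; the edges are configurable and both rounded
and unrounded values are exposed (lengths are reported unrounded).
F_ROH uses the total length of the scaffolds included in the analysis
as its denominator — the analysis universe, not the full assembly.

## IBD-ROH sharing

For a pair of individuals, ROH interval sets are intersected per
scaffold (sorted two-pointer sweep, verified in tests against a per-bp
bitmap oracle). Overlaps shorter than 1 Mb are discarded by default:
tract ends carry sub-window jitter and fragments below that scale
mostly reflect it. Overlap alone can pair two *different* homozygous
haplotypes, so when consensus genomes are supplied each overlap must
also agree at ≥ 95% of jointly callable homozygous sites (both modes
are available because interval overlap alone is the weaker but simpler
operationalization). The pairwise matrix is symmetric by construction,
its diagonal is each individual's F_ROH over the same denominator, and
every off-diagonal entry is bounded by the smaller of its two
diagonals.

## Local ancestry

Diagnostic sites are positions where one panel is uniformly homozygous
for one base and the other panel uniformly homozygous for a different
base; any N or heterozygote in either panel excludes the site. With
small panels a private polymorphism can masquerade as a fixed
difference with probability (1/4)^(panel size), which the per-site
error term absorbs.

The three ancestry states of a diploid genome — homozygous A, homozygous
B, heterozygous ancestry (MIXED, one haplotype from each source) — are
decoded by Viterbi over the diagnostic sites only. Emissions: the
expected observation (hom-A, hom-B, het respectively) with probability
1−ε, the two other informative outcomes with ε/2 each; N or an
off-pattern base is treated as missing. Transitions over a physical gap
d are stay = exp(−τd), with the switch mass split evenly — a
continuous-time approximation to ancestry-block turnover. Defaults
ε = 0.01 and τ = 2×10⁻⁷ per bp; τ is sized for an admixture event
roughly 8 generations back at 1.1 cM/Mb (switch rate ≈ 2 haplotypes ×
8 generations × 1.1×10⁻⁸ per bp). Parameters are fixed rather than
EM-fitted by default: a three-state EM on sparse sites is fragile, and
decoding accuracy is insensitive to τ within an order of magnitude
because true blocks span thousands of diagnostic sites. Segment
boundaries fall at midpoints between adjacent differing-state sites and
extend to scaffold ends.

Each ROH is labelled by the state covering the majority of its length
(ties → MIXED). Because autozygosity requires coalescence *after* any
admixture event, genuine ROH must be single-ancestry; MIXED-labelled
ROH would indicate calling artifacts, and the admixed simulation
scenario reproduces their absence.

## Mitochondrial clock

Divergence between aligned mitogenomes is the fraction of comparable
sites (both ACGT; gaps and N excluded) that differ. Node ages average
divergence/rate over all cross-clade pairs and report the mean and the
across-pair standard deviation — the only dispersion statistic the
procedure defines. The default rate, 1.15% of sites per Myr, is the
composite feline mitochondrial rate and is interpreted as a *pairwise*
divergence rate; a per-lineage interpretation (which halves ages) is
available behind a flag because published usages are ambiguous between
the two.

## The simulator

Founders come from two populations, A and B, sharing a random reference
sequence. Standing variation is a Poisson process of biallelic sites at
rate 2θ with allele frequency 0.5 in both populations, so that a
non-inbred individual's expected heterozygosity is θ (default 10⁻³ per
bp, a realistic value for an outbred large mammal); fixed inter-
population differences are a second Poisson process at rate d_AB
(default 10⁻⁴). Sharing the polymorphic positions between populations
(ancestral standing variation) keeps spurious diagnostic sites rare
even with small panels.

Haplotypes propagate through explicit pedigrees as segment mosaics
labelled by founder haplotype copy. Meiosis draws crossovers as a
Poisson process at r×10⁻⁸ per bp (no interference — matching the
renewal-process derivation of the dating formula — and no de-novo
mutation, since founder-derived variation dominates at pedigree
timescales). Ground truth is exact: the focal individual is autozygous
wherever its two mosaics carry the same founder-copy label, and each
segment's ancestry is its founder's population. Tracts cut off by a
scaffold end are flagged, because excluding them under-samples long
tracts with a bias of order (tract length)/(scaffold length);
formula-recovery runs therefore use gigabase-scale scaffolds where the
bias is negligible. Sequences are rendered (reference + variants,
haplotype pair merged into IUPAC consensus) only on request, so
truth-only replicates cost milliseconds.

Two scenarios are built in. `isolated_inbred` places the loop ancestor
exactly g generations back: by default a single half-sib chain loop
(inbreeding coefficient 2^−(2g−1), the clean setting for formula
checks); with `n_founders = K` the two parental lineages instead
descend from a common K-founder generation — a bottleneck g generations
ago — where every IBD path still spans 2g meioses but the autozygous
fraction rises to ≈ 1/(2K), making deep loops (g = 8) testable at desk
scale. Adjacent-tract merging inflates the renewal mean by roughly a
factor 1/(1−1/(2K)); tests account for this by using K ≥ 8 where the
formula itself is asserted. `admixed_inbred` crosses a B founder into
an A pedigree and inbreeds around the admixed ancestor, reproducing the
situation where a genome combines high average heterozygosity with long
single-ancestry ROH.

Randomness is structured as one seed per scenario with counter-derived
sub-streams per meiosis and per founder haplotype, so identical seeds
reproduce byte-identical outputs regardless of evaluation order.

### What the simulator does not emulate

Coalescent depth beyond the pedigree (founders are unrelated by
construction), new mutation, gene conversion, crossover interference,
variable recombination maps, genotyping error, and reference bias.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not robustness to every artifact of real
resequencing data; in particular real callsets carry masked regions and
genotype errors whose aggregate effect is represented here only through
the exposure/missing-window mechanism and the ancestry error term.

## Problem sizes

Test and reproduction runs use genomes of 2–6 scaffolds at 25–30 Mb for
sequence-level stages (rendering, HMM calling, ancestry decoding) and
gigabase truth-only scaffolds for tract-length statistics; these sizes
give hundreds of HMM windows per scaffold and hundreds of tracts per
statistic, which is where the quantities of interest stabilize.
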