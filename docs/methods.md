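# Methods

## The equilibrium skew model

Only mutations interconverting a basepair's two orientations (A↔T on the
same strand, G↔C) are modelled. Mutation rates are assumed far below
1/N_e, so each site is effectively fixed and its state follows the
two-state stationary distribution set by the mutation-rate ratio and the
fixation-probability ratio e^S, S = 2·N_e·s. Writing μ = (v−u)/(v+u) and
κ = (1+μ)/(1−μ), the probability that a site carries the first-listed
(more expensive) base is κe^S/(1+κe^S) on the leading strand, with u and v
swapped (κ → 1/κ) on the lagging strand; the skew is 2p−1. The model
ignores transversions to the other basepair, context effects and linkage;
only S = 2·N_e·s is identifiable, never N_e or s separately.

Sign convention: positive S favours A over T and G over C. This makes the
headline pattern come out as S_RNA < 0 (cheaper T/U and C favoured by
transcription-linked selection) and S_AA > 0 (dearer A and G favoured at
NS sites through amino-acid cost). The convention is fixed jointly by
three constraints: at S = 0 the leading skew equals +μ; the lagging strand
swaps u and v; and S < 0 must mean the cheaper base is favoured.

Inversion is exact and closed-form (see README). Per-genome estimators:

- μ^io: the skew of pooled interoperonic sequence in leading-strand
  orientation (S = 0 there by assumption).
- μ^4s: the joint inverse of the two 4s strand skews.
- τ (per pair): slope of μ^4s on μ^io across genomes, least squares
  through the origin; 95% CI from the slope's normal-theory standard
  error. The operative relation is μ′ = τ·μ^io — amplification of the
  relative bias, which is what a through-origin regression of μ^4s on
  μ^io estimates.
- f (per pair): minimises Σ_genomes [invert_μ(γ_NS,lead/f, γ_NS,lag/f) −
  τ·μ^io]² over f ∈ (0.01, 1], bounded scalar minimisation (xatol 1e−6).
  Genomes whose upscaled skew leaves (−1, 1) at a candidate f drop out of
  that candidate's objective. The agreement metric (unweighted least
  squares) and the bootstrap CI (resampling genomes, default 1,000
  resamples, seeded) are this package's choices where the procedure was
  genuinely open; one global f per pair.
- S_RNA per strand from the 4s skew with bias τ·μ^io; S_total per strand
  from the f-upscaled NS skew; S_AA = S_total − S_RNA (selection pressures
  additive on the scaled scale). The "mean" strand estimate is the
  arithmetic mean of the leading and lagging estimates. A per-genome mode
  replaces τ·μ^io with the genome's own μ^4s for analyses that must not
  share information across genomes (the lifestyle comparison).

Degenerate inputs: zero-denominator skews are flagged undefined, boundary
skews (|γ| = 1) are flagged non-estimable, and flags propagate to NaN
estimates rather than silently becoming zeros; flagged genomes are
excluded from the global fits.

## Coordinates, strands and site classes

Chromosomes are circular; internal coordinates are 0-based half-open
(GFF3's 1-based inclusive converted on read); multi-record FASTA inputs
contribute only their largest record. The genome is rotated so the
replication origin is position 0; the terminus is taken antipodal, so
plus-strand features with midpoint in [0, L/2) are leading, etc. Features
straddling a boundary are assigned by midpoint. Interoperonic regions are
the circular complement of all annotated features (operons, genes, tRNAs,
rRNAs): gaps are merged across the rotated end, 60 bp abutting any
feature's 5′ end are trimmed (3′ flanks untrimmed), merged gaps shorter
than 100 bp after trimming are discarded, and surviving gaps are split at
the ori/ter boundaries with second-half fragments reverse-complemented, so
every returned sequence reads in leading-strand orientation.

Coding sites: gene sequences are taken on the sense strand; the annotated
first codon is always dropped (whatever its identity) along with a
trailing stop; genes with non-triplet length, ambiguity codes or internal
stops are skipped and logged. Each position of each sense codon is
classed by how many nucleotides there preserve the amino acid under the
bacterial code (table 11): NS (1), 2s, 3s, 4s. The 3s class (isoleucine
third positions) is tallied as "other" and excluded from estimation. The
classification is derived from the genetic code at runtime and asserted
against a packaged copy in tests. Counts are pooled per replication
strand genome-wide (the interchange TSV uses the A1le/…/Gio column
dialect). A context filter can restrict counts to sites whose flanking
pair is complementary-symmetric (left = complement(right): CxG, GxC, TxA,
AxT), the control for context-driven mutational explanations.

## Simulations

Random codon ensembles (null study, trade-off grid) draw codon counts
from one multinomial over the 64-codon product distribution conditioned
on not being a stop codon — exactly the stationary distribution of
stop-codon rejection sampling, at a fraction of the cost. The null study
defaults mirror the study conditions (1,200 genomes, GC equally spaced on
[0.20, 0.80], ~10^6 codons each); desk-scale runs (≥200 genomes, 10^5
codons) already pin the medians to three decimals. The trade-off grid
spans GC 10–90% and skews −0.8…0.8 (combined, AT-only, GC-only modes) and
reports the count-weighted mean amino-acid cost and mean RNA-nucleotide
cost per point.

The synthetic-genome generator emulates the statistical structure the
model assumes: single-gene operons alternating strand within each
replichore, interoperonic gaps at mutation equilibrium (S = 0) in
leading orientation, 4s sites at the (τ·μ^io, S_RNA) equilibrium, and NS
sites a mixture of a fraction f at the (τ·μ^io, S_RNA+S_AA) equilibrium
and 1−f with zero skew. Genes are built from six-codon units
([A/T]CN ×2, [G/C]CN, G[G/C]N ×3; Thr/Ser, Ala/Pro, Gly/Ala families)
chosen so that every position is deterministically NS or 4s, no in-frame
stop can occur, and the three fixed C's per unit are balanced by three
fixed G's; the balanced fixed sites are counted into the zero-skew NS
share, so the pooled NS skew equals f times the model skew exactly in
expectation (this bookkeeping caps the generator at f ≤ 0.4). Defaults
are the recovery study's conditions: μ^io = 0.05, τ = 1.5, S_RNA = −0.3,
S_AA = +0.8, f = 0.35 per pair; 112 operons × 450 units ≈ 10^5 sites per
class and pair per genome (L ≈ 1.1 Mb). What the generator does not
emulate: realistic codon usage (only fourfold families, so Wright's Nc is
undefined on its genes), operon structure with multiple genes, 2s sites,
context-dependent mutation, or between-genome variation in μ — passing
recovery therefore validates the estimators' algebra and statistics, not
robustness to annotation errors or biological heterogeneity. All
randomness flows from one user seed through numpy Generators.

## Costs

Costs are high-energy phosphate bonds per molecule synthesised de novo.
Amino-acid costs are the published E. coli values (Akashi–Gojobori); the
nucleotide table is a synthetic stand-in (so labelled in the file) built
to satisfy every reported ordering — G > A > T/U, G > C > T/U,
G + C > A + U — with magnitudes in the published range; no conclusion in
the package depends on its absolute values. DNA T is priced as RNA U in
transcript contexts. A genuine non-monotonicity worth knowing: with GC
skew alone (AT skew 0), the expected mean amino-acid cost is not strictly
monotone in skew — it rises again at strong positive skew at low/mid GC
(exact enumeration; Trp- and Arg-encoding codons) — while the combined-
and AT-only-skew gradients are strictly monotone; the trade-off direction
(positive skew cheaper than negative) holds in all modes.

## Expression and codon-usage statistics

tAI follows the reference geometric-mean definition: per codon, absolute
adaptiveness W sums perfectly and wobble-matched anticodon copies with
penalties s(G:U)=0.41, s(I:C)=0.28, s(I:A)=0.9999, s(U:G)=0.68 and the
prokaryote lysidine rule for ATA (s=0.89); w = W/max(W), zero w replaced
by the geometric mean of non-zeros; a gene's score is the geometric mean
of w over its codons. The s-values are configuration, not ground truth.
Genes are ranked per replication strand and cut into five equal-sized
(±1) quintiles, ties broken by stable input order. Codon bias uses
Wright's original Nc (2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, F̄₃ falling back to
the mean of F̄₂ and F̄₄, clamped to [20, 61]) rather than the
background-corrected variant — a deliberate substitution; the downstream
preferred-codon logic is unchanged. Preferred codons: per 4s family, the
codon whose within-family usage correlates most negatively (Spearman)
with Nc across genes at p < 0.05/n (n = family size); genome-level
T-vs-A and C-vs-G ending preferences summarised by Fisher's exact test on
the pooled 2×2 table.

## Phylogenetic statistics

Felsenstein's independent contrasts on an ultrametric newick tree
(polytomies resolved to zero-length caterpillars, a covariance-preserving
transform; leaves without data pruned and logged). Correlations and
regressions on contrasts run through the origin. Sign tests are exact
two-sided binomials against 1/2. The lifestyle model fits
S ~ INTRA × GC × L by OLS through the origin on contrasts (interactions
formed from tip-level products before contrasting) and removes the
highest-p removable term — marginality respected — until every remaining
term is significant at 0.05, recording the AIC at each step.

## Problem sizes and numerics

Default test-suite sizes: the recovery study uses 100 genomes at the
generator defaults above; the null ensemble 200–250 genomes × 10^5
codons; trade-off points 10^5 codons. Closed-form round-trips are exact
to 1e−9 over |μ| ≤ 0.9, |S| ≤ 5; Monte-Carlo checks use 3-standard-error
bands. The f optimiser is deterministic; bootstrap and simulation seeds
are explicit everywhere.

## Known limitations

Real-genome effects outside the model — selection on interoperonic
regulatory sites, transcription-coupled repair biases, strand-variable
gene density, horizontal transfer — are not represented in the generator,
so recovery results bound only statistical, not systematic, error.
Global values of τ and f estimated from large real-genome compendia
depend on those data and are not targets for the synthetic cohort. The
full stationary allele-frequency density beyond the fixed-allele limit
is out of scope, as are operon
prediction, tRNA gene finding, tree inference and flux-balance cost
derivation; operons, tRNA pools, trees and cost tables are inputs.
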