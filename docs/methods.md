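# Methods

## Crossover inference model

A quartet (father, mother, son, daughter) determines, at every usable SNP,
which allele each parent transmitted to each offspring. The inference runs
per site by exhaustive Mendelian assignment: every (paternal, maternal)
allele pair drawn from the parents' genotypes is tested against the
offspring genotype; a unique survivor is a phase, no survivor is a
Mendelian violation (logged, excluded), several survivors (e.g. all three
individuals heterozygous) leave the site undetermined. This generalizes
the usual "offspring heterozygous and at least one parent homozygous"
informativeness rule: it also determines transmission at
offspring-homozygous sites, which carry crossover information whenever the
focal parent is heterozygous. A site enters a parent's gamete-pair track
only when (a) all four genotypes pass the quality filters, (b) both
offspring are uniquely phased, and (c) that parent is heterozygous — a
homozygous parent transmits the same allele from either haplotype, so the
site cannot distinguish its haplotypes.

Phase is computed per site with no HMM smoothing; isolated errors are left
to the changepoint and validation stages. This keeps the phasing stage
transparent and pushes all noise handling into one place.

The two siblings' gametes from one parent are compared as a binary
allele-sharing track (0 = same allele transmitted to both, 1 = different).
A crossover in either gamete flips the track, so crossovers are
changepoints in a piecewise-Bernoulli series. Because only two of a
parent's gametes are observed, a sharing transition cannot be assigned to
a specific gamete, and two transitions cannot distinguish "one crossover
in each gamete" from "a double crossover in one"; all counting is per
sibling pair per parent. Three or more transitions on one chromosome do
imply at least one double-crossover gamete, and the package flags those
cases.

## Changepoint engine

Segment cost is the negative maximized Bernoulli log-likelihood; a
segmentation with k changepoints costs `sum of segment costs +
k·β·log(n)` with β = 3 by default and n the track length. The detector
returns the exact global minimizer rather than a greedy binary-segmentation
approximation: since the Bernoulli cost depends only on the count of ones,
an optimal segmentation always has its changepoints at value changes, so
an optimal-partitioning dynamic program over run boundaries (with
PELT-style pruning, which is exact for superadditive costs) finds the
optimum in far less than O(n²) time on realistic tracks. The test suite
verifies exactness against literal enumeration of all 2^(n-1)
segmentations on short tracks and against an unpruned full-grid dynamic
program on longer ones. An exact optimizer makes the detector's behaviour
reproducible and provable; heuristic segmentation could silently miss the
optimum on noisy tracks.

Candidate changepoints are then validated by the window rule: the mean
sharing code over the 100 kb of track left of the boundary and right of it
must fall on opposite sides of (0.1, 0.9). This absorbs sparse phasing
errors (a 5% error rate moves a window mean to ~0.05/0.95, still
straddling the thresholds) while rejecting oscillating regions. Finally,
two distance filters: validated crossovers of the same (parent, pair,
chromosome) whose midpoints are closer than 400 kb are **both** removed —
short-range pairs are gene-conversion or mapping-error look-alikes, and
with two gametes in play neither member is individually trustworthy — and
crossovers with midpoints within 400 kb of a chromosome end are removed,
where changepoint estimates at series boundaries are least reliable.
Midpoints (rather than interval edges) define both distances; intervals
are a few kb wide against 400-kb thresholds, so the choice is essentially
inconsequential, but midpoints are unambiguous for wide intervals.

## Map statistics

Map length is 100 × COs / meioses (cM). Female:male ratios are computed
from unrounded lengths in integer-count form (`female·M_m / (male·M_f)`)
because float division order can flip exact decimal ties (17/24 vs 10/30
is exactly 2.125) and rounding lengths first changes the second decimal on
several chromosomes. Report rounding is decimal half-up (lengths 1 dp,
ratios and correlations 2 dp).

The obligate-crossover test: if every meiosis places one chiasma on a
chromosome and each chiasma reaches the sampled gamete with probability ½
(two of four chromatids), the observed CO count is Binomial(meioses, ½),
and a low count is evidence of assembly or phasing artefacts on that
chromosome. The CV-equality test is the Feltz–Miller asymptotic
chi-square; the literature this pipeline follows names a CV test without
formulas, and Feltz–Miller is the standard asymptotic choice (its null
calibration is verified by simulation in the test suite).

Folded-chromosome analysis maps each CO midpoint to
`min(d, L−d)/(L/2) ∈ [0,1]` (relative distance to the nearest end),
bins it into n equal segments (n = 2…20; coordinate exactly 1 goes to the
last segment), and uses each segment's share of the chromosome's COs as
its relative map length. The short-arm deficit test pools autosomes whose
short arm is under 30% of the chromosome and compares observed short/long
arm counts with an expectation proportional to physical arm length — the
most natural null given no stated alternative — by a 1-df chi-square.

## Spatial mixed models

CO counts in 10 equal chromosome segments (per sex) are modelled with
Gaussian linear mixed models: chromosome as a random intercept, fixed
effects drawn from {telomere distance, centromere distance}. Telomere
distance is relative (scaled by half the chromosome's length); centromere
suppression is assumed to act on absolute distance, so that covariate is
distance in Mb scaled by the maximum arm length across included
chromosomes (one shared scale; a per-chromosome-scaled variant is also
emitted, and on data generated with an absolute-distance mechanism it fits
demonstrably worse). Sex chromosomes and chromosomes without a localized
centromere are excluded. Models are fit by full maximum likelihood — REML
likelihoods are not comparable across fixed-effect structures — and ranked
by AIC = 2k − 2 lnL with k counting fixed effects plus the two variance
parameters. A Gaussian response is the default (counts per segment are
large enough); the ledger machinery accepts any response column, so a
user can supply transformed counts if desired.

FST\* divides each 100-kb window's FST by its chromosome's mean,
removing between-chromosome level variation; per-chromosome mean FST\* is
exactly 1 by construction. The recombination–differentiation correlation
is the Pearson r between mean relative map length and mean FST\* over the
10 folded segments, computed for sex-averaged, male-only and female-only
recombination. FST window-level models use distance to the chromosome
center and to the centromere as candidate fixed effects.

## Permutation tests

Hotspots are non-overlapping fixed-length windows tiled from coordinate 0
(a tiled reading is reproducible; anchoring windows on COs would make the
statistic depend on the CO list itself) containing ≥ 2 COs, assigned by
midpoint. The null re-places every observed interval uniformly on its own
chromosome, preserving lengths, 10,000 times; p-values use the add-one
convention (1 + #{null ≥ obs})/(n+1) so Monte-Carlo p is never 0. Feature
overlap (genes, exons, introns, strand-aware 2-kb promoters) uses
any-shared-base overlap in half-open coordinates and reports enrichment,
depletion and two-sided p; an option constrains null placements away from
chromosome ends to mirror the caller's end rule (off by default — the
uniform null is the simpler reading). GC analysis compares each CO
interval's GC (ignoring N) with the pooled GC of its two 250-kb flanks,
truncated at chromosome ends, by paired t-test per sex.

## Simulator

The generator emulates an interspecific-cross quartet study. SNP positions
are a Poisson process (default mean spacing 2.5 kb); a configurable
fraction of sites (default 1.0) is haplotype-informative, split evenly
between the parents — the focal parent heterozygous, the other homozygous
— with the remainder species-diagnostic (both parents homozygous for
different alleles). With the default spacing this yields ~5-kb informative
spacing per parent.

Each meiosis draws 1 + Poisson(extra rate) chiasmata from a
piecewise-constant density: uniform base, multiplied by (1 + telomere
weight) within the distal fraction of each end, multiplied by the
suppression factor within the centromere radius, renormalized; a
hard-core minimum distance (default 1 Mb) thins the set as a simple
stand-in for crossover interference (a gamma renewal process is
deliberately out of scope). Each chiasma reaches the transmitted gamete
independently with probability ½ — the two-of-four chromatid rule — and
the gamete is a mosaic of the parent's two haplotypes switching at the
retained breakpoints. Sibling gametes come from independent meioses.

Default parameters encode the study conditions the package targets:
15 quartets (30 male meioses; the mother's side of 12 quartets analyzed,
24 female meioses, mirroring the exclusion of pseudo-replicated female
gametes); male placement strongly telomere-concentrated (weight 8 within
the distal 15%) and centromere-suppressed (factor 0.05 within 5 Mb), no
extra chiasmata (observed ≈ 0.5 COs/gamete/chromosome); female placement
near-uniform with extra-chiasma rate 0.6 (observed ≈ 0.8) and mild
suppression (factor 0.5 within 2 Mb) — the female suppression strength is
a free parameter, not an empirical claim, since no quantitative value is
established. The default genome has 21 chromosomes of 15–30 Mb, mostly
acrocentric, with three centromere-less chromosomes and two flagged sex
chromosomes so spatial analyses exercise their exclusions.

Genotyping error replaces a genotype with one of the other two classes at
the configured rate (default 10⁻³); a perturbed genotype receives a low GQ
with probability 0.5, so the GQ filter removes some errors while the rest
exercise the caller's noise handling. Missingness drops genotypes at a
configured rate. The simulator's truth table records every chiasma, every
retained breakpoint, and each sibling pair's observable transitions (the
symmetric difference of the two gametes' breakpoint sets) flagged by the
same 400-kb end/pair detectability rules the caller applies.

What the simulator does **not** emulate: gene conversion tracts
(crossovers are points), chromosomal rearrangements and mapping artefacts,
fine-scale GC structure (a planting device exists for testing the GC
statistics), LD/coalescent structure, and realistic GQ/TP score
distributions. Passing tests therefore demonstrate correctness of the
inference pipeline under the stated generative model, not robustness to
every artefact of real short-read data.

## Problem sizes and numerical choices

The test suite runs the full study-scale configuration (21 chromosomes,
~190k SNPs, 15 quartets) once; unit tests use 1–4 chromosome toys. The
mixed-model selection checks use 200 replicates for the effect-recovery
scenario and 100 for the null scenario; permutation calibration uses 199
null draws × 200 replicates. Changepoint exactness is enumerated literally
up to track length 12 and checked against the full-grid dynamic program up
to length 20 on 1,000 random tracks.

Ties in the changepoint optimum are broken toward fewer changepoints;
degenerate placement densities (everything suppressed) fall back to
uniform; chromosomes with zero crossovers are omitted from relative map
lengths (the share is undefined); Pearson correlations on zero-variance
inputs are reported as NaN rather than raised. The reference map-length
table packaged for worked examples reconstructs integer CO counts as
round(length × meioses / 100); the reconstruction reproduces every printed
length cell, and the ratio column on 19 of 21 chromosomes exactly — the
remaining two printed ratios are internally inconsistent with their own
length cells by one unit in the last digit under any rounding convention,
and the package reports the arithmetically consistent values.

## Known limitations

Crossovers within 400 kb of chromosome ends are undetectable by design,
which biases against the sex whose crossovers cluster distally; the
caller cannot separate tightly spaced double crossovers (both members of
a < 400 kb pair are removed); interference is a hard-core cartoon; and the
TP (phasing-confidence) analog emitted for internally phased data is a
binary pass/fail score, not a calibrated posterior — external VCFs
carrying a genuine TP field are honored unchanged.
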