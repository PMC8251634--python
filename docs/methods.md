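# Methods

This note documents the models, conventions and design choices behind
`duplexmut`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
emulate.

## Synthetic panel and reads (`panel_sim`)

**Panel.** The default panel is twenty 2.4-kb loci (48,000 bp), the
geometry of a genome-representative hybrid-capture mutagenesis panel.
Sequences come from a first-order Markov chain with stationary GC
fraction `gc_fraction` (default 0.41, human-like) and a C→G transition
multiplied by `cpg_weight`, so CpG dinucleotide density is tunable.
Coordinates are 0-based half-open everywhere; BED output is native and
FASTA headers carry the locus id.

**Molecules.** Source molecules are double-stranded fragments with
normal length (mean 300 bp, SD 30), placed uniformly within loci
(loci weighted by length). Each carries a random 10-nt tag pair; family
identity downstream uses the canonical (lexicographically sorted) pair
plus exact fragment endpoints — the simulator guarantees exact
coordinates, so no fuzzy clustering is needed and no aligner is run;
panel coordinates ride in the read metadata.

**Germline heterozygotes.** `n_germline_hets` distinct sites (default
20, collisions re-drawn); each molecule has a haplotype drawn
Bernoulli(0.5) and a het is tied to one haplotype, giving a molecular
allele fraction of 0.5 — the load the 1% VAF filter must remove. For a
non-default `germline_vaf`, carriers are drawn per molecule at that
probability instead.

**Somatic load.** The number of somatic events is Poisson with mean
`true_mutant_frequency` × total molecule bases. Each event draws a
substitution class from the 6-class spectrum (`ems_like`: C→T weight
0.70, others 0.06, uniform over contexts; `control_like`: C→T 0.45
with 70% of C→T events forced into CpG context, plus a T→C-leaning
remainder — a deamination-flavoured background), then picks a
compatible reference site inside a length-weighted random molecule.
Purine-reference sites are used via reverse complement, so programmed
spectra are strand-symmetric.

**Reads and errors.** Each strand of a molecule emits
Poisson(`reads_per_strand_mean`, default 3) reads, possibly zero. PCR
errors (default 1e-5/base) are applied once per strand lineage and
shared by all of that strand's reads — deliberately never
duplex-consistent, which makes error suppression by strand agreement
well-defined. Sequencing errors (default 1e-3/base) are independent
per read base. A single seeded generator drives panel, molecules and
reads in a documented order; everything is bit-reproducible for a
fixed `rng_seed`.

Not emulated: indels and structural variants, quality-score
distributions, end artifacts (hence no default consensus trimming,
though a trim option exists), off-target capture, real adapter
chemistry, and alignment (a vendor-infrastructure step, not part of
the analysis logic). Passing tests therefore demonstrate the analysis
chain's correctness on idealized single-nucleotide data, not
robustness to alignment or library artifacts.

## Duplex consensus (`duplex_consensus`)

Reads sharing (locus, fragment start, fragment end, canonical tag
pair) form a family; tag order relative to the canonical pair assigns
the strand. Per strand, a consensus base is emitted when the family
has at least `min_reads` (default 2) reads and the plurality base
reaches the `agreement` fraction (default 0.9 — unanimity at family
size 2); otherwise `N`. The duplex consensus is non-`N` only where
both strand consensuses agree. Defaults echo common duplex-sequencing
practice; with them, a sequencing artifact must hit the same position
with the same base in every read of both strands, and a PCR artifact
must arise independently on both strands, so the residual artifact
rate is far below 1e-7 per base (verified by simulation at > 5×10⁷
duplex bases). Non-ambiguous duplex bases are tallied per site into a
depth table whose total equals, exactly, the non-`N` base count over
all duplex sequences — the mutant-frequency denominator.

## Mutation calling (`mutation_call`)

Each (site, alt allele) with VAF = alt molecules / duplex depth
strictly below `vaf_threshold` (default 0.01) is a call; alleles at or
above it are treated as inherited. "Unique mutations" de-duplicates a
recurrent (site, alt) to one count per sample (clonal copies); a
molecule-count mode is available. Consequence of the threshold: the
method needs duplex depth > 1/threshold (> 100 at 1%) for a
single-molecule variant to be callable at all — the study regime
(~12,785×) satisfies this easily, and simulations here use depths of
several hundred.

Wilson score intervals are computed on the proportion count/bases (via
`statsmodels`, validated in tests against an independently coded
textbook formula) and rescaled to ×1e-7 for display, with two-decimal
half-away-from-zero rounding. Group summaries default to the
arithmetic mean ± SD of replicate frequencies; a pooled mode (summed
counts / summed bases) is provided because the published control-group
mean follows the pooled convention while the treated-group means are
arithmetic. The exact Wilson coverage for a true proportion p at n
trials is not 95% in the small-expected-count regime: at λ = np = 4 it
is 93.1% and at λ = 20 it is 94.4%, which is why coverage checks pool
several hundred simulated samples and accept a band around 95%.

## Spectra (`spectrum`)

Substitutions are pyrimidine-normalized: purine-reference events are
reverse-complemented (alleles and flanks, flanks swapping sides),
giving 6 classes × 16 flank pairs = 96 contexts. CpG C→T means 3'
neighbour G on the normalized strand. Proportions of total mutations
are the default representation (matching how such spectra are usually
plotted); normalization by panel trinucleotide availability is
available via `panel_context_availability`, and the CpG "availability
fraction" (share of C opportunities that are CpG) is the reference
point for enrichment claims. Group differences in one class's share
use a pooled two-proportion z-test — the simplest defensible choice,
since no specific test is canonical here; its size is verified by
permutation in the tests. Edge calls without a flanking base are
excluded and counted separately.

## Dose-response statistics (`dose_response`)

Endpoint tables are replicate-by-concentration data frames
(`concentration`, `value`, optional ids). Trend is OLS of value on
concentration on a linear scale (a log-index option exists), with a
t-test on the slope; `on="means"` regresses per-group means instead of
replicates — with the published mutant-frequency table, the group-mean
regression yields p = 0.0069. ANOVA is the standard between/within
decomposition (scipy), with singleton groups rejected rather than
silently pooled.

Dunnett's many-to-one test uses pooled within-group variance t
statistics and a Monte-Carlo critical value: draw independent normals
for each group mean and a chi-square for the pooled variance, form the
correlated null t-vector (correlation induced by the shared control
and the group sizes, so unequal n is handled exactly), and take the
(1−α) quantile of its max (one-tailed) or max-absolute (two-tailed)
over `mc_reps` draws (default 1e5, seed required; the quantile's
Monte-Carlo SE is reported, and the k = 1 case reduces to the plain t
quantile within that error). Adjusted p-values come from the same null
distribution. Tests cross-check the whole construction against
`scipy.stats.dunnett`.

**Analysis scale.** On the raw mutant-frequency scale, the one-tailed
Dunnett on the published replicate values leaves the 25 µg/mL group
non-significant (adjusted p ≈ 0.09), because the top-dose group's
large variance inflates the pooled SD. On log10 frequencies — the
conventional scale for mutant frequencies, whose dispersion grows with
the mean — the published significance pattern (25, 50, 100 µg/mL
significant; 6.25 not) reproduces exactly. `dunnett_test(..., log=True)`
is therefore used when reproducing that pattern, and the choice is
surfaced rather than buried: raw-scale results remain the default.

## Comet scoring (`comet`)

Each cell is a 1-D intensity profile along the electrophoresis axis
(the marginal that fully determines %DNA in Tail; a 2-D image adds
nothing to the score). The head is a Gaussian truncated at ±3 head
widths; the tail is an exponential (decay length 40 px) starting at
the head/tail boundary, which sits at head-center + k·head-width with
k = 3 — coincident with the head support edge, so an undamaged
noiseless cell scores exactly 0 and a noiseless cell with tail
fraction f scores exactly 100f. Per-cell tail fractions are
Beta-distributed with mean equal to the programmed fraction (so
cell-to-cell spread never biases the culture mean) and SD `cell_sd`
(default 0.06) where feasible; pixel noise is multiplicative gain
noise (default SD 2%), which keeps empty regions empty and the
intensity-ratio score unbiased. Scores are bounded in [0, 100] and
scale-invariant by construction. Default programmed fractions
(0.038, 0.102, 0.287, 0.585, 0.833 for 0–100 µg/mL) follow the
published 3-day damage series; 300 cells per culture matches common
chip-format scoring practice, and aggregation warns below that count.
Both mean and median per-culture summaries are reported (mean is the
default statistic). Real-image segmentation, Olive tail moment, and
reproduction of measured tail values from real micrographs are out of
scope.

## Problem sizes

The test and acceptance runs use desk-scale versions of the study
conditions: ~5×10⁷ duplex bases for the artifact-rate demonstration
(duplex depth ~1,100 after strand dropout, vs 12,785× in the study)
and 2×10⁷ duplex bases per sample for parameter-recovery studies, run
molecule-exactly (read simulation skipped) where error processes are
disabled — the tests include an exact equivalence check between the
molecule-level and read-level paths under those conditions.

## Known limitations

* The simulator's error model is substitution-only and
  position-homogeneous; real duplex data have context- and
  damage-dependent artifact classes the consensus thresholds here are
  not tuned against.
* Family identity relies on exact fragment endpoints; real pipelines
  must tolerate alignment jitter.
* The Dunnett implementation is Monte-Carlo; for very small α or very
  many groups, `mc_reps` must grow accordingly (the critical value's
  MC standard error is part of the result object).
* Mutant-frequency comparisons treat replicates as exchangeable
  cultures; no mixed-effects or overdispersion modelling is provided.
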