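# Methods

## The question and the measurement

Ribosome profiling assigns each protected mRNA fragment to the codon in the
ribosomal A site, so the per-codon read count along a coding sequence is a
proxy for local translation (dwell) time.  `ribocompare` asks whether these
occupancy profiles are conserved between paralogous protein domains — domains
in the same structural family within one genome — beyond what unrelated
domains of the same size show.  Conservation of the *shape* of the profile,
not its absolute scale, is the object of interest, which motivates a
rank-based similarity statistic.

## Profile processing

For a pair of domains the raw per-codon A-site counts are processed as
follows (single domains follow the same chain without the alignment steps):

1. **Gap filter.** The domains' amino-acid sequences are globally aligned
   (BLOSUM62, affine gaps −10 open / −0.5 extend).  Pairs whose alignment has
   more than 10 internal gap runs, or any run of ≥5 columns, are discarded;
   runs touching either alignment end are not counted.  The filter bounds how
   much of a processed profile is interpolated rather than observed.
2. **Gene-end trim.** Positions in the first 40 or last 20 codons of the
   full-length gene are removed; read density there is inflated by
   initiation and termination artifacts.
3. **Projection.** Both count vectors are laid onto the alignment columns.
   Columns whose position was trimmed in either domain, and columns inside a
   terminal gap run, are dropped from both profiles, so the pair shares one
   coordinate system.  (Terminal-gap columns carry no observation at all for
   one domain — there is nothing beyond the sequence end to interpolate
   between — so they are treated like trimmed columns rather than filled;
   constant-filling them makes whole blocks land in a single occupancy
   tercile and distorts the null of the downstream ranking.)
4. **Interpolation.** Zero-count positions and internal alignment gaps are
   filled by a cubic interpolating spline through the positive observed
   positions (anchors), holding every anchor exactly fixed; negative
   interpolants are clamped to 0.  With 2–3 anchors the fill is linear;
   positions outside the anchor hull take the nearest anchor's value.  Fewer
   than two anchors makes the profile uninterpolatable and the pair is
   skipped.
5. **Smoothing.** A 15-codon centered moving average; at the edges the
   window truncates to the available positions (the first position of a
   profile averages 8 values).
6. **Normalization.** Division by the sum ("area under the curve" with unit
   codon spacing), giving a discrete density.

Profiles shorter than 50 positions after step 3 are discarded.  Domains
enter the analysis only if they are contiguous, ≥100 residues, and have
reads on ≥70% of their codons.

## The fsmf statistic

Positions of each profile are ranked by occupancy (ties broken by position
index) and split into *fast*, *medium* and *slow* terciles — bottom, middle
and top third of occupancy; with L mod 3 ≠ 0, the extra positions go to the
lower-occupancy classes (label = ⌊3r/L⌋ for rank r).  The fsmf of two
profiles in shared coordinates is the fraction of positions with the same
label.  Being rank-based, fsmf is invariant under any strictly increasing
transform of a profile; two independent profiles agree at rate → 1/3, and
values live on the grid k/L.

## Ranking design

Each paralogous pair contributes one fsmf value.  Nineteen non-paralogous
competitors are then drawn at random (without replacement) among domains
that: pass the same coverage and length floors, lie on neither pair gene,
differ from both pair members in SCOP class, superfamily *and* family, and
are within 25 residues of the reference (first) pair member's length.  Each
competitor's trimmed count vector is truncated at the 3′ end to the pair
profile's length and run through the identical interpolate → smooth →
normalize chain, then scored against the reference member's profile.
Truncating *before* smoothing, rather than truncating the finished profile,
keeps the competitor statistically exchangeable with a pair member under the
null: both are identically processed contiguous count stretches of the same
length, with smoothing-edge positions at the same places.  A competitor too
short to cover the reference is rejected and another drawn.

The pair's rank among the 20 fsmf values (1 = most similar) is recorded;
fsmf ties are broken uniformly at random.  Under the null the rank is
uniform on 1..20 and the expected count per rank is n_pairs/20.  The
selection is repeated over 20 independent trials and per-rank means with
95% CIs (normal approximation over trials) are reported.  When calibration
itself is being tested (null uniformity, signal recovery), one trial per
pair is used instead: a pair's fsmf persists across trials, so pair-trials
from repeated trials are correlated and would invalidate chi-square or
binomial assessments.

**Random-pair control.** Random domain pairs (no family requirement, no
identity band) replace the paralogous pairs, all other machinery unchanged.
**Per-rank permutation test.** For each rank, the statistic is the absolute
difference of the two groups' mean per-trial counts; the null reassigns the
40 trial rows to two groups of 20 (default 10⁶ resamples), with the add-one
estimator p = (1+#{null ≥ obs})/(1+n_perm) and per-rank α = 0.05 flags, no
multiple-testing correction.

## Pair selection

Paralogous pairs are all unordered same-family domain pairs on distinct
genes.  Their DNA identity — identical columns over alignment columns,
terminal gap runs excluded — from a global DNA alignment (match +1,
mismatch −1, gaps −5/−2) must fall in [0.30, 0.80], removing nearly
identical recent duplicates and barely related pairs.

## %MinMax codon-usage arm

Per codon (window z = 1), %MinMax compares the usage frequency of the actual
codon against the most frequent (X_max), least frequent (X_min) and average
(X_avg) synonymous codon for that amino acid:
100·(X_act−X_avg)/(X_max−X_avg) if X_act ≥ X_avg, else
−100·(X_avg−X_act)/(X_avg−X_min); single-codon amino acids (Met, Trp) score
0.  Each domain's profile is shifted additively so its minimum is exactly 1
(the shift is order-preserving, so fsmf is unchanged), then substituted for
read counts and pushed through the identical processing and ranking
machinery, including trimming and smoothing.  A built-in genome-wide yeast
usage table is provided; only within-family frequency ratios enter the
formula, so the table's scale is irrelevant.

## Synthetic data

The generator produces what the machinery is designed to detect, with
tunable effect size.  Per family, an ancestral per-codon log-dwell vector
a ~ N(0, σ²) is moving-average smoothed (window `smooth_w`, default 5) to
give dwell local autocorrelation; each paralog's domain log-dwell is
ρ·a + √(1−ρ²)·e with fresh identically smoothed noise, so the latent
correlation between paralogs is ρ².  Flanks (20–60 codons each side)
receive independent noise.  Counts are Poisson with mean
depth·dwell/mean(dwell) per codon (optional Gamma mixing for
overdispersion; optional linear 5′ ramp emulating initiation pile-up,
off by default since the gene-end trim targets exactly that feature).
Defaults: domains 100–200 residues, σ = 0.5, ρ = 0.9, depth 50 reads/codon
— a high-coverage pooled-dataset regime in which per-codon coverage is
essentially complete.

Sequences: the ancestral domain protein is uniform over the 20 amino acids;
paralogs substitute residues at the per-site rate that makes the *expected*
DNA identity of the domains equal `target_dna_identity` (default 0.55, the
middle of the 30–80% band).  The rate is obtained in closed form: expected
nucleotide identity is quadratic in the substitution rate, with coefficients
computed from the usage-weighted expected codon agreement within and between
amino acids.  Codons are sampled per paralog, independently, proportional to
the usage table.  There are no indels, so paralogous domains align
gaplessly.  Binomial thinning (`thin_counts`) emulates reduced sequencing
depth for coverage-titration experiments.

Randomness: one seed sequence per study, spawned into one child stream per
family and per singleton, so the study is reproducible and families can be
regenerated independently.

### What the generator does *not* emulate, and its consequences

* Real codon-level determinants of dwell (tRNA abundance, wobble, proline
  stalling) are absent; dwell is a free latent field.  Passing tests show
  the *machinery* recovers planted profile conservation, not that real
  paralogs conserve translation speed.
* Protein sequences are uniform-random, which makes *unrelated* synthetic
  proteins far less alignable than real proteins of shared composition.
  Two consequences for the random-pair control, both inflating its rank-1
  count: (a) the gap filter accepts same-family pairs (which the design
  permits "by random chance") at a vastly higher rate than unrelated draws,
  so accepted "random" pairs are enriched for paralogs; (b) accepted
  unrelated pairs are biased toward alignments near the gap-filter limit,
  and interpolation over their gap stretches pulls both profiles toward
  mid-level values that co-occupy the medium tercile (fsmf ≈ 0.40 vs the
  1/3 null).  The published control shows the same direction of enrichment
  (38.15 rank-1 pairs vs 33.20 expected); on synthetic data the effect is
  larger, and the per-rank permutation test still separates the paralog arm
  from the control.

## Numerical choices

* Alignment: Needleman–Wunsch-style global alignment with affine gaps via
  Biopython's PairwiseAligner; a gap run of length L costs
  open + (L−1)·extend and terminal gaps are charged.  Among co-optimal
  alignments the aligner's first enumeration is taken (deterministic).
  Externally computed alignments can be imported from 2-record aligned
  FASTA to reproduce published alignments exactly.
* "Area under the curve" is the sum (unit spacing), not a trapezoid — the
  difference is a boundary term with no effect after tercile ranking.
* The %MinMax ratio is computed before scaling by ±100 so that sequences of
  extreme codons hit ±100 exactly in floating point.
* Interpolation uses an interpolating (not smoothing) spline so observed
  values are bit-preserved; it reproduces cubic polynomials to ~1e−9.
* Degenerate inputs: empty trims, <2 anchors, <50 final positions, and
  exhausted competitor pools each raise a tagged rejection; pairs are
  skipped for the affected trial and tallied, never imputed.

## Problem sizes used in the shipped experiments

The acceptance script and end-to-end tests use synthetic studies sized so
the statistical assertions have power at desk scale: null calibration with
~2000 independent pairs at depth 50; signal recovery with 200 families at
ρ = 0.9, depth 100; a full 20-trial study with 120 pairs, a matched random
control, 10⁶-sample permutation tests and the %MinMax arm; permutation-size
calibration with 200 replicate null table pairs of 664 pairs each at 10⁴
resamples.  The published-scale constants (664 pairs → 33.20 expected per
rank) enter analytically.

## Known limitations

* The built-in aligner is not MUSCLE; identity values and gap placements
  can differ slightly from the published pipeline (the import path exists
  for exact reproduction).
* The identity denominator (alignment columns excluding terminal gap runs)
  is one of several historical conventions.
* Whether %MinMax profiles should undergo the 40/20 gene-end trim is not
  settled; they are pushed through the identical chain here for
  comparability ("precisely the same fashion").
* The per-rank permutation test treats trials as exchangeable units; other
  groupings (e.g. pair-level relabeling) are defensible and would give
  different power.
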