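# Methods

## The estimation problem

Telomeres are tandem arrays of the hexamer TTAGGG at chromosome ends.
Classical sequencing-based estimators count telomeric reads and normalise
by overall coverage, which silently assumes a diploid karyotype: a
tetraploid tumour with unchanged telomere length doubles its telomeric
read count.  `telopair` instead normalises telomere *content* by telomere
*count*.  Complete telomeric read pairs (F1) measure content; read pairs
straddling the telomere/subtelomere boundary (F2a) count telomeres, since
every telomere has exactly one boundary.  The F1:F2a ratio is therefore a
ploidy-free length signal, and the whole pipeline reduces to measuring
those two counts well and inverting the ratio into base pairs.

The pipeline has three stages, each with its own module:

1. **TELBAM extraction** (`telbam`) — subset the BAM to candidate
   telomeric pairs: any pair where one mate contains ≥ 2 non-overlapping
   copies of TTAGGG or CCCTAA.  Capture is orientation-agnostic; strand
   information is used later.
2. **Error profiling and classification** (`error_profile`, `classify`) —
   decide per read whether it is *complete* telomere, tolerating
   sequencing error, then classify pairs into F1/F2/F3/F4 and form
   F2a = F2 − F4.
3. **Length inversion** (`length`) — solve for the telomere length whose
   simulated F1:F2a ratio matches the observed one, given the insert-size
   distribution.

## Mismatching loci by fragmentary alignment

A read is compared against the infinite tandem repeat (TTAGGG or CCCTAA,
whichever hexamer is more frequent in the read; ties default to TTAGGG and
are treated as unresolved during classification).  The algorithm:

1. decompose the read into greedy, maximal *phase runs* — substrings
   consistent with the infinite repeat under a single phase offset,
   partial hexamers included;
2. chain directly adjacent runs; a chain containing at least one complete
   literal hexamer is telomeric, and all its loci match;
3. each internal phase break inside a telomeric chain is an indel event
   and contributes exactly one mismatch, at the lower-Phred of the two
   junction loci;
4. residual intervals of length ≥ 4 are Hamming-aligned against all six
   phase offsets (fewest mismatches wins; ties by lowest mean Phred at the
   mismatching loci); shorter intervals are marked mismatching wholesale.
   N bases never match.

Reads shorter than one hexamer are fully mismatching.  On uniform random
sequence a read matches a fixed phase with probability ~¼ per base and the
best of six offsets does slightly better, so the mismatch count z tops out
around 0.75·L (empirically mean ≈ 0.69·L, 95th percentile ≈ 0.74·L for
L = 100); this is the signature of non-telomeric reads in the profile
matrices and is asserted as a property test.

## The error profile

For every read with z ≥ 1 mismatches, λ = ⌊mean Phred at mismatching
loci⌋ − P_min, where P_min/P_max are the extreme Phred values observed in
the TELBAM.  Matrix **X** counts reads per (λ, z) cell; **Y** repeats the
tally with each read's mismatch positions replaced by z uniformly sampled
distinct loci of the same read (one resample per read, seeded — a single
resample keeps ΣX = ΣY exact, and averaging resamples would only shrink
Y's variance, which the threshold step does not require).  Matrices have
P_max − P_min + 1 rows and L + 1 columns, so fully divergent reads
(z = L) are representable and the threshold quadrant below is well
defined.

Sequencing error concentrates at low Phred, so telomere reads damaged by
error form an excess of X over Y at low λ and low-to-moderate z.  The
mask is built from D = X − Y as:

* threshold: k = max D over the quadrant (p/2 < i ≤ p, L/2 < j ≤ L),
  p = P_max − P_min — a region where no error signal is expected;
  initially e_ij = 1 iff d_ij > k;
* noise removal: keep only 4-connected components that touch the
  low-Phred rows 0..⌊p/4⌋ and contain at least two cells;
* low-Phred capture: within rows 0..⌊p/4⌋, fill every cell with positive
  excess in columns up to the rightmost already-masked low-Phred column.

The component and fill rules implement the stated intent of the two
refinement steps (de-noising, then guaranteeing low-Phred capture); their
exact published pseudocode is not available, so the formulation here is
normative for this package.  A read is **complete** if ≥ 90% of its loci
match the repeat *or* its (λ, z) cell lies in the mask.  The 90% level is
a config constant; raising it is reported to hurt accuracy, consistent
with genuine telomere-variant repeats near the boundary.

## Pair classification and interstitial correction

F1: both mates complete.  F2: exactly one complete, reading CCCTAA.
F4: exactly one complete, reading TTAGGG.  F3: neither.  The asymmetry
between F2 and F4 is strand physics: paired-end reads are stored
as-sequenced, and at a true telomere the mate lying wholly in the repeat
is always read from the C-rich strand.  A chromosome ends at its
telomere, so TTAGGG-complete pairs can only arise at the far side of an
interstitial telomeric repeat (ITR); since an ITR has two boundaries, its
CCCTAA-side pair count (F2b) equals its F4 count in expectation, and

    F2a = F2 − F4

removes ITR contamination without any positional filtering.  Negative
values (pure sampling noise) are clamped to zero with a warning.

## Cohort correction

θ = F2a/(F2+F4) is the boundary fraction; across a cohort processed
together each sample's θ is shrunk toward the cohort mean θ_exp:

    θ_cor = (θ_obs·ψ + θ_exp·w) / (ψ + w),   w = 3 by default

with ψ the variance-to-mean ratio of X over rows 1..⌊2p/5⌋ (a dispersed,
information-rich error profile trusts its own θ; a flat one defers to the
cohort).  The published formula divides by ψ·w, under which a cohort of
identical θ is not a fixed point even though the operation is described
as a weighted average; the convex form above restores the fixed point and
keeps θ_cor between θ_obs and θ_exp.  The strict as-printed form is
available behind `eq9_as_printed=True`.  Adjusted F2a = θ_cor·(F2+F4);
single-sample cohorts are never corrected.

## Length inversion

Fragments are simulated with insert lengths from Normal(μ, σ) truncated
below at 2L and integer start positions uniform over a telomere of trial
length T (subtelomere beyond the boundary is implicit).  A fragment is F1
if it ends at or before T, F2a if its left read fits inside T but the
fragment crosses T.  With σ = 0 and fixed insert I the exhaustive
enumeration gives

    E[F1]/E[F2a] = (T − I + 1)/(I − L),

which is the test oracle for the simulation and its inversion.  The
observed ratio is inverted by bracketing + bisection on T to 1 bp (max 60
iterations), reusing the same fragment draws at every trial length
(common random numbers), which makes the simulated ratio monotone in T
and the whole estimate bit-reproducible for a fixed seed.  Defaults:
n_sim = 10,000 per evaluation for interactive use; the test-suite and
acceptance runs use 2·10⁵–10⁶ where the Monte-Carlo error must be small
against the band being checked.  Degenerate inputs: F2a = 0 raises (no
boundary reads — nothing to normalise by); F1 = 0 returns the lower
bracket with a warning (telomere shorter than the insert).

Insert-size parameters come from the template-length field of proper
pairs (one observation per pair, winsorised at the empirical 1st/99th
percentiles by rank to suppress chimeric outliers) or from an explicit
override.  When several platforms are mixed, per-platform means are
aligned to the alphabetically first (or designated) platform by an
additive shift, preserving within-group differences; with a single
platform the correction is a logged no-op unless an explicit offset is
supplied.

## The synthetic-data generator

`synth.SyntheticSpec` describes a sample generatively: telomere tract
length, number of telomeres, subtelomere length, ITR (length, copies)
list, coverage, read length, insert distribution, error rate, and the
quality model.  Telomere contigs carry the repeat at the contig start
(CCCTAA phase) followed by random subtelomere; ITR contigs embed a TTAGGG
run between random flanks long enough that boundary-crossing fragments
fit on both sides.  Reads store as-sequenced bases (the reverse mate is
the reverse complement of its slice), which is exactly what makes the
F2/F4 strand asymmetry emerge; coordinates and TLEN are written correctly
for insert estimation but are never otherwise interpreted.  Per-contig
random streams are derived from the sample seed and contig name, so an
ITR-free twin of a sample shares its telomere-derived reads
byte-for-byte — the twin comparison isolates the ITR effect exactly.

Qualities are two-level — phred_low (default 11) on a seeded fraction of
loci (default 0.2), phred_high (default 37) elsewhere — with small
per-locus integer jitter (±2 / ±3, clipped to [2, 41]).  The jitter
matters: with exactly two quality values λ collapses onto a sparse
lattice and the mask's connected-component structure becomes meaningless
on data no real sequencer produces.  A fraction `low_phred_bias` (default
0.9) of injected errors lands on low-quality loci; `indel_fraction`
(default 0.1) of errors are single-base indels, the rest substitutions.

Defaults represent a desk-scale WGS experiment: 100 bp reads, 350 ± 30 bp
inserts, 1% error concentrated at low Phred, 12 telomeres.  What the
generator does **not** emulate: a genomic background (no decoy
chromosomes beyond ITR flanks), variant repeats in the subtelomere,
GC-coverage bias, duplicate or chimeric fragments, and quality decay
along the read.  Passing tests therefore demonstrate the internal
consistency and statistical behaviour of the method under its own
generative assumptions, not performance on real sequencers.

## Problem sizes and numerical margins used by the test suite

Fixture sizes were set by a Poisson power analysis of the boundary-pair
counts before the suite was assembled.  Parameter recovery uses 12
telomeres at 50× coverage (boundary count ≈ 750, counting CV ≈ 3.7%,
leaving ≥ 2.5σ inside the ±10% recovery band) for ten seeded replicates
at 2, 5 and 10 kb.  The ITR-neutrality twin uses 95 bp runs — the
shortest ITR that still yields ≥ 90%-complete reads — precisely because
the variance of the F2 − F4 subtraction grows with the boundary-window
width; 70 copies put ITR pairs at ~37% of the TELBAM.  The error-profile
stress fixture uses a 12% substitution rate so that most truth-telomeric
reads fail the 90% rule and must be recovered through the mask, while a
bias-free twin of the same fixture checks that the mask stays essentially
empty without a Phred/error association.  The closed-form grid covers
tl ∈ {1, 2, 4, 8} kb × insert ∈ {300, 350, 400} bp at σ = 0.

## Known limitations

* The method yields a single mean length per sample; per-chromosome or
  allelic distributions are out of reach by design.
* F2a is a small count; its Poisson noise dominates the estimator
  variance (hence the cohort correction).
* The F2b ≡ F4 identity holds in expectation only; heavy ITR load adds
  √(2·F4) noise to F2a even when the mean cancels exactly.
* Orientation ties (equal TTAGGG and CCCTAA content in a complete read)
  are classified F3 and logged; they are vanishingly rare on reads longer
  than a few repeats.
* CRAM input and multi-process BAM decoding are not supported.
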