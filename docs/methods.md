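# Methods

## Trace decomposition model

A bulk Sanger trace of a PCR amplicon from an edited cell population is
modeled, downstream of the nuclease cut site, as a non-negative linear
superposition of indel-shifted copies of the wild-type (control) trace.
Working at one row per called base (four channel intensities per position,
A/C/G/T order), the component for indel size *d* over the decomposition
window is:

* deletion (*d* < 0): control intensity advanced by |*d*| positions —
  window position *p* reads control position *p* + |*d*|;
* insertion (*d* > 0): control delayed by *d*, with the *d* novel positions
  `[cut, cut + d)` masked, since the control carries no information about
  inserted bases;
* *d* = 0: the control itself.

The weights solve non-negative least squares over all unmasked
(position, channel) cells; frequencies are the normalized weights. Because
the joint regression needs a single shared cell set while each insertion
candidate masks a different prefix, the fit excludes the union of all
candidate insertion masks — window positions `[cut, cut + max_indel)`. With
the default window this sacrifices 30 of ~250 post-cut positions and makes
every component fully defined on the remaining cells.

Any solver reaching the global optimum of this convex problem is
acceptable; the implementation uses `scipy.optimize.nnls`, and the test
suite checks it against an exhaustive grid search over mixture fractions
(the grid oracle shares only the residual definition, not the solution
path).

### Registration and scaling

Sample and control are registered by maximizing Pearson correlation of the
flattened channel intensities over the first `alignment_window` (default
100) positions — a region upstream of the cut where every allele agrees
with wild type — over integer shifts in ±10. Both traces are then scaled to
equal total intensity over that window so weights are comparable mixture
fractions. A best correlation below 0.5 signals a sample/control mismatch:
`align_control` raises when called directly, while `fit()` proceeds at
offset 0 and lets the R² rule eliminate the well, matching screening
practice (an unreadable well is discarded, not a crashed run).

### Significance and reporting

Published decomposition practice specifies only a cutoff
(p < 1e-4), not a test. We refit the active (non-zero) component set by
unconstrained OLS and use the coefficient *t*-statistics, two-sided. This
is approximate — the active set was itself chosen by the data — but
standard for this model class. Components failing the cutoff or below
`min_report_freq` (0.5%, numerical dust guard, not part of the original
procedure) are dropped and the rest renormalized to 100%.

R² is computed with the *uncentered* total sum of squares, the standard
convention for regression without an intercept (cf. statsmodels OLS
without a constant): the model has no baseline term, and centering would
penalize exactly the signal the components are meant to explain. Fits with
R² < `min_r2` (default 0.95) get status `eliminated_low_fit`; efficiency
queries on eliminated results raise.

Degenerate inputs raise explicitly: a window smaller than the candidate
count is an under-determined error; an all-zero sample window is a
degenerate-input error.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `max_indel` | 30 bp | candidate indel sizes ±1..30 |
| `decomposition_window` | [115, 500) | trace positions regressed (intersected with [cut, end)) |
| `alignment_window` | 100 bp | upstream registration/scaling region |
| `p_cutoff` | 1e-4 | per-component significance |
| `min_r2` | 0.95 | fit-quality gate |
| `min_report_freq` | 0.5% | suppress numerically tiny components |

Coordinates are 0-based half-open everywhere; the cut site is an inter-base
index (a deletion of *d* removes `[cut, cut + d)`; an insertion sits at
`cut`). Basecall ties break alphabetically (A<C<G<T) for determinism.

## Synthetic data generator

The generator replaces genomic DNA from edited CHO pools; its defaults are
the conditions under which all validation numbers are computed.

Traces: each allele contributes `proportion × amplitude(i)` to the channel
of its base, with `amplitude(i) = base_amplitude · exp(−decay_rate · i)`
(defaults 1000 and 0.002/base — signal decays to ~33% across a 560 bp
read). Crosstalk redistributes a fraction (default 0.02) of each channel
into each other channel, emulating dye spectral overlap; additive Gaussian
noise (sd 30, ~3% of peak) is truncated at zero. These three knobs
reproduce the qualitative failure modes decomposition must tolerate —
baseline noise, 3′ degradation, miscalls — but not real-trace artifacts
such as mobility shifts, dye blobs, or position-dependent peak-width
changes; passing tests therefore demonstrate correctness of the estimator
against its own signal model, not performance on arbitrary real traces.

Wells: homozygous (one mutant allele at 100%), compound het (two mutant
alleles at 50:50, each side perturbed by N(0, jitter_sd), default 0.05),
het-with-WT (WT plus one mutant, jittered 50:50), nonclonal (3–5 alleles,
symmetric Dirichlet with concentration 2 — progenitor cells contribute
comparable mass; concentration 1 would frequently produce sub-detection
slivers that no screening assay could see).

Reads: single-end, constant phred 40 (a configurable fraction at phred 20
to exercise the quality filter), substitution errors i.i.d.; each read
spans the cut with ≥25 bp of context on both sides of the edited region so
the aligner can anchor the indel. Real paired-end 2×150 data adds nothing
to the indel-frequency oracle at this scale.

Mixing series: Mix-*k* pools the first *k* of up to five homozygous clones
at equal parts by default; the exact ratio vectors are a parameter because
the stepwise design admits any.

All outputs are bit-reproducible under a fixed seed; pipeline stages derive
independent substreams from one master seed via CRC32-named
`SeedSequence` children.

## Read-count oracle

Reads with mean phred below 30 are discarded (the per-read reading of the
upstream pipeline's ambiguous per-read/per-base phred-30 rule; on
constant-quality synthetic reads the two coincide). Passing reads are
aligned to the amplicon with an affine-gap semi-global Gotoh DP (read fully
aligned, reference overhangs free; match +2, mismatch −3, gap open −8,
extend −1 — chosen to favor one contiguous indel over scattered gaps, as
expected from single-cut repair). Ties break deterministically:
match/mismatch over gap, reference deletion over read insertion, earliest
reference end point. The net indel is summed over alignment operations
overlapping cut ± 10 bp, insulating calls from read-end errors. Duplicate
read sequences are aligned once (quantification is invariant to read order
and duplication). The aligner is implemented in-package because the
deterministic tie-break is part of its contract; Biopython's
PairwiseAligner independently cross-checks optimal scores in the tests.

## Triage rules

In order: (1) eliminated fits → indeterminate; (2) variants < 5% ignored;
(3) WT ≥ 10% → discard (wild-type allele survived); (4) more than
`max_variants` (default 2) mutant variants → discard non-clonal; (5) one
variant in [85, 100] → retain homozygous; (6) two variants each in
50 ± 15 → retain compound het; (7) otherwise discard non-clonal. The ±15 pp
bands comfortably exceed the decomposition-vs-read-oracle deviation scale
while rejecting three-way (33:33:33) mixtures. The variant-count cutoff is
exposed as a setting because the source procedure is ambiguous between 2
and 3; 2 is the default. Wells failing the 50:50 band are discarded rather
than given a separate "atypical genotype" class — the frequency pattern is
used as a crude clonality metric, and ambiguity is resolved toward
discarding. Retained wells carry a `confirm_by_imaging` flag: frequency
patterns cannot exclude co-founded wells with identical indels, so imaging
remains the late-stage filter.

In recovery experiments the ground-truth verdict of a well is obtained by
applying the same rules to its true mixture proportions (not by mapping
class names to verdicts): a multi-progenitor well containing WT is
*correctly* discarded by the WT rule, which precedes the count rule, and a
compound het whose jitter draw falls outside the band is genuinely
off-pattern.

## Spectrum aggregation and comparison

Mutant allele frequencies (WT excluded from the denominator) are summed
per indel size across samples and renormalized to 100%, binned as
deletions 1–15, insertions 1–15, and "other" (|size| > 15); the frameshift
fraction is the mutant mass at sizes not divisible by 3. Two groups of
replicate spectra are compared per bin with Welch's t-test and
Benjamini–Hochberg adjustment across bins; bins constant and equal in both
groups get p = 1. A two-way ANOVA would need a replicate structure the
source procedure does not describe; the per-bin formulation tests the same
hypotheses and its family-wise error under the global null is verified by
simulation (≤ 7% at BH level 0.05 over 500 runs).

## T7 mismatch-cleavage estimate

`indel% = 100 · (1 − √(1 − f_cut))` with
`f_cut = (frag1 + frag2) / (parent + frag1 + frag2)`: under random
re-annealing of two allele populations the uncut fraction is the squared
homoduplex probability. Monotone in `f_cut`, bounded in [0, 100]; band
intensities are numeric inputs (gel image processing is out of scope).

## Problem sizes in the validation suite

The packaged experiments run at desk scale: a 560 bp amplicon (cut at 250),
13 clones × 10,000 reads for the decomposition-vs-oracle deviation, 50
two-allele recoveries, 200 triage wells, 500 null simulations for error
control, 30 grid-oracle cases. These sizes put Monte-Carlo noise well below
every asserted tolerance while keeping the whole suite inside a coffee
break.

## Known limitations

* Inserted-base identities are unmodeled (masked from the residual); +1
  insertion identity calling is out of scope.
* Two alleles with the same indel size are unresolvable by construction.
* The significance test conditions on the NNLS-selected active set;
  p-values are approximate.
* Insertion components inherit slightly brighter upstream control signal
  under amplitude decay, biasing insertion frequencies by ~1 pp at the
  default decay rate; deletions are unaffected.
* Vendor binary chromatogram containers are not parsed; traces enter
  through the documented TSV dialect.
* Substitution (base-editing) outcomes, multi-guide dual cuts, and
  paired-end read handling are out of scope.
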