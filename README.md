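# tracedecomp

Indel decomposition of bulk Sanger chromatograms and clone triage for
gene-edited cell lines.

## The problem

After CRISPR/Cas9 or ZFN editing, a cell pool (or a clone well during
single-cell cloning) carries a mixture of alleles: wild type plus deletions
and insertions of various sizes at the cut site. A single bulk Sanger read of
the PCR amplicon superimposes all of them — downstream of the cut the trace
becomes a weighted overlay of frame-shifted copies of the wild-type trace.
`tracedecomp` recovers the underlying indel-allele frequency spectrum from
that overlay, and turns per-well spectra into retain/discard decisions during
knockout cell line development: wells showing wild type or more variants than
one progenitor cell can explain are discarded; wells matching a homozygous
(100%) or compound-heterozygous (50:50) pattern are retained.

## The model

Let $y$ be the sample trace's per-base channel intensities over a
decomposition window downstream of the cut, and $x_d$ the control
(wild-type) trace shifted by indel size $d \in \{-30,\dots,+30\}$ (deletion
$d<0$: control advanced by $|d|$ positions; insertion $d>0$: control delayed
by $d$ with the $d$ novel positions masked). The allele weights solve the
non-negative least-squares problem

$$\min_{w \ge 0}\;\Big\|\,y - \sum_d w_d\, x_d\,\Big\|^2 ,$$

with frequencies $f_d = 100\, w_d / \sum w$. Per-component significance
comes from an unconstrained OLS refit on the active set (two-sided, default
cutoff $p < 10^{-4}$); fits with uncentered $R^2 < 0.95$ are eliminated as
unreadable. An affine-gap semi-global read aligner provides an independent
read-count oracle (net indel within ±10 bp of the cut per read) for
validation, and the T7 mismatch-cleavage estimate
$100\,(1-\sqrt{1-f_\mathrm{cut}})$ is included for assay comparison.

Because no public chromatograms accompany this workflow, the package ships a
first-class synthetic generator: allele mixtures rendered as traces under an
exponential-decay / Gaussian-noise / channel-crosstalk signal model, labeled
clone wells of each genotype class, stepwise clone-mixing series, and
error-bearing cut-site-spanning reads.

## Worked example

```python
from tracedecomp import (
    Mixture, TraceNoiseModel, apply_indel, decompose,
    example_reference, simulate_trace, classify_well,
)

ref = example_reference()                  # 560 bp synthetic amplicon, cut at 250
wt = apply_indel(ref, 0)
mix = Mixture(components=((apply_indel(ref, -7), 0.5),
                          (apply_indel(ref, -11), 0.5)))   # compound het clone
noise = TraceNoiseModel(seed=11)           # amplitude 1000, decay 0.002, sd 30
sample = simulate_trace(mix, ref, noise)
control = simulate_trace(Mixture(components=((wt, 1.0),)), ref,
                         TraceNoiseModel(seed=12))

res = decompose(sample, control, ref)
print(res.summary())
print(classify_well(res).verdict)
```

prints

```
Trace decomposition results
==============================================
components tested   : 61
registration offset : +0
R-squared           : 0.9716
status              : ok
editing efficiency  : 100.0%
----------------------------------------------
 indel_size frequency  p_value  std_err
        -11     49.79 0.00e+00 0.00558
         -7     50.21 0.00e+00 0.00555
retain_compound_het
```

The two deletion alleles are recovered at 49.8% / 50.2% against a true
50:50, the fit explains 97.2% of the windowed signal, no wild type is
detected (efficiency 100%), and the triage rules retain the well as a
compound-heterozygous knockout.

The same operations are available from the shell (`tracedecomp
simulate-trace | decompose | quantify-reads | triage | ...`); every
simulation command writes a JSON manifest with its seed and parameters.

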