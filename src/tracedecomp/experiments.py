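"""Packaged validation experiments beyond the two headline pipelines.

These drive the library end to end at desk scale: triage recovery on
labeled synthetic plates, shuffled-control rejection, and the null
calibration of the spectrum comparison. They are used by the validation
suite and the reproduction script; parameters default to the study
conditions the generators emulate.
"""

from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .core import Chromatogram, Mixture, ReferenceAmplicon, apply_indel
from .decompose import DecompositionSettings, TraceDecomposition
from .pipeline import spawn_seeds
from .screening import TriageSettings, aggregate_spectrum, classify_well, compare_spectra
from .simulate import (
    GENOTYPE_CLASSES,
    TraceNoiseModel,
    example_reference,
    random_allele_pool,
    simulate_trace,
    simulate_well,
)

__all__ = [
    "truth_verdict",
    "run_triage_recovery",
    "run_shuffled_control_rejection",
    "spectrum_comparison_null_rate",
]


def truth_verdict(mixture: Mixture, settings: TriageSettings | None = None) -> str:
    """Verdict an oracle with perfect knowledge of the mixture would issue.

    Applies the same triage rules to the true allele proportions. This is
    the ground truth for recovery experiments: e.g. a multi-progenitor well
    that happens to contain wild type is correctly discarded by the
    wild-type rule, which precedes the variant-count rule.
    """
    table = pd.Series(
        {a.indel_size: 100.0 * p for a, p in mixture.components}, dtype=float
    )
    fake = SimpleNamespace(
        status="ok", r_squared=1.0, frequency_table=lambda t=table: t
    )
    return classify_well(fake, settings).verdict


def run_triage_recovery(
    n_per_class: int = 50,
    seed: int = 0,
    reference: ReferenceAmplicon | None = None,
    noise: TraceNoiseModel | None = None,
    decomposition: DecompositionSettings | None = None,
    triage: TriageSettings | None = None,
) -> pd.DataFrame:
    """Simulate labeled wells of every genotype class and triage them.

    Returns one row per well with its class, truth mixture, oracle verdict
    (triage rules applied to the truth), assigned verdict, and agreement
    flag; ``df.agree.mean()`` is the recovery rate.
    """
    reference = reference or example_reference()
    base_noise = noise or TraceNoiseModel()
    pool = random_allele_pool(reference, seed=spawn_seeds(seed, 1, "pool")[0])
    control = _control_trace(reference, base_noise, spawn_seeds(seed, 1, "control")[0])
    well_seeds = spawn_seeds(seed, n_per_class * len(GENOTYPE_CLASSES), "wells")
    rows = []
    k = 0
    for cls in GENOTYPE_CLASSES:
        for _ in range(n_per_class):
            trace, label = simulate_well(
                cls, pool, reference, base_noise, seed=well_seeds[k]
            )
            k += 1
            res = TraceDecomposition(trace, control, reference, decomposition).fit()
            verdict = classify_well(res, triage).verdict
            expected = truth_verdict(label.truth, triage)
            rows.append(
                {
                    "genotype_class": cls,
                    "truth": ";".join(
                        f"{a.indel_size:+d}:{p:.3f}" for a, p in label.truth.components
                    ),
                    "expected_verdict": expected,
                    "verdict": verdict,
                    "agree": verdict == expected,
                    "r_squared": res.r_squared,
                }
            )
    return pd.DataFrame(rows)


def run_shuffled_control_rejection(
    n_wells: int = 20,
    seed: int = 0,
    reference: ReferenceAmplicon | None = None,
    noise: TraceNoiseModel | None = None,
) -> float:
    """Fraction of wells eliminated when decomposed against a shuffled control.

    Shuffling the control's positions destroys the component structure; the
    R^2 < 0.95 rule should eliminate every such fit (returns 1.0 when it
    does).
    """
    reference = reference or example_reference()
    base_noise = noise or TraceNoiseModel()
    pool = random_allele_pool(reference, seed=spawn_seeds(seed, 1, "pool")[0])
    control = _control_trace(reference, base_noise, spawn_seeds(seed, 1, "control")[0])
    rng = np.random.default_rng(spawn_seeds(seed, 1, "shuffle")[0])
    shuffled = Chromatogram(channels=control.channels[rng.permutation(len(control))])
    well_seeds = spawn_seeds(seed, n_wells, "shuffle-wells")
    n_rejected = 0
    for i in range(n_wells):
        cls = GENOTYPE_CLASSES[i % len(GENOTYPE_CLASSES)]
        trace, _ = simulate_well(cls, pool, reference, base_noise, seed=well_seeds[i])
        res = TraceDecomposition(trace, shuffled, reference).fit()
        if res.status == "eliminated_low_fit":
            n_rejected += 1
    return n_rejected / n_wells


def spectrum_comparison_null_rate(
    n_sims: int = 500,
    n_replicates: int = 4,
    depth: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Family-wise false-positive rate of ``compare_spectra`` under the null.

    Both groups draw replicate spectra by multinomial sampling of ``depth``
    mutant reads from the same underlying indel distribution; returns the
    fraction of simulations flagging any bin significant (Benjamini-
    Hochberg at ``alpha``).
    """
    sizes = np.array([-1, -2, -3, -4, -6, -9, 1, 2])
    probs = np.array([0.22, 0.18, 0.14, 0.12, 0.1, 0.09, 0.09, 0.06])
    rng = np.random.default_rng(spawn_seeds(seed, 1, "null")[0])

    def draw_group():
        group = []
        for _ in range(n_replicates):
            counts = rng.multinomial(depth, probs)
            table = pd.Series(
                {int(s): 100.0 * c / depth for s, c in zip(sizes, counts) if c}
            )
            group.append(aggregate_spectrum([table]))
        return group

    n_any = 0
    for _ in range(n_sims):
        if compare_spectra(draw_group(), draw_group(), alpha=alpha).significant.any():
            n_any += 1
    return n_any / n_sims


def _control_trace(
    reference: ReferenceAmplicon, noise: TraceNoiseModel, seed: int
) -> Chromatogram:
    wt = Mixture(components=((apply_indel(reference, 0), 1.0),))
    return simulate_trace(wt, reference, replace(noise, seed=seed))
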