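"""Clone-well triage, indel-spectrum aggregation and the T7 assay formula.

Triage turns a per-well decomposition result into a keep/discard verdict:
wells showing wild type are discarded (the target allele survives), wells
with more distinct variants than one cell can carry are discarded as
non-clonal, and wells whose variant frequencies fit the expected 100%
(homozygous) or 50:50 (compound heterozygous) pattern are retained for
downstream verification. Spectrum aggregation pools mutant allele
frequencies across samples into a deletion/insertion size profile with a
frameshift fraction, and ``compare_spectra`` tests per-size-bin differences
between two groups of replicate spectra with Benjamini-Hochberg control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TriageSettings",
    "TriageDecision",
    "IndelSpectrum",
    "T7Bands",
    "classify_well",
    "screen_plate",
    "PlateReport",
    "frameshift_class",
    "aggregate_spectrum",
    "compare_spectra",
    "t7_indel_fraction",
    "SPECTRUM_MAX_SIZE",
]

#: Spectrum size bins run 1..15 bp for deletions and insertions; anything
#: larger pools into the "other" bin.
SPECTRUM_MAX_SIZE = 15


@dataclass(frozen=True)
class TriageSettings:
    """Decision thresholds for clone-well triage.

    ``max_variants`` — more distinct non-WT variants than this implies
    multiple progenitor cells. ``wt_min_freq`` — wild-type frequency at or
    above this discards the well. A single variant within
    ``[100 - hom_tolerance, 100]`` retains as homozygous; two variants each
    within ``50 ± het_tolerance`` retain as compound heterozygous. Variants
    below ``min_variant_freq`` percent are ignored as noise.
    """

    max_variants: int = 2
    wt_min_freq: float = 10.0
    hom_tolerance: float = 15.0
    het_tolerance: float = 15.0
    min_variant_freq: float = 5.0

    def __post_init__(self) -> None:
        if self.max_variants < 1:
            raise ValueError("max_variants must be >= 1")
        for tol in (self.hom_tolerance, self.het_tolerance):
            if not 0 < tol < 50:
                raise ValueError("tolerances must be in (0, 50)")


@dataclass(frozen=True)
class TriageDecision:
    """Verdict for one well, with the variants that drove it."""

    verdict: str
    reason: str
    variants_considered: tuple[tuple[int, float], ...]


VERDICTS = (
    "retain_homozygous",
    "retain_compound_het",
    "discard_wildtype",
    "discard_nonclonal",
    "indeterminate",
)


def classify_well(result, settings: TriageSettings | None = None) -> TriageDecision:
    """Apply the triage rules to one decomposition result.

    Rule order: (1) eliminated fits are indeterminate; (2) sub-threshold
    variants dropped; (3) wild type at >= wt_min_freq discards; (4) more
    than max_variants non-WT variants discards as non-clonal; (5) a single
    variant in the homozygous band retains; (6) two variants each in the
    50:50 band retain as compound het; (7) anything else discards as
    non-clonal (frequencies deviate from the one- or two-allele pattern).

    Pure function of (result, settings): variant order never matters.
    """
    st = settings or TriageSettings()
    if result.status == "eliminated_low_fit":
        return TriageDecision(
            verdict="indeterminate",
            reason=f"decomposition eliminated (R^2 {result.r_squared:.3f})",
            variants_considered=(),
        )
    table = result.frequency_table()
    considered = tuple(
        sorted(
            (int(s), float(f))
            for s, f in table.items()
            if f >= st.min_variant_freq
        )
    )
    wt_freq = next((f for s, f in considered if s == 0), 0.0)
    if wt_freq >= st.wt_min_freq:
        return TriageDecision(
            verdict="discard_wildtype",
            reason=f"wild type present at {wt_freq:.1f}%",
            variants_considered=considered,
        )
    mutants = [(s, f) for s, f in considered if s != 0]
    if len(mutants) > st.max_variants:
        return TriageDecision(
            verdict="discard_nonclonal",
            reason=f"{len(mutants)} variants exceed max of {st.max_variants}",
            variants_considered=considered,
        )
    if len(mutants) == 1:
        s, f = mutants[0]
        if 100.0 - st.hom_tolerance <= f <= 100.0:
            return TriageDecision(
                verdict="retain_homozygous",
                reason=f"single variant {s:+d} at {f:.1f}%",
                variants_considered=considered,
            )
    if len(mutants) == 2:
        if all(abs(f - 50.0) <= st.het_tolerance for _, f in mutants):
            desc = ", ".join(f"{s:+d} at {f:.1f}%" for s, f in mutants)
            return TriageDecision(
                verdict="retain_compound_het",
                reason=f"two variants near 50:50 ({desc})",
                variants_considered=considered,
            )
    return TriageDecision(
        verdict="discard_nonclonal",
        reason="variant frequencies deviate from 100% / 50:50 pattern",
        variants_considered=considered,
    )


@dataclass(frozen=True)
class PlateReport:
    """Per-well triage decisions plus verdict counts.

    Retained wells carry ``confirm_by_imaging=True``: frequency patterns
    cannot exclude a well founded by multiple cells with identical indels,
    so retained clones still need imaging confirmation.
    """

    wells: pd.DataFrame
    counts: dict[str, int]

    def summary(self) -> str:
        lines = ["Plate triage report", "=" * 46]
        for v in VERDICTS:
            lines.append(f"{v:<22}: {self.counts.get(v, 0)}")
        lines.append("-" * 46)
        lines.append(self.wells.to_string(index=False))
        return "\n".join(lines)


def screen_plate(
    results, settings: TriageSettings | None = None
) -> PlateReport:
    """Triage a plate of (well_id, decomposition result) pairs."""
    results = list(results)
    if not results:
        raise ValueError("empty plate")
    ids = [wid for wid, _ in results]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate well ids")
    rows = []
    for wid, res in sorted(results, key=lambda t: str(t[0])):
        d = classify_well(res, settings)
        rows.append(
            {
                "well": wid,
                "verdict": d.verdict,
                "reason": d.reason,
                "r_squared": round(float(res.r_squared), 4),
                "variants": ";".join(f"{s:+d}:{f:.1f}" for s, f in d.variants_considered),
                "confirm_by_imaging": d.verdict.startswith("retain"),
            }
        )
    df = pd.DataFrame(rows)
    counts = df.verdict.value_counts().to_dict()
    return PlateReport(wells=df, counts=counts)


def frameshift_class(indel_size: int) -> str:
    """wild_type for 0, in_frame for multiples of 3, frameshift otherwise."""
    if indel_size == 0:
        return "wild_type"
    return "in_frame" if indel_size % 3 == 0 else "frameshift"


@dataclass(frozen=True)
class IndelSpectrum:
    """Mutant-allele size profile: percent per deletion/insertion size 1-15.

    Frequencies are percentages of mutant alleles only (wild type is
    excluded from the denominator); sizes beyond +/-15 bp pool into
    ``other_freq``. ``frameshift_fraction`` is the percent of mutant mass
    at sizes not divisible by 3.
    """

    deletion_freq: np.ndarray  # index k -> deletion of k+1 bp
    insertion_freq: np.ndarray
    other_freq: float
    frameshift_fraction: float

    def as_series(self) -> pd.Series:
        idx = (
            [f"del{k}" for k in range(1, SPECTRUM_MAX_SIZE + 1)]
            + [f"ins{k}" for k in range(1, SPECTRUM_MAX_SIZE + 1)]
            + ["other"]
        )
        vals = np.concatenate(
            [self.deletion_freq, self.insertion_freq, [self.other_freq]]
        )
        return pd.Series(vals, index=idx, name="frequency")

    @property
    def total(self) -> float:
        return float(self.deletion_freq.sum() + self.insertion_freq.sum() + self.other_freq)


def aggregate_spectrum(tables) -> IndelSpectrum:
    """Pool mutant allele frequencies from several samples into one spectrum.

    Each table maps indel size to percent (decomposition or read-count
    output). Wild-type entries are dropped, mutant frequencies summed per
    size across tables, and the result renormalized to 100% of mutant mass.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to aggregate")
    pooled: dict[int, float] = {}
    for t in tables:
        items = t.items() if hasattr(t, "items") else t
        for size, freq in items:
            size = int(size)
            if size == 0:
                continue
            pooled[size] = pooled.get(size, 0.0) + float(freq)
    total = sum(pooled.values())
    if total <= 0:
        raise ValueError("all tables are pure wild type: empty mutant spectrum")
    dele = np.zeros(SPECTRUM_MAX_SIZE)
    ins = np.zeros(SPECTRUM_MAX_SIZE)
    other = 0.0
    frameshift = 0.0
    for size, mass in pooled.items():
        pct = 100.0 * mass / total
        if size < 0 and -size <= SPECTRUM_MAX_SIZE:
            dele[-size - 1] += pct
        elif size > 0 and size <= SPECTRUM_MAX_SIZE:
            ins[size - 1] += pct
        else:
            other += pct
        if frameshift_class(size) == "frameshift":
            frameshift += pct
    return IndelSpectrum(
        deletion_freq=dele,
        insertion_freq=ins,
        other_freq=other,
        frameshift_fraction=frameshift,
    )


def compare_spectra(
    a, b, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-size-bin comparison of two groups of replicate spectra.

    Welch two-sample t-test per bin on replicate frequencies, with
    Benjamini-Hochberg adjustment across bins. Bins with no variation in
    either group and equal means get p = 1. Returns a table with the mean
    difference (percentage points, group a minus group b), raw and
    adjusted p-values and a significance flag at ``alpha``.
    """
    a, b = list(a), list(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicate spectra per group")
    mat_a = pd.concat([s.as_series() for s in a], axis=1)
    mat_b = pd.concat([s.as_series() for s in b], axis=1)
    if not mat_a.index.equals(mat_b.index):
        raise ValueError("replicate spectra have mismatched bin domains")
    effects, pvals = [], []
    for bin_name in mat_a.index:
        xa = mat_a.loc[bin_name].to_numpy(dtype=float)
        xb = mat_b.loc[bin_name].to_numpy(dtype=float)
        effects.append(float(xa.mean() - xb.mean()))
        if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]):
            pvals.append(1.0 if math.isclose(xa[0], xb[0]) else 0.0)
            continue
        _, p = stats.ttest_ind(xa, xb, equal_var=False)
        pvals.append(1.0 if not np.isfinite(p) else float(p))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "bin": mat_a.index,
            "effect_pp": effects,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "significant": reject,
        }
    )


@dataclass(frozen=True)
class T7Bands:
    """Densitometry intensities of the parent band and two cleavage fragments."""

    parent: float
    frag1: float
    frag2: float

    def __post_init__(self) -> None:
        if min(self.parent, self.frag1, self.frag2) < 0:
            raise ValueError("band intensities must be non-negative")
        if self.parent + self.frag1 + self.frag2 <= 0:
            raise ValueError("all-zero band intensities")

    @property
    def cut_fraction(self) -> float:
        return (self.frag1 + self.frag2) / (self.parent + self.frag1 + self.frag2)


def t7_indel_fraction(bands: T7Bands) -> float:
    """Indel percentage from mismatch-cleavage band intensities.

    Uses the standard densitometry estimate ``100 * (1 - sqrt(1 - f_cut))``
    with ``f_cut = (frag1 + frag2) / (parent + frag1 + frag2)``: under
    random re-annealing of two allele populations the uncut fraction is the
    squared probability of a homoduplex.
    """
    f_cut = bands.cut_fraction
    return 100.0 * (1.0 - math.sqrt(1.0 - f_cut))
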