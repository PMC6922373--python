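"""End-to-end orchestration: plate screening and packaged validation experiments.

``run_screen`` drives decompose-then-triage over a plate of sample traces
against one control. The two packaged experiments mirror the validation
designs a screening lab runs before trusting decomposition:

* ``run_het_deviation_experiment`` — simulate compound-heterozygous clones,
  quantify each by trace decomposition and by the read-count oracle, and
  report the per-allele frequency deviation between the two methods.
* ``run_mixing_experiment`` — build a stepwise clone-mixing series (Mix-1
  pools one clone, Mix-k the first k at equal parts), decompose each mix,
  and report whether every constituent indel was detected and how far its
  estimated proportion falls from truth.

All randomness descends from a single integer seed through named
substreams, so every artifact is bit-reproducible.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Allele, Mixture, ReferenceAmplicon, apply_indel
from .decompose import DecompositionSettings, TraceDecomposition
from .io import read_reference, read_trace
from .ngs import AlignmentParams, ReadQuantification, compare_to_decomposition
from .screening import PlateReport, TriageSettings, screen_plate
from .simulate import TraceNoiseModel, example_reference, simulate_reads, simulate_trace, mixing_series

__all__ = [
    "RunConfig",
    "run_screen",
    "run_het_deviation_experiment",
    "run_mixing_experiment",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int, stream: str = "") -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed.

    ``stream`` names the substream (e.g. "noise", "reads") so different
    pipeline stages never share a seed. Uses CRC32 of the stream name so
    derivation is stable across processes.
    """
    root = np.random.SeedSequence([seed, zlib.crc32(stream.encode()) % (2**31)])
    rng = np.random.default_rng(root)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class RunConfig:
    """Validated configuration for a screening run.

    Loadable from YAML/JSON; CLI flags override file keys. Paths are
    checked at validation time, settings blocks against their own
    invariants.
    """

    reference_path: str
    cut_site: int
    control_path: str
    sample_paths: dict[str, str] = field(default_factory=dict)
    guide: str | None = None
    seed: int = 0
    output_dir: str | None = None
    decomposition: DecompositionSettings = field(default_factory=DecompositionSettings)
    triage: TriageSettings = field(default_factory=TriageSettings)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    noise: TraceNoiseModel = field(default_factory=TraceNoiseModel)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, typ in (
            ("decomposition", DecompositionSettings),
            ("triage", TriageSettings),
            ("alignment", AlignmentParams),
            ("noise", TraceNoiseModel),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not os.path.exists(self.reference_path):
            raise FileNotFoundError(f"reference not found: {self.reference_path}")
        if not os.path.exists(self.control_path):
            raise FileNotFoundError(f"control trace not found: {self.control_path}")
        for wid, p in self.sample_paths.items():
            if not os.path.exists(p):
                raise FileNotFoundError(f"sample trace for well {wid!r} not found: {p}")
        if not self.sample_paths:
            raise ValueError("no sample traces configured")


def run_screen(config: RunConfig) -> PlateReport:
    """Decompose every sample well against the control and triage the plate."""
    config.validate()
    reference = read_reference(config.reference_path, config.cut_site, config.guide)
    control = read_trace(config.control_path)
    results = []
    for wid in sorted(config.sample_paths):
        try:
            sample = read_trace(config.sample_paths[wid])
            res = TraceDecomposition(
                sample, control, reference, config.decomposition
            ).fit()
        except Exception as exc:
            raise RuntimeError(f"well {wid!r}, decomposition stage: {exc}") from exc
        results.append((wid, res))
    return screen_plate(results, config.triage)


def _draw_het_mixture(
    reference: ReferenceAmplicon, rng: np.random.Generator
) -> Mixture:
    """Two distinct non-WT alleles at 50:50, sizes in the 1-15 bp range."""
    sizes: list[int] = []
    while len(sizes) < 2:
        mag = int(rng.integers(1, 16))
        sign = -1 if rng.random() < 0.75 else 1  # deletions dominate repair
        s = sign * mag
        if s not in sizes:
            sizes.append(s)
    alleles = []
    for s in sizes:
        ins = "".join(rng.choice(list("ACGT"), size=s)) if s > 0 else ""
        alleles.append(apply_indel(reference, s, ins))
    return Mixture(components=((alleles[0], 0.5), (alleles[1], 0.5)))


def run_het_deviation_experiment(
    n_clones: int = 13,
    seed: int = 0,
    n_reads: int = 10_000,
    read_error_rate: float = 0.0,
    reference: ReferenceAmplicon | None = None,
    noise: TraceNoiseModel | None = None,
    settings: DecompositionSettings | None = None,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Decomposition-vs-read-oracle deviation on compound-het clones.

    Each clone carries two distinct mutant alleles at a true 50:50 ratio;
    its trace (default noise model) is decomposed and its reads (default
    10,000, error-free) quantified; the absolute per-allele frequency
    difference between the two estimates is recorded. The returned frame
    has one row per mutant allele per clone; ``df.abs_dev.mean()`` is the
    experiment's headline mean absolute deviation in percentage points.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    reference = reference or example_reference()
    base_noise = noise or TraceNoiseModel()
    geno_seeds = spawn_seeds(seed, n_clones, "genotype")
    noise_seeds = spawn_seeds(seed, n_clones, "noise")
    read_seeds = spawn_seeds(seed, n_clones, "reads")
    rows = []
    for i in range(n_clones):
        rng = np.random.default_rng(geno_seeds[i])
        mix = _draw_het_mixture(reference, rng)
        trace = simulate_trace(mix, reference, replace(base_noise, seed=noise_seeds[i]))
        control = simulate_trace(
            Mixture(components=((apply_indel(reference, 0), 1.0),)),
            reference,
            replace(base_noise, seed=noise_seeds[i] + 1),
        )
        decomp = TraceDecomposition(trace, control, reference, settings).fit()
        reads = simulate_reads(
            mix,
            reference,
            n_reads=n_reads,
            error_rate=read_error_rate,
            seed=read_seeds[i],
        )
        ngs = ReadQuantification(reads, reference, params).fit()
        report = compare_to_decomposition(ngs.frequencies, decomp)
        mutant = report.per_allele[report.per_allele.indel_size != 0]
        true_sizes = {a.indel_size for a in mix.alleles}
        for r in mutant.itertuples():
            rows.append(
                {
                    "clone": i,
                    "indel_size": int(r.indel_size),
                    "is_true_allele": int(r.indel_size) in true_sizes,
                    "ngs": r.ngs,
                    "decomposition": r.decomposition,
                    "abs_dev": r.abs_dev,
                    "r_squared": decomp.r_squared,
                }
            )
    return pd.DataFrame(rows)


def run_mixing_experiment(
    clones: Sequence[Allele] | None = None,
    seed: int = 0,
    reference: ReferenceAmplicon | None = None,
    noise: TraceNoiseModel | None = None,
    settings: DecompositionSettings | None = None,
    ratios: Sequence[Sequence[float]] | None = None,
    detect_freq: float = 0.5,
) -> pd.DataFrame:
    """Stepwise mixing-series sensitivity check for trace decomposition.

    Mix-k pools the first k of five homozygous clones at equal parts (or
    the supplied ``ratios``); each mix's trace is decomposed and every
    constituent variant scored for detection (present in the variant table
    at >= ``detect_freq`` percent, p below the settings cutoff) and for
    deviation from its expected proportion.
    """
    reference = reference or example_reference()
    if clones is None:
        rng = np.random.default_rng(seed)
        sizes = [-2, -5, -9, +1, -13]
        clones = []
        for s in sizes:
            ins = "".join(rng.choice(list("ACGT"), size=s)) if s > 0 else ""
            clones.append(apply_indel(reference, s, ins))
    base_noise = noise or TraceNoiseModel()
    mixes = mixing_series(clones, ratios=ratios)
    noise_seeds = spawn_seeds(seed, len(mixes) + 1, "mixing-noise")
    control = simulate_trace(
        Mixture(components=((apply_indel(reference, 0), 1.0),)),
        reference,
        replace(base_noise, seed=noise_seeds[-1]),
    )
    rows = []
    for k, mix in enumerate(mixes, start=1):
        trace = simulate_trace(mix, reference, replace(base_noise, seed=noise_seeds[k - 1]))
        res = TraceDecomposition(trace, control, reference, settings).fit()
        table = res.frequency_table()
        for allele, expected in mix.components:
            est = float(table.get(allele.indel_size, 0.0))
            rows.append(
                {
                    "mix": k,
                    "indel_size": allele.indel_size,
                    "expected_pct": 100.0 * expected,
                    "estimated_pct": est,
                    "detected": est >= detect_freq,
                    "abs_dev": abs(est - 100.0 * expected),
                    "r_squared": res.r_squared,
                }
            )
    return pd.DataFrame(rows)
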