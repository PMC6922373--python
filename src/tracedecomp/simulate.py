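"""Synthetic chromatograms, clone wells, mixing series and amplicon reads.

This module stands in for genomic DNA from edited cell pools. It renders
allele mixtures as per-base four-channel traces under a three-knob signal
model (exponential amplitude decay, additive truncated-Gaussian baseline
noise, linear inter-channel crosstalk), draws labeled clone wells per
genotype class, builds stepwise mixing series for sensitivity experiments,
and samples error-bearing cut-site-spanning reads for the read-count oracle.

All randomness is driven by explicit integer seeds; every output is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import (
    CHANNELS,
    Allele,
    Chromatogram,
    Mixture,
    ReadSet,
    ReferenceAmplicon,
    apply_indel,
)

__all__ = [
    "TraceNoiseModel",
    "WellLabel",
    "GENOTYPE_CLASSES",
    "simulate_trace",
    "simulate_well",
    "mixing_series",
    "simulate_reads",
    "example_reference",
    "random_allele_pool",
    "DEFAULT_GUIDE",
]

#: Protospacer used by the packaged example amplicon (Cas9 cuts between
#: protospacer positions 17 and 18, i.e. 3 bp upstream of the PAM).
DEFAULT_GUIDE = "GCCATACCAACTTTAGCACC"

GENOTYPE_CLASSES = ("homozygous", "compound_het", "het_with_wt", "nonclonal")


@dataclass(frozen=True)
class TraceNoiseModel:
    """Signal model for synthetic Sanger traces.

    amplitude(i) = base_amplitude * exp(-decay_rate * i). Crosstalk
    redistributes a fraction of each channel's signal equally into the other
    three channels (the donor keeps ``1 - 3*crosstalk``), emulating dye
    spectral overlap. Additive Gaussian noise of sd ``noise_sd`` is applied
    per channel and the result truncated at zero.
    """

    base_amplitude: float = 1000.0
    decay_rate: float = 0.002
    noise_sd: float = 30.0
    crosstalk: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be positive")
        if self.decay_rate < 0 or self.noise_sd < 0:
            raise ValueError("decay_rate and noise_sd must be non-negative")
        if not 0 <= self.crosstalk <= 0.25:
            raise ValueError("crosstalk must be in [0, 0.25]")

    def amplitude(self, positions: np.ndarray) -> np.ndarray:
        return self.base_amplitude * np.exp(-self.decay_rate * np.asarray(positions))


@dataclass(frozen=True)
class WellLabel:
    """Ground-truth genotype of a simulated clone well."""

    genotype_class: str
    truth: Mixture

    def __post_init__(self) -> None:
        cls, mix = self.genotype_class, self.truth
        if cls not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class {cls!r}")
        sizes = [a.indel_size for a in mix.alleles]
        n = len(mix)
        ok = {
            "homozygous": n == 1,
            "compound_het": n == 2 and 0 not in sizes,
            "het_with_wt": 0 in sizes,
            "nonclonal": n >= 3,
        }[cls]
        if not ok:
            raise ValueError(f"truth mixture inconsistent with class {cls!r}")


def _one_hot(seq: str, length: int) -> np.ndarray:
    """(length, 4) indicator matrix; positions beyond the sequence are zero."""
    mat = np.zeros((length, 4))
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for k, b in enumerate(CHANNELS):
        lut[ord(b)] = k
    cols = lut[idx]
    mat[np.arange(len(seq)), cols] = 1.0
    return mat


def simulate_trace(
    mixture: Mixture, reference: ReferenceAmplicon, noise: TraceNoiseModel
) -> Chromatogram:
    """Render an allele mixture as a superposed chromatogram.

    Each allele contributes ``proportion * amplitude(i)`` to the channel of
    its base at each position; contributions are summed across alleles,
    crosstalk-redistributed, noise-added and truncated at zero. The trace
    length is the longest allele's length; shorter alleles contribute
    nothing past their end (signal simply decays into baseline there).
    """
    if not len(mixture):
        raise ValueError("empty mixture")
    cut = reference.cut_site
    for a in mixture.alleles:
        if a.sequence[:cut] != reference.sequence[:cut]:
            raise ValueError(
                f"allele {a.label or a.indel_size} does not share the reference "
                "prefix up to the cut site"
            )
    length = max(len(a) for a in mixture.alleles)
    amp = noise.amplitude(np.arange(length))[:, None]
    raw = np.zeros((length, 4))
    for allele, prop in mixture.components:
        raw += prop * _one_hot(allele.sequence, length)
    raw *= amp
    k = noise.crosstalk
    if k > 0:
        total = raw.sum(axis=1, keepdims=True)
        raw = (1.0 - 4.0 * k) * raw + k * total
    if noise.noise_sd > 0:
        rng = np.random.default_rng(noise.seed)
        raw = raw + rng.normal(0.0, noise.noise_sd, size=raw.shape)
    return Chromatogram(channels=np.maximum(raw, 0.0))


def simulate_well(
    label_class: str,
    allele_pool: Sequence[Allele],
    reference: ReferenceAmplicon,
    noise: TraceNoiseModel | None = None,
    jitter_sd: float = 0.05,
    dirichlet_alpha: float = 2.0,
    seed: int = 0,
) -> tuple[Chromatogram, WellLabel]:
    """Draw one clone well of the given genotype class and render its trace.

    Classes: ``homozygous`` — a single mutant allele at 100%;
    ``compound_het`` — two distinct mutant alleles at 50:50 (each side
    perturbed by N(0, jitter_sd), renormalized); ``het_with_wt`` — wild type
    plus one mutant at jittered 50:50; ``nonclonal`` — 3-5 distinct alleles
    with proportions from a symmetric Dirichlet(alpha).

    The noise model's own seed is overridden by a substream of ``seed`` so a
    single well seed fixes both the genotype draw and the trace noise.
    """
    if label_class not in GENOTYPE_CLASSES:
        raise ValueError(f"unknown genotype class {label_class!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57E11]))
    mutants = [a for a in allele_pool if a.indel_size != 0]
    wt = next((a for a in allele_pool if a.indel_size == 0), None)

    def pick(pool: Sequence[Allele], n: int) -> list[Allele]:
        if len(pool) < n:
            raise ValueError(
                f"class {label_class!r} needs {n} distinct alleles, pool has {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]

    if label_class == "homozygous":
        (allele,) = pick(mutants, 1)
        mix = Mixture(components=((allele, 1.0),))
    elif label_class in ("compound_het", "het_with_wt"):
        if label_class == "compound_het":
            a, b = pick(mutants, 2)
        else:
            if wt is None:
                raise ValueError("het_with_wt requires a wild-type allele in the pool")
            (m,) = pick(mutants, 1)
            a, b = wt, m
        delta = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        p = float(np.clip(0.5 + delta, 0.05, 0.95))
        mix = Mixture(components=((a, p), (b, 1.0 - p)))
    else:  # nonclonal
        n = int(rng.integers(3, 6))
        alleles = pick(list(allele_pool), n)
        props = rng.dirichlet(np.full(n, dirichlet_alpha))
        props = props / props.sum()
        mix = Mixture(components=tuple(zip(alleles, props)))

    base = noise if noise is not None else TraceNoiseModel()
    trace_seed = int(rng.integers(0, 2**31 - 1))
    well_noise = TraceNoiseModel(
        base_amplitude=base.base_amplitude,
        decay_rate=base.decay_rate,
        noise_sd=base.noise_sd,
        crosstalk=base.crosstalk,
        seed=trace_seed,
    )
    trace = simulate_trace(mix, reference, well_noise)
    return trace, WellLabel(genotype_class=label_class, truth=mix)


def mixing_series(
    clones: Sequence[Allele],
    scheme: Literal["stepwise_equal"] = "stepwise_equal",
    ratios: Sequence[Sequence[float]] | None = None,
) -> list[Mixture]:
    """Stepwise clone-mixing series: Mix-k pools the first k clones.

    Under ``stepwise_equal`` each of the first k clones gets proportion 1/k.
    ``ratios`` (one proportion vector per mix) overrides the equal-parts
    default for other designs.
    """
    if not 2 <= len(clones) <= 5:
        raise ValueError("mixing series takes 2-5 clones")
    sizes = [c.indel_size for c in clones]
    if len(sizes) != len(set(sizes)):
        raise ValueError("clones must have pairwise-distinct indel sizes")
    if scheme != "stepwise_equal":
        raise ValueError(f"unknown scheme {scheme!r}")
    mixes = []
    for k in range(1, len(clones) + 1):
        if ratios is not None:
            props = list(ratios[k - 1])
            if len(props) != k:
                raise ValueError(f"ratios for Mix-{k} must have {k} entries")
            total = sum(props)
            props = [p / total for p in props]
        else:
            props = [1.0 / k] * k
        mixes.append(Mixture(components=tuple(zip(clones[:k], props))))
    return mixes


def simulate_reads(
    mixture: Mixture,
    reference: ReferenceAmplicon,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    low_quality_fraction: float = 0.0,
    seed: int = 0,
    span_margin: int = 25,
) -> ReadSet:
    """Sample cut-site-spanning single-end reads from an allele mixture.

    Each read draws its allele by mixture proportion and a uniform start
    such that the read covers the edited region with ``span_margin``
    reference bases of context on both sides. Substitution errors are
    injected i.i.d. at ``error_rate``; qualities are a constant phred 40,
    except a ``low_quality_fraction`` of reads set to constant phred 20.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    cut = reference.cut_site
    rng = np.random.default_rng(seed)
    if n_reads == 0:
        return ReadSet(reads=())
    for a in mixture.alleles:
        if read_length > len(a):
            raise ValueError(
                f"read_length {read_length} exceeds allele {a.label or a.indel_size} "
                f"length {len(a)}"
            )
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    alleles = mixture.alleles
    props = np.array(mixture.proportions)
    which = rng.choice(len(alleles), size=n_reads, p=props)
    low_q = rng.random(n_reads) < low_quality_fraction
    reads = []
    for i in range(n_reads):
        allele = alleles[which[i]]
        ins = max(allele.indel_size, 0)
        # read must cover allele positions [cut - m, cut + ins + m)
        lo = max(0, cut + ins + span_margin - read_length)
        hi = min(len(allele) - read_length, cut - span_margin)
        if hi < lo:
            raise ValueError(
                "read_length too short to span the cut with the requested margin"
            )
        start = int(rng.integers(lo, hi + 1))
        seq = np.frombuffer(
            allele.sequence[start : start + read_length].encode(), dtype=np.uint8
        ).copy()
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            if err.any():
                # substitute with a uniformly random *different* base
                shift = rng.integers(1, 4, size=int(err.sum()))
                lut = np.zeros(256, dtype=np.int64)
                for k, b in enumerate("ACGT"):
                    lut[ord(b)] = k
                cur = lut[seq[err]]
                seq[err] = bases[(cur + shift) % 4]
        q = 20 if low_q[i] else 40
        reads.append((seq.tobytes().decode(), (q,) * read_length))
    return ReadSet(reads=tuple(reads))


def example_reference(
    seed: int = 0,
    length: int = 560,
    cut_site: int = 250,
    guide: str = DEFAULT_GUIDE,
    name: str = "synthetic_amplicon",
) -> ReferenceAmplicon:
    """A synthetic amplicon embedding the packaged guide at the cut site.

    The guide's protospacer occupies positions ``[cut_site - 17,
    cut_site + 3)`` so the blunt cut (3 bp upstream of the PAM) falls
    exactly at ``cut_site``; the rest of the sequence is random under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    start = cut_site - (len(guide) - 3)
    if start < 0 or start + len(guide) > length:
        raise ValueError("guide does not fit at the requested cut site")
    seq[start : start + len(guide)] = list(guide)
    return ReferenceAmplicon(
        name=name, sequence="".join(seq), cut_site=cut_site, guide=guide
    )


def random_allele_pool(
    reference: ReferenceAmplicon,
    sizes: Sequence[int] | None = None,
    include_wt: bool = True,
    seed: int = 0,
) -> list[Allele]:
    """Build an allele pool with indel sizes typical of single-cut repair.

    Default sizes are deletions of 1-15 bp and insertions of 1-3 bp (small
    insertions dominate real repair outcomes); inserted bases are random
    under ``seed`` and recorded on the allele.
    """
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = list(range(-15, 0)) + [1, 2, 3]
    pool = []
    if include_wt:
        pool.append(apply_indel(reference, 0))
    for s in sizes:
        if s == 0:
            continue
        ins = "".join(rng.choice(list("ACGT"), size=s)) if s > 0 else ""
        pool.append(apply_indel(reference, s, ins))
    return pool
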