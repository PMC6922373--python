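"""Domain types for amplicon indel analysis.

Coordinate convention: 0-based, half-open everywhere. A cut site is an
inter-base index — the double-strand break falls between positions
``cut_site - 1`` and ``cut_site`` of the reference amplicon. Deletions of
size *d* remove reference positions ``[cut_site, cut_site + d)``;
insertions place novel bases starting at ``cut_site``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS",
    "ReferenceAmplicon",
    "Allele",
    "Mixture",
    "Chromatogram",
    "ReadSet",
    "apply_indel",
    "reverse_complement",
]

#: Channel order for chromatogram intensity matrices (alphabetical; ties in
#: basecalling resolve to the first maximal channel, i.e. A < C < G < T).
CHANNELS = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)!r}")


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A wild-type amplicon with the expected nuclease cut site.

    Parameters
    ----------
    name : str
        Label for reports.
    sequence : str
        Wild-type amplicon sequence, A/C/G/T only.
    cut_site : int
        Inter-base index of the expected double-strand break
        (``0 < cut_site < len(sequence)``).
    guide : str, optional
        Protospacer sequence; must occur in the amplicon on either strand.
    primer_fwd, primer_rev : str, optional
        PCR primer sequences (annotation only).
    """

    name: str
    sequence: str
    cut_site: int
    guide: str | None = None
    primer_fwd: str | None = None
    primer_rev: str | None = None

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "reference sequence")
        if not 0 < self.cut_site < len(self.sequence):
            raise ValueError(
                f"cut_site {self.cut_site} outside (0, {len(self.sequence)})"
            )
        if self.guide is not None:
            _check_dna(self.guide, "guide")
            if (
                self.guide not in self.sequence
                and reverse_complement(self.guide) not in self.sequence
            ):
                raise ValueError("guide not found in amplicon on either strand")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Allele:
    """One editing outcome: the reference with a single indel at the cut site.

    ``indel_size`` is signed: 0 = wild type, negative = deletion, positive =
    insertion of ``inserted_bases``.
    """

    indel_size: int
    sequence: str
    inserted_bases: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "allele sequence")
        if self.indel_size > 0 and len(self.inserted_bases) != self.indel_size:
            raise ValueError("inserted_bases length must equal insertion size")
        if self.indel_size <= 0 and self.inserted_bases:
            raise ValueError("inserted_bases must be empty for deletions / WT")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Mixture:
    """Weighted pool of alleles; proportions sum to one.

    Allele indel sizes must be pairwise distinct — decomposition identifies
    components by indel size, so two same-size alleles are unresolvable.
    """

    components: tuple[tuple[Allele, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((a, float(p)) for a, p in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("mixture must contain at least one component")
        if any(p < 0 for _, p in comps):
            raise ValueError("mixture proportions must be non-negative")
        total = sum(p for _, p in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        sizes = [a.indel_size for a, _ in comps]
        if len(sizes) != len(set(sizes)):
            raise ValueError("allele indel sizes must be pairwise distinct")

    @property
    def alleles(self) -> tuple[Allele, ...]:
        return tuple(a for a, _ in self.components)

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.components)

    def __len__(self) -> int:
        return len(self.components)


def _basecalls_from_channels(channels: np.ndarray) -> str:
    # argmax returns the first maximal index, which is the alphabetical
    # tie-break given CHANNELS order.
    idx = np.argmax(channels, axis=1)
    return "".join(CHANNELS[i] for i in idx)


@dataclass(frozen=True)
class Chromatogram:
    """Per-base four-channel trace with basecalls.

    ``channels`` is a float array of shape (length, 4) in A,C,G,T order,
    holding the registered peak intensity of each dye at each called base
    position (arbitrary units, non-negative). One row per base, not raw
    scanner resolution.
    """

    channels: np.ndarray
    basecalls: str = ""

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[1] != 4:
            raise ValueError("channels must have shape (length, 4)")
        if ch.size and ch.min() < 0:
            raise ValueError("channel intensities must be non-negative")
        object.__setattr__(self, "channels", ch)
        if not self.basecalls:
            object.__setattr__(self, "basecalls", _basecalls_from_channels(ch))
        if len(self.basecalls) != len(ch):
            raise ValueError("basecalls length must equal trace length")
        for i, b in enumerate(self.basecalls):
            row = ch[i]
            if row[CHANNELS.index(b)] != row.max():
                raise ValueError(
                    f"basecall {b!r} at position {i} is not a maximal channel"
                )

    def __len__(self) -> int:
        return self.channels.shape[0]

    def recall_bases(self) -> "Chromatogram":
        """Return a copy with basecalls recomputed from channels (idempotent)."""
        return Chromatogram(self.channels.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return self.basecalls == other.basecalls and np.array_equal(
            self.channels, other.channels
        )


@dataclass(frozen=True)
class ReadSet:
    """Amplicon reads with per-base phred scores (0-60)."""

    reads: tuple[tuple[str, tuple[int, ...]], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        reads = tuple((s, tuple(int(q) for q in quals)) for s, quals in self.reads)
        object.__setattr__(self, "reads", reads)
        for i, (seq, quals) in enumerate(reads):
            _check_dna(seq, f"read {i}")
            if len(quals) != len(seq):
                raise ValueError(f"read {i}: quality length != sequence length")
            if quals and (min(quals) < 0 or max(quals) > 60):
                raise ValueError(f"read {i}: phred scores must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def apply_indel(
    reference: ReferenceAmplicon, indel_size: int, inserted_bases: str = ""
) -> Allele:
    """Apply a single indel at the reference cut site.

    A deletion of size d removes reference positions
    ``[cut_site, cut_site + d)``; an insertion places ``inserted_bases``
    starting at ``cut_site``. ``indel_size == 0`` returns the wild-type
    allele.
    """
    cut = reference.cut_site
    seq = reference.sequence
    if indel_size < 0:
        d = -indel_size
        if d > cut or d > len(seq) - cut:
            raise ValueError(
                f"deletion of {d} bp overruns sequence bounds at cut {cut}"
            )
        if inserted_bases:
            raise ValueError("deletions take no inserted_bases")
        new_seq = seq[:cut] + seq[cut + d :]
    elif indel_size > 0:
        if len(inserted_bases) != indel_size:
            raise ValueError("inserted_bases length must equal indel_size")
        _check_dna(inserted_bases, "inserted_bases")
        new_seq = seq[:cut] + inserted_bases + seq[cut:]
    else:
        if inserted_bases:
            raise ValueError("wild type takes no inserted_bases")
        new_seq = seq
    label = (
        "WT"
        if indel_size == 0
        else (f"del{-indel_size}" if indel_size < 0 else f"ins{indel_size}")
    )
    return Allele(
        indel_size=indel_size,
        sequence=new_seq,
        inserted_bases=inserted_bases if indel_size > 0 else "",
        label=label,
    )
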