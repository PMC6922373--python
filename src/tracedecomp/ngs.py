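"""Indel quantification from amplicon reads — the sequencing gold standard.

Reads spanning the cut site are aligned to the reference amplicon with a
semi-global affine-gap alignment (read fully aligned, reference overhangs
free), the net indel inside a window around the cut is called per read, and
per-size frequencies over passing reads give the ground-truth allele
spectrum that trace decomposition is validated against.

The aligner is a Gotoh three-state dynamic program with a fixed,
documented tie-break (prefer match/mismatch over gap, deletion over
insertion, earliest reference end point) so results are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReadSet, ReferenceAmplicon

__all__ = [
    "AlignmentParams",
    "Alignment",
    "IndelCall",
    "align_read",
    "ReadQuantification",
    "ReadQuantificationResults",
    "quantify_reads",
    "compare_to_decomposition",
    "DeviationReport",
]

_NEG = -1e18


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scores and the read quality filter.

    Defaults favor one contiguous indel over scattered gaps (gap_open -8,
    gap_extend -1 against match +2 / mismatch -3), matching the single-cut
    repair outcomes being quantified. Reads with mean phred below
    ``min_phred`` are discarded before alignment.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    min_phred: int = 30

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 <= match")
        if self.min_phred < 0:
            raise ValueError("min_phred must be non-negative")


@dataclass(frozen=True)
class Alignment:
    """A read-to-reference alignment.

    ``ops`` is a list of (op, ref_pos, length) with op in {"M", "D", "I"}:
    M consumes both sequences starting at reference position ref_pos
    (matches and mismatches), D deletes ``length`` reference bases at
    ref_pos from the read, I inserts ``length`` read bases between
    reference positions ref_pos-1 and ref_pos.
    """

    score: float
    ref_start: int
    ref_end: int
    ops: tuple[tuple[str, int, int], ...]

    def net_indel(self, window: tuple[int, int] | None = None) -> int:
        """Insertions minus deletions, restricted to ops overlapping ``window``.

        ``window`` is a half-open reference interval; an insertion at
        anchor position r overlaps if ``window[0] <= r <= window[1]``.
        ``None`` counts the whole alignment.
        """
        net = 0
        for op, pos, length in self.ops:
            if op == "M":
                continue
            if window is not None:
                lo, hi = window
                if op == "D" and not (pos < hi and pos + length > lo):
                    continue
                if op == "I" and not (lo <= pos <= hi):
                    continue
            net += length if op == "I" else -length
        return net


@dataclass(frozen=True)
class IndelCall:
    """Per-read verdict: net indel near the cut, or discarded on quality."""

    read_index: int
    net_indel: int | None
    classified: str  # wt | deletion | insertion | discarded


def _dp_matrices(read: str, ref: str, p: AlignmentParams):
    """Fill the three Gotoh matrices row-vectorized over the reference."""
    m, n = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    go, ge = p.gap_open, p.gap_extend

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in read (reference deleted)
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in reference (read insertion)
    M[0, :] = 0.0  # free reference prefix (semi-global)
    for i in range(1, m + 1):
        Iy[i, 0] = go + ge * (i - 1)
        sub = np.where(
            ref_arr == ord(read[i - 1]), p.match, p.mismatch
        )
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = sub + prev_best
        Iy[i, 1:] = np.maximum(M[i - 1, 1:] + go, Iy[i - 1, 1:] + ge)
        # Ix has an intra-row recurrence: Ix[i,j] = max(M[i,j-1]+go, Ix[i,j-1]+ge)
        # = ge*j + running_max(max(M[i,k], Iy never) ...) — use accumulate trick.
        cand = np.maximum(M[i, :-1] + go, Iy[i, :-1] + go)  # open after M or Iy
        adj = cand - ge * np.arange(1, n + 1)
        run = np.maximum.accumulate(adj)
        Ix[i, 1:] = run + ge * np.arange(1, n + 1)
    return M, Ix, Iy


def align_read(
    read: str, reference: ReferenceAmplicon | str, params: AlignmentParams | None = None
) -> Alignment:
    """Optimal semi-global affine-gap alignment of a read to the amplicon.

    The read is aligned end to end; unaligned reference overhangs are free.
    Ties are broken deterministically: diagonal (match/mismatch) is
    preferred over a gap, a reference deletion over a read insertion, and
    the smallest reference end point among equal-scoring alignments.
    """
    if not read:
        raise ValueError("empty read")
    p = params or AlignmentParams()
    ref = reference.sequence if isinstance(reference, ReferenceAmplicon) else reference
    m, n = len(read), len(ref)
    M, Ix, Iy = _dp_matrices(read, ref, p)

    # terminal: free reference suffix; Ix (trailing reference gap) is never
    # terminal because trailing overhang is free anyway.
    finals = np.maximum(M[m], Iy[m])
    j = int(np.argmax(finals))  # argmax returns the smallest index on ties
    score = float(finals[j])

    ops_rev: list[tuple[str, int, int]] = []
    state = "M" if M[m, j] >= Iy[m, j] else "Y"
    i = m
    ref_end = j
    go, ge = p.gap_open, p.gap_extend
    while i > 0:
        if state == "M":
            sub = p.match if read[i - 1] == ref[j - 1] else p.mismatch
            target = M[i, j] - sub
            ops_rev.append(("M", j - 1, 1))
            i, j = i - 1, j - 1
            if i == 0:
                break
            # preference on ties: M > Ix (deletion) > Iy (insertion)
            if abs(M[i, j] - target) < 1e-9:
                state = "M"
            elif abs(Ix[i, j] - target) < 1e-9:
                state = "X"
            else:
                state = "Y"
        elif state == "X":  # gap in read: reference base j-1 deleted
            ops_rev.append(("D", j - 1, 1))
            target = Ix[i, j]
            j -= 1
            if abs((M[i, j] + go) - target) < 1e-9:
                state = "M"
            elif abs((Iy[i, j] + go) - target) < 1e-9:
                state = "Y"
            else:
                state = "X"  # extend
        else:  # state Y: gap in reference: read base i-1 inserted at j
            ops_rev.append(("I", j, 1))
            target = Iy[i, j]
            i -= 1
            if i == 0:
                break
            if abs((M[i, j] + go) - target) < 1e-9:
                state = "M"
            else:
                state = "Y"
    ref_start = j

    # merge runs of identical ops
    merged: list[tuple[str, int, int]] = []
    for op, pos, length in reversed(ops_rev):
        if merged and merged[-1][0] == op == "M" and merged[-1][1] + merged[-1][2] == pos:
            merged[-1] = (op, merged[-1][1], merged[-1][2] + length)
        elif merged and merged[-1][0] == op == "D" and merged[-1][1] + merged[-1][2] == pos:
            merged[-1] = (op, merged[-1][1], merged[-1][2] + length)
        elif merged and merged[-1][0] == op == "I" and merged[-1][1] == pos:
            merged[-1] = (op, pos, merged[-1][2] + length)
        else:
            merged.append((op, pos, length))
    return Alignment(
        score=score, ref_start=ref_start, ref_end=ref_end, ops=tuple(merged)
    )


class ReadQuantification:
    """Allele-frequency estimation from a read set (fit/results pattern).

    Reads failing the mean-phred filter are discarded; the rest are
    aligned (duplicate sequences aligned once) and their net indel within
    ``cut_site ± quant_halfwidth`` tallied into a frequency table.
    """

    def __init__(
        self,
        reads: ReadSet,
        reference: ReferenceAmplicon,
        params: AlignmentParams | None = None,
        quant_halfwidth: int = 10,
    ) -> None:
        self.reads = reads
        self.reference = reference
        self.params = params or AlignmentParams()
        self.quant_halfwidth = quant_halfwidth

    def fit(self) -> "ReadQuantificationResults":
        p = self.params
        cut = self.reference.cut_site
        window = (cut - self.quant_halfwidth, cut + self.quant_halfwidth)

        calls: list[IndelCall] = []
        passing: list[str] = []
        pass_idx: list[int] = []
        for i, (seq, quals) in enumerate(self.reads):
            if np.mean(quals) < p.min_phred:
                calls.append(IndelCall(i, None, "discarded"))
            else:
                passing.append(seq)
                pass_idx.append(i)
        if not passing:
            raise ValueError("no reads pass the quality filter")

        cache: dict[str, int] = {}
        for seq in set(passing):
            cache[seq] = align_read(seq, self.reference, p).net_indel(window)
        counts: Counter[int] = Counter()
        for i, seq in zip(pass_idx, passing):
            net = cache[seq]
            cls = "wt" if net == 0 else ("deletion" if net < 0 else "insertion")
            calls.append(IndelCall(i, net, cls))
            counts[net] += 1
        calls.sort(key=lambda c: c.read_index)

        n_pass = len(passing)
        freqs = pd.Series(
            {size: 100.0 * c / n_pass for size, c in sorted(counts.items())},
            name="frequency",
        )
        freqs.index.name = "indel_size"
        efficiency = 100.0 - float(freqs.get(0, 0.0))
        return ReadQuantificationResults(
            frequencies=freqs,
            efficiency=efficiency,
            n_reads=len(self.reads),
            n_discarded=len(self.reads) - n_pass,
            calls=tuple(calls),
        )


@dataclass(frozen=True)
class ReadQuantificationResults:
    """Read-count indel spectrum: percent of passing reads per net indel size."""

    frequencies: pd.Series
    efficiency: float
    n_reads: int
    n_discarded: int
    calls: tuple[IndelCall, ...] = field(repr=False, default=())

    def summary(self) -> str:
        lines = [
            "Read quantification results",
            "=" * 46,
            f"reads               : {self.n_reads}",
            f"discarded (quality) : {self.n_discarded}",
            f"editing efficiency  : {self.efficiency:.1f}%",
            "-" * 46,
            self.frequencies.to_string(float_format="{:.2f}".format),
        ]
        return "\n".join(lines)


def quantify_reads(
    reads: ReadSet,
    reference: ReferenceAmplicon,
    params: AlignmentParams | None = None,
    quant_halfwidth: int = 10,
) -> ReadQuantificationResults:
    """Functional wrapper: ``ReadQuantification(...).fit()``."""
    return ReadQuantification(reads, reference, params, quant_halfwidth).fit()


@dataclass(frozen=True)
class DeviationReport:
    """Per-allele disagreement between read counts and trace decomposition."""

    per_allele: pd.DataFrame
    mad: float
    mad_mutant: float
    max_deviation: float
    missed: tuple[int, ...]
    spurious: tuple[int, ...]


def compare_to_decomposition(
    ngs_table: pd.Series,
    decomp,
    min_missed_freq: float = 5.0,
) -> DeviationReport:
    """Compare a read-count frequency table with a decomposition result.

    Deviations are absolute differences in percentage points over the
    union of indel sizes (absent sizes count as 0%). ``missed`` lists
    sizes at >= ``min_missed_freq`` percent in the read counts but absent
    from the decomposition; ``spurious`` is the converse. ``mad_mutant``
    averages over non-wild-type sizes only.
    """
    if getattr(decomp, "status", "ok") == "eliminated_low_fit":
        raise ValueError("decomposition was eliminated (low R^2); nothing to compare")
    dec_table = decomp.frequency_table() if hasattr(decomp, "frequency_table") else decomp
    sizes = sorted(set(ngs_table.index) | set(dec_table.index))
    rows = []
    for s in sizes:
        a = float(ngs_table.get(s, 0.0))
        b = float(dec_table.get(s, 0.0))
        rows.append((s, a, b, abs(a - b)))
    df = pd.DataFrame(rows, columns=["indel_size", "ngs", "decomposition", "abs_dev"])
    missed = tuple(
        int(s)
        for s, a, b, _ in rows
        if a >= min_missed_freq and s not in set(dec_table.index)
    )
    spurious = tuple(
        int(s)
        for s, a, b, _ in rows
        if b >= min_missed_freq and s not in set(ngs_table.index)
    )
    mutant = df[df.indel_size != 0]
    return DeviationReport(
        per_allele=df,
        mad=float(df.abs_dev.mean()),
        mad_mutant=float(mutant.abs_dev.mean()) if len(mutant) else 0.0,
        max_deviation=float(df.abs_dev.max()),
        missed=missed,
        spurious=spurious,
    )
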