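"""Readers and writers: the tabular trace dialect, FASTA and FASTQ.

The tabular trace dialect is the normative, version-controllable trace
format: UTF-8 TSV with header ``pos\tA\tC\tG\tT\tcall``, positions 0-based
ascending, non-negative decimal intensities, call in {A,C,G,T}. Vendor
binary chromatogram containers are out of scope; convert them to this
dialect externally (e.g. via Bio.SeqIO's abi parser) before analysis.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CHANNELS, Chromatogram, ReadSet, ReferenceAmplicon

__all__ = [
    "read_trace",
    "write_trace",
    "read_reference",
    "write_reference",
    "read_fastq",
    "write_fastq",
    "TraceParseError",
]

_HEADER = "pos\tA\tC\tG\tT\tcall"


class TraceParseError(ValueError):
    """Malformed tabular trace file; message names the offending line."""


def read_trace(path: str | os.PathLike) -> Chromatogram:
    """Read a chromatogram from the tabular trace dialect.

    Basecalls are taken from the ``call`` column; a file whose calls are
    inconsistent with the channel maxima is rejected (the Chromatogram
    invariant re-checks them).
    """
    rows: list[list[float]] = []
    calls: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise TraceParseError(f"line 1: expected header {_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise TraceParseError(
                    f"line {lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                pos = int(fields[0])
                vals = [float(x) for x in fields[1:5]]
            except ValueError as exc:
                raise TraceParseError(f"line {lineno}: {exc}") from None
            if pos != len(rows):
                raise TraceParseError(
                    f"line {lineno}: position {pos} out of order (expected {len(rows)})"
                )
            if any(v < 0 for v in vals):
                raise TraceParseError(f"line {lineno}: negative intensity")
            if fields[5] not in CHANNELS:
                raise TraceParseError(f"line {lineno}: call {fields[5]!r} not in ACGT")
            rows.append(vals)
            calls.append(fields[5])
    channels = np.array(rows, dtype=float).reshape(len(rows), 4)
    try:
        return Chromatogram(channels=channels, basecalls="".join(calls))
    except ValueError as exc:
        raise TraceParseError(str(exc)) from None


def write_trace(trace: Chromatogram, path: str | os.PathLike) -> None:
    """Write a chromatogram in the tabular dialect.

    Intensities are written with ``repr`` (shortest round-tripping decimal)
    so ``read_trace(write_trace(t)) == t`` bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for i in range(len(trace)):
            vals = "\t".join(repr(float(v)) for v in trace.channels[i])
            fh.write(f"{i}\t{vals}\t{trace.basecalls[i]}\n")


def read_reference(
    path: str | os.PathLike,
    cut_site: int,
    guide: str | None = None,
    primer_fwd: str | None = None,
    primer_rev: str | None = None,
) -> ReferenceAmplicon:
    """Load the first record of a FASTA file as a ReferenceAmplicon.

    The cut site and guide are analysis parameters, not FASTA content, so
    they are supplied by the caller (CLI flag or config key).
    """
    record = next(SeqIO.parse(os.fspath(path), "fasta"))
    return ReferenceAmplicon(
        name=record.id,
        sequence=str(record.seq).upper(),
        cut_site=cut_site,
        guide=guide,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
    )


def write_reference(reference: ReferenceAmplicon, path: str | os.PathLike) -> None:
    record = SeqRecord(Seq(reference.sequence), id=reference.name, description="")
    SeqIO.write([record], os.fspath(path), "fasta")


def read_fastq(path: str | os.PathLike) -> ReadSet:
    """Read a phred+33 FASTQ file into a ReadSet."""
    reads = []
    for record in SeqIO.parse(os.fspath(path), "fastq"):
        reads.append(
            (str(record.seq).upper(), tuple(record.letter_annotations["phred_quality"]))
        )
    return ReadSet(reads=tuple(reads))


def write_fastq(
    reads: ReadSet, path: str | os.PathLike, ids: Iterable[str] | None = None
) -> None:
    records = []
    id_list = None if ids is None else list(ids)
    for i, (seq, quals) in enumerate(reads):
        rid = f"read{i}" if id_list is None else id_list[i]
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, os.fspath(path), "fastq")
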