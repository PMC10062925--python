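"""Alignment input/output for methylation-tagged bisulfite reads.

Reads carry a Bismark-style per-base methylation call string in the ``XM``
auxiliary tag.  This module decodes those strings into reference-anchored
binary CpG states (:class:`MethylRead`), attaches call strings to untagged
alignments given a reference genome, and writes BED-like measure output.

Coordinates are 0-based throughout; output intervals are half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import IO, Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

#: Auxiliary tag holding the per-base methylation call string.
CALL_TAG = "XM"

#: Default minimum mapping quality for a read to be kept.
DEFAULT_MAPQ_MIN = 10

# CIGAR operation codes (pysam numeric encoding).
_QUERY_AND_REF = frozenset((0, 7, 8))  # M, =, X
_QUERY_ONLY = frozenset((1, 4))        # I, S
_REF_ONLY = frozenset((2, 3))          # D, N
_NEITHER = frozenset((5, 6))           # H, P


class InputError(Exception):
    """Raised on contract violations in the input alignments."""


class UnsortedInputError(InputError):
    """Input alignments are not coordinate-sorted."""


class MissingCallStringError(InputError):
    """A kept read lacks the methylation call string tag."""


class CpGState(IntEnum):
    UNMETHYLATED = 0
    METHYLATED = 1


class ReadOrientation(Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class MethylRead:
    """One aligned read reduced to its phased CpG methylation calls.

    ``calls`` is an ordered tuple of ``(cpg_pos, state)`` where ``cpg_pos``
    is the 0-based forward-strand coordinate of the CpG cytosine.  Calls from
    reverse-strand reads are shifted by -1 so both strands collapse onto the
    forward-strand C.
    """

    chrom: str
    start: int
    calls: tuple[tuple[int, CpGState], ...]
    source_length: int

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.calls)

    @property
    def states(self) -> tuple[CpGState, ...]:
        return tuple(s for _, s in self.calls)


@dataclass(frozen=True)
class MeasureRecord:
    """One output row: 0-based half-open interval, value and read depth."""

    chrom: str
    start: int
    end: int
    value: float
    depth: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def parse_methylation_calls(
    read: pysam.AlignedSegment, mapq_min: int = DEFAULT_MAPQ_MIN
) -> MethylRead | None:
    """Decode one alignment into a :class:`MethylRead`, or ``None`` (skip).

    A read is skipped when it is unmapped, secondary, supplementary,
    duplicate, QC-fail, maps below ``mapq_min``, or yields no CpG call.
    'Z'/'z' characters in the call string become METHYLATED/UNMETHYLATED
    calls at their reference coordinate; every other character is dropped.
    For a reverse-strand read the call sits on the G of the CpG, so its
    coordinate is decremented by one.
    """
    if (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or read.mapping_quality < mapq_min
    ):
        return None
    if not read.has_tag(CALL_TAG):
        raise MissingCallStringError(
            f"read {read.query_name!r} has no {CALL_TAG} methylation call string; "
            f"run the 'tag' subcommand first"
        )
    xm = str(read.get_tag(CALL_TAG))
    cigar = read.cigartuples
    if cigar is None:
        raise InputError(f"read {read.query_name!r} has no CIGAR")
    qlen = sum(ln for op, ln in cigar if op in _QUERY_AND_REF or op in _QUERY_ONLY)
    if len(xm) != qlen:
        raise InputError(
            f"read {read.query_name!r}: call string length {len(xm)} does not "
            f"match CIGAR query length {qlen}"
        )
    if read.query_sequence is not None and len(read.query_sequence) != len(xm):
        raise InputError(
            f"read {read.query_name!r}: call string length {len(xm)} does not "
            f"match sequence length {len(read.query_sequence)}"
        )

    shift = -1 if read.is_reverse else 0
    calls: list[tuple[int, CpGState]] = []
    qpos = 0
    rpos = read.reference_start
    for op, ln in cigar:
        if op in _QUERY_AND_REF:
            for i in range(ln):
                ch = xm[qpos + i]
                if ch == "Z":
                    calls.append((rpos + i + shift, CpGState.METHYLATED))
                elif ch == "z":
                    calls.append((rpos + i + shift, CpGState.UNMETHYLATED))
            qpos += ln
            rpos += ln
        elif op in _QUERY_ONLY:
            qpos += ln
        elif op in _REF_ONLY:
            rpos += ln
        elif op in _NEITHER:
            pass
        else:
            raise InputError(f"read {read.query_name!r}: unsupported CIGAR op {op}")
    if not calls:
        return None
    return MethylRead(
        chrom=read.reference_name,
        start=read.reference_start,
        calls=tuple(calls),
        source_length=len(xm),
    )


def stream_methyl_reads(
    alignment_path: str, mapq_min: int = DEFAULT_MAPQ_MIN
) -> Iterator[MethylRead]:
    """Stream :class:`MethylRead` objects from a coordinate-sorted SAM/BAM.

    Each alignment record is touched exactly once; emitted reads are in
    non-decreasing (chrom, pos) order so consumers may flush any locus
    strictly left of the current read start.  Raises
    :class:`UnsortedInputError` on out-of-order input.
    """
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        last_tid = -1
        last_pos = -1
        for read in af:
            if not read.is_unmapped:
                tid, pos = read.reference_id, read.reference_start
                if tid < last_tid or (tid == last_tid and pos < last_pos):
                    raise UnsortedInputError(
                        f"input is not coordinate-sorted at read "
                        f"{read.query_name!r} ({read.reference_name}:{pos}); "
                        f"sort it (e.g. samtools sort) and retry"
                    )
                last_tid, last_pos = tid, pos
            mread = parse_methylation_calls(read, mapq_min=mapq_min)
            if mread is not None:
                yield mread


def _reference_fetch(reference, chrom: str, start: int, end: int) -> str:
    if hasattr(reference, "fetch"):
        return reference.fetch(chrom, start, end)
    return reference[chrom][start:end]


def _reference_length(reference, chrom: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(chrom)
    return len(reference[chrom])


def attach_methylation_tag(
    read: pysam.AlignedSegment, reference
) -> pysam.AlignedSegment | None:
    """Attach a CpG methylation call string to an untagged alignment.

    ``reference`` is a :class:`pysam.FastaFile` or a mapping of contig name
    to sequence.  Only CpG context is called: for a forward-strand read, an
    aligned read base over a reference ``CG`` dinucleotide becomes 'Z'
    (read C, methylated) or 'z' (read T, converted); for a reverse-strand
    read the call sits on the G (read G -> 'Z', read A -> 'z').  Everything
    else is '.'.  Returns ``None`` (skip, with a warning) when the
    alignment runs off the contig end.
    """
    chrom = read.reference_name
    try:
        clen = _reference_length(reference, chrom)
    except KeyError:
        raise InputError(f"reference contig {chrom!r} not found") from None
    if chrom is None:
        raise InputError(f"read {read.query_name!r} has no reference contig")
    if read.reference_end is None or read.reference_end > clen:
        logger.warning(
            "read %r extends past the end of contig %s; skipped",
            read.query_name,
            chrom,
        )
        return None

    span_start = max(0, read.reference_start - 1)
    span_end = min(clen, read.reference_end + 1)
    ref = _reference_fetch(reference, chrom, span_start, span_end).upper()
    seq = read.query_sequence
    if seq is None:
        raise InputError(f"read {read.query_name!r} has no sequence")
    seq = seq.upper()
    calls = ["."] * len(seq)

    def ref_base(rpos: int) -> str:
        i = rpos - span_start
        if 0 <= i < len(ref):
            return ref[i]
        return "N"

    reverse = read.is_reverse
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        base = seq[qpos]
        if not reverse:
            if ref_base(rpos) == "C" and ref_base(rpos + 1) == "G":
                if base == "C":
                    calls[qpos] = "Z"
                elif base == "T":
                    calls[qpos] = "z"
        else:
            if ref_base(rpos) == "G" and ref_base(rpos - 1) == "C":
                if base == "G":
                    calls[qpos] = "Z"
                elif base == "A":
                    calls[qpos] = "z"
    read.set_tag(CALL_TAG, "".join(calls), value_type="Z")
    return read


def cpgs_per_read_stat(
    stream: Iterable[MethylRead],
) -> tuple[float | None, dict[int, int]]:
    """Mean number of CpG calls per read and the integer histogram.

    Returns ``(None, {})`` on an empty stream.
    """
    hist: Counter[int] = Counter()
    total = 0
    n = 0
    for mread in stream:
        c = len(mread.calls)
        hist[c] += 1
        total += c
        n += 1
    if n == 0:
        return None, {}
    return total / n, dict(sorted(hist.items()))


def write_records(records: Iterable[MeasureRecord], path_or_handle) -> int:
    """Write measure records as BED-like TSV (chrom, start, end, value, depth).

    Records must arrive sorted by (chrom, start); values are formatted with
    six decimal places.  Returns the number of records written.
    """
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    handle: IO[str] = open(path_or_handle, "w") if own else path_or_handle
    n = 0
    seen_chroms: set[str] = set()
    cur_chrom: str | None = None
    last_start = -1
    try:
        for rec in records:
            if rec.chrom != cur_chrom:
                if rec.chrom in seen_chroms:
                    raise ValueError(
                        f"records are not sorted: chromosome {rec.chrom} revisited"
                    )
                seen_chroms.add(rec.chrom)
                cur_chrom = rec.chrom
                last_start = -1
            if rec.start < last_start:
                raise ValueError(
                    f"records are not sorted at {rec.chrom}:{rec.start}"
                )
            last_start = rec.start
            handle.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.value:.6f}\t{rec.depth}\n"
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n
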