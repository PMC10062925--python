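"""Epiallele-diversity measures over CpG quartets: PM and ME.

A quartet is a sliding window of four consecutive CpG calls within a read;
its identity is the exact 4-coordinate tuple, and its 16-bin pattern count
vector feeds epipolymorphism (PM) and methylation entropy (ME).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from ._sweep import sweep
from .alignment_io import CpGState, MeasureRecord, MethylRead

DEFAULT_MIN_DEPTH = 10

QUARTET_SIZE = 4
N_PATTERNS = 1 << QUARTET_SIZE


@dataclass(frozen=True)
class QuartetPatternCounts:
    """16-bin methylation pattern counts for four consecutive CpGs.

    Bit k of a pattern index is the state of the k-th CpG (METHYLATED=1).
    """

    chrom: str
    positions: tuple[int, int, int, int]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_PATTERNS:
            raise ValueError("expected 16 pattern counts")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("quartet positions must be strictly increasing")


def extract_quartets(
    mread: MethylRead,
) -> list[tuple[tuple[int, int, int, int], int]]:
    """All sliding 4-call windows of a read as (position key, 4-bit pattern).

    A read with c calls yields max(0, c - 3) observations; bit 0 of the
    pattern is the first CpG of the window.
    """
    calls = mread.calls
    out = []
    for i in range(len(calls) - QUARTET_SIZE + 1):
        window = calls[i : i + QUARTET_SIZE]
        key = tuple(p for p, _ in window)
        pattern = 0
        for k, (_, state) in enumerate(window):
            if state == CpGState.METHYLATED:
                pattern |= 1 << k
        out.append((key, pattern))
    return out


def epipolymorphism(counts: Sequence[int]) -> float:
    """PM = 1 - sum(p_i^2) over the 16 pattern frequencies."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("epipolymorphism is undefined with zero observations")
    value = 1.0
    for c in counts:
        p = c / total
        value -= p * p
    return value


def methylation_entropy(counts: Sequence[int]) -> float:
    """ME = -(1/4) * sum(p_i * log2 p_i); zero-count patterns contribute 0."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("methylation entropy is undefined with zero observations")
    value = 0.0
    for c in counts:
        if c:
            p = c / total
            value -= p * math.log2(p)
    return value / QUARTET_SIZE


def compute_pm_me(
    reads: Iterable[MethylRead], min_depth: int = DEFAULT_MIN_DEPTH
) -> tuple[list[MeasureRecord], list[MeasureRecord]]:
    """Per-quartet PM and ME records, one sweep.

    Record intervals span the first CpG's C through the last CpG's G.
    """

    def update(acc: dict, mread: MethylRead) -> None:
        for key, pattern in extract_quartets(mread):
            counts = acc.setdefault(key, [0] * N_PATTERNS)
            counts[pattern] += 1

    def flush(chrom: str, key, counts) -> Iterator[tuple[str, MeasureRecord]]:
        depth = sum(counts)
        if depth >= min_depth:
            start, end = key[0], key[3] + 2
            yield "pm", MeasureRecord(chrom, start, end, epipolymorphism(counts), depth)
            yield "me", MeasureRecord(
                chrom, start, end, methylation_entropy(counts), depth
            )

    pm_records: list[MeasureRecord] = []
    me_records: list[MeasureRecord] = []
    for kind, rec in sweep(reads, update, flush):
        (pm_records if kind == "pm" else me_records).append(rec)
    return pm_records, me_records
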