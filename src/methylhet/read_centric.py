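"""Read-centric heterogeneity measures: PDR, MHL and LPMD.

All three are computed in a single coordinate sweep over the sorted
:class:`~methylhet.alignment_io.MethylRead` stream.

* PDR — per CpG, the fraction of covering (classifiable) reads that carry
  both a methylated and an unmethylated call.
* MHL — per CpG, the length-weighted fraction of fully methylated
  contiguous CpG runs over the haplotypes of covering reads.
* LPMD — the fraction of same-read CpG pairs, at genomic distances within
  a window, whose states differ; reported globally, per pair and pooled
  per distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from ._sweep import sweep
from .alignment_io import CpGState, MeasureRecord, MethylRead

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_CPGS = 4
DEFAULT_D_MIN = 2
DEFAULT_D_MAX = 16
DEFAULT_MIN_PAIR_DEPTH = 4


class ReadClass(Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    UNCLASSIFIED = "unclassified"


def classify_read(mread: MethylRead, min_cpgs: int = DEFAULT_MIN_CPGS) -> ReadClass:
    """Classify a read as concordant/discordant, or unclassified below
    ``min_cpgs`` calls.  Discordant means both states occur on the read."""
    if len(mread.calls) < min_cpgs:
        return ReadClass.UNCLASSIFIED
    states = {s for _, s in mread.calls}
    if len(states) > 1:
        return ReadClass.DISCORDANT
    return ReadClass.CONCORDANT


def compute_pdr(
    reads: Iterable[MethylRead],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> Iterator[MeasureRecord]:
    """Per-CpG proportion of discordant reads, one sweep.

    Each classified read increments the (concordant, discordant) counter
    of every CpG it calls; unclassifiable reads contribute nothing.
    """

    def update(acc: dict, mread: MethylRead) -> None:
        cls = classify_read(mread, min_cpgs)
        if cls is ReadClass.UNCLASSIFIED:
            return
        d = 1 if cls is ReadClass.DISCORDANT else 0
        for pos, _ in mread.calls:
            counter = acc.setdefault((pos,), [0, 0])
            counter[0] += 1 - d
            counter[1] += d

    def flush(chrom: str, key, counter) -> Iterable[MeasureRecord]:
        n_con, n_dis = counter
        depth = n_con + n_dis
        if depth >= min_depth:
            yield MeasureRecord(chrom, key[0], key[0] + 2, n_dis / depth, depth)

    return sweep(reads, update, flush)


def mhl_from_haplotypes(haps: Sequence[Sequence[CpGState]]) -> float:
    """Methylation haplotype load of a multiset of binary call vectors.

    For substring length i, P(MH_i) is the fraction of contiguous
    length-i windows (across all haplotypes) that are fully methylated;
    the result is the i-weighted mean of the P(MH_i), with lengths whose
    window count is zero excluded from both sums.
    """
    if not haps:
        raise ValueError("MHL is undefined for an empty haplotype set")
    max_len = max(len(h) for h in haps)
    meth = [0] * (max_len + 1)
    total = [0] * (max_len + 1)
    for h in haps:
        n = len(h)
        for i in range(1, n + 1):
            total[i] += n - i + 1
        # runs of consecutive methylated calls
        run = 0
        for s in h:
            if s == CpGState.METHYLATED:
                run += 1
            else:
                for i in range(1, run + 1):
                    meth[i] += run - i + 1
                run = 0
        for i in range(1, run + 1):
            meth[i] += run - i + 1
    num = 0.0
    den = 0.0
    for i in range(1, max_len + 1):
        if total[i] == 0:
            continue
        num += i * (meth[i] / total[i])
        den += i
    return num / den


def compute_mhl(
    reads: Iterable[MethylRead], min_depth: int = DEFAULT_MIN_DEPTH
) -> Iterator[MeasureRecord]:
    """Per-CpG methylation haplotype load, one sweep.

    Every read covering a CpG contributes its full contiguous call vector
    to that CpG's haplotype set.
    """

    def update(acc: dict, mread: MethylRead) -> None:
        states = mread.states
        for pos, _ in mread.calls:
            acc.setdefault((pos,), []).append(states)

    def flush(chrom: str, key, haps) -> Iterable[MeasureRecord]:
        if len(haps) >= min_depth:
            yield MeasureRecord(
                chrom, key[0], key[0] + 2, mhl_from_haplotypes(haps), len(haps)
            )

    return sweep(reads, update, flush)


class PairCounter:
    """Concordant/discordant counts per (chrom, pos1, pos2) CpG pair."""

    def __init__(self, d_min: int = DEFAULT_D_MIN, d_max: int = DEFAULT_D_MAX):
        if d_min < 1:
            raise ValueError("d_min must be >= 1")
        if d_min > d_max:
            raise ValueError("d_min must not exceed d_max")
        self.d_min = d_min
        self.d_max = d_max
        self.counts: dict[tuple[str, int, int], list[int]] = {}

    def add(self, chrom: str, pos1: int, pos2: int, concordant: bool) -> None:
        counter = self.counts.setdefault((chrom, pos1, pos2), [0, 0])
        counter[0 if concordant else 1] += 1


def accumulate_lpmd(
    mread: MethylRead,
    counter: PairCounter,
    d_min: int | None = None,
    d_max: int | None = None,
) -> PairCounter:
    """Add every same-read CpG pair within the distance window to ``counter``.

    Pairs are counted once per read occurrence; distance is measured
    between the forward-strand C coordinates of the two CpGs.
    """
    d_min = counter.d_min if d_min is None else d_min
    d_max = counter.d_max if d_max is None else d_max
    calls = mread.calls
    for i in range(len(calls)):
        pos_i, state_i = calls[i]
        for j in range(i + 1, len(calls)):
            pos_j, state_j = calls[j]
            d = pos_j - pos_i
            if d > d_max:
                break
            if d >= d_min:
                counter.add(mread.chrom, pos_i, pos_j, state_i == state_j)
    return counter


@dataclass
class LpmdResult:
    """Pooled, per-pair and per-distance local pairwise methylation discordance."""

    global_value: float | None
    records: list[MeasureRecord] = field(default_factory=list)
    #: distance -> (number of pair observations, pooled discordance fraction)
    per_distance: dict[int, tuple[int, float]] = field(default_factory=dict)


def compute_lpmd(
    reads: Iterable[MethylRead],
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
    min_pair_depth: int = DEFAULT_MIN_PAIR_DEPTH,
) -> LpmdResult:
    """Global / per-pair / per-distance LPMD in one sweep.

    The global value pools all pair observations with no depth threshold;
    per-pair records require ``min_pair_depth`` observations.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    tot_con = 0
    tot_dis = 0
    dist_counts: dict[int, list[int]] = {}
    records: list[MeasureRecord] = []

    def update(acc: dict, mread: MethylRead) -> None:
        calls = mread.calls
        for i in range(len(calls)):
            pos_i, state_i = calls[i]
            for j in range(i + 1, len(calls)):
                pos_j, state_j = calls[j]
                d = pos_j - pos_i
                if d > d_max:
                    break
                if d >= d_min:
                    counter = acc.setdefault((pos_i, pos_j), [0, 0])
                    counter[0 if state_i == state_j else 1] += 1

    def flush(chrom: str, key, counter) -> Iterable[MeasureRecord]:
        nonlocal tot_con, tot_dis
        n_con, n_dis = counter
        tot_con += n_con
        tot_dis += n_dis
        d = key[1] - key[0]
        dc = dist_counts.setdefault(d, [0, 0])
        dc[0] += n_con
        dc[1] += n_dis
        depth = n_con + n_dis
        if depth >= min_pair_depth:
            yield MeasureRecord(chrom, key[0], key[1] + 2, n_dis / depth, depth)

    records.extend(sweep(reads, update, flush))
    total = tot_con + tot_dis
    global_value = (tot_dis / total) if total else None
    per_distance = {
        d: (c + x, x / (c + x)) for d, (c, x) in sorted(dist_counts.items())
    }
    return LpmdResult(global_value, records, per_distance)
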