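"""Per-CpG FDRP and qFDRP via bounded reservoir sampling of covering reads.

Every CpG keeps a uniform sample (Algorithm R) of the reads that call it;
at flush the measures are computed over all unordered pairs in the sample:

* FDRP — fraction of read pairs disagreeing at >= 1 shared CpG.
* qFDRP — mean normalized Hamming distance over shared CpGs.

Pairs sharing no CpG position are excluded from both denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np

from ._sweep import sweep
from .alignment_io import MeasureRecord, MethylRead

DEFAULT_CAPACITY = 40
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_OVERLAP = 1


@dataclass
class ReadReservoir:
    """Uniform bounded-size sample of the reads offered to one CpG."""

    cpg_pos: int
    capacity: int
    seen: int = 0
    sample: list[MethylRead] = field(default_factory=list)

    def offer(self, mread: MethylRead, rng) -> None:
        """Algorithm R update: read k replaces a uniform slot w.p. capacity/k.

        ``rng`` only needs an ``integers(n)`` method returning a uniform
        draw from ``[0, n)``; the RNG is consulted only once the reservoir
        is full, so determinism follows from a fixed offer order.
        """
        self.seen += 1
        if len(self.sample) < self.capacity:
            self.sample.append(mread)
        else:
            j = int(rng.integers(self.seen))
            if j < self.capacity:
                self.sample[j] = mread


def reservoir_offer(res: ReadReservoir, mread: MethylRead, rng) -> ReadReservoir:
    res.offer(mread, rng)
    return res


@dataclass(frozen=True)
class PairDiscordance:
    """Comparison of two reads over their shared CpG positions."""

    shared: int
    hamming: int

    @property
    def discordant(self) -> bool:
        return self.hamming >= 1


def pair_discordance(a: MethylRead, b: MethylRead) -> PairDiscordance | None:
    """Shared-position comparison of two reads; ``None`` when disjoint."""
    states_a = dict(a.calls)
    shared = 0
    hamming = 0
    for pos, state_b in b.calls:
        state_a = states_a.get(pos)
        if state_a is None:
            continue
        shared += 1
        if state_a != state_b:
            hamming += 1
    if shared == 0:
        return None
    return PairDiscordance(shared, hamming)


def compute_fdrp_qfdrp(
    reads: Iterable[MethylRead],
    capacity: int = DEFAULT_CAPACITY,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    seed: int = 0,
) -> tuple[list[MeasureRecord], list[MeasureRecord]]:
    """Per-CpG FDRP and qFDRP records, one sweep.

    A single seeded RNG serves every reservoir in sweep order, so output
    is deterministic for a fixed (input order, flags, seed).  The depth
    column reports the number of reads offered (``seen``), not the sample
    size.  When ``capacity`` exceeds the depth everywhere, the result is
    the exhaustive all-pairs computation.
    """
    rng = np.random.default_rng(seed)

    def update(acc: dict, mread: MethylRead) -> None:
        for pos, _ in mread.calls:
            res = acc.get((pos,))
            if res is None:
                res = acc[(pos,)] = ReadReservoir(pos, capacity)
            res.offer(mread, rng)

    def flush(chrom: str, key, res: ReadReservoir):
        if res.seen < min_depth:
            return
        n_pairs = 0
        n_discordant = 0
        q_sum = 0.0
        for a, b in combinations(res.sample, 2):
            pd = pair_discordance(a, b)
            if pd is None or pd.shared < min_overlap:
                continue
            n_pairs += 1
            if pd.discordant:
                n_discordant += 1
            q_sum += pd.hamming / pd.shared
        if n_pairs == 0:
            return
        start, end = key[0], key[0] + 2
        yield "fdrp", MeasureRecord(chrom, start, end, n_discordant / n_pairs, res.seen)
        yield "qfdrp", MeasureRecord(chrom, start, end, q_sum / n_pairs, res.seen)

    fdrp_records: list[MeasureRecord] = []
    qfdrp_records: list[MeasureRecord] = []
    for kind, rec in sweep(reads, update, flush):
        (fdrp_records if kind == "fdrp" else qfdrp_records).append(rec)
    return fdrp_records, qfdrp_records
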