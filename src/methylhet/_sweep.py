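"""One-sweep accumulator bookkeeping shared by the measure modules.

Input reads arrive sorted by (chrom, alignment start).  Because a
reverse-strand call may be shifted one base left of the alignment start,
an accumulator keyed at position ``p`` can still receive contributions
from reads starting at ``p + 1``; it is therefore safe to flush once the
sweep reaches a read starting strictly after ``p + 1``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

from .alignment_io import MethylRead

# Accumulator keys are tuples of coordinates; key[0] governs flush order.
Key = tuple[int, ...]


def sweep(
    reads: Iterable[MethylRead],
    update: Callable[[dict, MethylRead], None],
    flush: Callable[[str, Key, object], Iterable],
) -> Iterator:
    """Drive a coordinate sweep over sorted reads.

    ``update(acc, mread)`` adds one read to the accumulator table ``acc``
    (a dict keyed by coordinate tuples).  ``flush(chrom, key, value)`` is
    called exactly once per key, in coordinate order, when no later read
    can touch it; whatever iterable it returns is yielded onward.
    """
    acc: dict = {}
    chrom: str | None = None
    for mread in reads:
        if mread.chrom != chrom:
            yield from _drain(acc, chrom, None, flush)
            chrom = mread.chrom
        else:
            yield from _drain(acc, chrom, mread.start - 1, flush)
        update(acc, mread)
    yield from _drain(acc, chrom, None, flush)


def _drain(
    acc: dict,
    chrom: str | None,
    bound: int | None,
    flush: Callable[[str, Key, object], Iterable],
) -> Iterator:
    if not acc:
        return
    if bound is None:
        keys = sorted(acc)
    else:
        keys = sorted(k for k in acc if k[0] < bound)
    for key in keys:
        yield from flush(chrom, key, acc.pop(key))
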