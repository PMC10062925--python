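"""Independent CpG-centric brute-force recomputation of every measure.

Used as the equivalence oracle for the streaming one-sweep implementations:
all reads are held in memory, grouped per CpG / quartet / pair, and the
measures are evaluated directly from their definitions.  Arithmetic is kept
in the same order as the definitions so results are bit-comparable.
"""

from __future__ import annotations

from itertools import combinations

from methylhet.alignment_io import CpGState, MeasureRecord, MethylRead

M = CpGState.METHYLATED


def _group_by_chrom(reads: list[MethylRead]) -> dict[str, list[MethylRead]]:
    groups: dict[str, list[MethylRead]] = {}
    for r in reads:
        groups.setdefault(r.chrom, []).append(r)
    return groups


def oracle_pdr(reads, min_depth=10, min_cpgs=4) -> list[MeasureRecord]:
    out = []
    for chrom, group in _group_by_chrom(reads).items():
        tallies: dict[int, list[int]] = {}
        for r in group:
            if len(r.calls) < min_cpgs:
                continue
            discordant = len(set(r.states)) > 1
            for pos, _ in r.calls:
                t = tallies.setdefault(pos, [0, 0])
                t[1 if discordant else 0] += 1
        for pos in sorted(tallies):
            n_con, n_dis = tallies[pos]
            depth = n_con + n_dis
            if depth >= min_depth:
                out.append(MeasureRecord(chrom, pos, pos + 2, n_dis / depth, depth))
    return out


def _mhl_value(haps) -> float:
    max_len = max(len(h) for h in haps)
    num = 0.0
    den = 0.0
    for i in range(1, max_len + 1):
        tot = 0
        met = 0
        for h in haps:
            for s in range(len(h) - i + 1):
                tot += 1
                if all(x == M for x in h[s : s + i]):
                    met += 1
        if tot == 0:
            continue
        num += i * (met / tot)
        den += i
    return num / den


def oracle_mhl(reads, min_depth=10) -> list[MeasureRecord]:
    out = []
    for chrom, group in _group_by_chrom(reads).items():
        haps: dict[int, list] = {}
        for r in group:
            for pos, _ in r.calls:
                haps.setdefault(pos, []).append(r.states)
        for pos in sorted(haps):
            if len(haps[pos]) >= min_depth:
                out.append(
                    MeasureRecord(chrom, pos, pos + 2, _mhl_value(haps[pos]),
                                  len(haps[pos]))
                )
    return out


def oracle_pm_me(reads, min_depth=10):
    pm_out, me_out = [], []
    import math

    for chrom, group in _group_by_chrom(reads).items():
        quartets: dict[tuple, list[int]] = {}
        for r in group:
            calls = r.calls
            for i in range(len(calls) - 3):
                window = calls[i : i + 4]
                key = tuple(p for p, _ in window)
                pattern = sum(
                    (1 << k) for k, (_, s) in enumerate(window) if s == M
                )
                counts = quartets.setdefault(key, [0] * 16)
                counts[pattern] += 1
        for key in sorted(quartets):
            counts = quartets[key]
            depth = sum(counts)
            if depth < min_depth:
                continue
            pm = 1.0
            for c in counts:
                p = c / depth
                pm -= p * p
            ent = 0.0
            for c in counts:
                if c:
                    p = c / depth
                    ent -= p * math.log2(p)
            start, end = key[0], key[3] + 2
            pm_out.append(MeasureRecord(chrom, start, end, pm, depth))
            me_out.append(MeasureRecord(chrom, start, end, ent / 4.0, depth))
    return pm_out, me_out


def oracle_lpmd(reads, d_min=2, d_max=16, min_pair_depth=4):
    tot_con = tot_dis = 0
    per_distance_counts: dict[int, list[int]] = {}
    records = []
    for chrom, group in _group_by_chrom(reads).items():
        pairs: dict[tuple[int, int], list[int]] = {}
        for r in group:
            calls = r.calls
            for i in range(len(calls)):
                for j in range(i + 1, len(calls)):
                    d = calls[j][0] - calls[i][0]
                    if d_min <= d <= d_max:
                        t = pairs.setdefault((calls[i][0], calls[j][0]), [0, 0])
                        t[0 if calls[i][1] == calls[j][1] else 1] += 1
        for (p1, p2) in sorted(pairs):
            n_con, n_dis = pairs[(p1, p2)]
            tot_con += n_con
            tot_dis += n_dis
            dc = per_distance_counts.setdefault(p2 - p1, [0, 0])
            dc[0] += n_con
            dc[1] += n_dis
            depth = n_con + n_dis
            if depth >= min_pair_depth:
                records.append(MeasureRecord(chrom, p1, p2 + 2, n_dis / depth, depth))
    total = tot_con + tot_dis
    global_value = tot_dis / total if total else None
    per_distance = {
        d: (c + x, x / (c + x))
        for d, (c, x) in sorted(per_distance_counts.items())
    }
    return global_value, records, per_distance


def oracle_fdrp_qfdrp(reads, min_depth=10, min_overlap=1):
    """Exhaustive all-pairs FDRP/qFDRP (no reservoir, no sampling)."""
    fdrp_out, qfdrp_out = [], []
    for chrom, group in _group_by_chrom(reads).items():
        covering: dict[int, list[MethylRead]] = {}
        for r in group:
            for pos, _ in r.calls:
                covering.setdefault(pos, []).append(r)
        for pos in sorted(covering):
            rs = covering[pos]
            if len(rs) < min_depth:
                continue
            n_pairs = n_dis = 0
            q_sum = 0.0
            for a, b in combinations(rs, 2):
                sa = dict(a.calls)
                shared = hamming = 0
                for p, s in b.calls:
                    if p in sa:
                        shared += 1
                        if sa[p] != s:
                            hamming += 1
                if shared == 0 or shared < min_overlap:
                    continue
                n_pairs += 1
                if hamming >= 1:
                    n_dis += 1
                q_sum += hamming / shared
            if n_pairs == 0:
                continue
            fdrp_out.append(
                MeasureRecord(chrom, pos, pos + 2, n_dis / n_pairs, len(rs))
            )
            qfdrp_out.append(
                MeasureRecord(chrom, pos, pos + 2, q_sum / n_pairs, len(rs))
            )
    return fdrp_out, qfdrp_out
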