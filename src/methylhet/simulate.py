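"""Ground-truthed simulation of RRBS-like tagged bisulfite alignments.

Each locus is a cluster of CpGs with an epiallele frequency distribution
over the 2^k binary patterns.  Reads are drawn i.i.d. from that
distribution, anchored near the locus's first CpG (mimicking RRBS
restriction-site pile-ups), and written as valid coordinate-sorted tagged
SAM.  Analytic values of all seven heterogeneity measures are computed
from the pattern distribution by exhaustive enumeration — an independent
path from the streaming modules, usable as a test oracle.

Background reference sequence is drawn from {A, T} only, so the emitted
``CG`` dinucleotides at the configured CpG positions are the sole CpG
contexts; the `tag` subcommand therefore reproduces the simulated call
strings exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .alignment_io import CALL_TAG

logger = logging.getLogger(__name__)

DEFAULT_MAPQ = 42
#: Reads start up to this many bases left of the locus's first CpG.
MAX_START_OFFSET = 5


@dataclass(frozen=True)
class LocusConfig:
    """One simulated locus: CpG layout, epiallele distribution, coverage."""

    chrom: str
    cpg_positions: tuple[int, ...]
    epiallele_probs: tuple[float, ...]
    depth: int
    read_length: int
    call_error: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.cpg_positions)
        if k == 0:
            raise ValueError("a locus needs at least one CpG")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError("cpg_positions must be strictly increasing")
        if any(b - a < 2 for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("CpGs must be at least 2 bp apart")
        if len(self.epiallele_probs) != 1 << k:
            raise ValueError(f"epiallele_probs must have length 2^{k}")
        if any(p < 0 for p in self.epiallele_probs):
            raise ValueError("epiallele_probs must be non-negative")
        if not math.isclose(sum(self.epiallele_probs), 1.0, abs_tol=1e-9):
            raise ValueError("epiallele_probs must sum to 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.read_length < 2:
            raise ValueError("read_length must cover at least one CpG dinucleotide")
        if not 0.0 <= self.call_error <= 1.0:
            raise ValueError("call_error must be a probability")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval reads of this locus may touch (half-open)."""
        start = max(0, self.cpg_positions[0] - MAX_START_OFFSET)
        end = max(self.cpg_positions[0] + self.read_length, self.cpg_positions[-1] + 2)
        return start, end


@dataclass(frozen=True)
class GroundTruth:
    """Analytic (error-free, infinite-depth) measure values for one locus."""

    pdr: float
    mhl: float
    lpmd: float | None
    fdrp: float
    qfdrp: float
    pm: tuple[float, ...]
    me: tuple[float, ...]

    @property
    def pm_mean(self) -> float | None:
        return sum(self.pm) / len(self.pm) if self.pm else None

    @property
    def me_mean(self) -> float | None:
        return sum(self.me) / len(self.me) if self.me else None


def iid_epiallele_probs(k: int, theta: float) -> tuple[float, ...]:
    """Pattern distribution with each CpG independently methylated at rate theta."""
    probs = []
    for pattern in range(1 << k):
        ones = bin(pattern).count("1")
        probs.append(theta**ones * (1 - theta) ** (k - ones))
    return tuple(probs)


def mixture_epiallele_probs(k: int, weights: dict[int, float]) -> tuple[float, ...]:
    """Pattern distribution concentrated on the given pattern -> weight map."""
    probs = [0.0] * (1 << k)
    for pattern, w in weights.items():
        probs[pattern] = w
    return tuple(probs)


def _pattern_bits(pattern: int, k: int) -> tuple[int, ...]:
    return tuple((pattern >> i) & 1 for i in range(k))


def analytic_measures(
    probs: Sequence[float],
    positions: Sequence[int] | None = None,
    d_min: int = 2,
    d_max: int = 16,
) -> GroundTruth:
    """Closed-form / exhaustive-enumeration measure values for a pattern
    distribution over k CpGs.

    Assumes full-locus read coverage: every read realizes a complete
    pattern.  ``positions`` (default: consecutive CpGs 2 bp apart) sets the
    pair distances entering LPMD.  PM/ME are computed per sliding quartet.
    """
    q = np.asarray(probs, dtype=float)
    if q.ndim != 1 or q.size < 2 or q.size & (q.size - 1):
        raise ValueError("probs must have length 2^k for some k >= 1")
    if np.any(q < 0) or not math.isclose(float(q.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("probs must be a probability vector")
    k = q.size.bit_length() - 1
    if positions is None:
        positions = tuple(2 * i for i in range(k))
    if len(positions) != k:
        raise ValueError("positions must match the number of CpGs")

    bits = (np.arange(1 << k)[:, None] >> np.arange(k)) & 1  # (2^k, k)
    marginals = q @ bits  # P(CpG i methylated)

    # PDR: probability a drawn pattern mixes both states (k=1 never mixes).
    ones = bits.sum(axis=1)
    mixed = (ones > 0) & (ones < k)
    pdr = float(q[mixed].sum())

    # MHL: expected fully-methylated windows / expected windows, per length.
    num = 0.0
    den = 0.0
    for i in range(1, k + 1):
        windows = k - i + 1
        fully = sum(
            float(q @ bits[:, s : s + i].all(axis=1)) for s in range(windows)
        )
        num += i * (fully / windows)
        den += i
    mhl = num / den

    # LPMD: mean marginal discordance over pairs within the distance window.
    disc = []
    for i in range(k):
        for j in range(i + 1, k):
            d = positions[j] - positions[i]
            if d_min <= d <= d_max:
                p_diff = float(q @ (bits[:, i] != bits[:, j]))
                disc.append(p_diff)
    lpmd = float(np.mean(disc)) if disc else None

    # FDRP: two i.i.d. full patterns are discordant iff they differ.
    fdrp = float(1.0 - np.sum(q**2))

    # qFDRP: mean per-CpG mismatch rate of two i.i.d. patterns.
    qfdrp = float(np.sum(2 * marginals * (1 - marginals)) / k)

    # PM / ME per sliding quartet of consecutive CpGs.
    pm_vals: list[float] = []
    me_vals: list[float] = []
    for s in range(k - 3):
        idx = (
            bits[:, s]
            + 2 * bits[:, s + 1]
            + 4 * bits[:, s + 2]
            + 8 * bits[:, s + 3]
        )
        r = np.bincount(idx, weights=q, minlength=16)
        pm_vals.append(float(1.0 - np.sum(r**2)))
        nz = r[r > 0]
        me_vals.append(float(-np.sum(nz * np.log2(nz)) / 4.0))

    return GroundTruth(
        pdr=pdr,
        mhl=mhl,
        lpmd=lpmd,
        fdrp=fdrp,
        qfdrp=qfdrp,
        pm=tuple(pm_vals),
        me=tuple(me_vals),
    )


def _check_non_overlapping(configs: Sequence[LocusConfig]) -> None:
    by_chrom: dict[str, list[LocusConfig]] = {}
    for cfg in configs:
        by_chrom.setdefault(cfg.chrom, []).append(cfg)
    for chrom, loci in by_chrom.items():
        loci = sorted(loci, key=lambda c: c.cpg_positions[0])
        for a, b in zip(loci, loci[1:]):
            if a.span[1] > b.span[0]:
                raise ValueError(
                    f"loci overlap on {chrom}: spans {a.span} and {b.span}"
                )


def build_reference(
    configs: Sequence[LocusConfig], seed: int = 0, pad: int = 50
) -> dict[str, str]:
    """A/T background reference with ``CG`` exactly at the configured CpGs."""
    _check_non_overlapping(configs)
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    cpgs: dict[str, set[int]] = {}
    for cfg in configs:
        end = cfg.span[1] + pad
        lengths[cfg.chrom] = max(lengths.get(cfg.chrom, 0), end)
        cpgs.setdefault(cfg.chrom, set()).update(cfg.cpg_positions)
    ref: dict[str, str] = {}
    for chrom in lengths:
        seq = rng.choice(np.array(["A", "T"]), size=lengths[chrom])
        for pos in cpgs[chrom]:
            seq[pos] = "C"
            seq[pos + 1] = "G"
        ref[chrom] = "".join(seq)
    return ref


def _sam_header(configs: Sequence[LocusConfig], pad: int = 50) -> pysam.AlignmentHeader:
    lengths: dict[str, int] = {}
    for cfg in configs:
        end = cfg.span[1] + pad
        lengths[cfg.chrom] = max(lengths.get(cfg.chrom, 0), end)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in sorted(lengths.items())],
        }
    )


def simulate_alignments(
    configs: Sequence[LocusConfig],
    seed: int,
    sam_path: str,
    reverse_fraction: float = 0.0,
    paired_fraction: float = 0.0,
    reference: dict[str, str] | None = None,
) -> list[GroundTruth]:
    """Draw reads for every locus and write a coordinate-sorted tagged SAM.

    Returns the analytic :class:`GroundTruth` per locus (in input order),
    computed from ``epiallele_probs`` independently of the read draws.
    Ground-truth LPMD uses the 2-16 bp default window.
    """
    _check_non_overlapping(configs)
    if reference is None:
        reference = build_reference(configs, seed=seed)
    rng = np.random.default_rng(seed)
    header = _sam_header(configs)
    truths = []
    rows = []  # (tid, pos, serial, segment)
    serial = 0
    for li, cfg in enumerate(configs):
        truths.append(analytic_measures(cfg.epiallele_probs, cfg.cpg_positions))
        k = cfg.n_cpgs
        probs = np.asarray(cfg.epiallele_probs, dtype=float)
        probs = probs / probs.sum()
        ref_seq = reference[cfg.chrom]
        tid = header.get_tid(cfg.chrom)
        patterns = rng.choice(1 << k, size=cfg.depth, p=probs)
        offsets = rng.integers(0, MAX_START_OFFSET + 1, size=cfg.depth)
        is_rev = rng.random(cfg.depth) < reverse_fraction
        is_paired = rng.random(cfg.depth) < paired_fraction
        for ri in range(cfg.depth):
            start = max(0, cfg.cpg_positions[0] - int(offsets[ri]))
            length = cfg.read_length
            end = start + length
            states = list(_pattern_bits(int(patterns[ri]), k))
            if cfg.call_error > 0:
                flips = rng.random(k) < cfg.call_error
                states = [s ^ int(f) for s, f in zip(states, flips)]
            seq = list(ref_seq[start:end])
            xm = ["."] * length
            if is_rev[ri]:
                for pos, state in zip(cfg.cpg_positions, states):
                    g = pos + 1
                    if start <= g < end:
                        seq[g - start] = "G" if state else "A"
                        xm[g - start] = "Z" if state else "z"
            else:
                for pos, state in zip(cfg.cpg_positions, states):
                    if start <= pos < end:
                        seq[pos - start] = "C" if state else "T"
                        xm[pos - start] = "Z" if state else "z"
            if "Z" not in xm and "z" not in xm:
                continue  # read missed every CpG of its locus
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"locus{li}_read{ri}"
            seg.reference_id = tid
            seg.reference_start = start
            seg.mapping_quality = DEFAULT_MAPQ
            seg.cigarstring = f"{length}M"
            flag = 0
            if is_rev[ri]:
                flag |= 0x10
            if is_paired[ri]:
                flag |= 0x1 | 0x40  # mate intentionally left unmapped-unknown
            seg.flag = flag
            seg.query_sequence = "".join(seq)
            seg.set_tag(CALL_TAG, "".join(xm), value_type="Z")
            rows.append((tid, start, serial, seg))
            serial += 1
    rows.sort(key=lambda r: r[:3])
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for _, _, _, seg in rows:
            out.write(seg)
    return truths


def write_reference_fasta(reference: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_ground_truth(
    configs: Sequence[LocusConfig], truths: Sequence[GroundTruth], path: str
) -> None:
    """Per-locus analytic measure table (TSV)."""

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.6f}"

    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tn_cpgs\tdepth\tpdr\tmhl\tlpmd\tfdrp\tqfdrp\tpm_mean\tme_mean\n"
        )
        for cfg, gt in zip(configs, truths):
            fh.write(
                "\t".join(
                    [
                        cfg.chrom,
                        str(cfg.cpg_positions[0]),
                        str(cfg.cpg_positions[-1] + 2),
                        str(cfg.n_cpgs),
                        str(cfg.depth),
                        fmt(gt.pdr),
                        fmt(gt.mhl),
                        fmt(gt.lpmd),
                        fmt(gt.fdrp),
                        fmt(gt.qfdrp),
                        fmt(gt.pm_mean),
                        fmt(gt.me_mean),
                    ]
                )
                + "\n"
            )


_QUERY_OPS = frozenset((0, 1, 4, 7, 8))  # M, I, S, =, X
_REF_OPS = frozenset((0, 2, 3, 7, 8))  # M, D, N, =, X


def _cigar_take_front(cigar, n_query):
    """CIGAR for the first n_query query bases; trailing D/N dropped."""
    out = []
    left = n_query
    for op, ln in cigar:
        if left == 0:
            break
        if op in _QUERY_OPS:
            take = min(ln, left)
            out.append((op, take))
            left -= take
        elif op in _REF_OPS or op in (5, 6):
            out.append((op, ln))
    while out and out[-1][0] in (2, 3, 5, 6):
        out.pop()
    return out


def _cigar_drop_front(cigar, n_query):
    """Drop the first n_query query bases; returns (ref_shift, remainder)."""
    shift = 0
    rest = []
    left = n_query
    it = iter(cigar)
    for op, ln in it:
        if left > 0 and op in _QUERY_OPS:
            take = min(ln, left)
            left -= take
            if op in _REF_OPS:
                shift += take
            if take < ln:
                rest.append((op, ln - take))
        elif left > 0:
            if op in _REF_OPS:
                shift += ln
        else:
            rest.append((op, ln))
    # strip leading D/N at the new left edge
    while rest and rest[0][0] in (2, 3):
        shift += rest[0][1]
        rest.pop(0)
    return shift, rest


def trim_read_3prime(seg: pysam.AlignedSegment, target_length: int) -> bool:
    """Truncate one alignment to its first ``target_length`` query bases in
    read orientation (3'-end removal).  Returns False (read untouched, warn
    upstream) when the read is already at or below the target length.

    For a reverse-strand read the 3' end is the left end of the forward
    projection, so leading query bases are removed and ``pos`` advances.
    """
    xm = str(seg.get_tag(CALL_TAG)) if seg.has_tag(CALL_TAG) else None
    qlen = seg.query_length
    if target_length >= qlen:
        return target_length == qlen
    cigar = seg.cigartuples
    seq = seg.query_sequence
    qual = seg.query_qualities
    if seg.is_reverse:
        cut = qlen - target_length
        shift, new_cigar = _cigar_drop_front(cigar, cut)
        seg.reference_start += shift
        new_seq = seq[cut:]
        new_xm = xm[cut:] if xm is not None else None
        new_qual = qual[cut:] if qual is not None else None
    else:
        new_cigar = _cigar_take_front(cigar, target_length)
        new_seq = seq[:target_length]
        new_xm = xm[:target_length] if xm is not None else None
        new_qual = qual[:target_length] if qual is not None else None
    seg.cigartuples = new_cigar
    seg.query_sequence = new_seq
    if new_qual is not None:
        seg.query_qualities = new_qual
    if new_xm is not None:
        seg.set_tag(CALL_TAG, new_xm, value_type="Z")
    return True


def trim_calls_3prime(
    alignment_in: str,
    target_lengths: Iterable[int],
    out_paths: dict[int, str],
) -> dict[int, int]:
    """Write one 3'-trimmed copy of the input per target length.

    Reads shorter than the target are left unmodified and counted as
    warnings; output is re-sorted (trimming reverse reads advances their
    positions).  Returns a target_length -> warning-count map.
    """
    warnings: dict[int, int] = {}
    for length in target_lengths:
        n_warn = 0
        with pysam.AlignmentFile(str(alignment_in), check_sq=False) as src:
            header = src.header
            rows = []
            for serial, seg in enumerate(src):
                if seg.query_length and seg.query_length < length:
                    n_warn += 1
                else:
                    trim_read_3prime(seg, length)
                rows.append((seg.reference_id, seg.reference_start, serial, seg))
        rows.sort(key=lambda r: r[:3])
        with pysam.AlignmentFile(str(out_paths[length]), "w", header=header) as out:
            for _, _, _, seg in rows:
                out.write(seg)
        if n_warn:
            logger.warning(
                "%d reads shorter than %d bp left unmodified", n_warn, length
            )
        warnings[length] = n_warn
    return warnings
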