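from __future__ import annotations

import numpy as np
import pysam
import pytest

from methylhet.alignment_io import CpGState, MethylRead
from methylhet.simulate import LocusConfig, iid_epiallele_probs

M = CpGState.METHYLATED
U = CpGState.UNMETHYLATED

_STATE = {"M": M, "U": U, 1: M, 0: U, M: M, U: U}

HEADER_DICT = {
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [
        {"SN": "chr1", "LN": 1_000_000},
        {"SN": "chr2", "LN": 1_000_000},
    ],
}


def mread(calls, chrom="chr1", start=None, source_length=50):
    """Build a MethylRead from [(pos, 'M'/'U'), ...]."""
    calls = tuple((pos, _STATE[s]) for pos, s in calls)
    if start is None:
        start = calls[0][0] if calls else 0
    return MethylRead(chrom=chrom, start=start, calls=calls,
                      source_length=source_length)


def pattern_read(positions, pattern, chrom="chr1", **kw):
    """Read calling every position; pattern is a string like 'MMUU'."""
    return mread(list(zip(positions, pattern)), chrom=chrom, **kw)


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(HEADER_DICT)


def make_segment(header, name="r1", chrom="chr1", pos=100, cigar="9M",
                 xm=None, seq=None, flag=0, mapq=42):
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = header.get_tid(chrom)
    seg.reference_start = pos
    seg.mapping_quality = mapq
    seg.cigarstring = cigar
    seg.flag = flag
    if xm is not None and seq is None:
        seq = "A" * len(xm)
    if seq is not None:
        seg.query_sequence = seq
    if xm is not None:
        seg.set_tag("XM", xm, value_type="Z")
    return seg


def write_sam(path, segments, header_dict=HEADER_DICT):
    header = pysam.AlignmentHeader.from_dict(header_dict)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)
    return str(path)


def random_locus_configs(rng: np.random.Generator, n_loci=6, chroms=("chr1", "chr2"),
                         max_depth=40, call_error=0.2):
    """Randomized non-overlapping loci for equivalence sweeps."""
    configs = []
    cursor = {c: 100 for c in chroms}
    for _ in range(n_loci):
        chrom = str(rng.choice(chroms))
        k = int(rng.integers(2, 7))
        spacing = [int(rng.integers(2, 9)) for _ in range(k - 1)]
        first = cursor[chrom]
        positions = [first]
        for s in spacing:
            positions.append(positions[-1] + s)
        read_length = int(rng.integers(10, 40))
        depth = int(rng.integers(2, max_depth + 1))
        theta = float(rng.uniform(0.05, 0.95))
        cfg = LocusConfig(
            chrom=chrom,
            cpg_positions=tuple(positions),
            epiallele_probs=iid_epiallele_probs(k, theta),
            depth=depth,
            read_length=read_length,
            call_error=float(rng.uniform(0, call_error)),
        )
        cursor[chrom] = cfg.span[1] + 20
        configs.append(cfg)
    return configs
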