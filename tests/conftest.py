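"""Shared fixture generators: random-but-seeded SAM/VCF content."""

from __future__ import annotations

import numpy as np
import pytest

from alnvar import sam
from alnvar.sam import AlignmentRecord, ReadGroup, SamHeader

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_cigar(rng: np.random.Generator, read_len: int) -> list[tuple[str, int]]:
    """Random valid CIGAR consuming exactly read_len query bases."""
    ops: list[tuple[str, int]] = []
    remaining = read_len
    trailing_clip = 0
    if rng.random() < 0.2 and remaining > 6:
        trailing_clip = int(rng.integers(1, 4))
        remaining -= trailing_clip
    # optional leading soft clip
    if rng.random() < 0.3 and remaining > 2:
        n = int(rng.integers(1, remaining // 2))
        ops.append(("S", n))
        remaining -= n
    while remaining > 0:
        n = int(rng.integers(1, remaining + 1))
        ops.append(("M", n))
        remaining -= n
        if remaining > 1 and rng.random() < 0.3:
            kind = rng.choice(["I", "D"])
            if kind == "I":
                k = int(rng.integers(1, min(remaining - 1, 4) + 1))
                ops.append(("I", k))
                remaining -= k
            else:
                ops.append(("D", int(rng.integers(1, 5))))
    # alignments must not end on a gap
    if ops and ops[-1][0] == "D":
        ops.pop()
    if ops and ops[-1][0] == "I":
        ops[-1] = ("M", ops[-1][1])
    if trailing_clip:
        ops.append(("S", trailing_clip))
    # merge adjacent same ops to keep the text canonical
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def make_record(
    rng: np.random.Generator,
    header: SamHeader,
    qname: str | None = None,
    rid: int | None = None,
    pos: int | None = None,
    flag: int | None = None,
) -> AlignmentRecord:
    rid = int(rng.integers(0, len(header.references))) if rid is None else rid
    ref_len = header.references[rid][1]
    pos = int(rng.integers(0, max(ref_len - 200, 1))) if pos is None else pos
    read_len = int(rng.integers(20, 80))
    cigar = random_cigar(rng, 0)
    while True:
        cigar = random_cigar(rng, read_len)
        if sum(n for op, n in cigar if op in "MDN=X") + pos < ref_len:
            break
    seq = random_sequence(rng, read_len)
    qual = [int(q) for q in rng.integers(2, 41, read_len)]
    if flag is None:
        flag = 0
        if rng.random() < 0.5:
            flag |= 0x10
        if rng.random() < 0.1:
            flag |= 0x400
        if rng.random() < 0.05:
            flag |= 0x200
        if rng.random() < 0.05:
            flag |= 0x100
    return AlignmentRecord(
        qname or f"read{int(rng.integers(0, 10**6))}",
        flag,
        rid,
        pos,
        int(rng.integers(0, 61)),
        cigar,
        -1,
        -1,
        0,
        seq,
        qual,
        {"RG": ("Z", "rg0"), "NM": ("i", int(rng.integers(0, 4)))},
    )


def make_sam_fixture(
    seed: int, n_records: int = 100, n_refs: int = 2, ref_len: int = 10000
) -> tuple[SamHeader, list[AlignmentRecord]]:
    rng = np.random.default_rng(seed)
    header = SamHeader(references=[(f"chr{i+1}", ref_len) for i in range(n_refs)])
    header._reindex()
    header.read_groups.append(ReadGroup("rg0", "sample0"))
    records = [make_record(rng, header, qname=f"r{i}") for i in range(n_records)]
    return header, records


@pytest.fixture
def sam_fixture():
    return make_sam_fixture(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
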