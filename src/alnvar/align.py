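"""Alignment-side toolbox: filtering, sorting, merging, statistics, mate
fixing, duplicate marking, MD/NM recalculation, and FASTQ export.

All operations work on in-memory :class:`~alnvar.sam.AlignmentRecord`
streams; coordinate conventions follow the package-wide 0-based half-open
rule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Iterator, Sequence

from .sam import (
    FDUP,
    FMREVERSE,
    FMUNMAP,
    FPAIRED,
    FQCFAIL,
    FREAD1,
    FREVERSE,
    FSECONDARY,
    FSUPPLEMENTARY,
    FUNMAP,
    AlignmentRecord,
    SamHeader,
    aligned_pairs,
    cigar_ref_length,
    reverse_complement,
)

DEFAULT_EXCLUDED_FLAGS = FUNMAP | FSECONDARY | FQCFAIL | FDUP


class OrderError(ValueError):
    """Records are not in the order the operation requires."""


# ---------------------------------------------------------------------------
# view

def view_filter(
    records: Iterable[AlignmentRecord],
    required_flags: int = 0,
    forbidden_flags: int = 0,
    min_mapq: int = 0,
    region: tuple[int, int, int] | None = None,  # (rid, start, end) 0-based half-open
    read_groups: set[str] | None = None,
) -> Iterator[AlignmentRecord]:
    for r in records:
        if (r.flag & required_flags) != required_flags:
            continue
        if r.flag & forbidden_flags:
            continue
        if r.mapq < min_mapq:
            continue
        if region is not None:
            rid, start, end = region
            if r.rid != rid or r.is_unmapped:
                continue
            if r.pos >= end or r.reference_end <= start:
                continue
        if read_groups is not None and r.read_group() not in read_groups:
            continue
        yield r


# ---------------------------------------------------------------------------
# sorting

_DIGIT_RE = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Case-sensitive alphanumeric key: digit runs compare numerically,
    shorter string first on prefix ties."""
    parts = _DIGIT_RE.split(name)
    key = []
    for i, p in enumerate(parts):
        if i % 2:  # digit run
            key.append((1, int(p), ""))
        elif p:
            key.append((0, 0, p))
    return tuple(key)


def coordinate_key(r: AlignmentRecord) -> tuple:
    # unmapped records without a coordinate sort last
    if r.rid < 0:
        return (1, 0, 0)
    return (0, r.rid, r.pos)


def queryname_key(r: AlignmentRecord) -> tuple:
    return (natural_key(r.qname), 0 if r.is_read1 else (1 if r.is_read2 else 2))


def sort_records(
    records: Sequence[AlignmentRecord],
    mode: str = "coordinate",
    header: SamHeader | None = None,
) -> list[AlignmentRecord]:
    if mode == "coordinate":
        out = sorted(records, key=coordinate_key)
    elif mode == "queryname":
        out = sorted(records, key=queryname_key)
    else:
        raise ValueError(f"unknown sort mode {mode!r}")
    if header is not None:
        header.sort_order = mode
    return out


def merge_sorted(
    streams: list[tuple[SamHeader, Sequence[AlignmentRecord]]]
) -> tuple[SamHeader, list[AlignmentRecord]]:
    """Merge coordinate-sorted streams into one, reconciling headers.

    Reference lists are unified by name (same name must carry the same
    length); duplicate read-group ids from later files get a ``.N`` suffix.
    """
    merged = SamHeader(sort_order="coordinate")
    rg_ids: set[str] = set()
    out: list[AlignmentRecord] = []
    for idx, (hdr, records) in enumerate(streams):
        # reconcile references
        remap: dict[int, int] = {}
        for rid, (name, length) in enumerate(hdr.references):
            if merged.has_ref(name):
                mid = merged.ref_id(name)
                if merged.references[mid][1] != length:
                    raise ValueError(
                        f"reference {name!r} has conflicting lengths "
                        f"({merged.references[mid][1]} vs {length})"
                    )
            else:
                merged.references.append((name, length))
                merged._reindex()
                mid = merged.ref_id(name)
            remap[rid] = mid
        rg_rename: dict[str, str] = {}
        for rg in hdr.read_groups:
            new_id = rg.id
            n = 1
            while new_id in rg_ids:
                new_id = f"{rg.id}.{n}"
                n += 1
            rg_rename[rg.id] = new_id
            rg_ids.add(new_id)
            merged.read_groups.append(type(rg)(new_id, rg.sample, rg.library))
        merged.programs.extend(hdr.programs)
        last = None
        for r in records:
            key = coordinate_key(r)
            if last is not None and key < last:
                raise OrderError(
                    f"input stream {idx} is not coordinate-sorted at {r.qname!r}"
                )
            last = key
            r2 = AlignmentRecord(
                r.qname,
                r.flag,
                remap.get(r.rid, -1) if r.rid >= 0 else -1,
                r.pos,
                r.mapq,
                list(r.cigar),
                remap.get(r.mrid, -1) if r.mrid >= 0 else -1,
                r.mpos,
                r.tlen,
                r.seq,
                list(r.qual) if r.qual is not None else None,
                dict(r.tags),
            )
            rg = r2.read_group()
            if rg is not None and rg in rg_rename and rg_rename[rg] != rg:
                r2.tags["RG"] = ("Z", rg_rename[rg])
            out.append(r2)
    out.sort(key=coordinate_key)
    return merged, out


# ---------------------------------------------------------------------------
# statistics

@dataclass
class FlagstatCounts:
    total: int = 0
    secondary: int = 0
    supplementary: int = 0
    duplicates: int = 0
    mapped: int = 0
    paired: int = 0
    read1: int = 0
    read2: int = 0
    properly_paired: int = 0
    with_mate_mapped: int = 0
    singletons: int = 0


@dataclass
class FlagstatReport:
    passed: FlagstatCounts = dc_field(default_factory=FlagstatCounts)
    failed: FlagstatCounts = dc_field(default_factory=FlagstatCounts)


def flagstat(records: Iterable[AlignmentRecord]) -> FlagstatReport:
    rep = FlagstatReport()
    for r in records:
        c = rep.failed if r.is_qcfail else rep.passed
        c.total += 1
        if r.is_secondary:
            c.secondary += 1
        if r.is_supplementary:
            c.supplementary += 1
        if r.is_duplicate:
            c.duplicates += 1
        if not r.is_unmapped:
            c.mapped += 1
        if r.is_secondary or r.is_supplementary:
            continue  # pairing categories count primaries only
        if r.is_paired:
            c.paired += 1
            if r.is_read1:
                c.read1 += 1
            if r.is_read2:
                c.read2 += 1
            if r.is_proper_pair and not r.is_unmapped:
                c.properly_paired += 1
            if not r.is_unmapped and not r.mate_unmapped:
                c.with_mate_mapped += 1
            if not r.is_unmapped and r.mate_unmapped:
                c.singletons += 1
    return rep


def idxstats(
    records: Iterable[AlignmentRecord], header: SamHeader
) -> list[tuple[str, int, int, int]]:
    """Per-reference (name, length, mapped, unmapped) plus a final unplaced row."""
    mapped = [0] * len(header.references)
    unmapped = [0] * len(header.references)
    unplaced = 0
    for r in records:
        if r.rid < 0:
            unplaced += 1
        elif r.is_unmapped:
            unmapped[r.rid] += 1
        else:
            mapped[r.rid] += 1
    rows = [
        (name, length, mapped[i], unmapped[i])
        for i, (name, length) in enumerate(header.references)
    ]
    rows.append(("*", 0, 0, unplaced))
    return rows


@dataclass
class StatsReport:
    raw_total_sequences: int = 0
    reads_mapped: int = 0
    bases_mapped: int = 0
    error_rate: float | None = None
    average_length: float = 0.0
    maximum_length: int = 0
    insert_size_average: float | None = None
    insert_size_stddev: float | None = None


def stats_basic(records: Iterable[AlignmentRecord]) -> StatsReport:
    rep = StatsReport()
    nm_sum = 0
    nm_seen = False
    length_sum = 0
    inserts: list[int] = []
    for r in records:
        if r.is_secondary or r.is_supplementary:
            continue
        rep.raw_total_sequences += 1
        if r.seq is not None:
            length_sum += len(r.seq)
            rep.maximum_length = max(rep.maximum_length, len(r.seq))
        if not r.is_unmapped:
            rep.reads_mapped += 1
            rep.bases_mapped += sum(n for op, n in r.cigar if op in "M=X")
            if "NM" in r.tags:
                nm_seen = True
                nm_sum += int(r.tags["NM"][1])  # type: ignore[arg-type]
            if r.is_proper_pair and r.tlen > 0:
                inserts.append(r.tlen)
    if rep.raw_total_sequences:
        rep.average_length = length_sum / rep.raw_total_sequences
    if nm_seen and rep.bases_mapped:
        rep.error_rate = nm_sum / rep.bases_mapped
    if inserts:
        mean = sum(inserts) / len(inserts)
        rep.insert_size_average = mean
        rep.insert_size_stddev = math.sqrt(
            sum((x - mean) ** 2 for x in inserts) / len(inserts)
        )
    return rep


# ---------------------------------------------------------------------------
# depth / bedcov

def depth(
    records: Iterable[AlignmentRecord],
    region: tuple[int, int, int] | None = None,
    min_mapq: int = 0,
    min_baseq: int = 0,
    excluded_flags: int = DEFAULT_EXCLUDED_FLAGS,
) -> dict[tuple[int, int], int]:
    """Per-position read depth as {(rid, pos): count}.

    A read covers the positions its M/=/X ops align to; deletions and
    reference skips do not count.  Base-quality filtering drops individual
    bases below ``min_baseq``.
    """
    counts: dict[tuple[int, int], int] = {}
    for r in records:
        if r.flag & excluded_flags or r.mapq < min_mapq or r.rid < 0:
            continue
        if region is not None and (
            r.rid != region[0] or r.pos >= region[2] or r.reference_end <= region[1]
        ):
            continue
        q, rp = 0, r.pos
        for op, n in r.cigar:
            if op in "M=X":
                for i in range(n):
                    ok = True
                    if min_baseq and r.qual is not None and r.qual[q + i] < min_baseq:
                        ok = False
                    p = rp + i
                    if region is not None and not (region[1] <= p < region[2]):
                        ok = False
                    if ok:
                        counts[(r.rid, p)] = counts.get((r.rid, p), 0) + 1
                q += n
                rp += n
            elif op in "IS":
                q += n
            elif op in "DN":
                rp += n
    return counts


def bedcov(
    records: Sequence[AlignmentRecord],
    intervals: Iterable[tuple[int, int, int]],  # (rid, start, end) 0-based half-open
    **depth_kwargs,
) -> list[int]:
    """Sum of per-base depth over each BED interval."""
    d = depth(records, **depth_kwargs)
    out = []
    for rid, start, end in intervals:
        out.append(sum(d.get((rid, p), 0) for p in range(start, end)))
    return out


# ---------------------------------------------------------------------------
# fixmate / markdup

def fixmate(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Synchronise mate fields within queryname-grouped input.

    For each primary pair, mate position/reference/strand flags are made
    mutually consistent and TLEN is set to (rightmost end − leftmost start)
    signed positive on the leftmost record.  Mates on different references
    get TLEN 0.
    """
    out = list(records)
    seen: dict[str, list[int]] = {}
    order: list[str] = []
    last_name = None
    for i, r in enumerate(out):
        if r.qname != last_name:
            if r.qname in seen:
                raise OrderError(
                    f"input is not grouped by query name: {r.qname!r} reappears"
                )
            order.append(r.qname)
            last_name = r.qname
        seen.setdefault(r.qname, []).append(i)
    for name in order:
        idxs = [i for i in seen[name] if not (out[i].is_secondary or out[i].is_supplementary)]
        primaries = [out[i] for i in idxs]
        pair = [r for r in primaries if r.is_paired]
        if len(pair) == 2:
            a, b = pair
            _sync_pair(a, b)
        elif len(pair) == 1:
            r = pair[0]
            r.flag |= FMUNMAP
            r.mrid, r.mpos, r.tlen = -1, -1, 0
    return out


def _sync_pair(a: AlignmentRecord, b: AlignmentRecord) -> None:
    for x, y in ((a, b), (b, a)):
        if y.is_unmapped:
            x.flag |= FMUNMAP
            x.flag &= ~FMREVERSE
        else:
            x.flag &= ~FMUNMAP
            if y.is_reverse:
                x.flag |= FMREVERSE
            else:
                x.flag &= ~FMREVERSE
    if a.is_unmapped and not b.is_unmapped:
        # unmapped mate adopts the mapped read's coordinates
        a.rid, a.pos = b.rid, b.pos
    if b.is_unmapped and not a.is_unmapped:
        b.rid, b.pos = a.rid, a.pos
    for x, y in ((a, b), (b, a)):
        x.mrid, x.mpos = y.rid, y.pos
    if a.is_unmapped or b.is_unmapped or a.rid != b.rid:
        a.tlen = b.tlen = 0
        return
    left, right = (a, b) if (a.pos, a.reference_end) <= (b.pos, b.reference_end) else (b, a)
    span = max(a.reference_end, b.reference_end) - min(a.pos, b.pos)
    left.tlen, right.tlen = span, -span


def _duplicate_key(r: AlignmentRecord):
    strand = 1 if r.is_reverse else 0
    five_prime = r.unclipped_end() - 1 if r.is_reverse else r.unclipped_start()
    if r.is_paired and not r.mate_unmapped and r.mrid >= 0:
        mate_strand = 1 if r.flag & FMREVERSE else 0
        # mate 5' unclipped coordinate is not recoverable without the mate's
        # CIGAR; use its start position (consistent across the group after
        # fixmate, which is a documented precondition)
        mate_five = r.mpos
        ends = sorted(
            [(r.rid, five_prime, strand), (r.mrid, mate_five, mate_strand)]
        )
        return ("pair", tuple(ends))
    return ("single", r.rid, five_prime, strand)


def markdup(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag duplicates among coordinate-sorted, fixmated records.

    Grouping key is the 5'-unclipped position and orientation (of both mates
    for pairs).  Within each group the read (or pair) with the highest base
    quality sum keeps its flag; all others are marked.  Secondary and
    supplementary records inherit their primary's status.
    """
    out = list(records)
    last = None
    for r in out:
        key = coordinate_key(r)
        if last is not None and key < last:
            raise OrderError(f"input not coordinate-sorted at {r.qname!r}")
        last = key
    groups: dict[object, list[int]] = {}
    for i, r in enumerate(out):
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        groups.setdefault(_duplicate_key(r), []).append(i)
    scores: dict[str, int] = {}
    for r in out:
        if not (r.is_secondary or r.is_supplementary):
            scores[r.qname] = scores.get(r.qname, 0) + r.quality_sum()
    dup_names: set[str] = set()
    for key, idxs in groups.items():
        if key[0] == "pair":
            names = sorted({out[i].qname for i in idxs})
            if len(names) < 2:
                continue
            best = max(names, key=lambda n: (scores.get(n, 0), n))
            dup_names.update(n for n in names if n != best)
        else:
            if len(idxs) < 2:
                continue
            best = max(idxs, key=lambda i: (out[i].quality_sum(), -i))
            for i in idxs:
                if i != best:
                    out[i].flag |= FDUP
    for r in out:
        if r.qname in dup_names:
            r.flag |= FDUP
    # secondary/supplementary inherit the primary's status
    flagged = {r.qname for r in out if r.is_duplicate and not (r.is_secondary or r.is_supplementary)}
    for r in out:
        if (r.is_secondary or r.is_supplementary) and r.qname in flagged:
            r.flag |= FDUP
    return out


# ---------------------------------------------------------------------------
# calmd

def calmd(
    records: Sequence[AlignmentRecord], reference: dict[int, str]
) -> list[AlignmentRecord]:
    """Recompute MD and NM tags against the reference.

    NM counts mismatches plus inserted and deleted bases; MD encodes matched
    run lengths, mismatched reference bases, and ``^``-prefixed deleted
    runs.  Comparison is case-insensitive.
    """
    out = []
    for r in records:
        if r.is_unmapped or r.seq is None:
            out.append(r)
            continue
        ref = reference[r.rid]
        md: list[str] = []
        run = 0
        nm = 0
        pending_del: list[str] = []
        for q, p, op in aligned_pairs(r):
            if op in "M=X":
                if pending_del:
                    md.append(str(run))
                    md.append("^" + "".join(pending_del))
                    run = 0
                    pending_del = []
                rb = ref[p].upper()
                qb = r.seq[q].upper()
                if qb == rb:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(rb)
                    run = 0
                    nm += 1
            elif op == "I":
                nm += 1
            elif op == "D":
                pending_del.append(ref[p].upper())
                nm += 1
        if pending_del:
            md.append(str(run))
            md.append("^" + "".join(pending_del))
            run = 0
        md.append(str(run))
        r2 = AlignmentRecord(
            r.qname, r.flag, r.rid, r.pos, r.mapq, list(r.cigar), r.mrid, r.mpos,
            r.tlen, r.seq, list(r.qual) if r.qual is not None else None, dict(r.tags),
        )
        r2.tags["MD"] = ("Z", "".join(md))
        r2.tags["NM"] = ("i", nm)
        out.append(r2)
    return out


# ---------------------------------------------------------------------------
# FASTQ export

def to_fastq(
    records: Iterable[AlignmentRecord], include_secondary: bool = False
) -> list[tuple[str, str, str]]:
    """(name, seq, qual-string) tuples; reverse-flagged reads come back in
    original read orientation (reverse-complemented sequence, reversed
    qualities)."""
    out = []
    for r in records:
        if r.seq is None:
            continue
        if (r.is_secondary or r.is_supplementary) and not include_secondary:
            continue
        seq = r.seq
        qual = r.qual if r.qual is not None else [30] * len(seq)
        if r.is_reverse:
            seq = reverse_complement(seq)
            qual = qual[::-1]
        out.append((r.qname, seq, "".join(chr(q + 33) for q in qual)))
    return out
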