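"""Pileup construction and per-base alignment quality (BAQ).

The pileup walks coordinate-sorted alignments and, for every covered
reference position, collects the vertical slice of read bases (or deletion
placeholders) across all reads, grouped by sample.  Insertions attach to the
column *preceding* the inserted bases via the entry's ``indel`` field, the
convention shared by the variant callers downstream.

BAQ re-aligns each read against its local reference window with a banded
three-state (match/insert/delete) profile HMM and caps every base quality at
the Phred-scaled posterior probability that the base is correctly aligned,
so bases in ambiguous contexts (homopolymer indels, repeats) lose weight in
genotype likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .align import DEFAULT_EXCLUDED_FLAGS, OrderError, coordinate_key
from .sam import AlignmentRecord, SamHeader

DEFAULT_MAX_DEPTH = 250

# BAQ defaults follow the published method's parameterization
BAQ_GAP_OPEN = 0.001
BAQ_GAP_EXT = 0.1
BAQ_BAND = 7


@dataclass(slots=True)
class PileupEntry:
    record: AlignmentRecord
    qpos: int | None  # query index; None inside a deletion
    base: str | None
    baseq: int | None
    mapq: int
    is_deletion: bool = False
    indel: int = 0  # +n insertion / -n deletion starting after this position
    indel_seq: str | None = None  # inserted bases for indel > 0
    sample: str = "default"


@dataclass(slots=True)
class PileupColumn:
    rid: int
    pos: int  # 0-based
    entries: dict[str, list[PileupEntry]] = field(default_factory=dict)

    def depth(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def all_entries(self) -> list[PileupEntry]:
        out: list[PileupEntry] = []
        for v in self.entries.values():
            out.extend(v)
        return out


def _sample_of(record: AlignmentRecord, header: SamHeader | None, default: str) -> str:
    rg = record.read_group()
    if rg is not None and header is not None:
        sm = header.sample_of_rg(rg)
        if sm is not None:
            return sm
    if rg is not None and header is None:
        return rg
    return default


def pileup(
    records: Iterable[AlignmentRecord],
    header: SamHeader | None = None,
    min_mapq: int = 0,
    min_baseq: int = 0,
    excluded_flags: int = DEFAULT_EXCLUDED_FLAGS,
    max_depth: int = DEFAULT_MAX_DEPTH,
    reference: dict[int, str] | None = None,
    baq: bool = False,
    adjust_overlaps: bool = True,
    default_sample: str = "default",
    region: tuple[int, int, int] | None = None,
) -> Iterator[PileupColumn]:
    """Yield pileup columns in coordinate order from sorted records.

    ``max_depth`` caps entries per sample per column, keeping the first
    reads in input order (deterministic, seedless).  When ``baq`` is true a
    reference must be supplied; qualities are capped before filtering.
    """
    if baq and reference is None:
        raise ValueError("BAQ requires a reference")
    columns: dict[int, PileupColumn] = {}
    cur_rid = -1
    last_key = None

    def flush(upto: int | None) -> Iterator[PileupColumn]:
        for p in sorted(columns):
            if upto is not None and p >= upto:
                break
            col = columns.pop(p)
            if region is not None and not (region[1] <= p < region[2]):
                continue
            if adjust_overlaps:
                _adjust_overlaps(col)
            _filter_baseq(col, min_baseq)
            if col.depth():
                yield col

    for r in records:
        if r.rid < 0 or r.is_unmapped:
            continue
        key = coordinate_key(r)
        if last_key is not None and key < last_key:
            raise OrderError(f"input not coordinate-sorted at {r.qname!r}")
        last_key = key
        if r.flag & excluded_flags or r.mapq < min_mapq:
            continue
        if region is not None and (
            r.rid != region[0] or r.pos >= region[2] or r.reference_end <= region[1]
        ):
            continue
        if r.rid != cur_rid:
            yield from flush(None)
            cur_rid = r.rid
        else:
            yield from flush(r.pos)
        sample = _sample_of(r, header, default_sample)
        quals = r.qual
        if baq and r.seq is not None and quals is not None:
            quals = apply_baq(r, reference[r.rid])  # type: ignore[index]
        _add_read(columns, r, sample, quals, max_depth, cur_rid)
    yield from flush(None)


def _add_read(
    columns: dict[int, PileupColumn],
    r: AlignmentRecord,
    sample: str,
    quals: list[int] | None,
    max_depth: int,
    rid: int,
) -> None:
    q, p = 0, r.pos
    prev_entry: PileupEntry | None = None
    for op, n in r.cigar:
        if op in "M=X":
            for i in range(n):
                col = columns.setdefault(p + i, PileupColumn(rid, p + i))
                lst = col.entries.setdefault(sample, [])
                if len(lst) >= max_depth:
                    prev_entry = None
                    continue
                e = PileupEntry(
                    r,
                    q + i,
                    r.seq[q + i] if r.seq is not None else None,
                    quals[q + i] if quals is not None else None,
                    r.mapq,
                    sample=sample,
                )
                lst.append(e)
                prev_entry = e
            q += n
            p += n
        elif op == "I":
            if prev_entry is not None:
                prev_entry.indel = n
                prev_entry.indel_seq = (
                    r.seq[q : q + n] if r.seq is not None else "N" * n
                )
            q += n
        elif op == "S":
            q += n
        elif op == "D":
            if prev_entry is not None:
                prev_entry.indel = -n
            for i in range(n):
                col = columns.setdefault(p + i, PileupColumn(rid, p + i))
                lst = col.entries.setdefault(sample, [])
                if len(lst) < max_depth:
                    lst.append(
                        PileupEntry(r, None, None, None, r.mapq, is_deletion=True,
                                    sample=sample)
                    )
            p += n
            prev_entry = None
        elif op == "N":
            p += n
            prev_entry = None


def _adjust_overlaps(col: PileupColumn) -> None:
    """When both mates of a pair cover a position, zero the lower-quality
    base so the fragment contributes evidence only once."""
    for entries in col.entries.values():
        by_name: dict[str, PileupEntry] = {}
        for e in entries:
            if not e.record.is_paired or e.baseq is None:
                continue
            prev = by_name.get(e.record.qname)
            if prev is None:
                by_name[e.record.qname] = e
            else:
                if prev.baseq is None or (e.baseq or 0) > (prev.baseq or 0):
                    prev.baseq = 0
                    by_name[e.record.qname] = e
                else:
                    e.baseq = 0


def _filter_baseq(col: PileupColumn, min_baseq: int) -> None:
    if min_baseq <= 0:
        return
    for sample in list(col.entries):
        col.entries[sample] = [
            e
            for e in col.entries[sample]
            if e.is_deletion or (e.baseq is not None and e.baseq >= min_baseq)
        ]
        if not col.entries[sample]:
            del col.entries[sample]


# ---------------------------------------------------------------------------
# BAQ

class BaqWindowError(ValueError):
    """Reference window does not span the alignment plus the band."""


def _baq_centers(record: AlignmentRecord) -> tuple[list[int], list[int]]:
    """Aligned query indices and their expected reference positions.

    Insertion bases inherit the reference position of the preceding aligned
    base, giving the band a sensible diagonal through indels.
    """
    qidx: list[int] = []
    centers: list[int] = []
    q, p = 0, record.pos
    last_ref = record.pos
    for op, n in record.cigar:
        if op in "M=X":
            for i in range(n):
                qidx.append(q + i)
                centers.append(p + i)
            last_ref = p + n - 1
            q += n
            p += n
        elif op == "I":
            for i in range(n):
                qidx.append(q + i)
                centers.append(last_ref)
            q += n
        elif op == "S":
            q += n
        elif op in "DN":
            p += n
            last_ref = p - 1
    return qidx, centers


def baq_adjust(
    record: AlignmentRecord,
    ref_window: str,
    window_start: int,
    gap_open: float = BAQ_GAP_OPEN,
    gap_ext: float = BAQ_GAP_EXT,
    band: int = BAQ_BAND,
    return_likelihoods: bool = False,
    allow_clipped_band: bool = False,
):
    """Quality caps from a banded match/insert/delete profile HMM.

    Returns the full adjusted quality list (soft-clipped bases keep their
    original quality).  With ``return_likelihoods`` the forward and backward
    total log-likelihoods are also returned, for numerical cross-checks.
    ``allow_clipped_band`` permits a window narrower than alignment ± band
    (the band is clamped at the window edges), for reads near contig ends.
    """
    if record.is_unmapped or record.seq is None or record.qual is None:
        raise ValueError("BAQ needs a mapped record with sequence and qualities")
    qidx, centers = _baq_centers(record)
    if not qidx:
        return list(record.qual)
    W = len(ref_window)
    cols = [c - window_start for c in centers]
    if min(cols) < 0 or max(cols) >= W:
        raise BaqWindowError(
            f"reference window [{window_start}, {window_start + W}) does not "
            "cover the alignment"
        )
    if not allow_clipped_band and (min(cols) - band < 0 or max(cols) + band >= W):
        raise BaqWindowError(
            f"reference window [{window_start}, {window_start + W}) too small for "
            f"band {band} around alignment"
        )
    L = len(qidx)
    x = [record.seq[i].upper() for i in qidx]
    qs = [record.qual[i] for i in qidx]
    y = ref_window.upper()

    # emission of read base i against window column k
    def em(i: int, k: int) -> float:
        rb = y[k]
        qb = x[i]
        if rb == "N" or qb == "N":
            return 0.25
        err = 10.0 ** (-qs[i] / 10.0)
        return 1.0 - err if qb == rb else err / 3.0

    d, e = gap_open, gap_ext
    tMM, tMI, tIM, tII = 1.0 - 2.0 * d, d, 1.0 - e, e
    # deletions are folded into column jumps: M_k -> M_{k+g+1} costs
    # d * e^(g-1) * (1-e) for g >= 1 deleted columns

    lo = [max(0, c - band) for c in cols]
    hi = [min(W - 1, c + band) for c in cols]

    fM = [[0.0] * W for _ in range(L)]
    fI = [[0.0] * W for _ in range(L)]
    fscale = [0.0] * L
    entry = 1.0 / (2.0 * W)
    for k in range(lo[0], hi[0] + 1):
        fM[0][k] = entry * em(0, k)
        fI[0][k] = entry * 0.25
    s = sum(fM[0]) + sum(fI[0])
    fscale[0] = math.log(s)
    for k in range(W):
        fM[0][k] /= s
        fI[0][k] /= s
    for i in range(1, L):
        prevM, prevI = fM[i - 1], fI[i - 1]
        curM, curI = fM[i], fI[i]
        # running sum for deletion jumps: run(k) = sum_{j<=k-2} prevM[j] e^{k-2-j}
        run = 0.0
        for k in range(hi[i] + 1):
            if k - 2 >= 0:
                run = run * e + prevM[k - 2]
            if k < lo[i]:
                continue
            m = 0.0
            if k - 1 >= 0:
                m = prevM[k - 1] * tMM + prevI[k - 1] * tIM
            m += run * d * (1.0 - e)
            curM[k] = m * em(i, k)
            curI[k] = (prevM[k] * tMI + prevI[k] * tII) * 0.25
        s = sum(curM) + sum(curI)
        if s <= 0.0:
            s = 1e-300
        fscale[i] = math.log(s)
        for k in range(lo[i], hi[i] + 1):
            curM[k] /= s
            curI[k] /= s
    logL_fwd = sum(fscale)

    bM = [[0.0] * W for _ in range(L)]
    bI = [[0.0] * W for _ in range(L)]
    bscale = [0.0] * L
    for k in range(lo[L - 1], hi[L - 1] + 1):
        bM[L - 1][k] = 1.0
        bI[L - 1][k] = 1.0
    s = sum(bM[L - 1]) + sum(bI[L - 1])
    bscale[L - 1] = math.log(s)
    for k in range(W):
        if bM[L - 1][k]:
            bM[L - 1][k] /= s
            bI[L - 1][k] /= s
    for i in range(L - 2, -1, -1):
        nxtM, nxtI = bM[i + 1], bI[i + 1]
        curM, curI = bM[i], bI[i]
        emn = [0.0] * W
        for k in range(lo[i + 1], hi[i + 1] + 1):
            emn[k] = em(i + 1, k)
        # run2(k) = sum_{j >= k+2} e^{j-k-2} emn[j] nxtM[j]
        run2 = 0.0
        for k in range(W - 1, lo[i] - 1, -1):
            if k + 2 < W:
                run2 = run2 * e + emn[k + 2] * nxtM[k + 2]
            if k > hi[i]:
                continue
            m = 0.0
            if k + 1 < W:
                m = tMM * emn[k + 1] * nxtM[k + 1]
            m += d * (1.0 - e) * run2
            m += tMI * 0.25 * nxtI[k]
            curM[k] = m
            ival = 0.0
            if k + 1 < W:
                ival = tIM * emn[k + 1] * nxtM[k + 1]
            ival += tII * 0.25 * nxtI[k]
            curI[k] = ival
        s = sum(curM) + sum(curI)
        if s <= 0.0:
            s = 1e-300
        bscale[i] = math.log(s)
        for k in range(lo[i], hi[i] + 1):
            curM[k] /= s
            curI[k] /= s
    # backward total likelihood over the entry distribution
    tot = 0.0
    for k in range(lo[0], hi[0] + 1):
        tot += entry * em(0, k) * bM[0][k] + entry * 0.25 * bI[0][k]
    logL_bwd = math.log(tot) + sum(bscale)

    # cumulative log scale factors: true f[i] = f̂[i]·exp(cumf[i]),
    # true b[i] = b̂[i]·exp(cumb[i]); posterior = f·b / L
    cumf = [0.0] * L
    acc = 0.0
    for i in range(L):
        acc += fscale[i]
        cumf[i] = acc
    cumb = [0.0] * L
    acc = 0.0
    for i in range(L - 1, -1, -1):
        acc += bscale[i]
        cumb[i] = acc

    adjusted = list(record.qual)
    for i in range(L):
        k = cols[i]
        post = fM[i][k] * bM[i][k] * math.exp(cumf[i] + cumb[i] - logL_fwd)
        post = min(max(post, 0.0), 1.0)
        cap = 93 if post >= 1.0 - 1e-10 else int(-10.0 * math.log10(max(1.0 - post, 1e-10)))
        adjusted[qidx[i]] = min(adjusted[qidx[i]], max(cap, 0))
    if return_likelihoods:
        return adjusted, logL_fwd, logL_bwd
    return adjusted


def apply_baq(record: AlignmentRecord, ref_seq: str, band: int = BAQ_BAND) -> list[int]:
    """Convenience wrapper: build the reference window (alignment ± band,
    clipped to the reference) and run :func:`baq_adjust`."""
    start = max(0, record.pos - band - 1)
    end = min(len(ref_seq), record.reference_end + band + 1)
    window = ref_seq[start:end]
    return baq_adjust(  # type: ignore[return-value]
        record, window, start, band=band, allow_clipped_band=True
    )


# ---------------------------------------------------------------------------
# text pileup rendering (the mpileup dialect this package emits)

def render_column(
    col: PileupColumn, header: SamHeader, reference: dict[int, str] | None
) -> str:
    """chrom, 1-based pos, ref base, depth, base string, quality string.

    Dialect: ``.``/``,`` for ref match on forward/reverse strand, base letter
    (case by strand) for mismatch, ``*`` inside deletions, ``+n<seq>``/``-n``
    after the anchoring base, ``^`` + mapq char at read starts, ``$`` at read
    ends.
    """
    ref_base = "N"
    if reference is not None and col.rid in reference:
        ref_base = reference[col.rid][col.pos].upper()
    bases = []
    quals = []
    for e in col.all_entries():
        s = ""
        if e.qpos == 0 or (e.is_deletion and e.record.pos == col.pos):
            s += "^" + chr(min(e.mapq, 93) + 33)
        if e.is_deletion:
            s += "*"
        else:
            b = e.base or "N"
            if b.upper() == ref_base:
                s += "," if e.record.is_reverse else "."
            else:
                s += b.lower() if e.record.is_reverse else b.upper()
            quals.append(chr(min(e.baseq or 0, 93) + 33))
        if e.indel > 0:
            s += f"+{e.indel}{e.indel_seq or ''}"
        elif e.indel < 0:
            s += f"{e.indel}"
        if not e.is_deletion and e.qpos is not None and e.record.seq is not None:
            if e.qpos == len(e.record.seq) - 1:
                s += "$"
        bases.append(s)
    chrom = header.ref_name(col.rid)
    return "\t".join(
        [chrom, str(col.pos + 1), ref_base, str(col.depth()), "".join(bases),
         "".join(quals)]
    )
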