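"""SAM header/record data model, parsing and formatting, and FASTA faidx.

Internal coordinates are 0-based half-open everywhere; the 1-based
conventions of SAM text and ``name:start-end`` region strings are converted
exactly at the text boundary.  Reference lengths and positions are plain
Python integers, so chromosomes longer than 2 Gb need no special handling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

# flag bits
FPAIRED = 0x1
FPROPER_PAIR = 0x2
FUNMAP = 0x4
FMUNMAP = 0x8
FREVERSE = 0x10
FMREVERSE = 0x20
FREAD1 = 0x40
FREAD2 = 0x80
FSECONDARY = 0x100
FQCFAIL = 0x200
FDUP = 0x400
FSUPPLEMENTARY = 0x800

CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = set("MIS=X")
REF_CONSUMING = set("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

COMPLEMENT = str.maketrans("ACGTNacgtnRYKMrykm", "TGCANtgcanYRMKyrmk")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SamParseError(ValueError):
    pass


@dataclass
class ReadGroup:
    id: str
    sample: str | None = None
    library: str | None = None


@dataclass
class SamHeader:
    version: str = "1.6"
    sort_order: str = "unknown"  # unknown|unsorted|queryname|coordinate
    references: list[tuple[str, int]] = field(default_factory=list)
    read_groups: list[ReadGroup] = field(default_factory=list)
    programs: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._ref_ids: dict[str, int] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._ref_ids = {name: i for i, (name, _) in enumerate(self.references)}
        if len(self._ref_ids) != len(self.references):
            raise SamParseError("duplicate reference names in header")

    def ref_id(self, name: str) -> int:
        if name not in self._ref_ids:
            raise SamParseError(f"unknown reference name {name!r}")
        return self._ref_ids[name]

    def has_ref(self, name: str) -> bool:
        return name in self._ref_ids

    def ref_name(self, rid: int) -> str:
        return self.references[rid][0]

    def sample_of_rg(self, rg_id: str) -> str | None:
        for rg in self.read_groups:
            if rg.id == rg_id:
                return rg.sample
        return None

    def to_text(self) -> str:
        lines = [f"@HD\tVN:{self.version}\tSO:{self.sort_order}"]
        for name, length in self.references:
            lines.append(f"@SQ\tSN:{name}\tLN:{length}")
        for rg in self.read_groups:
            parts = [f"@RG\tID:{rg.id}"]
            if rg.sample is not None:
                parts.append(f"SM:{rg.sample}")
            if rg.library is not None:
                parts.append(f"LB:{rg.library}")
            lines.append("\t".join(parts))
        for pg in self.programs:
            lines.append("@PG\t" + "\t".join(f"{k}:{v}" for k, v in pg.items()))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "SamHeader":
        hdr = cls()
        for line in lines:
            line = line.rstrip("\n")
            if not line.startswith("@"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            kv = {}
            for f in fields[1:]:
                if ":" in f:
                    k, _, v = f.partition(":")
                    kv[k] = v
            if tag == "@HD":
                hdr.version = kv.get("VN", hdr.version)
                hdr.sort_order = kv.get("SO", hdr.sort_order)
            elif tag == "@SQ":
                if "SN" not in kv or "LN" not in kv:
                    raise SamParseError(f"@SQ line missing SN or LN: {line!r}")
                length = int(kv["LN"])
                if length < 1:
                    raise SamParseError(f"reference {kv['SN']!r} has length < 1")
                hdr.references.append((kv["SN"], length))
            elif tag == "@RG":
                hdr.read_groups.append(
                    ReadGroup(kv.get("ID", ""), kv.get("SM"), kv.get("LB"))
                )
            elif tag == "@PG":
                hdr.programs.append(kv)
        hdr._reindex()
        return hdr


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise SamParseError(f"malformed CIGAR {text!r}")
        n = int(m.group(1))
        if n < 1:
            raise SamParseError(f"zero-length CIGAR op in {text!r}")
        ops.append((m.group(2), n))
        pos = m.end()
    if pos != len(text):
        raise SamParseError(f"malformed CIGAR {text!r}")
    return ops


def cigar_to_text(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) if cigar else "*"


def cigar_query_length(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in QUERY_CONSUMING)


def cigar_ref_length(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in REF_CONSUMING)


_TAG_CASTERS = {
    "A": str,
    "i": int,
    "f": float,
    "Z": str,
    "H": str,
}


@dataclass
class AlignmentRecord:
    qname: str
    flag: int
    rid: int  # -1 when unmapped without coordinate
    pos: int  # 0-based leftmost; -1 when unplaced
    mapq: int
    cigar: list[tuple[str, int]]
    mrid: int
    mpos: int
    tlen: int
    seq: str | None
    qual: list[int] | None
    tags: dict[str, tuple[str, object]] = field(default_factory=dict)

    # --- flag helpers -----------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FPAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FPROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FUNMAP)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FMUNMAP)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FREVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FREAD1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FREAD2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FSECONDARY)

    @property
    def is_qcfail(self) -> bool:
        return bool(self.flag & FQCFAIL)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FDUP)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FSUPPLEMENTARY)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.pos + cigar_ref_length(self.cigar)

    def unclipped_start(self) -> int:
        n = 0
        for op, ln in self.cigar:
            if op in "SH":
                n += ln
            else:
                break
        return self.pos - n

    def unclipped_end(self) -> int:
        n = 0
        for op, ln in reversed(self.cigar):
            if op in "SH":
                n += ln
            else:
                break
        return self.reference_end + n

    def read_group(self) -> str | None:
        tag = self.tags.get("RG")
        return str(tag[1]) if tag else None

    def quality_sum(self) -> int:
        return sum(self.qual) if self.qual else 0


GAP = None  # sentinel for a gapped coordinate in aligned_pairs


def aligned_pairs(record: AlignmentRecord) -> list[tuple[int | None, int | None, str]]:
    """(query index, reference position, op) triples for a mapped record.

    Match-type ops emit both coordinates; insertions and soft clips emit the
    query side only; deletions and skips the reference side only.
    """
    if record.is_unmapped:
        raise ValueError(f"record {record.qname!r} is unmapped")
    if not record.cigar:
        raise ValueError(f"record {record.qname!r} has no CIGAR")
    out: list[tuple[int | None, int | None, str]] = []
    q, r = 0, record.pos
    for op, n in record.cigar:
        if op in "M=X":
            for _ in range(n):
                out.append((q, r, op))
                q += 1
                r += 1
        elif op in "IS":
            for _ in range(n):
                out.append((q, GAP, op))
                q += 1
        elif op in "DN":
            for _ in range(n):
                out.append((GAP, r, op))
                r += 1
        # H and P consume neither
    return out


def _parse_tag(field_: str, lineno: int | None) -> tuple[str, str, object]:
    parts = field_.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2:
        raise SamParseError(_at(f"malformed tag field {field_!r}", lineno))
    key, typ, raw = parts
    if typ in _TAG_CASTERS:
        try:
            return key, typ, _TAG_CASTERS[typ](raw)
        except ValueError as exc:
            raise SamParseError(_at(f"bad {typ} tag value {raw!r}", lineno)) from exc
    if typ == "B":
        sub = raw[0]
        caster = float if sub == "f" else int
        return key, typ, (sub, [caster(x) for x in raw[1:].lstrip(",").split(",") if x])
    # unknown type: keep the raw text so round-tripping is lossless
    return key, typ, raw


def _at(msg: str, lineno: int | None) -> str:
    return f"line {lineno}: {msg}" if lineno is not None else msg


def parse_sam_record(
    line: str, header: SamHeader, lineno: int | None = None
) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(_at(f"expected >= 11 fields, got {len(fields)}", lineno))
    qname = fields[0]
    try:
        flag = int(fields[1])
    except ValueError as exc:
        raise SamParseError(_at(f"invalid flag {fields[1]!r}", lineno)) from exc
    if not 0 <= flag < 0x10000:
        raise SamParseError(_at(f"flag {flag} out of range", lineno))
    rname = fields[2]
    if rname == "*":
        rid = -1
    else:
        try:
            rid = header.ref_id(rname)
        except SamParseError as exc:
            raise SamParseError(_at(str(exc), lineno)) from exc
    pos = int(fields[3]) - 1
    mapq = int(fields[4])
    cigar = parse_cigar(fields[5])
    mrname = fields[6]
    if mrname == "*":
        mrid = -1
    elif mrname == "=":
        mrid = rid
    else:
        mrid = header.ref_id(mrname)
    mpos = int(fields[7]) - 1
    tlen = int(fields[8])
    seq = None if fields[9] == "*" else fields[9]
    qual = None
    if fields[10] != "*":
        qual = [ord(c) - 33 for c in fields[10]]
    if seq is not None and cigar:
        qlen = cigar_query_length(cigar)
        if qlen != len(seq):
            raise SamParseError(
                _at(
                    f"CIGAR consumes {qlen} query bases but SEQ has {len(seq)}",
                    lineno,
                )
            )
    if qual is not None and seq is not None and len(qual) != len(seq):
        raise SamParseError(_at("QUAL length differs from SEQ length", lineno))
    tags: dict[str, tuple[str, object]] = {}
    for f in fields[11:]:
        key, typ, val = _parse_tag(f, lineno)
        tags[key] = (typ, val)
    return AlignmentRecord(
        qname, flag, rid, pos, mapq, cigar, mrid, mpos, tlen, seq, qual, tags
    )


def _format_tag(key: str, typ: str, val: object) -> str:
    if typ == "B":
        sub, items = val  # type: ignore[misc]
        return f"{key}:B:{sub}," + ",".join(str(x) for x in items)
    if typ == "f":
        return f"{key}:f:{val:g}"
    return f"{key}:{typ}:{val}"


def format_sam_record(record: AlignmentRecord, header: SamHeader) -> str:
    rname = "*" if record.rid < 0 else header.ref_name(record.rid)
    if record.mrid < 0:
        mrname = "*"
    elif record.mrid == record.rid and record.rid >= 0:
        mrname = "="
    else:
        mrname = header.ref_name(record.mrid)
    qual = "*" if record.qual is None else "".join(chr(q + 33) for q in record.qual)
    fields = [
        record.qname,
        str(record.flag),
        rname,
        str(record.pos + 1),
        str(record.mapq),
        cigar_to_text(record.cigar),
        mrname,
        str(record.mpos + 1),
        str(record.tlen),
        record.seq if record.seq is not None else "*",
        qual,
    ]
    fields.extend(_format_tag(k, t, v) for k, (t, v) in record.tags.items())
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# SAM file reading/writing (plain text or BGZF-compressed text)

def read_sam(text: str) -> tuple[SamHeader, list[AlignmentRecord]]:
    lines = text.splitlines()
    header_lines = [ln for ln in lines if ln.startswith("@")]
    header = SamHeader.from_lines(header_lines)
    records = []
    for i, ln in enumerate(lines, 1):
        if ln and not ln.startswith("@"):
            records.append(parse_sam_record(ln, header, lineno=i))
    return header, records


def write_sam(header: SamHeader, records: Iterable[AlignmentRecord]) -> str:
    out = [header.to_text()]
    for r in records:
        out.append(format_sam_record(r, header) + "\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# region strings

_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)(?:-([\d,]+))?)?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``name``, ``name:start`` or ``name:start-end`` (1-based inclusive)
    into (name, 0-based start, exclusive end)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region string {region!r}")
    name = m.group(1)
    if m.group(2) is None:
        return name, None, None
    start1 = int(m.group(2).replace(",", ""))
    if start1 < 1:
        raise ValueError(f"region start must be >= 1 in {region!r}")
    end1 = int(m.group(3).replace(",", "")) if m.group(3) else None
    if end1 is not None and end1 < start1:
        raise ValueError(f"region end before start in {region!r}")
    return name, start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA + faidx

@dataclass
class FaidxEntry:
    name: str
    length: int
    offset: int  # byte offset of the first base
    linebases: int
    linewidth: int  # bytes per line incl. newline


class FastaIndex:
    """The standard 5-column faidx layout over an uncompressed FASTA."""

    def __init__(self, entries: list[FaidxEntry]):
        self.entries = entries
        self._by_name = {e.name: e for e in entries}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FaidxEntry:
        return self._by_name[name]

    def to_text(self) -> str:
        return "".join(
            f"{e.name}\t{e.length}\t{e.offset}\t{e.linebases}\t{e.linewidth}\n"
            for e in self.entries
        )

    @classmethod
    def from_text(cls, text: str) -> "FastaIndex":
        entries = []
        for ln in text.splitlines():
            if not ln:
                continue
            name, length, offset, lb, lw = ln.split("\t")
            entries.append(FaidxEntry(name, int(length), int(offset), int(lb), int(lw)))
        return cls(entries)


def faidx_build(data: bytes) -> FastaIndex:
    """Index the byte content of a FASTA file.

    Body lines of each sequence must share one width (the final line may be
    shorter), as required for O(1) coordinate arithmetic.
    """
    entries: list[FaidxEntry] = []
    name = None
    length = 0
    offset = 0
    linebases = 0
    linewidth = 0
    last_short = False
    lineno = 0
    pos = 0
    for raw in data.split(b"\n"):
        lineno += 1
        line_len = len(raw) + 1  # assume \n-terminated; trailing chunk handled below
        if raw.startswith(b">"):
            if name is not None:
                entries.append(FaidxEntry(name, length, offset, linebases, linewidth))
            name = raw[1:].split()[0].decode() if len(raw) > 1 else ""
            length = 0
            offset = pos + line_len
            linebases = 0
            linewidth = 0
            last_short = False
        elif raw:
            if name is None:
                raise ValueError("FASTA data does not start with a header line")
            if linebases == 0:
                linebases = len(raw)
                linewidth = line_len
            elif len(raw) > linebases or last_short:
                raise ValueError(
                    f"ragged FASTA body line {lineno} in sequence {name!r}"
                )
            if len(raw) < linebases:
                last_short = True
            length += len(raw)
        pos += line_len
    if name is not None:
        entries.append(FaidxEntry(name, length, offset, linebases, linewidth))
    return FastaIndex(entries)


def faidx_fetch(data: bytes, index: FastaIndex, name: str, start1: int, end1: int) -> str:
    """1-based inclusive subsequence fetch using index arithmetic only."""
    if name not in index:
        raise KeyError(f"unknown sequence name {name!r}")
    e = index[name]
    if start1 < 1 or end1 < start1 or end1 > e.length:
        raise ValueError(
            f"region {name}:{start1}-{end1} out of bounds (length {e.length})"
        )
    start = start1 - 1
    first = e.offset + (start // e.linebases) * e.linewidth + start % e.linebases
    last = e.offset + ((end1 - 1) // e.linebases) * e.linewidth + (end1 - 1) % e.linebases
    chunk = data[first : last + 1]
    return chunk.replace(b"\n", b"").replace(b"\r", b"").decode()


def read_fasta(text: str) -> dict[str, str]:
    """Whole-file FASTA parse into an ordered name → sequence mapping."""
    seqs: dict[str, list[str]] = {}
    name = None
    for ln in text.splitlines():
        if ln.startswith(">"):
            name = ln[1:].split()[0]
            seqs[name] = []
        elif ln and name is not None:
            seqs[name].append(ln.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], width: int = 60) -> str:
    out = []
    for name, seq in seqs.items():
        out.append(f">{name}\n")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width] + "\n")
    return "".join(out)
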