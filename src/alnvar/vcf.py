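"""VCF data model, parsing, formatting, header handling, and BGZF-backed
random access.

Positions are 0-based internally and converted at the text boundary.  Header
handling has a strict and a lenient mode: strict validates Number arities
and requires every field to be declared; lenient (the default) auto-declares
unknown fields with a warning, since real-world VCFs are messy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from . import bgzf

MISSING = "."


class VcfParseError(ValueError):
    pass


def genotype_index(j: int, k: int) -> int:
    """Index of diploid genotype (j, k), j <= k, in the PL/GL ordering.

    The standard ordering places genotype (j, k) at k(k+1)/2 + j, so the
    vector grows quadratically with the allele count.
    """
    if not 0 <= j <= k:
        raise ValueError(f"need 0 <= j <= k, got ({j}, {k})")
    return k * (k + 1) // 2 + j


def genotype_from_index(idx: int) -> tuple[int, int]:
    """Inverse of :func:`genotype_index`."""
    if idx < 0:
        raise ValueError("index must be non-negative")
    k = int((math.isqrt(8 * idx + 1) - 1) // 2)
    while genotype_index(0, k + 1) <= idx:
        k += 1
    while k > 0 and genotype_index(0, k) > idx:
        k -= 1
    j = idx - k * (k + 1) // 2
    return j, k


def n_genotypes(n_alleles: int) -> int:
    return n_alleles * (n_alleles + 1) // 2


@dataclass
class FieldDef:
    id: str
    number: str  # '1', 'A', 'R', 'G', '.', or any integer string
    type: str  # Integer, Float, Flag, Character, String
    description: str = ""


@dataclass
class VcfHeader:
    fileformat: str = "VCFv4.2"
    contigs: dict[str, int | None] = field(default_factory=dict)
    infos: dict[str, FieldDef] = field(default_factory=dict)
    formats: dict[str, FieldDef] = field(default_factory=dict)
    filters: dict[str, FieldDef] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"##fileformat={self.fileformat}"]
        for fid, fd in self.filters.items():
            lines.append(f'##FILTER=<ID={fd.id},Description="{fd.description}">')
        for fd in self.infos.values():
            lines.append(
                f'##INFO=<ID={fd.id},Number={fd.number},Type={fd.type},'
                f'Description="{fd.description}">'
            )
        for fd in self.formats.values():
            lines.append(
                f'##FORMAT=<ID={fd.id},Number={fd.number},Type={fd.type},'
                f'Description="{fd.description}">'
            )
        for name, length in self.contigs.items():
            if length is None:
                lines.append(f"##contig=<ID={name}>")
            else:
                lines.append(f"##contig=<ID={name},length={length}>")
        lines.extend(self.extra_lines)
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if self.samples:
            cols += ["FORMAT"] + self.samples
        lines.append("\t".join(cols))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "VcfHeader":
        hdr = cls()
        for line in lines:
            line = line.rstrip("\n")
            if line.startswith("##fileformat="):
                hdr.fileformat = line.split("=", 1)[1]
            elif line.startswith("##contig=<"):
                kv = _parse_structured(line)
                hdr.contigs[kv["ID"]] = int(kv["length"]) if "length" in kv else None
            elif line.startswith("##INFO=<"):
                kv = _parse_structured(line)
                hdr.infos[kv["ID"]] = FieldDef(
                    kv["ID"], kv.get("Number", "."), kv.get("Type", "String"),
                    kv.get("Description", ""),
                )
            elif line.startswith("##FORMAT=<"):
                kv = _parse_structured(line)
                hdr.formats[kv["ID"]] = FieldDef(
                    kv["ID"], kv.get("Number", "."), kv.get("Type", "String"),
                    kv.get("Description", ""),
                )
            elif line.startswith("##FILTER=<"):
                kv = _parse_structured(line)
                hdr.filters[kv["ID"]] = FieldDef(
                    kv["ID"], ".", "String", kv.get("Description", "")
                )
            elif line.startswith("##"):
                hdr.extra_lines.append(line)
            elif line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    hdr.samples = cols[9:]
                elif len(cols) == 10:
                    hdr.samples = cols[9:]
        return hdr


def _parse_structured(line: str) -> dict[str, str]:
    inner = line[line.index("<") + 1 : line.rindex(">")]
    kv: dict[str, str] = {}
    key = []
    val = []
    in_val = False
    in_quotes = False
    for ch in inner:
        if in_val:
            if in_quotes:
                if ch == '"':
                    in_quotes = False
                else:
                    val.append(ch)
            elif ch == '"':
                in_quotes = True
            elif ch == ",":
                kv["".join(key)] = "".join(val)
                key, val, in_val = [], [], False
            else:
                val.append(ch)
        elif ch == "=":
            in_val = True
        else:
            key.append(ch)
    if key:
        kv["".join(key)] = "".join(val)
    return kv


@dataclass
class Genotype:
    alleles: tuple[int | None, ...]  # None for '.'
    phased: bool = False

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join(MISSING if a is None else str(a) for a in self.alleles)

    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    def is_hom_ref(self) -> bool:
        return all(a == 0 for a in self.alleles)

    def is_het(self) -> bool:
        known = [a for a in self.alleles if a is not None]
        return len(set(known)) > 1

    def has_alt(self) -> bool:
        return any(a is not None and a > 0 for a in self.alleles)

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        phased = "|" in text
        parts = text.replace("|", "/").split("/")
        return cls(
            tuple(None if p == MISSING or p == "" else int(p) for p in parts), phased
        )


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 0-based internal
    id: str
    ref: str
    alts: list[str]
    qual: float | None
    filters: list[str]  # empty list = missing; ["PASS"] = pass
    info: dict[str, object] = field(default_factory=dict)
    format_keys: list[str] = field(default_factory=list)
    samples: list[dict[str, object]] = field(default_factory=list)

    @property
    def alleles(self) -> list[str]:
        return [self.ref] + self.alts

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference (END-aware for gVCF blocks)."""
        if "END" in self.info:
            return int(self.info["END"])  # END is 1-based inclusive == 0-based excl.
        return self.pos + len(self.ref)

    def genotype(self, sample_idx: int) -> Genotype | None:
        if sample_idx >= len(self.samples):
            return None
        gt = self.samples[sample_idx].get("GT")
        return gt if isinstance(gt, Genotype) else None

    def copy(self) -> "VariantRecord":
        return VariantRecord(
            self.chrom, self.pos, self.id, self.ref, list(self.alts), self.qual,
            list(self.filters), dict(self.info), list(self.format_keys),
            [dict(s) for s in self.samples],
        )


_TYPE_PARSERS = {
    "Integer": int,
    "Float": float,
    "Character": str,
    "String": str,
}


def _expected_arity(number: str, n_alts: int) -> int | None:
    if number == "A":
        return n_alts
    if number == "R":
        return n_alts + 1
    if number == "G":
        return n_genotypes(n_alts + 1)
    if number == ".":
        return None
    try:
        return int(number)
    except ValueError:
        return None


def _parse_typed(raw: str, fd: FieldDef, n_alts: int, strict: bool, where: str):
    if fd.type == "Flag":
        return True
    caster = _TYPE_PARSERS.get(fd.type, str)
    vals = []
    for tok in raw.split(","):
        if tok == MISSING:
            vals.append(None)
        else:
            try:
                vals.append(caster(tok))
            except ValueError as exc:
                raise VcfParseError(f"{where}: cannot parse {tok!r} as {fd.type}") from exc
    exp = _expected_arity(fd.number, n_alts)
    if strict and exp is not None and len(vals) != exp:
        raise VcfParseError(
            f"{where}: field {fd.id} expects {exp} values (Number={fd.number}), "
            f"got {len(vals)}"
        )
    if fd.number == "1" or (exp == 1 and fd.number not in "ARG."):
        return vals[0]
    return vals


def _auto_declare(section: dict[str, FieldDef], fid: str, strict: bool, kind: str,
                  number: str = ".", typ: str = "String") -> FieldDef:
    if fid in section:
        return section[fid]
    if strict:
        raise VcfParseError(f"undeclared {kind} field {fid!r} in strict mode")
    warnings.warn(f"auto-declaring undeclared {kind} field {fid!r}", stacklevel=3)
    fd = FieldDef(fid, number, typ)
    section[fid] = fd
    return fd


def parse_vcf_record(
    line: str, header: VcfHeader, strict: bool = False, lineno: int | None = None
) -> VariantRecord:
    where = f"line {lineno}" if lineno is not None else "record"
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise VcfParseError(f"{where}: expected >= 8 fields, got {len(fields)}")
    chrom = fields[0]
    if header.contigs and chrom not in header.contigs:
        if strict:
            raise VcfParseError(f"{where}: unknown contig {chrom!r}")
        warnings.warn(f"{where}: contig {chrom!r} not declared in header", stacklevel=2)
    try:
        pos = int(fields[1]) - 1
    except ValueError as exc:
        raise VcfParseError(f"{where}: invalid POS {fields[1]!r}") from exc
    length = header.contigs.get(chrom)
    if length is not None and pos >= length:
        warnings.warn(
            f"{where}: position {pos + 1} beyond declared length of {chrom}",
            stacklevel=2,
        )
    vid = fields[2]
    ref = fields[3]
    if not ref:
        raise VcfParseError(f"{where}: empty REF")
    alts = [] if fields[4] == MISSING else fields[4].split(",")
    qual = None if fields[5] == MISSING else float(fields[5])
    filters = [] if fields[6] == MISSING else fields[6].split(";")
    n_alts = len(alts)
    info: dict[str, object] = {}
    if fields[7] != MISSING:
        for item in fields[7].split(";"):
            if not item:
                continue
            if "=" in item:
                k, _, v = item.partition("=")
                fd = _auto_declare(header.infos, k, strict, "INFO")
                info[k] = _parse_typed(v, fd, n_alts, strict, where)
            else:
                fd = _auto_declare(header.infos, item, strict, "INFO", "0", "Flag")
                info[item] = True
    format_keys: list[str] = []
    samples: list[dict[str, object]] = []
    if len(fields) > 8:
        format_keys = fields[8].split(":")
        for fid in format_keys:
            if fid == "GT":
                header.formats.setdefault(
                    "GT", FieldDef("GT", "1", "String", "Genotype")
                )
            else:
                _auto_declare(header.formats, fid, strict, "FORMAT")
        for si, raw in enumerate(fields[9:]):
            vals = raw.split(":")
            sample: dict[str, object] = {}
            for fid, val in zip(format_keys, vals):
                if val == MISSING or val == "":
                    continue
                if fid == "GT":
                    sample[fid] = Genotype.parse(val)
                else:
                    sample[fid] = _parse_typed(
                        val, header.formats[fid], n_alts, strict, where
                    )
            samples.append(sample)
        if header.samples and len(samples) != len(header.samples):
            raise VcfParseError(
                f"{where}: {len(samples)} sample columns but header declares "
                f"{len(header.samples)}"
            )
    return VariantRecord(
        chrom, pos, vid, ref, alts, qual, filters, info, format_keys, samples
    )


def _fmt_value(v: object) -> str:
    if v is None:
        return MISSING
    if isinstance(v, bool):
        return ""
    if isinstance(v, float):
        if v == int(v) and abs(v) < 1e15:
            return f"{v:g}"
        return repr(v)
    if isinstance(v, (list, tuple)):
        return ",".join(_fmt_value(x) for x in v)
    return str(v)


def format_vcf_record(record: VariantRecord, header: VcfHeader) -> str:
    info_parts = []
    for k, v in record.info.items():
        if v is True:
            info_parts.append(k)
        else:
            info_parts.append(f"{k}={_fmt_value(v)}")
    fields = [
        record.chrom,
        str(record.pos + 1),
        record.id or MISSING,
        record.ref,
        ",".join(record.alts) if record.alts else MISSING,
        MISSING if record.qual is None else _fmt_value(record.qual),
        ";".join(record.filters) if record.filters else MISSING,
        ";".join(info_parts) if info_parts else MISSING,
    ]
    if record.format_keys:
        fields.append(":".join(record.format_keys))
        for sample in record.samples:
            parts = []
            for fid in record.format_keys:
                if fid not in sample:
                    parts.append(MISSING)
                else:
                    parts.append(_fmt_value(sample[fid]))
            # trailing missing fields may be dropped, but keep them for clarity
            fields.append(":".join(parts))
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# whole-file I/O

def read_vcf(data: bytes | str, strict: bool = False) -> tuple[VcfHeader, list[VariantRecord]]:
    """Parse plain or BGZF-compressed VCF text."""
    if isinstance(data, bytes):
        if data[:2] == b"\x1f\x8b":
            data = bgzf.decompress(data)
        text = data.decode()
    else:
        text = data
    lines = text.splitlines()
    header_lines = [ln for ln in lines if ln.startswith("#")]
    header = VcfHeader.from_lines(header_lines)
    records = []
    for i, ln in enumerate(lines, 1):
        if ln and not ln.startswith("#"):
            records.append(parse_vcf_record(ln, header, strict=strict, lineno=i))
    return header, records


def write_vcf(
    header: VcfHeader, records: Iterable[VariantRecord], compress: bool = False
) -> bytes:
    text = header.to_text() + "".join(
        format_vcf_record(r, header) + "\n" for r in records
    )
    raw = text.encode()
    return bgzf.compress(raw) if compress else raw


def write_vcf_indexed(
    header: VcfHeader, records: Iterable[VariantRecord]
) -> tuple[bytes, bgzf.LinearIndex]:
    """BGZF-compressed VCF plus a linear index built while writing."""
    import io

    contig_ids = {name: i for i, name in enumerate(header.contigs)}
    buf = io.BytesIO()
    writer = bgzf.BgzfWriter(buf)
    writer.write(header.to_text().encode())
    entries = []
    for r in records:
        voff = writer.tell()
        writer.write((format_vcf_record(r, header) + "\n").encode())
        rid = contig_ids.setdefault(r.chrom, len(contig_ids))
        entries.append((rid, r.pos, max(r.end, r.pos + 1), voff))
    writer.close()
    index = bgzf.build_linear_index(entries, n_refs=len(contig_ids))
    return buf.getvalue(), index


def query_region(
    data: bytes,
    index: bgzf.LinearIndex,
    header: VcfHeader,
    chrom: str,
    start: int,
    end: int,
    strict: bool = False,
) -> list[VariantRecord]:
    """Records whose [pos, end) interval overlaps [start, end), via the index."""
    contig_ids = {name: i for i, name in enumerate(header.contigs)}
    if chrom not in contig_ids:
        raise KeyError(f"unknown reference name {chrom!r}")
    rid = contig_ids[chrom]
    voff = index.min_offset(rid, start)
    if voff is None:
        return []
    reader = bgzf.BgzfReader(data)
    reader.seek(voff)
    out = []
    for raw in reader:
        line = raw.decode().rstrip("\n")
        if not line or line.startswith("#"):
            continue
        rec = parse_vcf_record(line, header, strict=strict)
        if rec.chrom != chrom:
            if contig_ids.get(rec.chrom, rid) > rid:
                break
            continue
        if rec.pos >= end:
            break
        if max(rec.end, rec.pos + 1) > start:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# header merging

def merge_vcf_headers(headers: list[VcfHeader]) -> tuple[VcfHeader, list[list[str]]]:
    """Union of definitions and contigs; sample lists concatenated with
    duplicate names suffixed ``:N``.  Returns (header, per-input renamed
    sample lists)."""
    out = VcfHeader()
    sample_names: set[str] = set()
    renamed: list[list[str]] = []
    for hdr in headers:
        out.fileformat = hdr.fileformat
        for name, length in hdr.contigs.items():
            if name in out.contigs:
                if out.contigs[name] is not None and length is not None and \
                        out.contigs[name] != length:
                    raise ValueError(f"contig {name!r} has conflicting lengths")
                if out.contigs[name] is None:
                    out.contigs[name] = length
            else:
                out.contigs[name] = length
        for section, src in (
            (out.infos, hdr.infos),
            (out.formats, hdr.formats),
            (out.filters, hdr.filters),
        ):
            for fid, fd in src.items():
                if fid in section:
                    cur = section[fid]
                    if cur.type != fd.type:
                        raise ValueError(
                            f"field {fid!r} has conflicting types "
                            f"({cur.type} vs {fd.type})"
                        )
                    if cur.number != fd.number:
                        cur.number = "."
                else:
                    section[fid] = FieldDef(fd.id, fd.number, fd.type, fd.description)
        names = []
        for s in hdr.samples:
            new = s
            n = 2
            while new in sample_names:
                new = f"{s}:{n}"
                n += 1
            sample_names.add(new)
            names.append(new)
        renamed.append(names)
        out.samples.extend(names)
    return out, renamed
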