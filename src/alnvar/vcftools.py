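"""Variant-side toolbox: normalization, multiallelic split/join, merge,
concat, isec, annotate, consensus, query formatting, a filter-expression
language, stats, and genotype concordance checks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .vcf import (
    FieldDef,
    Genotype,
    VariantRecord,
    VcfHeader,
    genotype_from_index,
    genotype_index,
    merge_vcf_headers,
    n_genotypes,
)


class ReferenceMismatchError(ValueError):
    pass


class OverlapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization

def normalize(record: VariantRecord, ref_seq: str) -> VariantRecord:
    """Left-align and trim alleles to their minimal representation.

    Repeatedly: strip a shared final base (extending left with the previous
    reference base whenever an allele would empty), then strip shared
    leading bases while every allele keeps at least one base.  The result is
    the unique left-aligned minimal representation; REF always matches the
    reference sequence at the final position.
    """
    if any(_is_symbolic(a) for a in record.alts):
        raise ValueError("cannot normalize symbolic or breakend alleles")
    ref_check = ref_seq[record.pos : record.pos + len(record.ref)].upper()
    if ref_check != record.ref.upper():
        raise ReferenceMismatchError(
            f"REF {record.ref!r} at {record.chrom}:{record.pos + 1} does not match "
            f"reference {ref_check!r}"
        )
    rec = record.copy()
    alleles = [rec.ref.upper()] + [a.upper() for a in rec.alts]
    pos = rec.pos
    if len(set(alleles)) == 1 and len(alleles) > 1:
        # degenerate ref==alt; nothing to do beyond trimming below
        pass
    changed = True
    while changed:
        changed = False
        # shared last base
        while (
            len(set(a[-1] for a in alleles)) == 1
            and len(alleles) > 1
        ):
            if any(len(a) == 1 for a in alleles):
                if pos == 0:
                    break
                prev = ref_seq[pos - 1].upper()
                alleles = [prev + a for a in alleles]
                pos -= 1
            alleles = [a[:-1] for a in alleles]
            changed = True
        # shared first base
        while (
            all(len(a) > 1 for a in alleles)
            and len(set(a[0] for a in alleles)) == 1
        ):
            alleles = [a[1:] for a in alleles]
            pos += 1
            changed = True
    rec.pos = pos
    rec.ref = alleles[0]
    rec.alts = alleles[1:]
    return rec


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele == "*"


# ---------------------------------------------------------------------------
# multiallelic split / join

def _slice_value(
    value: object, number: str, alt_idx: int, n_alts: int
) -> object:
    """Project a Number=A/R/G value onto the biallelic record for alt_idx."""
    if not isinstance(value, list):
        return value
    if number == "A":
        return [value[alt_idx]] if alt_idx < len(value) else [None]
    if number == "R":
        return [value[0], value[alt_idx + 1] if alt_idx + 1 < len(value) else None]
    if number == "G":
        mapping = [0, alt_idx + 1]
        out = []
        for k in range(2):
            for j in range(k + 1):
                oj, ok = sorted((mapping[j], mapping[k]))
                idx = genotype_index(oj, ok)
                out.append(value[idx] if idx < len(value) else None)
        return out
    return value


def split_multiallelic(
    record: VariantRecord, header: VcfHeader
) -> list[VariantRecord]:
    """One record per alternate allele, slicing A/R/G fields accordingly.

    Genotype alleles pointing at other alternates are recoded as reference.
    """
    if len(record.alts) <= 1:
        return [record.copy()]
    n_alts = len(record.alts)
    out = []
    for i, alt in enumerate(record.alts):
        rec = record.copy()
        rec.alts = [alt]
        for k, v in list(rec.info.items()):
            fd = header.infos.get(k)
            if fd is not None and fd.number in "ARG":
                rec.info[k] = _slice_value(v, fd.number, i, n_alts)
        for sample in rec.samples:
            for k, v in list(sample.items()):
                if k == "GT" and isinstance(v, Genotype):
                    sample[k] = Genotype(
                        tuple(
                            None if a is None else (1 if a == i + 1 else 0)
                            for a in v.alleles
                        ),
                        v.phased,
                    )
                    continue
                fd = header.formats.get(k)
                if fd is not None and fd.number in "ARG":
                    sample[k] = _slice_value(v, fd.number, i, n_alts)
        out.append(rec)
    return out


def join_multiallelic(
    records: Sequence[VariantRecord], header: VcfHeader
) -> VariantRecord:
    """Inverse of :func:`split_multiallelic` on its own output.

    Cross-alternate entries of Number=G fields, which a biallelic split
    cannot carry, are filled with the field's maximum value (the least
    confident entry).
    """
    if len(records) == 1:
        return records[0].copy()
    base = records[0]
    if any(
        (r.chrom, r.pos, r.ref) != (base.chrom, base.pos, base.ref) for r in records
    ):
        raise ValueError("join requires identical CHROM/POS/REF")
    alts: list[str] = []
    for r in records:
        for a in r.alts:
            if a not in alts:
                alts.append(a)
    alt_of = [
        [alts.index(a) + 1 for a in r.alts] for r in records
    ]
    out = base.copy()
    out.alts = alts
    n = len(alts) + 1
    for k in list(out.info.keys()):
        fd = header.infos.get(k)
        if fd is None or fd.number not in "ARG":
            continue
        out.info[k] = _join_values(
            [r.info.get(k) for r in records], fd.number, alt_of, n
        )
    for si in range(len(out.samples)):
        merged: dict[str, object] = {}
        for k in base.format_keys:
            if k == "GT":
                merged["GT"] = _join_gt([r.samples[si].get("GT") for r in records], alt_of)
                continue
            fd = header.formats.get(k)
            vals = [r.samples[si].get(k) for r in records]
            if fd is not None and fd.number in "ARG":
                merged[k] = _join_values(vals, fd.number, alt_of, n)
            else:
                merged[k] = next((v for v in vals if v is not None), None)
            if merged[k] is None:
                del merged[k]
        out.samples[si] = merged
    return out


def _join_gt(gts: list[Genotype | None], alt_of: list[list[int]]) -> Genotype:
    alleles: list[int | None] = [0, 0]
    phased = False
    for ri, gt in enumerate(gts):
        if gt is None:
            continue
        phased = phased or gt.phased
        for ai, a in enumerate(gt.alleles[:2]):
            if a is None:
                alleles[ai] = None
            elif a > 0:
                alleles[ai] = alt_of[ri][a - 1]
    return Genotype(tuple(alleles), phased)


def _join_values(vals, number: str, alt_of: list[list[int]], n: int):
    if number == "A":
        out = [None] * (n - 1)
        for ri, v in enumerate(vals):
            if isinstance(v, list):
                for ai, x in enumerate(v):
                    out[alt_of[ri][ai] - 1] = x
        return out
    if number == "R":
        out = [None] * n
        for ri, v in enumerate(vals):
            if isinstance(v, list):
                out[0] = v[0]
                for ai, x in enumerate(v[1:]):
                    out[alt_of[ri][ai]] = x
        return out
    # G
    out: list = [None] * n_genotypes(n)
    mx = None
    for ri, v in enumerate(vals):
        if not isinstance(v, list):
            continue
        mapping = [0] + alt_of[ri]
        nv = [x for x in v if x is not None]
        if nv:
            mx = max(nv) if mx is None else max(mx, max(nv))
        for k in range(len(mapping)):
            for j in range(k + 1):
                idx = genotype_index(j, k)
                if idx < len(v) and v[idx] is not None:
                    oj, ok = sorted((mapping[j], mapping[k]))
                    out[genotype_index(oj, ok)] = v[idx]
    for i, x in enumerate(out):
        if x is None:
            out[i] = mx
    return out


# ---------------------------------------------------------------------------
# merge / concat / isec

def _contig_rank(header: VcfHeader) -> dict[str, int]:
    return {name: i for i, name in enumerate(header.contigs)}


def merge_variant_files(
    inputs: list[tuple[VcfHeader, Sequence[VariantRecord]]]
) -> tuple[VcfHeader, list[VariantRecord]]:
    """Merge position-sorted files carrying different samples.

    Records at the same (chrom, pos) with compatible REF (one a prefix of
    the other) are unified: allele lists unioned, genotype-indexed fields
    remapped, absent samples filled with missing.  QUAL resolves to the
    maximum, FILTER to PASS only when all inputs pass.  INFO fields declared
    Number=1 Integer are summed; other INFO fields are dropped with a
    warning.
    """
    hdr, renamed = merge_vcf_headers([h for h, _ in inputs])
    sample_offsets = []
    off = 0
    for names in renamed:
        sample_offsets.append(off)
        off += len(names)
    total_samples = off
    rank = _contig_rank(hdr)
    keyed: dict[tuple[int, int], list[tuple[int, VariantRecord]]] = {}
    for fi, (h, records) in enumerate(inputs):
        for r in records:
            keyed.setdefault((rank.get(r.chrom, len(rank)), r.pos), []).append((fi, r))
    out: list[VariantRecord] = []
    for key in sorted(keyed):
        group = keyed[key]
        out.extend(_merge_site(group, hdr, sample_offsets, total_samples, len(inputs)))
    return hdr, out


def _merge_site(
    group: list[tuple[int, VariantRecord]],
    hdr: VcfHeader,
    offsets: list[int],
    total_samples: int,
    n_files: int,
) -> list[VariantRecord]:
    # unify REF by prefix extension
    ref = max((r.ref for _, r in group), key=len)
    for _, r in group:
        if not ref.upper().startswith(r.ref.upper()):
            raise ValueError(
                f"incompatible REF alleles at {r.chrom}:{r.pos + 1}: "
                f"{r.ref!r} vs {ref!r}"
            )
    alts: list[str] = []
    per_file_map: dict[int, list[int]] = {}
    for fi, r in group:
        suffix = ref[len(r.ref) :]
        mapping = [0]
        for a in r.alts:
            aa = a + suffix
            if aa not in alts:
                alts.append(aa)
            mapping.append(alts.index(aa) + 1)
        per_file_map[fi] = mapping
    first = group[0][1]
    rec = VariantRecord(
        chrom=first.chrom,
        pos=first.pos,
        id=next((r.id for _, r in group if r.id not in (".", "")), "."),
        ref=ref,
        alts=alts,
        qual=max((r.qual for _, r in group if r.qual is not None), default=None),
        filters=(
            ["PASS"]
            if all(r.filters == ["PASS"] for _, r in group)
            else sorted({f for _, r in group for f in r.filters if f != "PASS"})
        ),
        info={},
        format_keys=[],
        samples=[{} for _ in range(total_samples)],
    )
    # INFO: sum Number=1 Integer fields, drop the rest
    info_keys = {k for _, r in group for k in r.info}
    for k in info_keys:
        fd = hdr.infos.get(k)
        if fd is not None and fd.number == "1" and fd.type == "Integer":
            rec.info[k] = sum(int(r.info[k]) for _, r in group if k in r.info)
        else:
            warnings.warn(
                f"dropping INFO/{k} during merge (no cross-file semantics defined)",
                stacklevel=2,
            )
    fmt_keys: list[str] = []
    for _, r in group:
        for k in r.format_keys:
            if k not in fmt_keys:
                fmt_keys.append(k)
    rec.format_keys = fmt_keys
    n_new = len(alts) + 1
    for fi, r in group:
        mapping = per_file_map[fi]
        for si, sample in enumerate(r.samples):
            new_sample: dict[str, object] = {}
            for k, v in sample.items():
                if k == "GT" and isinstance(v, Genotype):
                    new_sample["GT"] = Genotype(
                        tuple(None if a is None else mapping[a] for a in v.alleles),
                        v.phased,
                    )
                    continue
                fd = hdr.formats.get(k)
                if fd is not None and fd.number in "ARG" and isinstance(v, list):
                    new_sample[k] = _remap_arity(v, fd.number, mapping, n_new)
                else:
                    new_sample[k] = v
            rec.samples[offsets[fi] + si] = new_sample
    return [rec]


def _remap_arity(v: list, number: str, mapping: list[int], n_new: int) -> list:
    if number == "A":
        out = [None] * (n_new - 1)
        for ai, x in enumerate(v):
            if ai + 1 < len(mapping):
                out[mapping[ai + 1] - 1] = x
        return out
    if number == "R":
        out = [None] * n_new
        for ai, x in enumerate(v):
            if ai < len(mapping):
                out[mapping[ai]] = x
        return out
    out = [None] * n_genotypes(n_new)
    n_old = len(mapping)
    for k in range(n_old):
        for j in range(k + 1):
            idx = genotype_index(j, k)
            if idx < len(v):
                oj, ok = sorted((mapping[j], mapping[k]))
                out[genotype_index(oj, ok)] = v[idx]
    return out


def concat_variant_files(
    inputs: list[tuple[VcfHeader, Sequence[VariantRecord]]]
) -> tuple[VcfHeader, list[VariantRecord]]:
    """Concatenate files with identical sample lists (e.g. per-chromosome
    partitions), preserving input order."""
    if not inputs:
        raise ValueError("no inputs")
    samples0 = inputs[0][0].samples
    for h, _ in inputs[1:]:
        if h.samples != samples0:
            raise ValueError(
                f"sample lists differ: {samples0} vs {h.samples}"
            )
    hdr, _ = merge_vcf_headers([h for h, _ in inputs])
    hdr.samples = list(samples0)
    out: list[VariantRecord] = []
    for _, records in inputs:
        out.extend(r.copy() for r in records)
    return hdr, out


def site_key(record: VariantRecord, alleles: bool = True):
    if alleles:
        return (record.chrom, record.pos, record.ref.upper(),
                frozenset(a.upper() for a in record.alts))
    return (record.chrom, record.pos)


def isec(
    inputs: list[Sequence[VariantRecord]],
    use_alleles: bool = True,
) -> dict[object, tuple[int, list[list[VariantRecord]]]]:
    """Partition records by presence across files.

    Returns {site key: (presence bitmask, per-file record lists)}; bit i of
    the mask is set when file i contains the key.  Selection rules
    (private-to-i, shared-by-all, present-in->=k) are set operations over
    the masks, see :func:`isec_select`.
    """
    table: dict[object, tuple[int, list[list[VariantRecord]]]] = {}
    for fi, records in enumerate(inputs):
        for r in records:
            key = site_key(r, use_alleles)
            if key not in table:
                table[key] = (0, [[] for _ in inputs])
            mask, lists = table[key]
            table[key] = (mask | (1 << fi), lists)
            lists[fi].append(r)
    return table


def isec_select(
    table: dict[object, tuple[int, list[list[VariantRecord]]]],
    rule: Callable[[int], bool],
    file_idx: int,
) -> list[VariantRecord]:
    """Records of file ``file_idx`` whose presence mask satisfies ``rule``."""
    out = []
    for key, (mask, lists) in table.items():
        if rule(mask):
            out.extend(lists[file_idx])
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def private_to(i: int, n_files: int) -> Callable[[int], bool]:
    return lambda mask: mask == (1 << i)


def shared_by_all(n_files: int) -> Callable[[int], bool]:
    return lambda mask: mask == (1 << n_files) - 1


def present_in_at_least(k: int) -> Callable[[int], bool]:
    return lambda mask: bin(mask).count("1") >= k


# ---------------------------------------------------------------------------
# annotate

def annotate(
    records: Sequence[VariantRecord],
    header: VcfHeader,
    source: Sequence[VariantRecord] | None = None,
    source_header: VcfHeader | None = None,
    transfer: Sequence[str] = (),
    remove: Sequence[str] = (),
    match_alleles: bool = True,
) -> list[VariantRecord]:
    """Add/overwrite INFO (and ID) from a source VCF; remove annotations.

    ``transfer`` names fields like ``INFO/DP`` or ``ID``; ``remove`` accepts
    the same plus the ``INFO/*`` wildcard.  Matching is by site key.
    """
    src_index: dict[object, VariantRecord] = {}
    if source is not None:
        for r in source:
            src_index[site_key(r, match_alleles)] = r
    out = []
    remove_all_info = "INFO/*" in remove
    remove_info = {x.split("/", 1)[1] for x in remove if x.startswith("INFO/") and x != "INFO/*"}
    for r in records:
        rec = r.copy()
        if remove_all_info:
            rec.info = {}
        else:
            for k in remove_info:
                rec.info.pop(k, None)
        if "ID" in remove:
            rec.id = "."
        if "QUAL" in remove:
            rec.qual = None
        if "FILTER" in remove:
            rec.filters = []
        src = src_index.get(site_key(r, match_alleles))
        if src is not None:
            for t in transfer:
                if t == "ID":
                    if src.id not in (".", ""):
                        rec.id = src.id
                elif t.startswith("INFO/"):
                    k = t.split("/", 1)[1]
                    if k in src.info:
                        rec.info[k] = src.info[k]
                        if source_header is not None and k in source_header.infos:
                            header.infos.setdefault(k, source_header.infos[k])
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# consensus

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def consensus_apply(
    ref_seq: str,
    records: Sequence[VariantRecord],
    haplotype: int | str = 1,
    sample_idx: int = 0,
    missing_as_ref: bool = True,
) -> str:
    """Apply variants to a reference sequence.

    ``haplotype`` selects allele 1 or 2 of each genotype, or ``"IUPAC"`` to
    encode heterozygous SNPs as ambiguity codes.  Records must be sorted and
    non-overlapping after allele selection; overlap is a hard error.
    """
    out: list[str] = []
    cursor = 0
    last_site = None
    for r in sorted(records, key=lambda x: x.pos):
        if any(_is_symbolic(a) for a in r.alts):
            raise ValueError(f"symbolic allele at {r.chrom}:{r.pos + 1}")
        allele = _select_allele(r, haplotype, sample_idx, missing_as_ref)
        if allele is None:
            continue
        alt, ambiguous = allele
        if alt == r.ref and not ambiguous:
            continue
        if r.pos < cursor:
            raise OverlapError(
                f"variant at {r.chrom}:{r.pos + 1} overlaps the edit ending at "
                f"{cursor} (previous site {last_site})"
            )
        out.append(ref_seq[cursor : r.pos])
        ref_here = ref_seq[r.pos : r.pos + len(r.ref)]
        if ref_here.upper() != r.ref.upper():
            raise ReferenceMismatchError(
                f"REF {r.ref!r} at {r.chrom}:{r.pos + 1} does not match reference"
            )
        out.append(alt)
        cursor = r.pos + len(r.ref)
        last_site = r.pos + 1
    out.append(ref_seq[cursor:])
    return "".join(out)


def _select_allele(
    r: VariantRecord, haplotype: int | str, sample_idx: int, missing_as_ref: bool
) -> tuple[str, bool] | None:
    gt = r.genotype(sample_idx)
    if gt is None:
        # GT-less record: apply the first ALT
        return (r.alts[0], False) if r.alts else None
    if gt.is_missing():
        return (r.ref, False) if missing_as_ref else None
    if haplotype == "IUPAC":
        known = sorted({a for a in gt.alleles if a is not None})
        seqs = {r.alleles[a] for a in known}
        if len(seqs) > 1 and all(len(s) == 1 for s in seqs) and len(r.ref) == 1:
            code = IUPAC.get(frozenset(s.upper() for s in seqs))
            if code:
                return (code, True)
        a = max(known)
        return (r.alleles[a], False)
    idx = 0 if haplotype == 1 else min(1, len(gt.alleles) - 1)
    a = gt.alleles[idx]
    if a is None:
        a = 0
    return (r.alleles[a], False)


# ---------------------------------------------------------------------------
# query formatting

_FMT_TOKEN = re.compile(r"%(INFO/[A-Za-z0-9_.]+|[A-Za-z0-9_.]+)|\\t|\\n|\[|\]|[^%\\\[\]]+")


def query_format(
    records: Iterable[VariantRecord],
    fmt: str,
    header: VcfHeader,
) -> list[str]:
    """Render records through a placeholder format string.

    ``%CHROM %POS %ID %REF %ALT %QUAL %FILTER %INFO/x`` address site fields;
    a ``[...]`` block repeats per sample with ``%SAMPLE %GT`` and FORMAT
    tags; ``\\t`` and ``\\n`` escape; missing values render ``.``.
    """
    lines = []
    for r in records:
        lines.append(_render_one(r, fmt, header))
    return lines


def _fmt_scalar(v: object) -> str:
    if v is None:
        return "."
    if isinstance(v, bool):
        return "1"
    if isinstance(v, float):
        return f"{v:g}"
    if isinstance(v, list):
        return ",".join(_fmt_scalar(x) for x in v)
    return str(v)


def _site_field(r: VariantRecord, name: str) -> str:
    if name == "CHROM":
        return r.chrom
    if name == "POS":
        return str(r.pos + 1)
    if name == "ID":
        return r.id or "."
    if name == "REF":
        return r.ref
    if name == "ALT":
        return ",".join(r.alts) if r.alts else "."
    if name == "QUAL":
        return _fmt_scalar(r.qual)
    if name == "FILTER":
        return ";".join(r.filters) if r.filters else "."
    if name.startswith("INFO/"):
        return _fmt_scalar(r.info.get(name[5:]))
    if name in r.info:
        return _fmt_scalar(r.info[name])
    return "."


def _render_one(r: VariantRecord, fmt: str, header: VcfHeader) -> str:
    out = []
    i = 0
    n = len(fmt)
    while i < n:
        ch = fmt[i]
        if ch == "[":
            j = fmt.index("]", i)
            block = fmt[i + 1 : j]
            for si, sample_name in enumerate(header.samples or [None] * len(r.samples)):
                out.append(_render_sample(r, block, si, sample_name))
            i = j + 1
        elif ch == "\\" and i + 1 < n:
            out.append({"t": "\t", "n": "\n"}.get(fmt[i + 1], fmt[i + 1]))
            i += 2
        elif ch == "%":
            m = re.match(r"%(INFO/[A-Za-z0-9_.]+|[A-Za-z0-9_.]+)", fmt[i:])
            if not m:
                out.append(ch)
                i += 1
                continue
            out.append(_site_field(r, m.group(1)))
            i += m.end()
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _render_sample(r: VariantRecord, block: str, si: int, name: str | None) -> str:
    out = []
    i = 0
    n = len(block)
    sample = r.samples[si] if si < len(r.samples) else {}
    while i < n:
        ch = block[i]
        if ch == "\\" and i + 1 < n:
            out.append({"t": "\t", "n": "\n"}.get(block[i + 1], block[i + 1]))
            i += 2
        elif ch == "%":
            m = re.match(r"%([A-Za-z0-9_.]+)", block[i:])
            if not m:
                out.append(ch)
                i += 1
                continue
            tag = m.group(1)
            if tag == "SAMPLE":
                out.append(name or str(si))
            elif tag == "GT":
                gt = sample.get("GT")
                out.append(str(gt) if gt is not None else "./.")
            else:
                out.append(_fmt_scalar(sample.get(tag)))
            i += m.end()
        else:
            out.append(ch)
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# filter expression language

class FilterSyntaxError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<num>-?\d+\.?\d*(?:[eE][+-]?\d+)?)
      | (?P<str>"[^"]*"|'[^']*')
      | (?P<op><=|>=|==|!=|=|<|>)
      | (?P<and>&&|&)
      | (?P<or>\|\||\|)
      | (?P<not>!(?!=))
      | (?P<lp>\()
      | (?P<rp>\))
      | (?P<field>(?:INFO|FORMAT|FMT)/[A-Za-z0-9_.]+|[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)


@dataclass
class FilterExpression:
    """Parsed boolean expression over VCF fields.

    Comparisons against missing values are false (never an error); FORMAT
    fields quantify over samples, keeping a record when *any* sample
    matches.
    """

    root: object
    text: str

    def evaluate(self, record: VariantRecord, header: VcfHeader | None = None) -> bool:
        return bool(_eval_node(self.root, record))


def parse_filter_expression(text: str) -> FilterExpression:
    tokens = _tokenize(text)
    node, rest = _parse_or(tokens)
    if rest:
        raise FilterSyntaxError(f"unexpected token {rest[0]!r} in {text!r}")
    return FilterExpression(node, text)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise FilterSyntaxError(f"cannot tokenize {text[pos:]!r}")
        for kind in ("num", "str", "op", "and", "or", "not", "lp", "rp", "field"):
            v = m.group(kind)
            if v is not None:
                tokens.append((kind, v))
                break
        pos = m.end()
    return tokens


def _parse_or(tokens):
    left, tokens = _parse_and(tokens)
    while tokens and tokens[0][0] == "or":
        right, tokens = _parse_and(tokens[1:])
        left = ("or", left, right)
    return left, tokens


def _parse_and(tokens):
    left, tokens = _parse_unary(tokens)
    while tokens and tokens[0][0] == "and":
        right, tokens = _parse_unary(tokens[1:])
        left = ("and", left, right)
    return left, tokens


def _parse_unary(tokens):
    if not tokens:
        raise FilterSyntaxError("unexpected end of expression")
    kind, val = tokens[0]
    if kind == "not":
        node, rest = _parse_unary(tokens[1:])
        return ("not", node), rest
    if kind == "lp":
        node, rest = _parse_or(tokens[1:])
        if not rest or rest[0][0] != "rp":
            raise FilterSyntaxError("missing closing parenthesis")
        return _maybe_comparison(node, rest[1:])
    return _parse_comparison(tokens)


def _maybe_comparison(node, tokens):
    return node, tokens


def _parse_operand(tokens):
    if not tokens:
        raise FilterSyntaxError("unexpected end of expression")
    kind, val = tokens[0]
    if kind == "num":
        return ("const", float(val)), tokens[1:]
    if kind == "str":
        return ("const", val[1:-1]), tokens[1:]
    if kind == "field":
        return ("field", val), tokens[1:]
    raise FilterSyntaxError(f"expected operand, got {val!r}")


def _parse_comparison(tokens):
    left, rest = _parse_operand(tokens)
    if rest and rest[0][0] == "op":
        op = rest[0][1]
        right, rest = _parse_operand(rest[1:])
        return ("cmp", op, left, right), rest
    # bare field: flag/presence test
    return ("truthy", left), rest


def _field_values(record: VariantRecord, name: str) -> list[object]:
    """All values a field reference addresses (FORMAT fields: one per sample)."""
    if name == "QUAL":
        return [record.qual]
    if name == "FILTER":
        return [";".join(record.filters) if record.filters else None]
    if name in ("CHROM", "POS", "ID", "REF", "ALT"):
        return [
            {
                "CHROM": record.chrom,
                "POS": record.pos + 1,
                "ID": record.id,
                "REF": record.ref,
                "ALT": ",".join(record.alts) if record.alts else None,
            }[name]
        ]
    if name.startswith(("FORMAT/", "FMT/")):
        tag = name.split("/", 1)[1]
        vals: list[object] = []
        for s in record.samples:
            v = s.get(tag)
            if tag == "GT" and isinstance(v, Genotype):
                v = str(v)
            if isinstance(v, list):
                vals.extend(v)
            else:
                vals.append(v)
        return vals
    tag = name.split("/", 1)[1] if name.startswith("INFO/") else name
    v = record.info.get(tag)
    if isinstance(v, list):
        return list(v)
    return [v]


_CMP = {
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def _eval_node(node, record: VariantRecord) -> bool:
    tag = node[0]
    if tag == "or":
        return _eval_node(node[1], record) or _eval_node(node[2], record)
    if tag == "and":
        return _eval_node(node[1], record) and _eval_node(node[2], record)
    if tag == "not":
        return not _eval_node(node[1], record)
    if tag == "truthy":
        kind, val = node[1]
        if kind == "const":
            return bool(val)
        return any(v is not None and v is not False for v in _field_values(record, val))
    if tag == "cmp":
        _, op, left, right = node
        lvals = _operand_values(left, record)
        rvals = _operand_values(right, record)
        fn = _CMP[op]
        any_true = False
        for lv in lvals:
            for rv in rvals:
                if lv is None or rv is None:
                    continue
                try:
                    lv2, rv2 = _coerce(lv, rv)
                    if fn(lv2, rv2):
                        any_true = True
                except (TypeError, ValueError):
                    continue
        return any_true
    raise FilterSyntaxError(f"bad node {node!r}")


def _operand_values(operand, record: VariantRecord) -> list[object]:
    kind, val = operand
    if kind == "const":
        return [val]
    return _field_values(record, val)


def _coerce(a, b):
    if isinstance(a, str) and isinstance(b, (int, float)) and not isinstance(b, bool):
        return float(a), float(b)
    if isinstance(b, str) and isinstance(a, (int, float)) and not isinstance(a, bool):
        return float(a), float(b)
    if isinstance(a, bool) or isinstance(b, bool):
        return bool(a), bool(b)
    return a, b


def eval_filter(
    record: VariantRecord,
    expr: FilterExpression | str,
    mode: str = "include",
    header: VcfHeader | None = None,
) -> bool:
    """Keep decision for one record: include keeps on match, exclude keeps
    on non-match."""
    if isinstance(expr, str):
        expr = parse_filter_expression(expr)
    hit = expr.evaluate(record, header)
    return hit if mode == "include" else not hit


# ---------------------------------------------------------------------------
# stats

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class VcfStatsReport:
    n_records: int = 0
    n_snps: int = 0
    n_indels: int = 0
    n_multiallelic: int = 0
    n_singletons: int = 0
    ts: int = 0
    tv: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def ts_tv(self) -> float | None:
        return self.ts / self.tv if self.tv else None


def vcf_stats(
    records: Iterable[VariantRecord], header: VcfHeader
) -> VcfStatsReport:
    rep = VcfStatsReport()
    for name in header.samples:
        rep.per_sample[name] = {"nNonRefHom": 0, "nHet": 0, "nMissing": 0}
    for r in records:
        rep.n_records += 1
        if not r.alts:
            continue
        if len(r.alts) > 1:
            rep.n_multiallelic += 1
        is_snp = all(len(a) == 1 for a in r.alts) and len(r.ref) == 1
        if is_snp:
            rep.n_snps += 1
            if len(r.alts) == 1:
                pair = frozenset((r.ref.upper(), r.alts[0].upper()))
                if pair in TRANSITIONS:
                    rep.ts += 1
                elif len(pair) == 2:
                    rep.tv += 1
        else:
            rep.n_indels += 1
        carriers = 0
        for si, name in enumerate(header.samples):
            gt = r.genotype(si)
            stats = rep.per_sample[name]
            if gt is None or gt.is_missing():
                stats["nMissing"] += 1
                continue
            if gt.has_alt():
                carriers += 1
                if gt.is_het():
                    stats["nHet"] += 1
                else:
                    stats["nNonRefHom"] += 1
        if carriers == 1:
            rep.n_singletons += 1
    return rep


# ---------------------------------------------------------------------------
# gtcheck

def gtcheck(
    records_a: Sequence[VariantRecord],
    header_a: VcfHeader,
    records_b: Sequence[VariantRecord],
    header_b: VcfHeader,
    pairs: Sequence[tuple[str, str]],
    use_alleles: bool = True,
) -> list[tuple[str, str, int, int, float]]:
    """Genotype concordance per sample pair at shared sites.

    Returns (sample_a, sample_b, sites compared, discordant, discordance
    rate); genotypes compare as unordered allele multisets.
    """
    index_b = {site_key(r, use_alleles): r for r in records_b}
    out = []
    for sa, sb in pairs:
        ia = header_a.samples.index(sa)
        ib = header_b.samples.index(sb)
        n = disc = 0
        for ra in records_a:
            rb = index_b.get(site_key(ra, use_alleles))
            if rb is None:
                continue
            ga, gb = ra.genotype(ia), rb.genotype(ib)
            if ga is None or gb is None or ga.is_missing() or gb.is_missing():
                continue
            n += 1
            if sorted(a for a in ga.alleles if a is not None) != sorted(
                b for b in gb.alleles if b is not None
            ):
                disc += 1
        out.append((sa, sb, n, disc, disc / n if n else 0.0))
    return out
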