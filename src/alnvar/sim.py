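"""Deterministic synthetic-data generators: reference sequences, individual
haplotypes with planted variants, and sequencing reads with known origin.

Every generator draws from its own pseudo-random stream derived from the
master seed and a fixed per-generator label, so adding a new generator never
perturbs the output of the others, and the same configuration and seed
always reproduce byte-identical output.

The defaults describe the package's reference simulation scenario: a 100 kb
random reference, one diploid sample, SNPs at 1/kb and short indels at
0.1/kb (half heterozygous), 30x coverage of 100 bp paired-end reads with a
uniform 0.1% substitution error rate (Phred 30 base qualities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sam import (
    FMREVERSE,
    FPAIRED,
    FPROPER_PAIR,
    FREAD1,
    FREAD2,
    FREVERSE,
    AlignmentRecord,
    ReadGroup,
    SamHeader,
    reverse_complement,
)
from .vcf import FieldDef, Genotype, VariantRecord, VcfHeader

BASES = "ACGT"

# fixed per-generator stream labels (documented contract: never reuse)
_STREAM_LABELS = {"reference": 11, "individuals": 22, "reads": 33, "panel": 44}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM_LABELS[label]])


@dataclass
class SimulationConfig:
    seed: int = 1
    ref_length: int = 100_000
    gc_fraction: float = 0.5
    n_homopolymers: int = 20  # planted homopolymer tracts (indel/BAQ territory)
    homopolymer_length: int = 12
    read_length: int = 100
    depth: float = 30.0
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.001  # substitution rate; quality strings match it
    snp_density: float = 0.001
    indel_density: float = 0.0001
    het_fraction: float = 0.5
    n_samples: int = 1
    mapq: int = 60

    @property
    def base_quality(self) -> int:
        return int(round(-10.0 * np.log10(max(self.error_rate, 1e-9))))

    @property
    def sample_names(self) -> list[str]:
        return [f"sample{i}" for i in range(self.n_samples)]


@dataclass
class TruthVariant:
    pos: int  # 0-based anchor position
    ref: str
    alt: str
    genotypes: list[tuple[int, int]]  # per sample, allele per haplotype

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class TruthSet:
    config: SimulationConfig
    reference: str
    variants: list[TruthVariant]
    # (sample index, haplotype index) -> (sequence, per-base ref position, -1 for insertions)
    haplotypes: dict[tuple[int, int], tuple[str, np.ndarray]] = field(
        default_factory=dict
    )

    def truth_vcf(self) -> tuple[VcfHeader, list[VariantRecord]]:
        hdr = VcfHeader()
        hdr.contigs["ref1"] = len(self.reference)
        hdr.formats["GT"] = FieldDef("GT", "1", "String", "Genotype")
        hdr.samples = list(self.config.sample_names)
        records = []
        for v in self.variants:
            rec = VariantRecord(
                chrom="ref1",
                pos=v.pos,
                id=".",
                ref=v.ref,
                alts=[v.alt],
                qual=None,
                filters=["PASS"],
                info={},
                format_keys=["GT"],
                samples=[{"GT": Genotype(g)} for g in v.genotypes],
            )
            records.append(rec)
        return hdr, records


def simulate_reference(config: SimulationConfig) -> str:
    """Pseudo-random reference with the configured GC fraction, with planted
    homopolymer tracts that exercise indel normalization and BAQ."""
    rng = _rng(config.seed, "reference")
    gc = config.gc_fraction / 2.0
    at = (1.0 - config.gc_fraction) / 2.0
    seq = rng.choice(list("ACGT"), size=config.ref_length, p=[at, gc, gc, at])
    seq = np.array(seq, dtype="U1")
    for _ in range(config.n_homopolymers):
        start = int(rng.integers(0, max(config.ref_length - config.homopolymer_length, 1)))
        base = BASES[int(rng.integers(4))]
        seq[start : start + config.homopolymer_length] = base
    return "".join(seq)


def simulate_individuals(reference: str, config: SimulationConfig) -> TruthSet:
    """Plant SNPs and short indels and build per-sample haplotype pairs.

    Variant sites are spaced so alleles never overlap; indel records are
    kept only when their anchored representation is already left-aligned and
    minimal, so the truth VCF normalizes to itself by construction.
    """
    rng = _rng(config.seed, "individuals")
    L = len(reference)
    n_snps = rng.poisson(config.snp_density * L)
    n_indels = rng.poisson(config.indel_density * L)
    margin = 12
    candidates = rng.choice(
        np.arange(margin, L - margin), size=min(L // 20, (n_snps + n_indels) * 4),
        replace=False,
    )
    candidates = np.sort(candidates)
    # enforce spacing so variants cannot overlap even with deletions
    chosen: list[int] = []
    last = -100
    for p in candidates:
        if p - last >= 2 * margin:
            chosen.append(int(p))
            last = int(p)
    rng.shuffle(chosen)  # type: ignore[arg-type]
    variants: list[TruthVariant] = []
    n_indels_made = 0
    for p in chosen:
        if len(variants) >= n_snps + n_indels:
            break
        make_indel = n_indels_made < n_indels
        ref_base = reference[p]
        if make_indel:
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                ins = "".join(BASES[int(b)] for b in rng.integers(0, 4, size))
                ref_a, alt_a = ref_base, ref_base + ins
            else:
                ref_a, alt_a = reference[p : p + 1 + size], ref_base
            cand = TruthVariant(p, ref_a, alt_a, [])
            if not _is_minimal(cand, reference):
                continue
            n_indels_made += 1
            v = cand
        else:
            alt = BASES[(BASES.index(ref_base.upper()) + int(rng.integers(1, 4))) % 4] \
                if ref_base.upper() in BASES else "A"
            if alt == ref_base.upper():
                continue
            v = TruthVariant(p, ref_base, alt, [])
        for _ in range(config.n_samples):
            if rng.random() < config.het_fraction:
                g = (0, 1) if rng.random() < 0.5 else (1, 0)
            else:
                g = (1, 1)
            v.genotypes.append(g)
        variants.append(v)
    variants.sort(key=lambda v: v.pos)
    truth = TruthSet(config, reference, variants)
    for si in range(config.n_samples):
        for hi in range(2):
            truth.haplotypes[(si, hi)] = _build_haplotype(reference, variants, si, hi)
    return truth


def _is_minimal(v: TruthVariant, reference: str) -> bool:
    """True when the anchored indel representation is left-aligned minimal."""
    ref, alt = v.ref.upper(), v.alt.upper()
    if ref[0] != alt[0]:
        return True
    # would a shared final base allow trimming? then not minimal
    if len(ref) > 1 and len(alt) > 1:
        return False
    longer = ref if len(ref) > len(alt) else alt
    inserted = longer[1:]
    if not inserted:
        return True
    # fixed point of normalization iff no shared final base invites trimming
    return inserted[-1] != longer[0]


def _build_haplotype(
    reference: str, variants: list[TruthVariant], sample: int, hap: int
) -> tuple[str, np.ndarray]:
    parts: list[str] = []
    maps: list[np.ndarray] = []
    cursor = 0
    for v in variants:
        allele = v.genotypes[sample][hap]
        if allele == 0:
            continue
        parts.append(reference[cursor : v.pos])
        maps.append(np.arange(cursor, v.pos))
        parts.append(v.alt)
        m = np.full(len(v.alt), -1, dtype=np.int64)
        for i in range(min(len(v.alt), len(v.ref))):
            m[i] = v.pos + i
        maps.append(m)
        cursor = v.pos + len(v.ref)
    parts.append(reference[cursor:])
    maps.append(np.arange(cursor, len(reference)))
    seq = "".join(parts)
    hap2ref = np.concatenate(maps) if maps else np.arange(len(reference))
    return seq, hap2ref


def _cigar_from_map(hap2ref: np.ndarray, s: int, length: int) -> tuple[int, list[tuple[str, int]]] | None:
    """Alignment position and CIGAR for the read covering hap[s : s+length]."""
    window = hap2ref[s : s + length]
    if len(window) < length or window[0] < 0 or window[-1] < 0:
        return None
    pos = int(window[0])
    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    prev = int(window[0])
    push("M", 1)
    for i in range(1, length):
        r = int(window[i])
        if r < 0:
            push("I", 1)
        else:
            if r > prev + 1:
                push("D", r - prev - 1)
            push("M", 1)
            prev = r
    return pos, cigar


def simulate_reads(
    truth: TruthSet, config: SimulationConfig | None = None
) -> tuple[SamHeader, list[AlignmentRecord]]:
    """Draw reads uniformly from the haplotypes, inject substitution errors,
    and emit alignment records with correct coordinates, CIGARs (including
    planted indels), flags, and mutually consistent mate fields.

    Records come back in generation order (queryname-grouped); sort by
    coordinate before pileup.
    """
    config = config or truth.config
    rng = _rng(config.seed, "reads")
    header = SamHeader(sort_order="unsorted")
    header.references.append(("ref1", len(truth.reference)))
    header._reindex()
    for name in config.sample_names:
        header.read_groups.append(ReadGroup(name, name))
    records: list[AlignmentRecord] = []
    rl = config.read_length
    bq = config.base_quality
    for si, sample in enumerate(config.sample_names):
        if config.paired:
            n_fragments = int(config.depth * len(truth.reference) / (2 * rl))
        else:
            n_fragments = int(config.depth * len(truth.reference) / rl)
        for fi in range(n_fragments):
            hap = int(rng.integers(2))
            seq, hap2ref = truth.haplotypes[(si, hap)]
            qname = f"sim_{sample}_{fi}"
            if config.paired:
                frag = max(int(rng.normal(config.insert_mean, config.insert_sd)), 2 * rl)
                if frag >= len(seq):
                    continue
                s = int(rng.integers(0, len(seq) - frag + 1))
                r1 = _make_read(seq, hap2ref, s, rl, rng, config, False)
                r2 = _make_read(seq, hap2ref, s + frag - rl, rl, rng, config, True)
                if r1 is None or r2 is None:
                    continue
                (pos1, cig1, sq1, ql1) = r1
                (pos2, cig2, sq2, ql2) = r2
                end1 = pos1 + sum(n for op, n in cig1 if op in "MDN=X")
                end2 = pos2 + sum(n for op, n in cig2 if op in "MDN=X")
                span = max(end1, end2) - min(pos1, pos2)
                tlen1 = span if pos1 <= pos2 else -span
                f1 = FPAIRED | FPROPER_PAIR | FREAD1 | FMREVERSE
                f2 = FPAIRED | FPROPER_PAIR | FREAD2 | FREVERSE
                records.append(
                    AlignmentRecord(qname, f1, 0, pos1, config.mapq, cig1, 0, pos2,
                                    tlen1, sq1, ql1, {"RG": ("Z", sample)})
                )
                # SEQ of a reverse-strand record is stored in reference
                # orientation, which is how the fragment was sampled
                records.append(
                    AlignmentRecord(qname, f2, 0, pos2, config.mapq, cig2, 0, pos1,
                                    -tlen1, sq2, ql2, {"RG": ("Z", sample)})
                )
            else:
                if len(seq) <= rl:
                    continue
                s = int(rng.integers(0, len(seq) - rl + 1))
                r = _make_read(seq, hap2ref, s, rl, rng, config, False)
                if r is None:
                    continue
                pos, cig, sq, ql = r
                records.append(
                    AlignmentRecord(qname, 0, 0, pos, config.mapq, cig, -1, -1, 0,
                                    sq, ql, {"RG": ("Z", sample)})
                )
    return header, records


def _make_read(
    seq: str,
    hap2ref: np.ndarray,
    s: int,
    rl: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    reverse: bool,
):
    # nudge the start so the read does not begin or end inside an insertion
    for shift in range(6):
        for cand in (s - shift, s + shift):
            if 0 <= cand and cand + rl <= len(seq):
                res = _cigar_from_map(hap2ref, cand, rl)
                if res is not None:
                    pos, cigar = res
                    bases = list(seq[cand : cand + rl])
                    quals = [config.base_quality] * rl
                    if config.error_rate > 0:
                        errs = np.nonzero(rng.random(rl) < config.error_rate)[0]
                        for i in errs:
                            cur = bases[i].upper()
                            choices = [b for b in BASES if b != cur]
                            bases[i] = choices[int(rng.integers(3))]
                    return pos, cigar, "".join(bases), quals
    return None


# ---------------------------------------------------------------------------
# genotype-likelihood panels (for frequency estimation and ROH studies)

def simulate_gl_panel(
    f: float,
    n_samples: int,
    depth: float,
    base_quality: int,
    rng: np.random.Generator,
) -> tuple[list[list[int]], list[int]]:
    """Biallelic PL panel: genotypes drawn from HWE(f), reads binomially.

    Returns (per-sample PL triples, true genotypes coded 0/1/2 alt copies).
    """
    eps = 10.0 ** (-base_quality / 10.0)
    pls: list[list[int]] = []
    gts: list[int] = []
    probs = [(1 - f) ** 2, 2 * f * (1 - f), f**2]
    for _ in range(n_samples):
        g = int(rng.choice(3, p=probs))
        n = max(int(rng.poisson(depth)), 0)
        # per-read alt probability given genotype, with symmetric error
        p_alt = {0: eps, 1: 0.5, 2: 1 - eps}[g]
        k = int(rng.binomial(n, p_alt)) if n else 0
        ll = [0.0, 0.0, 0.0]
        for reads_alt, count in ((1, k), (0, n - k)):
            for gi, p in enumerate((eps, 0.5, 1 - eps)):
                p_read = p if reads_alt else (1 - p)
                ll[gi] += count * np.log10(max(p_read, 1e-300))
        m = max(ll)
        pls.append([int(round(-10 * (x - m))) for x in ll])
        gts.append(g)
    return pls, gts
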