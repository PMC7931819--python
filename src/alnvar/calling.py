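"""Genotype likelihoods and the two-step variant callers.

Per-site genotype likelihoods treat each read base as an independent draw:
with per-base error ``ε`` (from the smaller of base quality after BAQ and
mapping quality), a base supports a homozygous allele with probability
``1-ε`` and any other allele with ``ε/3``; heterozygous genotypes average
the two allele emissions.  Likelihoods are reported as Phred-scaled PL
vectors, minimum normalised to zero, in the standard diploid ordering
(genotype (j,k) at index k(k+1)/2+j).

Two callers consume the likelihoods: a biallelic consensus caller with a
fixed prior over {hom-ref, het, hom-alt}, and a multiallelic caller that
estimates allele frequencies from the sample panel by EM and applies a
Hardy-Weinberg genotype prior.  Non-variant sites can be grouped into gVCF
blocks banded by genotype quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .pileup import PileupColumn
from .vcf import (
    FieldDef,
    Genotype,
    VariantRecord,
    VcfHeader,
    genotype_from_index,
    genotype_index,
    n_genotypes,
)

QUAL_CAP = 9999.0
GQ_CAP = 99
DEFAULT_PRIOR_HET = 1e-3
DEFAULT_PRIOR_HOM_ALT = 5e-4
DEFAULT_GAP_QUALITY = 30  # flat per-read confidence in an observed indel
DEFAULT_MAX_ALTS = 3
EM_TOL = 1e-10
EM_MAX_ITER = 50


@dataclass
class SampleLikelihoods:
    log10: list[float]  # per-genotype log10 likelihoods (unnormalised)
    pl: list[int]  # Phred-scaled, min 0
    depth: int


@dataclass
class GenotypeLikelihoods:
    """Per-site likelihoods over an ordered allele list (REF first)."""

    alleles: list[str]
    samples: dict[str, SampleLikelihoods]
    qs: dict[str, float]  # per-allele quality sums, summed over samples
    is_indel: bool = False

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def _pl_from_log10(log10s: Sequence[float]) -> list[int]:
    m = max(log10s)
    return [int(round(-10.0 * (v - m))) for v in log10s]


def _phred(p: float, cap: float = QUAL_CAP) -> float:
    if p <= 0.0:
        return cap
    return min(-10.0 * math.log10(p), cap)


def site_likelihoods(
    column: PileupColumn,
    ref_base: str,
    sample_names: Sequence[str] | None = None,
    max_alts: int = DEFAULT_MAX_ALTS,
    alleles: Sequence[str] | None = None,
) -> GenotypeLikelihoods:
    """Base-substitution genotype likelihoods for one pileup column.

    Candidate alternate alleles are the non-reference bases observed in the
    column, ranked by quality sum (ties alphabetical) and truncated to
    ``max_alts``; an explicit ``alleles`` list (REF first) overrides the
    candidate search, which also allows likelihoods for an unobserved alt.
    Samples without data get flat likelihoods.
    """
    ref_base = ref_base.upper()
    names = list(sample_names) if sample_names is not None else sorted(column.entries)
    qs: dict[str, float] = {ref_base: 0.0}
    obs: dict[str, list[tuple[str, float]]] = {}  # sample -> [(base, q)]
    for sample, entries in column.entries.items():
        rows = []
        for e in entries:
            if e.base is None or e.baseq is None:
                continue
            b = e.base.upper()
            if b not in "ACGT":
                continue
            q = min(e.baseq, e.mapq)
            rows.append((b, float(q)))
            qs[b] = qs.get(b, 0.0) + q
        obs[sample] = rows
    if alleles is None:
        alts = sorted(
            (b for b in qs if b != ref_base and qs[b] > 0),
            key=lambda b: (-qs[b], b),
        )[:max_alts]
        alleles = [ref_base] + alts
    else:
        alleles = list(alleles)
    ng = n_genotypes(len(alleles))
    samples: dict[str, SampleLikelihoods] = {}
    for name in names:
        rows = obs.get(name, [])
        log10s = [0.0] * ng
        for b, q in rows:
            eps = 10.0 ** (-q / 10.0)
            pa = [1.0 - eps if b == a else eps / 3.0 for a in alleles]
            for k in range(len(alleles)):
                for j in range(k + 1):
                    log10s[genotype_index(j, k)] += math.log10(
                        0.5 * (pa[j] + pa[k])
                    )
        samples[name] = SampleLikelihoods(log10s, _pl_from_log10(log10s), len(rows))
    return GenotypeLikelihoods(alleles, samples, qs)


def indel_likelihoods(
    column: PileupColumn,
    sample_names: Sequence[str] | None = None,
    gap_quality: int = DEFAULT_GAP_QUALITY,
    max_alts: int = DEFAULT_MAX_ALTS,
) -> GenotypeLikelihoods | None:
    """Indel genotype likelihoods from the column's indel observations.

    Alleles are symbolic: ``""`` for the reference (no indel), ``+SEQ`` for
    insertions, ``-N`` for deletions, all anchored immediately after this
    column's position.  Each read supports its own observation with
    probability ``1-ε_g`` and every other allele with ``ε_g``, where ``ε_g``
    derives from one flat gap quality.  Returns None when no indel was seen.
    """
    names = list(sample_names) if sample_names is not None else sorted(column.entries)
    eps = 10.0 ** (-gap_quality / 10.0)
    qs: dict[str, float] = {"": 0.0}
    obs: dict[str, list[str]] = {}
    seen_indel = False
    for sample, entries in column.entries.items():
        rows = []
        for e in entries:
            if e.is_deletion:
                continue  # mid-deletion placeholder carries no indel signal
            if e.indel > 0:
                sym = "+" + (e.indel_seq or "N" * e.indel).upper()
                seen_indel = True
            elif e.indel < 0:
                sym = str(e.indel)
                seen_indel = True
            else:
                sym = ""
            rows.append(sym)
            qs[sym] = qs.get(sym, 0.0) + gap_quality
        obs[sample] = rows
    if not seen_indel:
        return None
    alts = sorted(
        (a for a in qs if a != "" and qs[a] > 0), key=lambda a: (-qs[a], a)
    )[:max_alts]
    alleles = [""] + alts
    ng = n_genotypes(len(alleles))
    samples: dict[str, SampleLikelihoods] = {}
    for name in names:
        log10s = [0.0] * ng
        for sym in obs.get(name, []):
            pa = [1.0 - eps if sym == a else eps for a in alleles]
            for k in range(len(alleles)):
                for j in range(k + 1):
                    log10s[genotype_index(j, k)] += math.log10(0.5 * (pa[j] + pa[k]))
        samples[name] = SampleLikelihoods(
            log10s, _pl_from_log10(log10s), len(obs.get(name, []))
        )
    return GenotypeLikelihoods(alleles, samples, qs, is_indel=True)


# ---------------------------------------------------------------------------
# EM allele-frequency estimation

def _hwe_prior(f: Sequence[float]) -> list[float]:
    n = len(f)
    prior = [0.0] * n_genotypes(n)
    for k in range(n):
        for j in range(k + 1):
            prior[genotype_index(j, k)] = (
                f[j] * f[k] if j == k else 2.0 * f[j] * f[k]
            )
    return prior


def hwe_log_likelihood(panel: Sequence[Sequence[float]], f: Sequence[float]) -> float:
    """Panel log-likelihood under Hardy-Weinberg genotype proportions.

    ``panel`` holds linear-scale genotype likelihood vectors per sample.
    """
    prior = _hwe_prior(f)
    total = 0.0
    for gl in panel:
        s = sum(l * p for l, p in zip(gl, prior))
        total += math.log(max(s, 1e-300))
    return total


def estimate_af_em(
    panel: Sequence[Sequence[float]],
    n_alleles: int,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> list[float]:
    """Maximum-likelihood allele frequencies under HWE by EM.

    Each iteration computes per-sample genotype responsibilities under the
    current frequencies and re-estimates frequencies as the expected allele
    dosage over 2N chromosomes.  The panel log-likelihood is checked to be
    non-decreasing (a guaranteed property of the EM update).
    """
    if not panel:
        raise ValueError("need at least one sample with data")
    n = n_alleles
    f = [1.0 / n] * n
    ll_prev = hwe_log_likelihood(panel, f)
    for _ in range(max_iter):
        counts = [0.0] * n
        total = 0.0
        prior = _hwe_prior(f)
        for gl in panel:
            resp = [l * p for l, p in zip(gl, prior)]
            s = sum(resp)
            if s <= 0.0:
                continue
            for idx, r in enumerate(resp):
                j, k = genotype_from_index(idx)
                w = r / s
                counts[j] += w
                counts[k] += w
            total += 2.0
        if total == 0.0:
            break
        new_f = [c / total for c in counts]
        ll = hwe_log_likelihood(panel, new_f)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        delta = max(abs(a - b) for a, b in zip(f, new_f))
        f = new_f
        ll_prev = ll
        if delta < tol:
            break
    s = sum(f)
    return [x / s for x in f]


def _linear_panel(gl: GenotypeLikelihoods) -> list[list[float]]:
    return [
        [10.0 ** (-p / 10.0) for p in s.pl] for s in gl.samples.values()
    ]


# ---------------------------------------------------------------------------
# callers

@dataclass
class SiteCall:
    """One called site, ready to be rendered as a VCF record."""

    alleles: list[str]  # final allele list, REF placeholder first
    qual: float
    is_variant: bool
    af: list[float]  # alt allele frequencies (multiallelic caller)
    gts: dict[str, tuple[int, int]]
    gqs: dict[str, int]
    pls: dict[str, list[int]]
    dps: dict[str, int]
    is_indel: bool = False


def call_consensus(
    gl: GenotypeLikelihoods,
    prior_het: float = DEFAULT_PRIOR_HET,
    prior_hom_alt: float = DEFAULT_PRIOR_HOM_ALT,
) -> SiteCall:
    """Biallelic consensus caller: fixed prior over {RR, RA, AA}.

    Only the highest-quality-sum alternate allele is considered.  Site QUAL
    is the Phred-scaled posterior probability that every sample is
    homozygous reference.
    """
    ref = gl.alleles[0]
    alts = gl.alleles[1:]
    alt = alts[0] if alts else None
    priors = [1.0 - prior_het - prior_hom_alt, prior_het, prior_hom_alt]
    gts: dict[str, tuple[int, int]] = {}
    gqs: dict[str, int] = {}
    pls: dict[str, list[int]] = {}
    dps: dict[str, int] = {}
    log_p_all_rr = 0.0
    genos = [(0, 0), (0, 1), (1, 1)]
    for name, s in gl.samples.items():
        if alt is None:
            lik = [10.0 ** (-s.pl[0] / 10.0), 0.0, 0.0]
            pl3 = [s.pl[0], 255, 255]
        else:
            idxs = [genotype_index(0, 0), genotype_index(0, 1), genotype_index(1, 1)]
            pl3 = [s.pl[i] for i in idxs]
            lik = [10.0 ** (-p / 10.0) for p in pl3]
        post = [l * p for l, p in zip(lik, priors)]
        tot = sum(post) or 1.0
        post = [p / tot for p in post]
        best = max(range(3), key=lambda i: post[i])
        gts[name] = genos[best]
        gqs[name] = min(int(round(_phred(max(1.0 - post[best], 0.0), 990))), GQ_CAP)
        pls[name] = pl3
        dps[name] = s.depth
        log_p_all_rr += math.log10(max(post[0], 1e-300))
    qual = _phred(10.0 ** log_p_all_rr)
    alleles = [ref] + ([alt] if alt is not None else [])
    is_variant = any(g != (0, 0) for g in gts.values()) and alt is not None
    return SiteCall(alleles, qual, is_variant, [], gts, gqs, pls, dps, gl.is_indel)


def call_multiallelic(
    gl: GenotypeLikelihoods,
    allele_frequencies: Sequence[float] | None = None,
    max_alts: int = DEFAULT_MAX_ALTS,
) -> SiteCall:
    """Multiallelic caller with HWE genotype priors.

    Allele frequencies come from :func:`estimate_af_em` unless supplied by
    the caller, in which case they replace the EM estimate entirely.  Alts
    with zero estimated frequency and no supporting genotype are dropped,
    with PL vectors re-indexed to the final allele list.
    """
    alleles = list(gl.alleles[: 1 + max_alts])
    n = len(alleles)
    ng = n_genotypes(n)
    sample_names = list(gl.samples)
    panel = []
    for s in gl.samples.values():
        pl = s.pl[:ng] if len(s.pl) >= ng else s.pl + [0] * (ng - len(s.pl))
        panel.append([10.0 ** (-p / 10.0) for p in pl])
    if allele_frequencies is not None:
        f = list(allele_frequencies)[:n]
        s = sum(f) or 1.0
        f = [x / s for x in f]
    else:
        f = estimate_af_em(panel, n)
    prior = _hwe_prior(f)
    gts: dict[str, tuple[int, int]] = {}
    gqs: dict[str, int] = {}
    pls: dict[str, list[int]] = {}
    dps: dict[str, int] = {}
    log_p_all_rr = 0.0
    for name, lik, s in zip(sample_names, panel, gl.samples.values()):
        post = [l * p for l, p in zip(lik, prior)]
        tot = sum(post) or 1.0
        post = [p / tot for p in post]
        best = max(range(ng), key=lambda i: post[i])
        gts[name] = genotype_from_index(best)
        gqs[name] = min(int(round(_phred(max(1.0 - post[best], 0.0), 990))), GQ_CAP)
        pls[name] = s.pl[:ng]
        dps[name] = s.depth
        log_p_all_rr += math.log10(max(post[0], 1e-300))
    # drop unsupported alts
    used = {a for g in gts.values() for a in g}
    keep = [0] + [
        i for i in range(1, n) if f[i] > 1e-9 or i in used
    ]
    if len(keep) != n:
        remap = {old: new for new, old in enumerate(keep)}
        alleles = [alleles[i] for i in keep]
        nn = len(keep)
        new_pls = {}
        for name in sample_names:
            old_pl = pls[name]
            np_ = [0] * n_genotypes(nn)
            for k in range(nn):
                for j in range(k + 1):
                    np_[genotype_index(j, k)] = old_pl[
                        genotype_index(min(keep[j], keep[k]), max(keep[j], keep[k]))
                    ]
            m = min(np_)
            new_pls[name] = [p - m for p in np_]
            gts[name] = tuple(sorted(remap.get(a, 0) for a in gts[name]))  # type: ignore[assignment]
        pls = new_pls
        f = [f[i] for i in keep]
    qual = _phred(10.0 ** log_p_all_rr)
    is_variant = len(alleles) > 1 and (
        any(g != (0, 0) for g in gts.values()) or any(x > 1e-6 for x in f[1:])
    )
    return SiteCall(alleles, qual, is_variant, f[1:], gts, gqs, pls, dps, gl.is_indel)


# ---------------------------------------------------------------------------
# gVCF blocks

DEFAULT_GQ_BINS = (1, 20, 60)


def _gq_bin(gq: int, bounds: Sequence[int]) -> int:
    b = 0
    for i, bound in enumerate(bounds):
        if gq >= bound:
            b = i + 1
    return b


@dataclass
class GvcfBlock:
    chrom: str
    start: int  # 0-based
    end: int  # 0-based inclusive of last site
    min_dp: int
    gq_bin: int
    pl: list[int]  # most conservative (elementwise max) PL over the block
    n_sites: int


def gvcf_blocks(
    calls: Iterable[tuple[str, int, SiteCall]],
    sample: str,
    bounds: Sequence[int] = DEFAULT_GQ_BINS,
) -> Iterator[GvcfBlock]:
    """Merge consecutive hom-ref sites whose GQ falls in one band.

    ``calls`` supplies (chrom, 0-based pos, SiteCall) in coordinate order; a
    variant site or a band change closes the current block.  Expanding the
    blocks site-by-site reproduces the hom-ref coverage exactly.
    """
    cur: GvcfBlock | None = None
    last: tuple[str, int] | None = None
    for chrom, pos, call in calls:
        if last is not None and (chrom, pos) <= last:
            raise ValueError(f"gVCF input out of order at {chrom}:{pos + 1}")
        last = (chrom, pos)
        hom_ref = call.gts.get(sample) == (0, 0) and not call.is_variant
        if not hom_ref:
            if cur is not None:
                yield cur
                cur = None
            continue
        gq = call.gqs.get(sample, 0)
        dp = call.dps.get(sample, 0)
        pl = call.pls.get(sample, [0, 0, 0])[:3]
        while len(pl) < 3:
            pl = pl + [pl[-1] if pl else 0]
        b = _gq_bin(gq, bounds)
        if (
            cur is not None
            and cur.chrom == chrom
            and cur.gq_bin == b
            and pos == cur.end + 1
        ):
            cur.end = pos
            cur.min_dp = min(cur.min_dp, dp)
            cur.pl = [max(a, c) for a, c in zip(cur.pl, pl)]
            cur.n_sites += 1
        else:
            if cur is not None:
                yield cur
            cur = GvcfBlock(chrom, pos, pos, dp, b, list(pl), 1)
    if cur is not None:
        yield cur


# ---------------------------------------------------------------------------
# pileup -> VCF driver

def make_caller_header(
    sample_names: Sequence[str], contigs: dict[str, int]
) -> VcfHeader:
    hdr = VcfHeader()
    hdr.contigs.update(contigs)
    hdr.infos["DP"] = FieldDef("DP", "1", "Integer", "Raw read depth")
    hdr.infos["AF"] = FieldDef("AF", "A", "Float", "Estimated allele frequency")
    hdr.infos["END"] = FieldDef("END", "1", "Integer", "End of gVCF block")
    hdr.infos["MIN_DP"] = FieldDef("MIN_DP", "1", "Integer", "Minimum depth in block")
    hdr.infos["INDEL"] = FieldDef("INDEL", "0", "Flag", "Site is an indel")
    hdr.formats["GT"] = FieldDef("GT", "1", "String", "Genotype")
    hdr.formats["PL"] = FieldDef("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    hdr.formats["GQ"] = FieldDef("GQ", "1", "Integer", "Genotype quality")
    hdr.formats["DP"] = FieldDef("DP", "1", "Integer", "Read depth")
    hdr.filters["PASS"] = FieldDef("PASS", ".", "String", "All filters passed")
    hdr.samples = list(sample_names)
    return hdr


def _site_to_record(
    chrom: str, pos: int, ref_context: str, call: SiteCall, samples: Sequence[str]
) -> VariantRecord:
    """Render a SiteCall as a VariantRecord; indel alleles are anchored on
    the reference base at ``pos``."""
    if call.is_indel:
        anchor = ref_context[pos]
        max_del = max(
            (-int(a) for a in call.alleles[1:] if a.startswith("-")), default=0
        )
        ref = ref_context[pos : pos + 1 + max_del]
        alts = []
        for a in call.alleles[1:]:
            if a.startswith("+"):
                alts.append(anchor + a[1:] + ref[1:])
            else:
                ndel = -int(a)
                alts.append(anchor + ref_context[pos + 1 + ndel : pos + 1 + max_del])
        alleles = [ref] + alts
    else:
        alleles = call.alleles
    rec = VariantRecord(
        chrom=chrom,
        pos=pos,
        id=".",
        ref=alleles[0],
        alts=alleles[1:],
        qual=round(call.qual, 4),
        filters=["PASS"] if call.is_variant else [],
        info={},
        format_keys=["GT", "PL", "GQ", "DP"],
        samples=[],
    )
    if call.is_indel:
        rec.info["INDEL"] = True
    dp = sum(call.dps.values())
    rec.info["DP"] = dp
    if call.af:
        rec.info["AF"] = [round(x, 6) for x in call.af]
    for name in samples:
        if name in call.gts:
            g = call.gts[name]
            rec.samples.append(
                {
                    "GT": Genotype((g[0], g[1])),
                    "PL": call.pls[name],
                    "GQ": call.gqs[name],
                    "DP": call.dps[name],
                }
            )
        else:
            rec.samples.append({})
    return rec


def call_pileup(
    columns: Iterable[PileupColumn],
    reference: dict[int, str],
    ref_names: Sequence[str],
    sample_names: Sequence[str],
    mode: str = "multiallelic",
    variants_only: bool = True,
    min_qual: float = 20.0,
    allele_frequencies: Sequence[float] | None = None,
    prior_het: float = DEFAULT_PRIOR_HET,
    prior_hom_alt: float = DEFAULT_PRIOR_HOM_ALT,
    max_alts: int = DEFAULT_MAX_ALTS,
) -> Iterator[VariantRecord]:
    """Run a caller over a pileup column stream and yield VCF records.

    In variants-only mode, sites whose QUAL (Phred-scaled posterior that all
    samples are homozygous reference) falls below ``min_qual`` are
    suppressed; the default of 20 is the conventional 1%-error confidence
    cutoff.  Set ``variants_only=False`` to emit every site.
    """
    for col in columns:
        ref_seq = reference[col.rid]
        chrom = ref_names[col.rid]
        ref_base = ref_seq[col.pos].upper()
        if ref_base not in "ACGT":
            continue
        gl = site_likelihoods(col, ref_base, sample_names, max_alts=max_alts)
        calls = []
        if mode == "consensus":
            calls.append(call_consensus(gl, prior_het, prior_hom_alt))
        else:
            calls.append(call_multiallelic(gl, allele_frequencies, max_alts))
        igl = indel_likelihoods(col, sample_names, max_alts=max_alts)
        if igl is not None:
            if mode == "consensus":
                calls.append(call_consensus(igl, prior_het, prior_hom_alt))
            else:
                calls.append(call_multiallelic(igl, allele_frequencies, max_alts))
        for call in calls:
            if variants_only and (not call.is_variant or call.qual < min_qual):
                continue
            yield _site_to_record(chrom, col.pos, ref_seq, call, sample_names)
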