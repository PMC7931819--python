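"""Runs-of-homozygosity detection with a two-state hidden Markov model.

The two states are HW (genotypes follow Hardy-Weinberg proportions at the
population allele frequency) and AZ (autozygous: the two haplotypes
coalesce, so the genotype is homozygous with probability equal to the
allele's frequency).  Transition probabilities decay with physical distance
``d`` between consecutive informative sites as ``1 - exp(-rate * d)``, so
sparse regions are harder to switch in.  Both the Viterbi path and the
posterior state probabilities are computed in log/scaled space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .vcf import Genotype, VariantRecord, VcfHeader

DEFAULT_HW_TO_AZ = 6.7e-8  # per bp
DEFAULT_AZ_TO_HW = 5e-9  # per bp
DEFAULT_AF = 0.4


@dataclass
class RohParams:
    rate_hw_to_az: float = DEFAULT_HW_TO_AZ
    rate_az_to_hw: float = DEFAULT_AZ_TO_HW
    use_pl: bool = True  # False: hard GT calls
    default_af: float = DEFAULT_AF

    def __post_init__(self):
        if self.rate_hw_to_az <= 0 or self.rate_az_to_hw <= 0:
            raise ValueError("transition rates must be positive")

    def trans_probs(self, d: int) -> tuple[float, float]:
        """(P(HW->AZ), P(AZ->HW)) over a gap of d base pairs."""
        d = max(d, 1)
        return (
            1.0 - math.exp(-self.rate_hw_to_az * d),
            1.0 - math.exp(-self.rate_az_to_hw * d),
        )


@dataclass
class RohSite:
    pos: int  # 0-based
    emit_az: float
    emit_hw: float


@dataclass
class RohSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_sites: int
    mean_posterior: float
    quality: float  # Phred-scaled mean AZ posterior confidence


def roh_emissions(
    gt_likelihoods: Sequence[float], f: float
) -> tuple[float, float]:
    """Emission probabilities (P(data|AZ), P(data|HW)) for one site.

    ``gt_likelihoods`` holds linear-scale likelihoods for (hom-ref, het,
    hom-alt); ``f`` is the alternate allele frequency.  Under HW the
    genotype prior is ((1-f)^2, 2f(1-f), f^2); under autozygosity the
    haplotypes coalesce and the prior collapses to ((1-f), 0, f).
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"allele frequency {f} outside (0, 1)")
    lrr, lra, laa = gt_likelihoods[:3]
    p_hw = (1 - f) ** 2 * lrr + 2 * f * (1 - f) * lra + f**2 * laa
    p_az = (1 - f) * lrr + f * laa
    return p_az, p_hw


def _site_likelihoods_from_record(
    r: VariantRecord, sample_idx: int, params: RohParams
) -> list[float] | None:
    sample = r.samples[sample_idx] if sample_idx < len(r.samples) else {}
    if params.use_pl and "PL" in sample:
        pl = sample["PL"]
        if isinstance(pl, list) and len(pl) >= 3 and all(p is not None for p in pl[:3]):
            return [10.0 ** (-float(p) / 10.0) for p in pl[:3]]
    gt = r.genotype(sample_idx)
    if gt is None or gt.is_missing() or len([a for a in gt.alleles if a is not None]) < 2:
        return None
    a, b = sorted(a for a in gt.alleles if a is not None)[:2]
    lik = [0.0, 0.0, 0.0]
    if a == 0 and b == 0:
        lik[0] = 1.0
    elif a != b:
        lik[1] = 1.0
    else:
        lik[2] = 1.0
    return lik


def sites_from_vcf(
    records: Sequence[VariantRecord],
    header: VcfHeader,
    sample: str,
    params: RohParams | None = None,
    af_tag: str = "AF",
) -> tuple[list[RohSite], int]:
    """Extract informative biallelic SNP sites for one sample.

    Allele frequency precedence: INFO tag, then panel genotypes, then the
    configured default.  Returns (sites, number skipped)."""
    params = params or RohParams()
    sample_idx = header.samples.index(sample)
    sites: list[RohSite] = []
    skipped = 0
    for r in records:
        if len(r.alts) != 1 or len(r.ref) != 1 or len(r.alts[0]) != 1:
            skipped += 1
            continue
        f = _allele_frequency(r, af_tag, params.default_af)
        if not 0.0 < f < 1.0:
            skipped += 1
            continue
        lik = _site_likelihoods_from_record(r, sample_idx, params)
        if lik is None:
            skipped += 1
            continue
        az, hw = roh_emissions(lik, f)
        sites.append(RohSite(r.pos, az, hw))
    return sites, skipped


def _allele_frequency(r: VariantRecord, af_tag: str, default: float) -> float:
    v = r.info.get(af_tag)
    if isinstance(v, list):
        v = v[0]
    if v is not None:
        try:
            return float(v)
        except (TypeError, ValueError):
            pass
    # compute from panel genotypes when possible
    n = alt = 0
    for s in r.samples:
        gt = s.get("GT")
        if isinstance(gt, Genotype) and not gt.is_missing():
            for a in gt.alleles:
                if a is not None:
                    n += 1
                    alt += int(a > 0)
    if n >= 4:  # at least two diploid genotypes
        f = alt / n
        return f
    return default


def _check_sorted(sites: Sequence[RohSite]) -> None:
    for i in range(1, len(sites)):
        if sites[i].pos < sites[i - 1].pos:
            raise ValueError(
                f"sites not sorted: position {sites[i].pos + 1} after "
                f"{sites[i - 1].pos + 1}"
            )


def roh_viterbi(sites: Sequence[RohSite], params: RohParams | None = None) -> list[int]:
    """Most probable state path (1 = AZ, 0 = HW) by Viterbi in log space.

    The stationary distribution of the two rates provides the initial state
    probabilities.
    """
    params = params or RohParams()
    _check_sorted(sites)
    n = len(sites)
    if n == 0:
        return []
    pi_az = params.rate_hw_to_az / (params.rate_hw_to_az + params.rate_az_to_hw)
    LOG0 = -1e300

    def lg(x: float) -> float:
        return math.log(x) if x > 0 else LOG0

    v_hw = lg(1 - pi_az) + lg(sites[0].emit_hw)
    v_az = lg(pi_az) + lg(sites[0].emit_az)
    back: list[tuple[int, int]] = [(0, 1)]
    prev_pos = sites[0].pos
    for i in range(1, n):
        d = sites[i].pos - prev_pos
        prev_pos = sites[i].pos
        p_ha, p_ah = params.trans_probs(d)
        cands_hw = (v_hw + lg(1 - p_ha), v_az + lg(p_ah))
        cands_az = (v_hw + lg(p_ha), v_az + lg(1 - p_ah))
        b_hw = 0 if cands_hw[0] >= cands_hw[1] else 1
        b_az = 0 if cands_az[0] >= cands_az[1] else 1
        new_hw = cands_hw[b_hw] + lg(sites[i].emit_hw)
        new_az = cands_az[b_az] + lg(sites[i].emit_az)
        back.append((b_hw, b_az))
        v_hw, v_az = new_hw, new_az
    path = [0] * n
    path[-1] = 0 if v_hw >= v_az else 1
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i][path[i]]
    return path


def roh_posterior(
    sites: Sequence[RohSite], params: RohParams | None = None
) -> tuple[list[float], float, float]:
    """Per-site P(AZ | data) by scaled forward-backward.

    Returns (posteriors, forward log-likelihood, backward log-likelihood);
    the two log-likelihoods agree to numerical precision, a built-in
    consistency check.
    """
    params = params or RohParams()
    _check_sorted(sites)
    n = len(sites)
    if n == 0:
        return [], 0.0, 0.0
    pi_az = params.rate_hw_to_az / (params.rate_hw_to_az + params.rate_az_to_hw)
    f_hw = [0.0] * n
    f_az = [0.0] * n
    scale = [0.0] * n
    f_hw[0] = (1 - pi_az) * sites[0].emit_hw
    f_az[0] = pi_az * sites[0].emit_az
    s = f_hw[0] + f_az[0]
    scale[0] = s
    f_hw[0] /= s
    f_az[0] /= s
    trans = []
    for i in range(1, n):
        d = sites[i].pos - sites[i - 1].pos
        p_ha, p_ah = params.trans_probs(d)
        trans.append((p_ha, p_ah))
        f_hw[i] = (f_hw[i - 1] * (1 - p_ha) + f_az[i - 1] * p_ah) * sites[i].emit_hw
        f_az[i] = (f_hw[i - 1] * p_ha + f_az[i - 1] * (1 - p_ah)) * sites[i].emit_az
        s = f_hw[i] + f_az[i]
        if s <= 0:
            s = 1e-300
        scale[i] = s
        f_hw[i] /= s
        f_az[i] /= s
    log_fwd = sum(math.log(s) for s in scale)
    b_hw = [0.0] * n
    b_az = [0.0] * n
    b_hw[-1] = b_az[-1] = 1.0
    bscale = [1.0] * n
    for i in range(n - 2, -1, -1):
        p_ha, p_ah = trans[i]
        eh, ea = sites[i + 1].emit_hw, sites[i + 1].emit_az
        b_hw[i] = (1 - p_ha) * eh * b_hw[i + 1] + p_ha * ea * b_az[i + 1]
        b_az[i] = p_ah * eh * b_hw[i + 1] + (1 - p_ah) * ea * b_az[i + 1]
        s = b_hw[i] + b_az[i]
        if s <= 0:
            s = 1e-300
        bscale[i] = s
        b_hw[i] /= s
        b_az[i] /= s
    log_bwd = (
        math.log(
            (1 - pi_az) * sites[0].emit_hw * b_hw[0]
            + pi_az * sites[0].emit_az * b_az[0]
        )
        + sum(math.log(s) for s in bscale[:-1])
    )
    # posterior via scaled products: the scale factors cancel in the ratio
    post = [0.0] * n
    for i in range(n):
        num_az = f_az[i] * b_az[i]
        num_hw = f_hw[i] * b_hw[i]
        # scaled f and b share the same normalisation at each i
        tot = num_az + num_hw
        post[i] = num_az / tot if tot > 0 else 0.0
    return post, log_fwd, log_bwd


def viterbi_segments(
    sites: Sequence[RohSite],
    path: Sequence[int],
    posteriors: Sequence[float],
    chrom: str,
) -> list[RohSegment]:
    """Maximal AZ runs of the Viterbi path as reportable segments."""
    segs: list[RohSegment] = []
    i = 0
    n = len(sites)
    while i < n:
        if path[i] == 1:
            j = i
            while j + 1 < n and path[j + 1] == 1:
                j += 1
            ps = [posteriors[k] for k in range(i, j + 1)]
            mean_p = sum(ps) / len(ps)
            qual = -10.0 * math.log10(max(1.0 - mean_p, 1e-10))
            segs.append(
                RohSegment(
                    chrom,
                    sites[i].pos + 1,
                    sites[j].pos + 1,
                    j - i + 1,
                    mean_p,
                    min(qual, 99.0),
                )
            )
            i = j + 1
        else:
            i += 1
    return segs


def detect_roh(
    records: Sequence[VariantRecord],
    header: VcfHeader,
    sample: str,
    params: RohParams | None = None,
    af_tag: str = "AF",
) -> tuple[list[RohSegment], list[float], int]:
    """End-to-end: VCF records -> AZ segments for one sample.

    Returns (segments, per-site AZ posteriors, skipped site count); segments
    come from the Viterbi path, confidences from the posterior decoding.
    """
    params = params or RohParams()
    skipped_total = 0
    last = None
    groups: list[tuple[str, list[VariantRecord]]] = []
    for r in records:
        if last is None or r.chrom != last:
            groups.append((r.chrom, []))
            last = r.chrom
        groups[-1][1].append(r)
    segments: list[RohSegment] = []
    all_post: list[float] = []
    for chrom, recs in groups:
        sites, skipped = sites_from_vcf(recs, header, sample, params, af_tag)
        skipped_total += skipped
        if not sites:
            continue
        path = roh_viterbi(sites, params)
        post, _, _ = roh_posterior(sites, params)
        all_post.extend(post)
        segments.extend(viterbi_segments(sites, path, post, chrom))
    return segments, all_post, skipped_total
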