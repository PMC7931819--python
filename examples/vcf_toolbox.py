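"""VCF manipulation: normalization, merging, filtering, stats, consensus.

Builds two tiny single-sample call sets by hand, left-aligns a redundant
indel representation, merges the files, filters with a boolean expression,
and applies the variants back to the reference.
"""

from alnvar import vcftools
from alnvar.vcf import FieldDef, Genotype, VariantRecord, VcfHeader

reference = "GGGCACACACAGGGTTACGGATTACA"


def header(sample):
    h = VcfHeader()
    h.contigs["chr1"] = len(reference)
    h.infos["DP"] = FieldDef("DP", "1", "Integer")
    h.formats["GT"] = FieldDef("GT", "1", "String")
    h.samples = [sample]
    return h


# a redundant indel representation: CACA/CA at 1-based position 8
messy = VariantRecord("chr1", 7, ".", "CACA", ["CA"], 60.0, ["PASS"],
                      {"DP": 18}, ["GT"], [{"GT": Genotype((0, 1))}])
tidy = vcftools.normalize(messy, reference)
print(f"normalize: {messy.pos + 1}:{messy.ref}>{messy.alts[0]}  ->  "
      f"{tidy.pos + 1}:{tidy.ref}>{tidy.alts[0]}")
# the two-base deletion left-aligns to the start of the CA repeat.

snp = VariantRecord("chr1", 16, ".", "A", ["G"], 90.0, ["PASS"], {"DP": 30},
                    ["GT"], [{"GT": Genotype((1, 1))}])
low = VariantRecord("chr1", 20, ".", "G", ["T"], 9.0, ["PASS"], {"DP": 4},
                    ["GT"], [{"GT": Genotype((0, 1))}])

merged_header, merged = vcftools.merge_variant_files(
    [(header("alice"), [tidy, snp]), (header("bob"), [snp.copy(), low])]
)
print(f"merge: {len(merged)} sites across samples {merged_header.samples}")

kept = [r for r in merged if vcftools.eval_filter(r, "QUAL>30 && INFO/DP>10")]
print(f"filter 'QUAL>30 && INFO/DP>10': kept {len(kept)} of {len(merged)}")

stats = vcftools.vcf_stats(merged, merged_header)
print(f"stats: {stats.n_snps} SNPs, {stats.n_indels} indels, "
      f"ts/tv={'NA' if stats.ts_tv is None else f'{stats.ts_tv:.1f}'}")

consensus = vcftools.consensus_apply(reference, [tidy, snp], haplotype=2)
print(f"consensus (hap 2): {consensus}")
# the deletion and the hom-alt SNP are spliced into the reference.
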