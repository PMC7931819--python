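"""End-to-end variant calling on simulated data.

Simulates a 100 kb reference, one diploid individual with planted SNPs and
indels, and 30x paired-end Q30 reads; then runs pileup -> genotype
likelihoods -> the multiallelic EM/Hardy-Weinberg caller, and scores the
calls against the planted truth.
"""

from alnvar import align, calling, pileup, sim

cfg = sim.SimulationConfig(seed=1)  # 100 kb, 1 sample, 30x, Q30
reference = sim.simulate_reference(cfg)
truth = sim.simulate_individuals(reference, cfg)
header, reads = sim.simulate_reads(truth, cfg)
reads = align.sort_records(reads, "coordinate", header)

columns = pileup.pileup(reads, header=header, reference={0: reference})
calls = list(
    calling.call_pileup(columns, {0: reference}, ["ref1"], cfg.sample_names)
)

truth_snps = {(v.pos, v.ref, v.alt) for v in truth.variants if v.is_snp}
called = {(r.pos, r.ref, a) for r in calls for a in r.alts}
truth_pos = {v.pos for v in truth.variants}
false_sites = sum(1 for r in calls if r.pos not in truth_pos)

print(f"planted variants : {len(truth.variants)} "
      f"({len(truth_snps)} SNPs)")
print(f"called sites     : {len(calls)}")
print(f"SNP recall       : {len(truth_snps & called) / len(truth_snps):.4f}")
print(f"false-site rate  : {false_sites / len(calls):.4f}")
# recall = fraction of planted SNPs recovered with the right allele;
# false-site rate = fraction of calls at positions with no planted variant.
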