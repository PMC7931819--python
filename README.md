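# alnvar

A compact, tested Python toolkit for the classic short-read analysis chain:
SAM alignment processing, BGZF compression with random-access indexing,
pileup construction with per-base alignment quality (BAQ), genotype-likelihood
variant calling under Hardy-Weinberg priors, VCF manipulation (normalize,
merge, concat, isec, annotate, consensus, query, filter, stats, gtcheck), and
a hidden Markov model for runs of homozygosity.

It is aimed at people who want the semantics of the standard alignment/variant
toolchain in importable, inspectable Python: method developers prototyping
against well-defined reference behaviour, teachers walking through how a
variant caller actually works, and pipeline authors who need deterministic,
dependency-light fixtures. Everything is driven from Python; two thin command
line wrappers (`alntool` for the alignment side, `vartool` for the variant
side) cover shell use.

## The models at the core

**Genotype likelihoods.** For a diploid sample at one site, each read base
*b* with error probability ε = 10^(−q/10) (q = min(base quality after BAQ,
mapping quality)) contributes

    P(b | a,a)  = 1−ε          if b = a, else ε/3
    P(b | a1,a2) = ½ P(b|a1) + ½ P(b|a2)

and the per-genotype log-likelihoods are sums over reads, reported as
Phred-scaled PLs (min-normalised to 0) in the standard ordering that places
genotype (j,k), j ≤ k, at index k(k+1)/2 + j.

**Two callers.** The biallelic consensus caller applies a fixed prior over
{hom-ref, het, hom-alt} (defaults 1−1.5·10⁻³, 10⁻³, 5·10⁻⁴). The
multiallelic caller estimates allele frequencies **f** from the sample panel
by EM and uses the Hardy-Weinberg genotype prior P(j,k) = 2^{[j≠k]} f_j f_k;
site QUAL is the Phred-scaled posterior probability that every sample is
hom-ref, and gVCF output merges hom-ref runs banded by genotype quality.

**BAQ.** Each read is re-aligned to its local reference window with a banded
three-state (match/insert/delete) profile HMM (gap open 0.001, extension 0.1,
band 7); every base quality is capped at the Phred-scaled posterior
probability that the base sits at its original alignment column, so bases in
ambiguous context (e.g. homopolymer indels) lose weight in calling.

**ROH.** A two-state HMM over per-site genotype evidence: under HW the
genotype prior is ((1−f)², 2f(1−f), f²); under autozygosity (AZ) it collapses
to ((1−f), 0, f). Transitions decay with physical distance d as
1 − exp(−rate·d) (defaults 6.7·10⁻⁸/bp into AZ, 5·10⁻⁹/bp out). Segments come
from the Viterbi path; confidences from posterior decoding.

## Worked example

`examples/simulate_and_call.py` simulates a 100 kb reference, one diploid
individual (SNPs at 1/kb, indels at 0.1/kb, half heterozygous), 30x paired
Q30 reads, and runs pileup → likelihoods → the multiallelic caller:

```
$ python examples/simulate_and_call.py
planted variants : 101 (93 SNPs)
called sites     : 101
SNP recall       : 1.0000
false-site rate  : 0.0000
```

Recall is the fraction of planted SNPs recovered with the correct allele;
the false-site rate is the fraction of emitted sites at positions with no
planted variant. The other scripts in `examples/` demonstrate BGZF indexing
and region queries, the VCF toolbox (the printed normalization
`8:CACA>CA → 3:GCA>G` is the left-alignment of a deletion in a CA repeat),
the ROH scan (one segment covering the planted 200-site run), and BAQ
quality capping inside a homopolymer.

Command-line equivalents:

```
alntool simulate reads --seed 1 --length 100000 -o reads.sam
alntool mpileup reads.sam -f ref.fa | head
vartool call reads.sam ref.fa -o calls.vcf
vartool roh calls.vcf -s sample0
```

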