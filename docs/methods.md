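# Methods

This note records the models the package implements, the defaults it ships,
what the synthetic-data generators do and do not emulate, and the numerical
and design choices made where the design was genuinely open.

## Coordinates, formats, and compression

Internally every coordinate is 0-based half-open; conversion to the 1-based
inclusive conventions of SAM/VCF text, `.fai` regions, and `name:start-end`
strings happens only at the text boundary. Reference lengths and positions
are plain Python integers, so >2 Gb chromosomes need no special casing.

Alignment records travel as SAM text (v1.6 subset), variant records as VCF
text; when compression is requested either goes through the BGZF layer
(gzip members carrying the `BC` extra subfield, terminated by the fixed
28-byte EOF sentinel; the sentinel constant is byte-identical to what
existing BGZF writers emit). Binary BAM/BCF encodings and CRAM are out of
scope; pipeline stages exchange in-memory objects instead of a binary
stream. Truncated BGZF input (missing sentinel) yields the recoverable
payload plus a warning rather than a hard error, so partial files remain
inspectable.

Random access uses a linear index only: per reference, one virtual offset
per 16 kb window (the tabix/BAI window size), the offset of the first record
in file order overlapping that window or any later one. Queries seek there
and overlap-filter forward. This is exactly equivalent in results to
hierarchical binning, with worse worst-case speed on pathological long-read
layouts — acceptable at the scales this package targets. The index
serialises to a documented flat format (magic `SVLI1`, little-endian window
arrays); it is self-consistent but deliberately not BAI/CSI/TBI-compatible.
The compression level defaults to 6 (zlib's usual speed/size compromise),
configurable 0-9.

## Alignment toolbox conventions

- `depth` defaults: min MAPQ 0, min baseQ 0, excluded flags
  unmapped|secondary|qcfail|duplicate. Deletions and reference skips do not
  count toward depth.
- Queryname "natural" order: case-sensitive, digit runs compare numerically,
  shorter string wins prefix ties; read1 sorts before read2.
- `fixmate` sets TLEN = rightmost end − leftmost start, positive on the
  leftmost mate; 0 when mates map to different references or one is
  unmapped (the text format leaves these edges loose; 0 is the least
  surprising sentinel).
- `markdup` keys single reads by (reference, 5′-unclipped position,
  orientation) and pairs by the canonical sorted pair of mate coordinates,
  using the mate's stored position (a documented precondition: run `fixmate`
  first). The highest base-quality-sum read or pair survives per key; ties
  break toward the earlier record for determinism. Optical-duplicate
  sub-classification is not implemented.
- `calmd` compares case-insensitively and writes MD runs per the optional
  field standard; lowercase bases are otherwise preserved end to end.

## Pileup and BAQ

The pileup walks coordinate-sorted records once, buffering only columns that
can still receive entries. Insertions attach to the preceding column's
`indel` field (+length and sequence); deletions contribute placeholder
entries at each deleted position and −length on the anchor. Per sample the
column is capped at 250 entries, truncated deterministically in input order
— no randomness, so identical inputs give identical columns. Sample
identity comes from the read group's SM field, falling back to a
configurable default. When both mates of a pair cover a position the
lower-quality base's quality is zeroed so a fragment is counted once
(toggleable).

BAQ runs a banded glocal profile HMM of the read against its reference
window: states match/insert with deletions folded into column jumps
(M_k → M_{k'} costs d·e^{k'−k−2}·(1−e) for k' > k+1), gap open d = 0.001,
gap extension e = 0.1, band 7 — the published defaults of the method the
field uses. Match emission is 1−ε for agreement, ε/3 for mismatch, 0.25
against N; insertions emit 0.25. The band is centred on each base's original
alignment column (so planted indels keep a sensible diagonal) and clamped at
window edges for reads near contig ends. Scaled forward/backward recursions
give per-base posteriors; the quality cap is −10·log10(1−P(base at its
original column)) and the adjusted quality is min(original, cap) — BAQ can
only lower a quality. Forward and backward total likelihoods are computed
independently and agree to <10⁻⁶ relative, a standing numerical check.
BAQ is opt-in at the library level (`pileup(..., baq=True)` with a
reference); the `mpileup` CLI enables it whenever a reference is given,
mirroring common tooling, with `-B` to disable.

## Genotype likelihoods and the callers

Base error ε = 10^(−q/10) with q = min(baseQ after BAQ, MAPQ). Homozygous
emission 1−ε (match) or ε/3 (mismatch); heterozygous emission is the mean of
the two allele emissions. PLs are min-normalised rounded Phred values in the
k(k+1)/2+j ordering; QS (per-allele quality sums) rank candidate alleles,
ties alphabetical, at most 3 alternates by default.

Indel evidence is deliberately simple: distinct indel observations in a
column become symbolic alleles; each read supports its own observation with
1−ε_g and any other allele with ε_g, where ε_g derives from one flat gap
quality (default Q30). There is no per-read indel realignment; the
simplification keeps the allele-as-symbol architecture testable. Indel sites
are emitted as separate VCF records anchored on the reference base before
the event.

The consensus caller's priors default to P(het) = 10⁻³ and
P(hom-alt) = 5·10⁻⁴ (configurable). The multiallelic caller estimates allele
frequencies by EM (responsibilities ∝ GL·HWE prior; update = expected
dosage / 2N; tolerance 10⁻¹⁰ on max |Δf|, at most 50 iterations; the HWE
log-likelihood is asserted non-decreasing every step). User-supplied
frequencies replace the EM estimate entirely rather than acting as a prior —
the simplest interpretation of "user-customizable" and the documented one.
Site QUAL is the Phred-scaled posterior that all samples are hom-ref, capped
at 9999; GQ capped at 99. In variants-only mode sites with QUAL < 20 are
suppressed (Phred 20 = 1% error, the conventional confidence cutoff);
`variants_only=False` emits everything. Alternates with zero estimated
frequency and no supporting genotype are dropped, with PL vectors re-indexed
through the genotype-index bijection.

gVCF blocks merge consecutive hom-ref sites of one sample whose GQ falls in
one band (default bounds 1, 20, 60), carrying END, MIN_DP, and the
elementwise-maximum PL over the block (the least confident representative).
Ploidy is fixed at 2 throughout; a haploid override is not implemented.

## VCF toolbox

Parsing is lenient by default (undeclared fields are auto-declared with a
warning, positions beyond the declared contig length warn) because
real-world files are messy; strict mode turns both into errors and enforces
Number arities. Symbolic/breakend alleles are carried opaquely; only
`normalize` and `consensus_apply` refuse them.

Normalization repeats two steps to a fixed point: strip a shared final base
(prepending the previous reference base first whenever stripping would empty
an allele), then strip shared leading bases while every allele keeps one.
The result is the left-aligned minimal representation; an apply-to-reference
oracle (splicing either representation into the reference must give the same
haplotype) backs the fuzz tests.

`split_multiallelic` slices Number=A/R/G fields per alternate (G through the
genotype-index bijection) and recodes genotypes referencing other alternates
as reference. `join_multiallelic` inverts the split where the information
exists; the cross-alternate entries of a G field were never present in any
biallelic slice, so they are filled with the field's maximum value (the
least confident choice). This is the one place the split/join round trip is
lossy, and it is inherent to the quadratic-to-linear projection.

Merging files with different samples unifies sites at identical (chrom, pos)
whose REFs are prefix-compatible (the shorter REF's alternates gain the
extension suffix), unions allele lists, remaps genotype-indexed fields, and
fills absent samples with missing. QUAL resolves to the maximum, FILTER to
PASS only if all inputs pass; INFO fields declared Number=1 Integer are
summed (DP-like semantics) and all others dropped with a warning, since no
general cross-file semantics exists. Site identity for isec/merge/gtcheck
compares alleles by default (inputs are assumed normalized); a flag switches
to position-only matching.

The filter language covers comparisons (=, !=, <, <=, >, >=), string
matches, flag presence, &&, ||, !, and parentheses over QUAL, FILTER,
CHROM/POS/ID/REF/ALT, INFO/x and FORMAT/x. Missing values make a comparison
false, never an error; FORMAT fields quantify over samples as "any sample
matches". Arithmetic between fields and function calls are excluded in this
version; the grammar is small enough to extend.

Consensus application is strict about overlapping edits (error naming both
sites) rather than last-wins — silent overwrites hide upstream data errors.
Haplotype 1/2 selects the respective genotype allele; IUPAC mode encodes
heterozygous SNPs as ambiguity codes; GT-less records apply the first
alternate; missing genotypes keep the reference (configurable).

## ROH HMM

Emissions per informative biallelic site, from PLs when present or hard
genotypes otherwise: P(data|HW) = Σ_g HWE(g|f)·L(g),
P(data|AZ) = (1−f)·L(RR) + f·L(AA). Allele-frequency precedence: INFO tag,
then panel genotypes (≥2 diploid calls), then a configured default of 0.4
with a warning. Monomorphic and missing-genotype sites are skipped; skipped
distance still feeds the transition decay. Default rates (6.7·10⁻⁸/bp into
AZ, 5·10⁻⁹/bp out) put the stationary AZ fraction near 1.3% with megabase-
scale expected segment lengths, a reasonable prior for outbred populations;
both are flags. Viterbi (log space) defines segment boundaries; scaled
forward-backward posteriors provide per-site P(AZ) and segment confidence,
and both are reported side by side since either convention is defensible.
Viterbi boundaries can extend a few sites into a run of homozygous flanking
genotypes — each hom site multiplies the AZ odds by 1/(1−f) — so planted
200-site segments are recovered with boundary error typically ≤5 sites, not
exactly 0. Genetic-map (cM) transitions and multi-sample joint HMMs are out
of scope.

## Synthetic data

The generators define the package's reference study conditions: a 100 kb
uniform-composition reference (GC 0.5) with 20 planted 12 bp homopolymer
tracts; one diploid sample; SNPs at 10⁻³/bp and 1-5 bp indels at 10⁻⁴/bp,
half heterozygous; 30x coverage of 100 bp paired-end reads (insert
300 ± 30 bp) with uniform 10⁻³ substitution errors and matching Q30 base
qualities; MAPQ 60. Each generator draws from its own stream derived from
the master seed and a fixed label, so outputs are byte-stable and adding a
generator never perturbs the others. Variant sites are spaced ≥24 bp so
alleles cannot overlap, and indels are planted only where their anchored
representation is already left-aligned and minimal — hence the truth VCF
normalizes to itself, and applying it to the reference reproduces each
haplotype exactly (both are tested invariants). Read CIGARs are derived from
an explicit haplotype-to-reference coordinate map, so planted indels appear
as I/D operations at their true positions, and mate fields are emitted
already consistent (`fixmate` is a no-op on simulator output).

What the simulation does **not** emulate: mapping error and mismapped or
soft-clipped reads (MAPQ is uniform), context-dependent and indel
sequencing errors, base-quality miscalibration, coverage bias, structural
variants, and contamination. Passing the end-to-end tests therefore shows
the chain is correct under its own model — clean alignments with calibrated
qualities — not that it matches production callers on real data, where BAQ,
duplicate marking, and filtering carry much more weight.

Acceptance-scale runs use that default scenario (the end-to-end study runs
the full 100 kb at 30x; fuzzing studies use 10⁴ cases; the ROH study 20
replicates of 800 sites), sized so the whole suite and the acceptance script
each finish in minutes on one CPU.

## Known limitations

- No BAM/BCF/CRAM binary encodings; BGZF-compressed text stands in. The
  linear index does not interoperate with tabix/BAI consumers.
- The indel model has no local realignment; complex alleles are not
  atomized, and the localized-allele PL extension is not implemented.
- Diploid-only calling (the PL ordering contract supports higher ploidies,
  but the callers assume 2n).
- `markdup` uses mate start positions, not mate unclipped 5′ ends, for the
  pair key (exact only after fixmate, and differing from read-level
  unclipped coordinates when the mate is clipped).
- Multi-file pileup is limited to streams sharing one reference list.
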