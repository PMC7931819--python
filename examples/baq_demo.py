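"""Per-base alignment quality (BAQ) around a homopolymer indel.

A read carrying a one-base deletion inside a 12-base homopolymer aligns
equally well with the deletion at any position in the run.  The banded
match/insert/delete HMM detects this: posterior alignment certainty drops
inside the run, and base qualities are capped accordingly.  Outside the run
the alignment is unambiguous and qualities are untouched.
"""

from alnvar import pileup, sam

header = sam.SamHeader(references=[("chr1", 1000)])
reference = "ACGTGCTA" + "A" * 12 + "CTGATCGT" + "GCGC" * 4

# read with one A of the homopolymer deleted, base qualities Q30 throughout
read_seq = reference[2:8] + "A" * 11 + reference[20:30]
record = sam.parse_sam_record(
    "read1\t0\tchr1\t3\t60\t6M1D21M\t*\t0\t0\t"
    f"{read_seq}\t{chr(30 + 33) * len(read_seq)}",
    header,
)

adjusted = pileup.apply_baq(record, reference)
print("pos(base) original -> BAQ-capped")
for i, (orig, adj) in enumerate(zip(record.qual, adjusted)):
    marker = "  <-- capped" if adj < orig else ""
    if i < 3 or adj < orig or i > len(adjusted) - 3:
        print(f"{i:3d} ({read_seq[i]})   Q{orig} -> Q{adj}{marker}")
print("bases inside the ambiguous homopolymer lose quality;")
print("unambiguous flanks keep their original Q30.")
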