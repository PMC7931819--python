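"""Alignment toolbox: filtering, sorting, merging, stats, mate fixing,
duplicate marking, MD/NM recalculation, FASTQ export."""

import numpy as np
import pytest

from alnvar import align, sam
from alnvar.sam import (
    FDUP,
    FMUNMAP,
    FPAIRED,
    FREVERSE,
    FUNMAP,
    AlignmentRecord,
    SamHeader,
)

from conftest import make_sam_fixture, make_record, random_sequence


def _rec(header, qname, flag, rid, pos, cigar, seq="*", qual="*", extra=""):
    line = f"{qname}\t{flag}\t{header.ref_name(rid) if rid >= 0 else '*'}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
    if extra:
        line += "\t" + extra
    return sam.parse_sam_record(line, header)


@pytest.fixture
def header():
    return SamHeader(references=[("chr1", 100000), ("chr2", 50000)])


class TestViewFilter:
    def test_identity_with_no_criteria(self, sam_fixture):
        header, records = sam_fixture
        assert list(align.view_filter(records)) == records

    def test_exclude_unmapped(self, header):
        mapped = _rec(header, "a", 0, 0, 10, "5M", "ACGTA", "IIIII")
        unmapped = _rec(header, "b", 4, -1, -1, "*")
        out = list(align.view_filter([mapped, unmapped], forbidden_flags=FUNMAP))
        assert out == [mapped]

    def test_random_criteria_equal_brute_force(self, rng):
        header, records = make_sam_fixture(seed=5, n_records=300)
        for _ in range(30):
            req = int(rng.choice([0, 0x10, 0x400]))
            forb = int(rng.choice([0, 0x100, 0x200, 0x4]))
            mq = int(rng.integers(0, 50))
            got = list(
                align.view_filter(
                    records, required_flags=req, forbidden_flags=forb, min_mapq=mq
                )
            )
            expected = [
                r
                for r in records
                if (r.flag & req) == req and not (r.flag & forb) and r.mapq >= mq
            ]
            assert got == expected

    def test_region_overlap(self, header):
        r = _rec(header, "a", 0, 0, 100, "50M", "A" * 50, "I" * 50)
        assert list(align.view_filter([r], region=(0, 149, 200))) == [r]
        assert list(align.view_filter([r], region=(0, 150, 200))) == []
        assert list(align.view_filter([r], region=(1, 100, 200))) == []


class TestSort:
    def test_natural_queryname_order(self, header):
        recs = [
            _rec(header, n, 0, 0, 0, "1M", "A", "I")
            for n in ["r10", "r2", "r2a", "abc", "r02x"]
        ]
        out = align.sort_records(recs, "queryname")
        assert [r.qname for r in out] == ["abc", "r2", "r2a", "r02x", "r10"]

    def test_coordinate_sort_and_stability(self):
        header, records = make_sam_fixture(seed=9, n_records=200)
        out = align.sort_records(records, "coordinate", header)
        keys = [align.coordinate_key(r) for r in out]
        assert keys == sorted(keys)
        assert header.sort_order == "coordinate"
        assert align.sort_records(out, "coordinate") == out  # idempotent
        # stability: equal-key records preserve input order
        dup = [out[0], out[0]]
        assert align.sort_records(dup, "coordinate") == dup

    def test_unplaced_records_sort_last(self, header):
        mapped = _rec(header, "a", 0, 1, 10, "1M", "A", "I")
        unplaced = _rec(header, "b", 4, -1, -1, "*")
        assert align.sort_records([unplaced, mapped], "coordinate") == [mapped, unplaced]


class TestMerge:
    def test_merge_with_empty_is_identity(self, sam_fixture):
        header, records = sam_fixture
        records = align.sort_records(records, "coordinate", header)
        empty = SamHeader(references=list(header.references))
        merged_header, out = align.merge_sorted([(header, records), (empty, [])])
        assert [r.qname for r in out] == [r.qname for r in records]

    def test_split_then_merge_round_trip(self, rng):
        header, records = make_sam_fixture(seed=13, n_records=300)
        records = align.sort_records(records, "coordinate", header)
        mask = rng.random(len(records)) < 0.5
        part1 = [r for r, m in zip(records, mask) if m]
        part2 = [r for r, m in zip(records, mask) if not m]
        h1 = SamHeader(references=list(header.references))
        h2 = SamHeader(references=list(header.references))
        _, out = align.merge_sorted([(h1, part1), (h2, part2)])
        assert sorted(r.qname for r in out) == sorted(r.qname for r in records)
        keys = [align.coordinate_key(r) for r in out]
        assert keys == sorted(keys)

    def test_conflicting_reference_lengths(self, header):
        other = SamHeader(references=[("chr1", 999)])
        with pytest.raises(ValueError, match="conflicting lengths"):
            align.merge_sorted([(header, []), (other, [])])

    def test_duplicate_read_group_ids_renamed(self, header):
        from alnvar.sam import ReadGroup

        h1 = SamHeader(references=list(header.references))
        h1.read_groups.append(ReadGroup("rg", "s1"))
        h2 = SamHeader(references=list(header.references))
        h2.read_groups.append(ReadGroup("rg", "s2"))
        merged, _ = align.merge_sorted([(h1, []), (h2, [])])
        assert [rg.id for rg in merged.read_groups] == ["rg", "rg.1"]


class TestFlagstat:
    def test_empty(self):
        rep = align.flagstat([])
        assert rep.passed.total == 0 and rep.failed.total == 0

    def test_constructed_counts(self, header):
        recs = [_rec(header, f"m{i}", 0, 0, i * 10, "5M", "ACGTA", "IIIII") for i in range(10)]
        recs += [_rec(header, f"u{i}", 4, -1, -1, "*") for i in range(2)]
        rep = align.flagstat(recs)
        assert rep.passed.total == 12
        assert rep.passed.mapped == 10

    def test_random_fixture_matches_brute_force(self):
        header, records = make_sam_fixture(seed=21, n_records=400)
        rep = align.flagstat(records)
        for qcfail, counts in ((False, rep.passed), (True, rep.failed)):
            sub = [r for r in records if r.is_qcfail == qcfail]
            assert counts.total == len(sub)
            assert counts.mapped == sum(not r.is_unmapped for r in sub)
            assert counts.duplicates == sum(r.is_duplicate for r in sub)
            prim = [r for r in sub if not (r.is_secondary or r.is_supplementary)]
            assert counts.paired == sum(r.is_paired for r in prim)
            assert counts.read1 + counts.read2 == sum(
                r.is_paired and (r.is_read1 or r.is_read2) for r in prim
            )


class TestIdxstats:
    def test_counts_and_header_order(self, header):
        recs = [
            _rec(header, "a", 0, 0, 0, "1M", "A", "I"),
            _rec(header, "b", 0, 1, 0, "1M", "A", "I"),
            _rec(header, "c", 4, -1, -1, "*"),
        ]
        rows = align.idxstats(recs, header)
        assert rows[0] == ("chr1", 100000, 1, 0)
        assert rows[1] == ("chr2", 50000, 1, 0)
        assert rows[2] == ("*", 0, 0, 1)
        assert sum(m + u for _, _, m, u in rows) == len(recs)


class TestStats:
    def test_perfect_read(self, header):
        r = _rec(header, "a", 0, 0, 0, "100M", "A" * 100, "I" * 100, "NM:i:0")
        rep = align.stats_basic([r])
        assert rep.error_rate == 0.0
        assert rep.average_length == 100

    def test_error_rate_arithmetic(self, header):
        recs = [
            _rec(header, "a", 0, 0, 0, "100M", "A" * 100, "I" * 100, "NM:i:1"),
            _rec(header, "b", 0, 0, 200, "100M", "A" * 100, "I" * 100, "NM:i:1"),
        ]
        rep = align.stats_basic(recs)
        assert rep.error_rate == pytest.approx(2 / 200)

    def test_random_fixture_matches_recomputation(self):
        header, records = make_sam_fixture(seed=33, n_records=300)
        rep = align.stats_basic(records)
        prim = [r for r in records if not (r.is_secondary or r.is_supplementary)]
        assert rep.raw_total_sequences == len(prim)
        mapped = [r for r in prim if not r.is_unmapped]
        assert rep.reads_mapped == len(mapped)
        bases = sum(
            sum(n for op, n in r.cigar if op in "M=X") for r in mapped
        )
        assert rep.bases_mapped == bases
        nm = sum(int(r.tags["NM"][1]) for r in mapped if "NM" in r.tags)
        assert rep.error_rate == pytest.approx(nm / bases)
        assert rep.maximum_length >= rep.average_length


class TestDepth:
    def test_single_read(self, header):
        r = _rec(header, "a", 0, 0, 0, "10M", "A" * 10, "I" * 10)
        d = align.depth([r])
        assert all(d[(0, p)] == 1 for p in range(10))
        assert (0, 10) not in d

    def test_deletion_not_counted(self, header):
        r = _rec(header, "a", 0, 0, 0, "5M2D5M", "A" * 10, "I" * 10)
        d = align.depth([r])
        assert (0, 5) not in d and (0, 6) not in d
        assert d[(0, 7)] == 1

    def test_bedcov_sums_depth(self, header):
        r = _rec(header, "a", 0, 0, 5, "10M", "A" * 10, "I" * 10)
        assert align.bedcov([r], [(0, 5, 15)]) == [10]
        assert align.bedcov([r], [(0, 0, 5)]) == [0]
        assert align.bedcov([r], []) == []


class TestFixmate:
    def test_pair_tlen(self, header):
        a = _rec(header, "p", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        b = _rec(header, "p", FPAIRED | FREVERSE, 0, 200, "50M", "A" * 50, "I" * 50)
        out = align.fixmate([a, b])
        assert out[0].tlen == 150 and out[1].tlen == -150
        assert out[0].mpos == 200 and out[1].mpos == 100
        assert out[0].flag & sam.FMREVERSE

    def test_tlen_matches_external_convention(self, tmp_path):
        # cross-check the signed TLEN definition against samtools fixmate
        import shutil, subprocess

        if shutil.which("samtools") is None:
            pytest.skip("samtools unavailable")
        header = SamHeader(references=[("chr1", 100000)])
        a = _rec(header, "p", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        b = _rec(header, "p", FPAIRED | FREVERSE, 0, 200, "50M", "A" * 50, "I" * 50)
        src = tmp_path / "in.sam"
        src.write_text(sam.write_sam(header, [a, b]))
        out = subprocess.run(
            ["samtools", "fixmate", "-O", "sam", str(src), "-"],
            capture_output=True, text=True
        )
        tlens = [
            int(line.split("\t")[8])
            for line in out.stdout.splitlines()
            if not line.startswith("@")
        ]
        ours = [r.tlen for r in align.fixmate([a, b])]
        assert tlens == ours == [150, -150]

    def test_mate_unmapped(self, header):
        a = _rec(header, "p", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        b = _rec(header, "p", FPAIRED | FUNMAP, -1, -1, "*", "A" * 50, "I" * 50)
        out = align.fixmate([a, b])
        assert out[0].tlen == 0
        assert out[0].flag & FMUNMAP
        assert out[1].rid == 0 and out[1].pos == 100  # adopts mapped coordinates

    def test_singleton_without_mate(self, header):
        a = _rec(header, "p", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        out = align.fixmate([a])
        assert out[0].flag & FMUNMAP and out[0].tlen == 0

    def test_not_name_grouped_raises(self, header):
        a = _rec(header, "p", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        b = _rec(header, "q", FPAIRED, 0, 100, "50M", "A" * 50, "I" * 50)
        with pytest.raises(align.OrderError):
            align.fixmate([a, b, a])


class TestMarkdup:
    def test_highest_quality_single_end_kept(self, header):
        hi = _rec(header, "a", 0, 0, 100, "10M", "A" * 10, chr(33 + 30) * 10)
        lo = _rec(header, "b", 0, 0, 100, "10M", "A" * 10, chr(33 + 28) * 10)
        out = align.markdup([hi, lo])
        assert not out[0].is_duplicate and out[1].is_duplicate

    def test_opposite_strands_not_duplicates(self, header):
        f = _rec(header, "a", 0, 0, 100, "10M", "A" * 10, "I" * 10)
        r = _rec(header, "b", FREVERSE, 0, 100, "10M", "A" * 10, "I" * 10)
        out = align.markdup([f, r])
        assert not any(x.is_duplicate for x in out)

    def test_soft_clip_aware_grouping(self, header):
        clipped = _rec(header, "a", 0, 0, 12, "2S8M", "A" * 10, "I" * 10)
        plain = _rec(header, "b", 0, 0, 10, "10M", "A" * 10, chr(33 + 39) * 10)
        out = align.markdup([plain, clipped])
        # same unclipped 5' start 10 => grouped; higher quality sum retained
        assert sum(x.is_duplicate for x in out) == 1
        assert out[0].is_duplicate and not out[1].is_duplicate

    def test_group_size_minus_one_flagged(self, rng, header):
        records = []
        for g in range(10):
            pos = 100 + g * 50
            k = int(rng.integers(1, 5))
            for i in range(k):
                records.append(
                    _rec(header, f"g{g}_{i}", 0, 0, pos, "10M", "A" * 10,
                         chr(33 + int(rng.integers(10, 40))) * 10)
                )
        out = align.markdup(align.sort_records(records, "coordinate"))
        by_pos = {}
        for r in out:
            by_pos.setdefault(r.pos, []).append(r)
        for pos, group in by_pos.items():
            assert sum(r.is_duplicate for r in group) == len(group) - 1

    def test_unsorted_raises(self, header):
        a = _rec(header, "a", 0, 0, 100, "10M", "A" * 10, "I" * 10)
        b = _rec(header, "b", 0, 0, 50, "10M", "A" * 10, "I" * 10)
        with pytest.raises(align.OrderError):
            align.markdup([a, b])


class TestCalmd:
    def test_substitution(self, header):
        ref = {0: "ACGTACGT" + "A" * 100}
        r = _rec(header, "a", 0, 0, 0, "8M", "ACGAACGT", "I" * 8)
        out = align.calmd([r], ref)[0]
        assert out.tags["MD"] == ("Z", "3T4")
        assert out.tags["NM"] == ("i", 1)

    def test_perfect_match(self, header):
        ref = {0: "ACGTACGT"}
        r = _rec(header, "a", 0, 0, 0, "8M", "ACGTACGT", "I" * 8)
        out = align.calmd([r], ref)[0]
        assert out.tags["MD"] == ("Z", "8")
        assert out.tags["NM"] == ("i", 0)

    def test_deletion(self, header):
        #          0123456789
        ref = {0: "AAAACATTTT"}
        r = _rec(header, "a", 0, 0, 0, "4M2D4M", "AAAATTTT", "I" * 8)
        out = align.calmd([r], ref)[0]
        assert out.tags["MD"] == ("Z", "4^CA4")
        assert out.tags["NM"] == ("i", 2)

    def test_reference_reconstruction_round_trip(self, rng):
        # seq + MD must reproduce the aligned reference exactly
        header, records = make_sam_fixture(seed=17, n_records=100)
        reference = {
            i: random_sequence(rng, length)
            for i, (_, length) in enumerate(header.references)
        }
        for r in align.calmd(records, reference):
            if r.is_unmapped:
                continue
            rebuilt = _reference_from_md(r)
            truth = "".join(
                reference[r.rid][p]
                for q, p, op in sam.aligned_pairs(r)
                if p is not None and op in "M=X"
            )
            assert rebuilt.upper() == truth.upper()


def _reference_from_md(r):
    md = r.tags["MD"][1]
    matched = [r.seq[q] for q, p, op in sam.aligned_pairs(r) if op in "M=X"]
    out = []
    i = qi = 0
    num = ""
    while i < len(md):
        c = md[i]
        if c.isdigit():
            num += c
            i += 1
            continue
        if num:
            out.extend(matched[qi : qi + int(num)])
            qi += int(num)
            num = ""
        if c == "^":
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1  # deleted reference bases: not part of M columns
            continue
        out.append(c)  # mismatched reference base
        qi += 1
        i += 1
    if num:
        out.extend(matched[qi : qi + int(num)])
    return "".join(out)


class TestToFastq:
    def test_forward_read(self, header):
        r = _rec(header, "a", 0, 0, 0, "4M", "AACC", "IIII")
        assert align.to_fastq([r]) == [("a", "AACC", "IIII")]

    def test_reverse_read_recovers_original_orientation(self, header):
        r = _rec(header, "a", FREVERSE, 0, 0, "4M", "AACC", "IIJJ")
        name, seq, qual = align.to_fastq([r])[0]
        assert seq == "GGTT" and qual == "JJII"

    def test_secondary_excluded_by_default(self, header):
        r = _rec(header, "a", 0x100, 0, 0, "4M", "AACC", "IIII")
        assert align.to_fastq([r]) == []
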