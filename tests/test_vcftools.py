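"""Variant toolbox: norm, split/join, merge/concat/isec, annotate, consensus,
query, filter expressions, stats, gtcheck."""

import numpy as np
import pytest

from alnvar import vcftools
from alnvar.vcf import (
    FieldDef,
    Genotype,
    VariantRecord,
    VcfHeader,
    parse_vcf_record,
)
from alnvar.vcftools import (
    OverlapError,
    ReferenceMismatchError,
    consensus_apply,
    eval_filter,
    normalize,
    parse_filter_expression,
)

from conftest import random_sequence


def _hdr(samples=("s1",)):
    hdr = VcfHeader()
    hdr.contigs["chr1"] = 10**9
    hdr.infos["DP"] = FieldDef("DP", "1", "Integer")
    hdr.infos["AF"] = FieldDef("AF", "A", "Float")
    hdr.infos["AC"] = FieldDef("AC", "A", "Integer")
    hdr.formats["GT"] = FieldDef("GT", "1", "String")
    hdr.formats["PL"] = FieldDef("PL", "G", "Integer")
    hdr.formats["AD"] = FieldDef("AD", "R", "Integer")
    hdr.formats["DP"] = FieldDef("DP", "1", "Integer")
    hdr.samples = list(samples)
    return hdr


def _rec(chrom, pos0, ref, alts, samples=None, info=None, fmt=None, qual=50.0):
    return VariantRecord(
        chrom, pos0, ".", ref, list(alts), qual, ["PASS"], dict(info or {}),
        list(fmt or ([] if samples is None else ["GT"])),
        [dict(s) for s in (samples or [])],
    )


def _apply_to_ref(ref, rec, alt_idx=0):
    """Haplotype oracle: splice one alt into the reference."""
    assert ref[rec.pos : rec.pos + len(rec.ref)].upper() == rec.ref.upper()
    return ref[: rec.pos] + rec.alts[alt_idx] + ref[rec.pos + len(rec.ref) :]


class TestNormalize:
    def test_left_align_in_repeat(self):
        ref = "GGGCACACACAGGG"
        r = _rec("chr1", 8, "ACA", ["A"])
        n = normalize(r, ref)
        assert (n.pos, n.ref, n.alts) == (2, "GCA", ["G"])

    def test_minimal_snp_unchanged(self):
        ref = "ACGTACGT"
        r = _rec("chr1", 3, "T", ["G"])
        n = normalize(r, ref)
        assert (n.pos, n.ref, n.alts) == (3, "T", ["G"])

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            normalize(_rec("chr1", 0, "T", ["G"]), "AAAA")

    def test_symbolic_rejected(self):
        with pytest.raises(ValueError):
            normalize(_rec("chr1", 0, "A", ["<DEL>"]), "AAAA")

    def test_idempotent_and_haplotype_preserving_on_fuzz(self, rng):
        """Random redundant indel representations: normalize is idempotent,
        REF matches the reference, and the edited haplotype is unchanged."""
        for _ in range(300):
            ref = random_sequence(rng, 120)
            pos = int(rng.integers(20, 80))
            if rng.random() < 0.5:
                ins = random_sequence(rng, int(rng.integers(1, 5)))
                ref_a, alt_a = ref[pos], ref[pos] + ins
            else:
                k = int(rng.integers(1, 6))
                ref_a, alt_a = ref[pos : pos + 1 + k], ref[pos]
            # pad with shared context to make the representation redundant
            lpad = int(rng.integers(0, 4))
            rpad = int(rng.integers(0, 4))
            pref = ref[pos - lpad : pos]
            suff = ref[pos + len(ref_a) : pos + len(ref_a) + rpad]
            r = _rec("chr1", pos - lpad, pref + ref_a + suff,
                     [pref + alt_a + suff])
            n = normalize(r, ref)
            n2 = normalize(n, ref)
            assert (n2.pos, n2.ref, n2.alts) == (n.pos, n.ref, n.alts)
            assert ref[n.pos : n.pos + len(n.ref)].upper() == n.ref.upper()
            assert _apply_to_ref(ref, r) == _apply_to_ref(ref, n)


class TestSplitJoin:
    def _tri(self):
        hdr = _hdr(samples=("s1", "s2"))
        line = (
            "chr1\t100\t.\tA\tT,G\t50\tPASS\tDP=9;AF=0.1,0.2;AC=1,2\t"
            "GT:PL:AD:DP\t0/1:10,0,20,30,40,50:5,3,1:9\t1/2:50,40,30,20,10,0:1,4,4:9"
        )
        return hdr, parse_vcf_record(line, hdr)

    def test_biallelic_passthrough(self):
        hdr = _hdr()
        r = parse_vcf_record("chr1\t5\t.\tA\tT\t.\t.\tDP=3\tGT\t0/1", hdr)
        out = vcftools.split_multiallelic(r, hdr)
        assert len(out) == 1 and out[0] == r

    def test_triallelic_pl_slicing(self):
        hdr, r = self._tri()
        a, b = vcftools.split_multiallelic(r, hdr)
        # PL over {REF, T}: indices (0,0)=0, (0,1)=1, (1,1)=2 of the original
        assert a.samples[0]["PL"] == [10, 0, 20]
        # PL over {REF, G}: indices (0,0)=0, (0,2)=3, (2,2)=5
        assert b.samples[0]["PL"] == [10, 30, 50]
        assert a.info["AF"] == [0.1] and b.info["AF"] == [0.2]
        assert a.samples[0]["AD"] == [5, 3] and b.samples[0]["AD"] == [5, 1]
        # GT recoding: other alt becomes ref
        assert str(a.samples[1]["GT"]) == "1/0"
        assert str(b.samples[1]["GT"]) == "0/1"

    def test_join_inverts_split(self):
        hdr, r = self._tri()
        parts = vcftools.split_multiallelic(r, hdr)
        joined = vcftools.join_multiallelic(parts, hdr)
        assert joined.alts == r.alts
        assert joined.info["AF"] == r.info["AF"]
        assert joined.info["AC"] == r.info["AC"]
        for si in range(2):
            assert str(joined.samples[si]["GT"]) == str(r.samples[si]["GT"])
            assert joined.samples[si]["AD"] == r.samples[si]["AD"]
            # determined PL entries recovered exactly; the cross-alt entry
            # (1,2) is unrecoverable from biallelic slices
            pl_j, pl_r = joined.samples[si]["PL"], r.samples[si]["PL"]
            for idx in (0, 1, 2, 3, 5):
                assert pl_j[idx] == pl_r[idx]


class TestMerge:
    def test_disjoint_positions_interleave(self):
        h1, h2 = _hdr(("a",)), _hdr(("b",))
        r1 = [_rec("chr1", 10, "A", ["T"], [{"GT": Genotype((0, 1))}])]
        r2 = [_rec("chr1", 5, "C", ["G"], [{"GT": Genotype((1, 1))}])]
        hdr, out = vcftools.merge_variant_files([(h1, r1), (h2, r2)])
        assert hdr.samples == ["a", "b"]
        assert [r.pos for r in out] == [5, 10]
        # absent samples filled with missing
        assert out[0].samples[0] == {}
        assert str(out[0].samples[1]["GT"]) == "1/1"

    def test_same_position_different_alts_unioned(self):
        h1, h2 = _hdr(("a",)), _hdr(("b",))
        r1 = [_rec("chr1", 10, "A", ["T"], [{"GT": Genotype((0, 1))}])]
        r2 = [_rec("chr1", 10, "A", ["G"], [{"GT": Genotype((1, 1))}])]
        hdr, out = vcftools.merge_variant_files([(h1, r1), (h2, r2)])
        assert len(out) == 1
        site = out[0]
        assert site.alts == ["T", "G"]
        assert str(site.samples[0]["GT"]) == "0/1"
        assert str(site.samples[1]["GT"]) == "2/2"

    def test_pl_remap_through_genotype_index(self):
        h1, h2 = _hdr(("a",)), _hdr(("b",))
        r1 = [_rec("chr1", 10, "A", ["T"],
                   [{"GT": Genotype((0, 1)), "PL": [10, 0, 20]}], fmt=["GT", "PL"])]
        r2 = [_rec("chr1", 10, "A", ["G"],
                   [{"GT": Genotype((1, 1)), "PL": [30, 5, 0]}], fmt=["GT", "PL"])]
        hdr, out = vcftools.merge_variant_files([(h1, r1), (h2, r2)])
        pl_a = out[0].samples[0]["PL"]
        # sample a: alleles {0:0, 1:1}: (0,0)->0, (0,1)->1, (1,1)->2; G entries missing
        assert pl_a[0] == 10 and pl_a[1] == 0 and pl_a[2] == 20
        pl_b = out[0].samples[1]["PL"]
        # sample b: old alt 1 maps to new allele 2: (0,2)->idx 3, (2,2)->idx 5
        assert pl_b[0] == 30 and pl_b[3] == 5 and pl_b[5] == 0

    def test_incompatible_ref_raises(self):
        h1, h2 = _hdr(("a",)), _hdr(("b",))
        r1 = [_rec("chr1", 10, "AT", ["A"])]
        r2 = [_rec("chr1", 10, "AG", ["A"])]
        with pytest.raises(ValueError, match="incompatible REF"):
            vcftools.merge_variant_files([(h1, r1), (h2, r2)])

    def test_info_dp_summed(self):
        h1, h2 = _hdr(("a",)), _hdr(("b",))
        r1 = [_rec("chr1", 10, "A", ["T"], [{}], info={"DP": 7})]
        r2 = [_rec("chr1", 10, "A", ["T"], [{}], info={"DP": 5})]
        hdr, out = vcftools.merge_variant_files([(h1, r1), (h2, r2)])
        assert out[0].info["DP"] == 12


class TestConcat:
    def test_identity(self):
        h = _hdr()
        recs = [_rec("chr1", i, "A", ["T"], [{}]) for i in (1, 5, 9)]
        hdr, out = vcftools.concat_variant_files([(h, recs)])
        assert [(r.pos) for r in out] == [1, 5, 9]

    def test_partitioned_union(self):
        h1, h2 = _hdr(), _hdr()
        a = [_rec("chr1", 1, "A", ["T"], [{}])]
        b = [_rec("chr1", 100, "C", ["G"], [{}])]
        _, out = vcftools.concat_variant_files([(h1, a), (h2, b)])
        assert len(out) == 2

    def test_mismatched_samples_error(self):
        with pytest.raises(ValueError, match="differ"):
            vcftools.concat_variant_files([(_hdr(("a",)), []), (_hdr(("b",)), [])])


class TestIsec:
    def _random_files(self, rng, n_files=3, n_sites=120):
        positions = rng.choice(np.arange(10, 5000), size=n_sites, replace=False)
        files = []
        membership = {}
        for fi in range(n_files):
            recs = []
            for p in sorted(positions):
                if rng.random() < 0.5:
                    recs.append(_rec("chr1", int(p), "A", ["T"]))
                    membership.setdefault(int(p), set()).add(fi)
            files.append(recs)
        return files, membership

    def test_file_vs_itself_all_shared(self):
        recs = [_rec("chr1", i, "A", ["T"]) for i in (1, 5)]
        table = vcftools.isec([recs, recs])
        assert all(mask == 0b11 for mask, _ in table.values())

    def test_disjoint_files_only_private(self):
        a = [_rec("chr1", 1, "A", ["T"])]
        b = [_rec("chr1", 2, "A", ["T"])]
        table = vcftools.isec([a, b])
        assert vcftools.isec_select(table, vcftools.shared_by_all(2), 0) == []
        assert len(vcftools.isec_select(table, vcftools.private_to(0, 2), 0)) == 1

    def test_matches_brute_force_set_algebra(self, rng):
        files, membership = self._random_files(rng)
        table = vcftools.isec(files)
        for fi in range(3):
            private = {
                r.pos
                for r in vcftools.isec_select(table, vcftools.private_to(fi, 3), fi)
            }
            expected = {p for p, m in membership.items() if m == {fi}}
            assert private == expected
        shared = {
            r.pos for r in vcftools.isec_select(table, vcftools.shared_by_all(3), 0)
        }
        assert shared == {p for p, m in membership.items() if len(m) == 3}
        atleast2 = {
            r.pos
            for r in vcftools.isec_select(table, vcftools.present_in_at_least(2), 0)
        }
        assert atleast2 == {
            p for p, m in membership.items() if len(m) >= 2 and 0 in m
        }

    def test_different_alleles_are_different_keys(self):
        a = [_rec("chr1", 1, "A", ["T"])]
        b = [_rec("chr1", 1, "A", ["G"])]
        assert len(vcftools.isec([a, b])) == 2
        assert len(vcftools.isec([a, b], use_alleles=False)) == 1


class TestAnnotate:
    def test_remove_all_info(self):
        hdr = _hdr()
        recs = [_rec("chr1", 1, "A", ["T"], [{}], info={"DP": 3, "AF": [0.5]})]
        out = vcftools.annotate(recs, hdr, remove=["INFO/*"])
        assert out[0].info == {}
        assert out[0].pos == 1 and out[0].alts == ["T"]

    def test_self_annotation_idempotent(self):
        hdr = _hdr()
        recs = [_rec("chr1", 1, "A", ["T"], [{}], info={"DP": 3})]
        out = vcftools.annotate(recs, hdr, source=recs, source_header=hdr,
                                transfer=["INFO/DP"])
        assert out[0].info == recs[0].info

    def test_random_table_transfer_matches_join(self, rng):
        hdr = _hdr()
        positions = sorted(int(p) for p in rng.choice(5000, 200, replace=False))
        recs = [_rec("chr1", p, "A", ["T"], [{}]) for p in positions]
        src_pos = set(
            int(p) for p in rng.choice(positions, 80, replace=False)
        )
        source = [
            _rec("chr1", p, "A", ["T"], [{}], info={"DP": p * 2}) for p in sorted(src_pos)
        ]
        out = vcftools.annotate(recs, hdr, source=source, source_header=hdr,
                                transfer=["INFO/DP"])
        for r in out:
            if r.pos in src_pos:
                assert r.info["DP"] == r.pos * 2
            else:
                assert "DP" not in r.info


class TestConsensus:
    def test_snp_substitution(self):
        r = _rec("chr1", 2, "G", ["C"], [{"GT": Genotype((1, 1))}])
        # "ACGT" with pos 2 G->C
        assert consensus_apply("ACGT", [r]) == "ACCT"

    def test_deletion(self):
        r = _rec("chr1", 1, "CG", ["C"], [{"GT": Genotype((1, 1))}])
        assert consensus_apply("ACGT", [r]) == "ACT"

    def test_insertion(self):
        r = _rec("chr1", 1, "C", ["CTT"], [{"GT": Genotype((1, 1))}])
        assert consensus_apply("ACGT", [r]) == "ACTTGT"

    def test_het_haplotype_selection(self):
        r = _rec("chr1", 2, "G", ["C"], [{"GT": Genotype((0, 1), phased=True)}])
        assert consensus_apply("ACGT", [r], haplotype=1) == "ACGT"
        assert consensus_apply("ACGT", [r], haplotype=2) == "ACCT"

    def test_iupac_het_snp(self):
        r = _rec("chr1", 2, "G", ["C"], [{"GT": Genotype((0, 1))}])
        assert consensus_apply("ACGT", [r], haplotype="IUPAC") == "ACST"

    def test_missing_gt_leaves_reference(self):
        r = _rec("chr1", 2, "G", ["C"], [{"GT": Genotype((None, None))}])
        assert consensus_apply("ACGT", [r]) == "ACGT"

    def test_overlap_is_error(self):
        a = _rec("chr1", 1, "CGT", ["C"], [{"GT": Genotype((1, 1))}])
        b = _rec("chr1", 2, "G", ["A"], [{"GT": Genotype((1, 1))}])
        with pytest.raises(OverlapError):
            consensus_apply("ACGTACGT", [a, b])

    def test_diff_round_trip(self, rng):
        """Variants generated as the diff of two sequences reproduce the
        target exactly when applied to the source."""
        from alnvar.sim import SimulationConfig, simulate_individuals

        for seed in range(5):
            cfg = SimulationConfig(seed=seed, ref_length=3000, het_fraction=0.0,
                                   snp_density=0.004, indel_density=0.002)
            ref = random_sequence(np.random.default_rng(seed), 3000)
            truth = simulate_individuals(ref, cfg)
            _, recs = truth.truth_vcf()
            target, _ = truth.haplotypes[(0, 0)]
            assert consensus_apply(ref, recs) == target


class TestQueryFormat:
    def test_site_columns(self):
        hdr = _hdr(samples=())
        recs = [_rec("chr1", 99, "A", ["T"], info={"DP": 4})]
        out = vcftools.query_format(recs, "%CHROM\\t%POS\\t%INFO/DP\\n", hdr)
        assert out == ["chr1\t100\t4\n"]

    def test_sample_block(self):
        hdr = _hdr(samples=("a", "b", "c"))
        recs = [
            _rec("chr1", 0, "A", ["T"],
                 [{"GT": Genotype((0, 1))}, {"GT": Genotype((1, 1))}, {}])
        ]
        out = vcftools.query_format(recs, "[%GT,]\\n", hdr)
        assert out == ["0/1,1/1,./.,\n"]

    def test_projection_matches_model(self, rng):
        hdr = _hdr(samples=("x",))
        recs = [
            _rec("chr1", int(p), "A", ["T"], [{"GT": Genotype((0, 1))}],
                 info={"DP": int(p) % 37}, qual=float(int(p) % 91))
            for p in sorted(rng.choice(10000, 50, replace=False))
        ]
        lines = vcftools.query_format(
            recs, "%CHROM\\t%POS\\t%REF\\t%ALT\\t%QUAL\\t%INFO/DP\\n", hdr
        )
        for r, line in zip(recs, lines):
            chrom, pos, ref, alt, qual, dp = line.rstrip("\n").split("\t")
            assert (chrom, int(pos) - 1, ref, alt) == (r.chrom, r.pos, r.ref, r.alts[0])
            assert float(qual) == r.qual and int(dp) == r.info["DP"]


class TestFilterExpressions:
    def test_qual_comparison(self):
        r = _rec("chr1", 0, "A", ["T"], qual=50.0)
        assert eval_filter(r, "QUAL>30")
        assert not eval_filter(r, "QUAL>30", mode="exclude")
        assert not eval_filter(r, "QUAL<30")

    def test_boolean_algebra_truth_table(self):
        expr = parse_filter_expression("INFO/DP<10 && QUAL>30")
        cases = [
            ({"DP": 5}, 50.0, True),
            ({"DP": 5}, 10.0, False),
            ({"DP": 20}, 50.0, False),
            ({"DP": 20}, 10.0, False),
        ]
        for info, qual, expected in cases:
            r = _rec("chr1", 0, "A", ["T"], info=info, qual=qual)
            assert expr.evaluate(r) is expected

    def test_missing_values_compare_false(self):
        r = _rec("chr1", 0, "A", ["T"], qual=None)
        assert not eval_filter(r, "QUAL>0")
        assert not eval_filter(r, "QUAL<=0")
        assert not eval_filter(r, "INFO/MISSING=1")

    def test_string_and_filter_matching(self):
        r = _rec("chr1", 0, "A", ["T"])
        assert eval_filter(r, 'FILTER="PASS"')
        assert eval_filter(r, 'REF="A" && ALT="T"')

    def test_not_and_parentheses(self):
        r = _rec("chr1", 0, "A", ["T"], info={"DP": 5}, qual=50.0)
        assert eval_filter(r, "!(QUAL<30) && (INFO/DP<10 || INFO/DP>100)")

    def test_format_any_sample_quantification(self):
        r = _rec("chr1", 0, "A", ["T"],
                 [{"DP": 3}, {"DP": 30}], fmt=["DP"])
        assert eval_filter(r, "FORMAT/DP>20")
        assert eval_filter(r, "FMT/DP<5")
        assert not eval_filter(r, "FORMAT/DP>50")

    def test_flag_presence(self):
        r = _rec("chr1", 0, "A", ["T"], info={"VALIDATED": True})
        assert eval_filter(r, "VALIDATED")
        assert not eval_filter(r, "INFO/OTHER")

    def test_random_expressions_match_direct_evaluation(self, rng):
        ops = {"<": np.less, "<=": np.less_equal, ">": np.greater,
               ">=": np.greater_equal, "=": np.equal, "!=": np.not_equal}
        for _ in range(100):
            dp = int(rng.integers(0, 50))
            qual = float(rng.integers(0, 99))
            r = _rec("chr1", 0, "A", ["T"], info={"DP": dp}, qual=qual)
            op1, op2 = rng.choice(list(ops), 2)
            t1, t2 = int(rng.integers(0, 50)), int(rng.integers(0, 99))
            joiner = "&&" if rng.random() < 0.5 else "||"
            text = f"INFO/DP{op1}{t1} {joiner} QUAL{op2}{t2}"
            expected = (
                bool(ops[op1](dp, t1)) and bool(ops[op2](qual, t2))
                if joiner == "&&"
                else bool(ops[op1](dp, t1)) or bool(ops[op2](qual, t2))
            )
            assert eval_filter(r, text) is expected, text

    def test_syntax_error(self):
        with pytest.raises(vcftools.FilterSyntaxError):
            parse_filter_expression("QUAL >")


class TestStats:
    def test_ts_tv_arithmetic(self):
        hdr = _hdr(samples=())
        recs = [
            _rec("chr1", 0, "A", ["G"]),  # transition
            _rec("chr1", 1, "C", ["T"]),  # transition
            _rec("chr1", 2, "A", ["T"]),  # transversion
        ]
        rep = vcftools.vcf_stats(recs, hdr)
        assert rep.ts == 2 and rep.tv == 1
        assert rep.ts_tv == pytest.approx(2.0)

    def test_empty(self):
        rep = vcftools.vcf_stats([], _hdr())
        assert rep.n_records == 0 and rep.ts_tv is None

    def test_random_fixture_matches_recount(self, rng):
        hdr = _hdr(samples=("a", "b"))
        recs = []
        for p in sorted(rng.choice(100000, 150, replace=False)):
            if rng.random() < 0.8:
                ref, alts = "A", [str(rng.choice(list("CGT")))]
            else:
                ref, alts = "AT", ["A"]
            gts = [
                Genotype(tuple(int(a) for a in rng.integers(0, 2, 2)))
                for _ in range(2)
            ]
            recs.append(
                _rec("chr1", int(p), ref, alts, [{"GT": g} for g in gts])
            )
        rep = vcftools.vcf_stats(recs, hdr)
        assert rep.n_snps == sum(
            1 for r in recs if len(r.ref) == 1 and len(r.alts[0]) == 1
        )
        assert rep.n_indels == rep.n_records - rep.n_snps
        assert rep.ts + rep.tv == sum(
            1 for r in recs
            if len(r.ref) == 1 and len(r.alts) == 1 and len(r.alts[0]) == 1
        )
        singles = sum(
            1
            for r in recs
            if sum(bool(g and g.has_alt()) for g in (r.genotype(0), r.genotype(1))) == 1
        )
        assert rep.n_singletons == singles


class TestGtcheck:
    def test_file_vs_itself_zero_discordance(self):
        hdr = _hdr(samples=("a",))
        recs = [
            _rec("chr1", p, "A", ["T"], [{"GT": Genotype((0, 1))}])
            for p in range(5)
        ]
        out = vcftools.gtcheck(recs, hdr, recs, hdr, [("a", "a")])
        assert out[0][2] == 5 and out[0][3] == 0

    def test_complementary_homs_all_discordant(self):
        ha, hb = _hdr(samples=("a",)), _hdr(samples=("b",))
        ra = [_rec("chr1", p, "A", ["T"], [{"GT": Genotype((0, 0))}]) for p in range(4)]
        rb = [_rec("chr1", p, "A", ["T"], [{"GT": Genotype((1, 1))}]) for p in range(4)]
        out = vcftools.gtcheck(ra, ha, rb, hb, [("a", "b")])
        assert out[0][2] == 4 and out[0][3] == 4 and out[0][4] == 1.0

    def test_random_panels_match_brute_force(self, rng):
        ha, hb = _hdr(samples=("a",)), _hdr(samples=("b",))
        positions = sorted(int(p) for p in rng.choice(10000, 100, replace=False))
        ra, rb = [], []
        expected_n = expected_d = 0
        for p in positions:
            ga = tuple(int(x) for x in rng.integers(0, 2, 2))
            gb = tuple(int(x) for x in rng.integers(0, 2, 2))
            in_b = rng.random() < 0.8
            ra.append(_rec("chr1", p, "A", ["T"], [{"GT": Genotype(ga)}]))
            if in_b:
                rb.append(_rec("chr1", p, "A", ["T"], [{"GT": Genotype(gb)}]))
                expected_n += 1
                expected_d += sorted(ga) != sorted(gb)
        out = vcftools.gtcheck(ra, ha, rb, hb, [("a", "b")])
        assert out[0][2] == expected_n and out[0][3] == expected_d
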