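"""Variant benchmarking: normalization, exclusions, comparison, curves.

The randomized suites check the implementation against independent
brute-force re-implementations (per-base bitmasks, pairwise scans,
threshold sweeps) on small instances.
"""

from collections import Counter

import numpy as np
import pytest

import gcatbench as gb
from gcatbench import vareval as vv
from gcatbench.errors import InputError
from gcatbench.simkit import HET, HOM_ALT
from conftest import random_truth_set


def seq_ref(seq, name="c"):
    return {name: seq}


def apply_record(seq, rec):
    p0 = rec.pos - 1
    assert seq[p0:p0 + len(rec.ref)] == rec.ref
    return seq[:p0] + rec.alt + seq[p0 + len(rec.ref):]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_shared_prefix_trim(self):
        ref = seq_ref("A" * 99 + "CTG" + "A" * 50)
        rec = gb.CallRecord("c", 100, "CT", "CA")
        n = vv.normalize_record(rec, ref)
        assert (n.pos, n.ref, n.alt) == (101, "T", "A")

    def test_minimal_snp_unchanged(self):
        ref = seq_ref("GATTACA")
        rec = gb.CallRecord("c", 4, "T", "C")
        assert vv.normalize_record(rec, ref) == rec

    def test_left_align_deletion_in_homopolymer(self):
        ref = seq_ref("GATTACACCCCTGA")
        n = vv.normalize_record(gb.CallRecord("c", 10, "CC", "C"), ref)
        assert (n.pos, n.ref, n.alt) == (7, "AC", "A")

    def test_ref_mismatch_rejected(self):
        with pytest.raises(InputError):
            vv.normalize_record(gb.CallRecord("c", 2, "G", "T"),
                                seq_ref("GATTACA"))

    def test_randomized_representations_converge(self, rng):
        """Equivalent padded representations normalize to one minimal form
        that reproduces the same edited sequence."""
        bases = "ACGT"
        for _ in range(500):
            L = 60
            seq = "".join(rng.choice(list(bases),
                                     size=L // 3)) * 1  # short core
            # embed repeat runs so left-alignment has real work to do
            run = str(rng.choice(list(bases))) * int(rng.integers(2, 7))
            seq = seq[:10] + run + seq[10:]
            pos0 = int(rng.integers(5, len(seq) - 12))
            anchor = seq[pos0]
            if rng.random() < 0.5:
                ilen = int(rng.integers(1, 5))
                ref_a = seq[pos0:pos0 + ilen + 1]
                alt_a = anchor
            else:
                ins = "".join(rng.choice(list(bases),
                                         size=int(rng.integers(1, 5))))
                ref_a, alt_a = anchor, anchor + ins
            base_rec = gb.CallRecord("c", pos0 + 1, ref_a, alt_a)
            ref = seq_ref(seq)
            mutated = apply_record(seq, base_rec)
            canon = vv.normalize_record(base_rec, ref)
            # padded equivalents: extend both alleles with reference context
            for _ in range(4):
                lead = int(rng.integers(0, min(3, pos0)))
                trail = int(rng.integers(0, 3))
                p0 = pos0 - lead
                pad_l = seq[p0:pos0]
                end0 = pos0 + len(ref_a)
                pad_r = seq[end0:end0 + trail]
                variant = gb.CallRecord("c", p0 + 1, pad_l + ref_a + pad_r,
                                        pad_l + alt_a + pad_r)
                assert apply_record(seq, variant) == mutated
                n = vv.normalize_record(variant, ref)
                assert (n.pos, n.ref, n.alt) == \
                    (canon.pos, canon.ref, canon.alt)
            # minimality: the canonical form has no shared suffix and
            # cannot shift further left
            assert not (len(canon.ref) > 1 and len(canon.alt) > 1
                        and canon.ref[-1] == canon.alt[-1])
            assert apply_record(seq, canon) == mutated

    def test_normalize_calls_idempotent(self, rng, small_ref, small_genome):
        once = vv.normalize_calls(small_genome.truth, small_ref)
        twice = vv.normalize_calls(once, small_ref)
        assert once == twice


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def brute_exclusion_bases(truth, window=10):
    """Independent pairwise scan collecting excluded base sets."""
    bases = set()
    for u in truth:
        if u.vclass == "SNP":
            continue
        for v in truth:
            if v is u or v.chrom != u.chrom:
                continue
            if abs(u.start0 - v.start0) <= window - 1:
                lo = min(u.start0, v.start0)
                hi = max(u.end0, v.end0)
                bases |= {(u.chrom, b) for b in range(lo, hi)}
    return bases


class TestBuildExclusions:
    def test_indel_plus_snp_excludes_spanning_interval(self):
        truth = [gb.TruthVariant("c", 100, "ACTG", "A"),  # 3-bp deletion
                 gb.TruthVariant("c", 105, "T", "G")]
        excl = vv.build_exclusions(truth)
        ivs = [(c, s, e) for c, s, e in excl]
        assert ivs == [("c", 99, 105)]  # 0-based span over both footprints

    def test_two_snps_produce_no_exclusion(self):
        truth = [gb.TruthVariant("c", 100, "A", "T"),
                 gb.TruthVariant("c", 105, "C", "G")]
        assert len(vv.build_exclusions(truth)) == 0

    def test_distant_indel_and_snp_not_excluded(self):
        truth = [gb.TruthVariant("c", 100, "AC", "A"),
                 gb.TruthVariant("c", 150, "C", "G")]
        assert len(vv.build_exclusions(truth)) == 0

    def test_random_truth_vs_pairwise_base_oracle(self, rng, small_ref):
        for _ in range(200):
            truth = random_truth_set(rng, small_ref,
                                     n=int(rng.integers(2, 15)),
                                     indel_prob=0.5)
            excl = vv.build_exclusions(truth)
            got = {(c, b) for c, s, e in excl for b in range(s, e)}
            assert got == brute_exclusion_bases(truth)


# ---------------------------------------------------------------------------
# comparison and TN counting
# ---------------------------------------------------------------------------

def as_call(t, quality=60.0, depth=30, genotype=None):
    return gb.CallRecord(t.chrom, t.pos, t.ref, t.alt,
                         genotype=genotype or t.genotype,
                         quality=quality, depth=depth)


def region_base_set(regions):
    return {(c, b) for c, s, e in regions for b in range(s, e)}


def brute_compare(test, truth, regions, exclusions, genotype_aware):
    """Per-base / multiset re-implementation of the comparison."""
    rbases = region_base_set(regions)
    xbases = {(c, b) for c, s, e in (exclusions or []) for b in range(s, e)}

    def evaluable(r):
        fp = {(r.chrom, b) for b in range(r.start0, r.end0)}
        return fp <= rbases and not (fp & xbases)

    t_eval = [t for t in truth if evaluable(t)]
    c_eval = [c for c in test if evaluable(c)]

    def key(r):
        k = (r.chrom, r.pos, r.ref, r.alt)
        return k + (r.genotype,) if genotype_aware else k

    tcount = Counter(key(t) for t in t_eval)
    ccount = Counter(key(c) for c in c_eval)
    tp = sum(min(tcount[k], ccount[k]) for k in tcount)
    return {"tp": tp, "fp": len(c_eval) - tp, "fn": len(t_eval) - tp,
            "excluded_test": len(test) - len(c_eval),
            "excluded_truth": len(truth) - len(t_eval)}


def brute_tn(test, truth, regions):
    rbases = region_base_set(regions)
    covered = set()
    for r in list(test) + list(truth):
        covered |= {(r.chrom, b) for b in range(r.start0, r.end0)}
    return len(rbases - covered)


class TestCompare:
    def test_self_comparison_identity(self, small_ref, small_genome):
        truth = vv.normalize_calls(small_genome.truth, small_ref)
        regions = gb.IntervalSet([(small_ref.name, 0, small_ref.length)])
        test = [as_call(t) for t in truth]
        c = vv.compare(test, truth, regions)
        m = vv.metrics(c)
        assert c.fp_count == c.fn_count == 0
        assert c.tp_count == len(truth)
        assert m.precision == 1.0 and m.sensitivity == 1.0

    def test_dropout_becomes_false_negatives(self, small_ref, small_genome):
        truth = vv.normalize_calls(small_genome.truth, small_ref)
        regions = gb.IntervalSet([(small_ref.name, 0, small_ref.length)])
        k = 5
        test = [as_call(t) for t in truth[k:]]
        c = vv.compare(test, truth, regions)
        assert c.fn_count == k and c.fp_count == 0
        assert c.tp_count == len(truth) - k

    def test_genotype_mismatch_counts_fp_and_fn(self):
        regions = gb.IntervalSet([("c", 0, 1000)])
        truth = [gb.TruthVariant("c", 100, "A", "T", genotype=HET,
                                 haplotype=0)]
        test = [gb.CallRecord("c", 100, "A", "T", genotype=HOM_ALT)]
        c = vv.compare(test, truth, regions, genotype_aware=True)
        assert (c.tp_count, c.fp_count, c.fn_count) == (0, 1, 1)
        c2 = vv.compare(test, truth, regions, genotype_aware=False)
        assert (c2.tp_count, c2.fp_count, c2.fn_count) == (1, 0, 0)

    def test_unnormalized_input_rejected(self):
        regions = gb.IntervalSet([("c", 0, 1000)])
        bad = [gb.CallRecord("c", 100, "CT", "AT")]  # shared suffix
        with pytest.raises(InputError):
            vv.compare(bad, [], regions)

    def test_conservation_identities_on_random_pairs(self, rng, small_ref):
        regions = gb.IntervalSet([(small_ref.name, 0, 10_000)])
        for _ in range(50):
            truth = random_truth_set(rng, small_ref, int(rng.integers(3, 20)))
            truth = [t for t in truth if t.pos < 9_000]
            test = [as_call(t) for t in truth if rng.random() < 0.8]
            c = vv.compare(test, truth, regions)
            assert c.tp_count + c.fn_count == \
                len(truth) - c.excluded_truth_count
            assert c.tp_count + c.fp_count == \
                len(test) - c.excluded_test_count

    def test_random_pairs_vs_per_site_oracle(self, rng, small_ref):
        region_list = [(small_ref.name, 0, 4_000),
                       (small_ref.name, 5_000, 10_000)]
        regions = gb.IntervalSet(region_list)
        n_cases = 0
        while n_cases < 200:
            truth = random_truth_set(rng, small_ref,
                                     n=int(rng.integers(2, 25)),
                                     indel_prob=0.4)
            truth = [t for t in truth if t.pos < 11_000]
            if not truth:
                continue
            n_cases += 1
            excl = vv.build_exclusions(truth)
            # perturb: drop some truth, add shifted/foreign calls
            test = []
            for t in truth:
                r = rng.random()
                if r < 0.6:
                    test.append(as_call(t))
                elif r < 0.75:  # genotype flip
                    other = HOM_ALT if t.genotype == HET else HET
                    test.append(as_call(t, genotype=other))
            for _ in range(int(rng.integers(0, 5))):
                p = int(rng.integers(1, 10_000))
                a = small_ref.sequence[p - 1]
                test.append(gb.CallRecord(small_ref.name, p, a,
                                          "ACGT".replace(a, "")[0],
                                          genotype=HET, quality=10.0))
            test = sorted(test, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
            for aware in (True, False):
                got = vv.compare(test, truth, regions, excl,
                                 genotype_aware=aware)
                want = brute_compare(test, truth, region_list, list(excl),
                                     aware)
                assert got.tp_count == want["tp"]
                assert got.fp_count == want["fp"]
                assert got.fn_count == want["fn"]
                assert got.excluded_test_count == want["excluded_test"]
                assert got.excluded_truth_count == want["excluded_truth"]
                assert got.tn_count == brute_tn(test, truth, region_list)

    def test_enlarging_exclusions_never_increases_fp_or_fn(self, rng,
                                                           small_ref):
        regions = gb.IntervalSet([(small_ref.name, 0, 10_000)])
        truth = random_truth_set(rng, small_ref, 20)
        truth = [t for t in truth if t.pos < 9_000]
        test = [as_call(t) for t in truth if rng.random() < 0.7]
        base = vv.compare(test, truth, regions, None)
        grown = gb.IntervalSet()
        for extra in ([(small_ref.name, 0, 500)],
                      [(small_ref.name, 0, 2_000)],
                      [(small_ref.name, 0, 9_000)]):
            grown = gb.IntervalSet(list(grown) + extra)
            c = vv.compare(test, truth, regions, grown)
            assert c.fp_count <= base.fp_count
            assert c.fn_count <= base.fn_count


class TestCountTrueNegatives:
    def test_no_variants_gives_all_bases(self):
        regions = gb.IntervalSet([("c", 0, 1000)])
        assert vv.count_true_negatives(regions, [], []) == 1000

    def test_single_shared_snp(self):
        regions = gb.IntervalSet([("c", 0, 1000)])
        t = [gb.TruthVariant("c", 500, "A", "T")]
        c = [gb.CallRecord("c", 500, "A", "T")]
        assert vv.count_true_negatives(regions, t, c) == 999

    def test_random_sets_vs_bitmask_oracle(self, rng, small_ref):
        region_list = [(small_ref.name, 100, 2_000),
                       (small_ref.name, 2_500, 4_000)]
        regions = gb.IntervalSet(region_list)
        for _ in range(200):
            truth = random_truth_set(rng, small_ref, int(rng.integers(0, 12)))
            test = [as_call(t) for t in truth if rng.random() < 0.5]
            got = vv.count_true_negatives(regions, truth, test)
            assert got == brute_tn(test, truth, region_list)


class TestMetrics:
    def test_arithmetic_example(self):
        c = vv.VariantComparison(
            tp=[gb.CallRecord("c", i + 1, "A", "T") for i in range(9)],
            fp=[gb.CallRecord("c", 100, "A", "T")],
            fn=[gb.TruthVariant("c", 200, "A", "T")],
            tn_count=990, excluded_test_count=0, excluded_truth_count=0)
        m = vv.metrics(c)
        assert m.precision == pytest.approx(0.9)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(990 / 991)

    def test_undefined_ratios_are_absent(self):
        c = vv.VariantComparison(tp=[], fp=[], fn=[], tn_count=0,
                                 excluded_test_count=0,
                                 excluded_truth_count=0)
        m = vv.metrics(c)
        assert m.precision is None and m.sensitivity is None
        assert m.specificity is None
        assert m.as_dict()["precision_pct"] is None

    def test_random_counts_vs_formula(self, rng):
        for _ in range(100):
            tp, fp, fn = (int(rng.integers(0, 30)) for _ in range(3))
            tn = int(rng.integers(0, 10_000))
            c = vv.VariantComparison(
                tp=[gb.CallRecord("c", i + 1, "A", "T") for i in range(tp)],
                fp=[gb.CallRecord("c", i + 1, "A", "G") for i in range(fp)],
                fn=[gb.TruthVariant("c", i + 1, "A", "C") for i in range(fn)],
                tn_count=tn, excluded_test_count=0, excluded_truth_count=0)
            m = vv.metrics(c)
            assert m.precision == (tp / (tp + fp) if tp + fp else None)
            assert m.sensitivity == (tp / (tp + fn) if tp + fn else None)
            assert m.specificity == (tn / (tn + fp) if tn + fp else None)


# ---------------------------------------------------------------------------
# quality ROC and depth strata
# ---------------------------------------------------------------------------

def make_comparison(rng, n_tp, n_fp, n_fn, tn, q_choices):
    def q():
        v = q_choices[int(rng.integers(0, len(q_choices)))]
        return v
    return vv.VariantComparison(
        tp=[gb.CallRecord("c", i + 1, "A", "T", quality=q(),
                          depth=int(rng.integers(1, 80)))
            for i in range(n_tp)],
        fp=[gb.CallRecord("c", 1000 + i, "A", "G", quality=q(),
                          depth=int(rng.integers(1, 80)))
            for i in range(n_fp)],
        fn=[gb.TruthVariant("c", 2000 + i, "A", "C") for i in range(n_fn)],
        tn_count=tn, excluded_test_count=0, excluded_truth_count=0)


class TestQualityRoc:
    def test_separable_scores(self, rng):
        c = vv.VariantComparison(
            tp=[gb.CallRecord("c", i + 1, "A", "T", quality=100.0)
                for i in range(8)],
            fp=[gb.CallRecord("c", 900 + i, "A", "G", quality=10.0)
                for i in range(2)],
            fn=[gb.TruthVariant("c", 2000, "A", "C")],
            tn_count=500, excluded_test_count=0, excluded_truth_count=0)
        curve = vv.quality_roc(c)
        top = curve.points[0]
        assert top.threshold == 100.0 and top.fpr == 0.0
        assert top.tpr == pytest.approx(8 / 9)

    def test_single_threshold_reproduces_overall_metrics(self, rng):
        c = make_comparison(rng, 5, 3, 2, 400, [30.0])
        curve = vv.quality_roc(c)
        assert len(curve) == 1
        p = curve.points[0]
        assert (p.tp, p.fp, p.fn, p.tn) == (5, 3, 2, 400)

    def test_lowest_threshold_matches_unthresholded_counts(self, rng):
        c = make_comparison(rng, 20, 10, 5, 900, [None, 10.0, 20.0, 30.0])
        last = vv.quality_roc(c).points[-1]
        assert (last.tp, last.fp, last.fn, last.tn) == \
            (c.tp_count, c.fp_count, c.fn_count, c.tn_count)

    def test_random_comparisons_vs_sweep_oracle(self, rng):
        for _ in range(200):
            c = make_comparison(rng, int(rng.integers(0, 15)),
                                int(rng.integers(0, 15)),
                                int(rng.integers(0, 8)),
                                int(rng.integers(0, 2000)),
                                [None, 5.0, 10.0, 20.0, 50.0])
            curve = vv.quality_roc(c)
            NOQ = float("-inf")
            quals = sorted({r.quality if r.quality is not None else NOQ
                            for r in c.tp + c.fp}, reverse=True)
            assert [p.threshold for p in curve] == quals
            for t, p in zip(quals, curve):
                tp = sum((r.quality if r.quality is not None else NOQ) >= t
                         for r in c.tp)
                fp = sum((r.quality if r.quality is not None else NOQ) >= t
                         for r in c.fp)
                assert (p.tp, p.fp) == (tp, fp)
                assert p.fn == c.fn_count + c.tp_count - tp
                assert p.tn == c.tn_count + c.fp_count - fp
                denom_t, denom_f = tp + p.fn, fp + p.tn
                assert p.tpr == (tp / denom_t if denom_t else None)
                assert p.fpr == (fp / denom_f if denom_f else None)


class TestDepthStrata:
    def test_all_calls_in_one_bin(self, rng):
        c = make_comparison(rng, 6, 2, 0, 100, [30.0])
        c = vv.VariantComparison(
            tp=[vv.dataclasses.replace(r, depth=35) for r in c.tp],
            fp=[vv.dataclasses.replace(r, depth=35) for r in c.fp],
            fn=[], tn_count=100, excluded_test_count=0,
            excluded_truth_count=0)
        strata = vv.stratify_by_depth(c, [0, 10, 20, 30, 100])
        loaded = [s for s in strata if s.tp + s.fp]
        assert len(loaded) == 1 and loaded[0].lo == 30
        assert loaded[0].precision == pytest.approx(6 / 8)

    def test_empty_comparison_gives_empty_strata(self):
        c = vv.VariantComparison(tp=[], fp=[], fn=[], tn_count=0,
                                 excluded_test_count=0,
                                 excluded_truth_count=0)
        assert vv.stratify_by_depth(c, [0, 10, 20]) == []

    def test_bad_edges_rejected(self, rng):
        c = make_comparison(rng, 1, 1, 0, 10, [30.0])
        with pytest.raises(InputError):
            vv.stratify_by_depth(c, [10, 10, 20])
        with pytest.raises(InputError):
            vv.stratify_by_depth(c, [30])

    def test_random_depths_vs_binning_oracle(self, rng):
        edges = [0, 10, 25, 40, 80]
        for _ in range(200):
            c = make_comparison(rng, int(rng.integers(0, 20)),
                                int(rng.integers(0, 20)), 0, 10, [30.0])
            strata = vv.stratify_by_depth(c, edges)
            if c.tp_count + c.fp_count == 0:
                assert strata == []
                continue
            for s in strata:
                def inside(r):
                    if s.lo is None:
                        return r.depth is None or not \
                            (edges[0] <= r.depth < edges[-1])
                    return s.lo <= r.depth < s.hi
                assert s.tp == sum(inside(r) for r in c.tp)
                assert s.fp == sum(inside(r) for r in c.fp)
            binned_tp = sum(s.tp for s in strata if s.lo is not None)
            assert binned_tp == sum(
                1 for r in c.tp
                if r.depth is not None and edges[0] <= r.depth < edges[-1])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

class TestVcfIO:
    def test_write_then_load_round_trip(self, tmp_path):
        recs = [gb.CallRecord("c", 10, "A", "T", genotype=HET, quality=50.0,
                              depth=12),
                gb.CallRecord("c", 40, "GT", "G", genotype=HOM_ALT,
                              quality=99.0, depth=33)]
        path = tmp_path / "x.vcf"
        vv.write_calls_vcf(recs, {"c": 1000}, str(path))
        back = vv.load_vcf(str(path))
        assert [(r.chrom, r.pos, r.ref, r.alt, r.genotype, r.depth)
                for r in back] == \
            [(r.chrom, r.pos, r.ref, r.alt, r.genotype, r.depth)
             for r in recs]

    def test_multiallelic_decomposition(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "##contig=<ID=c,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "c\t7\t.\tA\tT,G\t50\tPASS\t.\tGT\t1/2\n")
        back = vv.load_vcf(str(path))
        assert [(r.pos, r.ref, r.alt, r.genotype) for r in back] == \
            [(7, "A", "T", HET), (7, "A", "G", HET)]

    def test_filtered_records_dropped_by_default(self, tmp_path):
        path = tmp_path / "f.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##FILTER=<ID=LowQual,Description=\"low\">\n"
            "##contig=<ID=c,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t7\t.\tA\tT\t50\tLowQual\t.\n"
            "c\t9\t.\tA\tG\t50\tPASS\t.\n")
        assert [r.pos for r in vv.load_vcf(str(path))] == [9]
        assert [r.pos for r in vv.load_vcf(str(path),
                                           include_filtered=True)] == [7, 9]
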