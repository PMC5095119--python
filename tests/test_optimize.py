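import pytest
from hypothesis import given, strategies as st

from germinfer.optimize import (CandidateGermline, FilterMetrics, FilterThresholds,
                                candidate_supports, cohort_metrics, compute_metrics,
                                filter_fp, intersect_individuals, masked_distance,
                                merge_redundant, shm_filter)

from conftest import uniq


def cand(seq, segment="V", support=0, metrics=None, reads=None):
    return CandidateGermline(sequence=seq, segment=segment, support_reads=support,
                             metrics=metrics, cluster_reads=reads or [])


def metrics(ratio1=250.0, ratio2=250.0, rate1=100.0, rate2=100.0, more5=100.0):
    return FilterMetrics(trim5_ratio1=ratio1, trim5_ratio2=ratio2,
                         trim5_rate1=rate1, trim5_rate2=rate2, more5_rate=more5)


class TestComputeMetrics:
    # hand-computed fixture: candidate S with S_trim5 = S[:-5]
    S = "AAACCCGGGTTT"
    READS = uniq([
        (S + "ACGTA", 2),        # contains S and S_trim5; 5-base extension ACGTA
        ("T" + S + "ACGTAGG", 1),  # same, distinct sequence
        (S[:-5] + "TTTTT", 3),   # contains only the trimmed form
        ("GGGGGAAAA", 1),        # contains neither
    ])

    def test_hand_computed_supports_and_ratios(self):
        m = compute_metrics(self.S, self.READS, segment="V", _warn_empty=False)
        assert (m.supp_s_reads, m.supp_s_unique) == (3, 2)
        assert (m.supp_trim5_reads, m.supp_trim5_unique) == (6, 3)
        assert m.trim5_ratio1 == pytest.approx(200.0)  # 2.0-fold, printed x100
        assert m.trim5_ratio2 == pytest.approx(150.0)
        assert m.more5_ext == "ACGTA" and m.supp_more5_unique == 2

    def test_identical_cohort_rates_are_100(self):
        cands = [cand(self.S, reads=self.READS) for _ in range(3)]
        cohort_metrics(cands)
        for c in cands:
            assert c.metrics.trim5_rate1 == pytest.approx(100.0)
            assert c.metrics.trim5_rate2 == pytest.approx(100.0)
            assert c.metrics.more5_rate == pytest.approx(100.0)

    def test_trim_gains_nothing_ratio_is_100(self):
        reads = uniq([(self.S + "AAAAA", 4)])
        m = compute_metrics(self.S, reads, segment="V", _warn_empty=False)
        assert m.trim5_ratio1 == pytest.approx(100.0)  # lower bound: 1.0-fold

    def test_j_candidate_trims_five_prime(self):
        j = "TTTGGGCCCAAA"
        reads = uniq([("AG" + j, 1), ("CT" + j[5:] + "A", 2)])
        m = compute_metrics(j, reads, segment="J", _warn_empty=False)
        assert m.supp_s_reads == 1 and m.supp_trim5_reads == 3

    @given(st.lists(st.tuples(st.text("ACGT", min_size=12, max_size=30),
                              st.integers(1, 5)), min_size=1, max_size=12))
    def test_trim_ratios_never_below_one(self, read_spec):
        reads = uniq(read_spec)
        candidate = reads[0].seq
        m = compute_metrics(candidate, reads, segment="V", _warn_empty=False)
        assert m.trim5_ratio1 >= 100.0 and m.trim5_ratio2 >= 100.0


class TestFilterFP:
    def test_genuine_candidate_retained(self):
        kept, dropped = filter_fp([cand("A" * 10, metrics=metrics())])
        assert len(kept) == 1 and not dropped

    def test_nonspecific_amplification_filtered(self):
        # uniform S_trim5 support = S support -> fold ratio 1.0
        c = cand("A" * 10, metrics=metrics(ratio1=100.0, ratio2=100.0))
        kept, dropped = filter_fp([c])
        assert not kept and dropped[0].status == "fp_filtered"

    def test_zero_thresholds_filter_nothing(self):
        th = FilterThresholds(trim5_ratio=0.0, trim5_rate=0.0,
                              trim5_rate_trbj=0.0, more5_rate=0.0)
        cands = [cand("A" * 10, metrics=metrics()),
                 cand("C" * 10, metrics=metrics(ratio1=100.0, rate1=1.0, more5=6.0))]
        kept, _ = filter_fp(cands, th)
        assert len(kept) == 2

    def test_trbj_rate_override(self):
        c = cand("A" * 10, segment="J", metrics=metrics(rate1=1.0, rate2=1.0))
        assert not filter_fp([c])[0]
        c2 = cand("A" * 10, segment="J", metrics=metrics(rate1=1.0, rate2=1.0))
        assert filter_fp([c2], chain="TRB")[0]

    def test_gates_monotone_in_thresholds(self):
        cands = [cand(s, metrics=metrics(ratio1=r))
                 for s, r in [("A" * 10, 160.0), ("C" * 10, 200.0), ("G" * 10, 400.0)]]
        sizes = []
        for th in (1.5, 1.9, 3.9):
            for c in cands:
                c.status = "live"
            kept, _ = filter_fp(cands, FilterThresholds(trim5_ratio=th))
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)


class TestMerge:
    LONG = "ACGTACGTACGTACGTACGT"

    def test_exact_substring_merged(self):
        a, b = cand(self.LONG, support=10), cand(self.LONG[2:18], support=3)
        out = merge_redundant([a, b], "V")
        assert out == [a]
        assert b.status == "merged" and a.merged_from == [b.sequence]

    def test_two_terminal_mismatches_merged(self):
        w = self.LONG[:12]
        short = w[:10] + ("C" if w[10] != "C" else "G") + ("A" if w[11] != "A" else "T")
        assert sum(1 for x, y in zip(short, w) if x != y) == 2
        a, b = cand(self.LONG, support=10), cand(short, support=2)
        out = merge_redundant([a, b], "V")
        assert out == [a] and b.status == "merged"

    def test_internal_mismatch_not_merged(self):
        w = self.LONG[:12]
        short = w[:3] + ("C" if w[3] != "C" else "G") + w[4:]
        a, b = cand(self.LONG, support=10), cand(short, support=2)
        out = merge_redundant([a, b], "V")
        assert len(out) == 2 and b.status == "live"

    def test_j_mismatch_zone_is_five_prime(self):
        w = self.LONG[4:16]
        short = ("C" if w[0] != "C" else "G") + w[1:]
        a, b = cand(self.LONG, "J", support=10), cand(short, "J", support=2)
        assert merge_redundant([a, b], "J") == [a]
        # the same mismatch is 3'-internal for a V candidate: not merged
        a2, b2 = cand(self.LONG, support=10), cand(short, support=2)
        assert len(merge_redundant([a2, b2], "V")) == 2


class TestShmFilter:
    BASE = "ACGTACGTACGTACGTACGTACGTACGTAC"

    def variant(self, k):
        s = list(self.BASE)
        s[5 + k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[5 + k]]
        return "".join(s)

    def test_high_ratio_member_dropped(self):
        center = cand(self.BASE, support=1000)
        member = cand(self.variant(0), support=50)  # Ratio = 20
        retained = shm_filter([center, member], "V")
        assert retained == [center] and member.status == "shm_filtered"
        assert member.ratio_to_center == pytest.approx(20.0)

    def test_two_alleles_both_retained(self):
        center = cand(self.BASE, support=100)
        member = cand(self.variant(0), support=60)  # Ratio 1.67
        retained = shm_filter([center, member], "V")
        assert len(retained) == 2
        assert center.status == member.status == "retained"

    def test_at_most_two_per_group(self):
        center = cand(self.BASE, support=600)
        m1 = cand(self.variant(0), support=300)  # ratio 2
        m2 = cand(self.variant(1), support=200)  # ratio 3
        retained = shm_filter([center, m2, m1], "V")
        seqs = {c.sequence for c in retained}
        assert seqs == {self.BASE, self.variant(0)}
        assert m2.status == "shm_filtered"

    def test_distant_sequences_get_own_groups(self):
        a = cand(self.BASE, support=100)
        b = cand(self.BASE[::-1], support=90)
        retained = shm_filter([a, b], "V")
        assert len(retained) == 2
        assert a.group_id != b.group_id
        assert a.is_major and b.is_major


class TestMaskedDistance:
    def test_terminal_mask_v(self):
        a = "ACGTACGTAC"
        b = a[:-1] + ("G" if a[-1] != "G" else "T")
        assert masked_distance(a, b, "V") == 0  # 3' mismatch masked
        assert masked_distance(a, b, "J") == 1

    def test_offset_alignment_groups_fragments(self):
        full = "ACGTTGCAACGGTACCGGTAACGTTGCAAC"
        frag = full[4:24]
        assert masked_distance(full, frag, "V") == 0


class TestIntersect:
    def test_occurrence_counts_and_filter(self):
        s1 = [cand("AAAA"), cand("CCCC")]
        s2 = [cand("AAAA"), cand("GGGG")]
        s3 = [cand("AAAA")]
        occ = intersect_individuals([s1, s2, s3], min_samples=2)
        assert occ == {"AAAA": 3, "CCCC": 1, "GGGG": 1}
        assert s1[0].sample_occurrence == 3
        assert s1[1].status == "shm_filtered"

    def test_single_sample_passthrough(self):
        s1 = [cand("AAAA")]
        intersect_individuals([s1], min_samples=1)
        assert s1[0].status == "live"
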