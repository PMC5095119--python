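import numpy as np
import pytest

from germinfer.assembly import (DEFAULT_THRESHOLDS, ExtensionPath, PositionTree,
                                SUPPORT_WINDOW, ar, assemble, build_tree, ur)
from germinfer.preprocess import UniqueRead
from germinfer.seedclust import Cluster, extract_clusters

from conftest import uniq


def make_cluster(seqs_with_counts, seed):
    unique = uniq(seqs_with_counts)
    return Cluster(seed=seed, members=[(u, u.seq.find(seed)) for u in unique], score=0.0)


def seed_path(tree):
    return ExtensionPath(sequence=tree.seed, left=0, right=tree.k, steps=[])


class TestWorkedExample:
    def test_ar_reads_fraction(self, worked_cluster):
        tree = build_tree(worked_cluster)
        assert ar(tree, seed_path(tree), 4, "A") == pytest.approx(3 / 7)

    def test_ur_unique_fraction(self, worked_cluster):
        tree = build_tree(worked_cluster)
        assert ur(tree, seed_path(tree), 4, "A") == pytest.approx(2 / 6)

    def test_unsupported_base_zero(self, worked_cluster):
        tree = build_tree(worked_cluster)
        # every covering read shows A/C/G/T; a base absent at the position
        path = seed_path(tree)
        total = sum(ar(tree, path, 4, b) for b in "ACGT")
        assert total == pytest.approx(1.0)

    def test_no_coverage_returns_none(self, worked_cluster):
        tree = build_tree(worked_cluster)
        assert ar(tree, seed_path(tree), 40, "A") is None


class TestTree:
    def test_counts_and_coverage(self, worked_cluster):
        tree = build_tree(worked_cluster)
        assert tree.coverage[4] == (7, 6)
        assert tree.branches[4]["A"] == (3, 2)

    def test_single_read_single_branch(self):
        tree = build_tree(make_cluster([("ACGTACG", 1)], "CGTA"))
        for p, branches in tree.branches.items():
            assert len(branches) == 1
            assert list(branches.values())[0] == (1, 1)

    def test_offset_alignment_on_seed(self):
        # same seed at different offsets: relative coordinates line up
        tree = build_tree(make_cluster([("TTACGTA", 1), ("ACGTAGG", 1)], "ACGTA"))
        assert tree.coverage[0] == (2, 2)  # both cover the seed start
        assert tree.coverage[-2] == (1, 1)  # only the first read extends left
        assert tree.coverage[6] == (1, 1)  # only the second extends right

    def test_member_missing_seed_rejected(self):
        bad = Cluster(seed="AAAA", members=[(UniqueRead("CCCCC", 1), 0)], score=0)
        with pytest.raises(ValueError):
            build_tree(bad)


def oracle_paths(tree, segment, th_ar, th_ur, min_extend_cov, min_branch_unique,
                 window=SUPPORT_WINDOW):
    """Exhaustive enumeration of maximal gate-passing extensions, computing
    every support fraction definitionally (independent of the incremental
    bookkeeping in assemble)."""
    order = ("R", "L") if segment == "V" else ("L", "R")
    out = []

    def supports(left, right, sequence, i, b):
        reads = uu = 0
        win = (range(max(left, i - window + 1), right) if i >= right
               else range(left, min(right, i + window)))
        for seq, off, count in tree.members:
            if not (-off <= i < len(seq) - off) or seq[i + off] != b:
                continue
            if all(seq[p + off] == sequence[p - left]
                   for p in win if -off <= p < len(seq) - off):
                reads += count
                uu += 1
        return reads, uu

    def go(left, right, sequence, phase):
        i = right if order[phase] == "R" else left - 1
        cov = tree.coverage.get(i, (0, 0))
        accepted = []
        if cov[0] >= min_extend_cov:
            for b in "ACGT":
                r, u = supports(left, right, sequence, i, b)
                if r / cov[0] > th_ar and u / cov[1] > th_ur and u >= min_branch_unique:
                    accepted.append(b)
        if not accepted:
            if phase + 1 < 2:
                go(left, right, sequence, phase + 1)
            else:
                out.append(sequence)
            return
        for b in accepted:
            if order[phase] == "R":
                go(left, right + 1, sequence + b, phase)
            else:
                go(left - 1, right, b + sequence, phase)

    go(0, tree.k, tree.seed, 0)
    return sorted(out)


class TestAssemble:
    def test_noiseless_cluster_single_path(self):
        seq = "ACGTTGCAACGGTACCGGTA"
        tree = build_tree(make_cluster([(seq, 100)], "TGCAACG"))
        paths = assemble(tree, segment="V", min_branch_unique=1, min_extend_cov=1)
        assert [p.sequence for p in paths] == [seq]
        assert paths[0].support_reads == 100

    def test_two_alleles_branch_at_site(self):
        # 50/50 mixture differing at one downstream site -> two paths
        a = "ACGTACGTCCGGTTAAGGCC"
        b = a[:14] + "C" + a[15:]
        tree = build_tree(make_cluster([(a, 30), (b, 30)], "ACGTACGT"))
        paths = assemble(tree, segment="V", min_branch_unique=1, min_extend_cov=1)
        assert sorted(p.sequence for p in paths) == sorted([a, b])

    def test_low_frequency_variant_suppressed(self):
        a = "ACGTACGTCCGGTTAAGGCC"
        b = a[:14] + "C" + a[15:]
        tree = build_tree(make_cluster([(a, 95), (b, 5)], "ACGTACGT"))
        paths = assemble(tree, segment="V", min_branch_unique=1, min_extend_cov=1)
        assert [p.sequence for p in paths] == [a]

    @pytest.mark.parametrize("instance_seed", [0, 1, 2, 3, 4, 5])
    def test_matches_exhaustive_oracle(self, instance_seed):
        rng = np.random.default_rng(instance_seed)
        bases = np.array(list("ACGT"))
        template = "".join(rng.choice(bases, 26))
        seed = template[8:14]
        seqs = {}
        for _ in range(8):
            lo = int(rng.integers(0, 6))
            hi = int(rng.integers(18, 27))
            s = list(template[lo:hi])
            if rng.random() < 0.7:
                p = int(rng.integers(0, len(s)))
                s[p] = str(rng.choice(bases))
            s = "".join(s)
            if seed in s:
                seqs[s] = seqs.get(s, 0) + int(rng.integers(1, 4))
        if not seqs:
            pytest.skip("degenerate instance")
        cluster = make_cluster(list(seqs.items()), seed)
        tree = build_tree(cluster)
        for segment in ("V", "J"):
            th_a, th_u = DEFAULT_THRESHOLDS[segment]
            got = sorted(p.sequence for p in assemble(
                tree, segment=segment, min_extend_cov=1, min_branch_unique=1))
            want = oracle_paths(tree, segment, th_a, th_u, 1, 1)
            assert got == want

    def test_emitted_paths_replay_through_gates(self, worked_cluster):
        tree = build_tree(worked_cluster)
        th_a, th_u = DEFAULT_THRESHOLDS["V"]
        paths = assemble(tree, segment="V", min_extend_cov=1, min_branch_unique=1)
        assert paths
        for final in paths:
            replay = ExtensionPath(sequence=tree.seed, left=0, right=tree.k, steps=[])
            for (i, b, a_rec, u_rec) in final.steps:
                a = ar(tree, replay, i, b)
                u = ur(tree, replay, i, b)
                assert a == pytest.approx(a_rec) and u == pytest.approx(u_rec)
                assert a > th_a and u > th_u
                if i >= replay.right:
                    replay = ExtensionPath(replay.sequence + b, replay.left, i + 1, [])
                else:
                    replay = ExtensionPath(b + replay.sequence, i, replay.right, [])
            assert replay.sequence == final.sequence

    def test_random_shm_filtered_truth_recovered(self):
        # one 100 bp segment, 200 reads, 5% random per-base mutation: the
        # unmutated sequence is recovered via clustering + assembly
        for run_seed in range(5):
            rng = np.random.default_rng(run_seed)
            bases = np.array(list("ACGT"))
            truth = "".join(rng.choice(bases, 100))
            raw = []
            for _ in range(200):
                s = list(truth)
                hits = np.flatnonzero(rng.random(100) < 0.05)
                for p in hits:
                    s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
                raw.append("".join(s))
            reads = uniq([(s, 1) for s in set(raw)])
            clusters, _ = extract_clusters(reads, 30, "V", min_cluster_reads=5)
            assert clusters
            paths = assemble(build_tree(clusters[0]), segment="V")
            assert truth in [p.sequence for p in paths]

    def test_max_paths_pruning(self):
        # an adversarial cluster with a 2-way fork at many positions
        rng = np.random.default_rng(3)
        base = "ACGTACGT" + "".join(rng.choice(np.array(list("ACGT")), 12))
        variants = {}
        for mask in range(16):
            s = list(base)
            for bit in range(4):
                if mask >> bit & 1:
                    p = 9 + 2 * bit
                    s[p] = "A" if s[p] != "A" else "C"
            variants["".join(s)] = 10
        tree = build_tree(make_cluster(list(variants.items()), "ACGTACGT"))
        paths = assemble(tree, segment="V", min_extend_cov=1, min_branch_unique=1,
                         max_paths=4)
        assert len(paths) <= 4
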