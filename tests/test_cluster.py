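"""Windows, subsampling, Levenshtein, UPGMA, subcluster detection, consensus."""

import itertools

import numpy as np
import pytest

from vgerm.assign import VJAssignment
from vgerm.cluster import (
    DendrogramNode,
    consensus,
    detect_subclusters,
    distance_matrix,
    levenshtein,
    subsample,
    upgma,
    windowed_clusters,
)

BASES = "ACGT"


def levenshtein_oracle(a, b):
    """Plain quadratic edit-distance DP, independent of edlib."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def average_linkage_oracle(d):
    """Brute-force UPGMA: repeatedly merge the closest pair of clusters,
    recomputing inter-cluster means from the raw matrix each time."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            m = np.mean([d[i, j] for i in clusters[x] for j in clusters[y]])
            if best is None or m < best[0]:
                best = (m, x, y)
        m, x, y = best
        heights.append(m)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return sorted(heights)


def _wa(pct, seq, count=1, name="V"):
    return VJAssignment(query_id=f"q{pct}{seq[:4]}", v_name=name,
                        v_percent_difference=pct, v_sequence=seq, count=count)


class TestWindows:
    def test_half_open_bin_edges(self):
        asn = [_wa(0.0, "AAAA"), _wa(1.9, "AAAC"), _wa(2.0, "AACC"), _wa(3.5, "ACCC")]
        out = windowed_clusters(asn, width_percent=2, min_members=1)
        assert [(w.interval, w.n_unique) for w in out] == [
            ((0.0, 2.0), 2), ((2.0, 4.0), 2)
        ]

    def test_empty_input(self):
        assert windowed_clusters([]) == []

    def test_min_members_applied(self):
        asn = [_wa(0.5, f"AAA{b}") for b in "ACGT"]
        assert windowed_clusters(asn, min_members=5) == []
        assert len(windowed_clusters(asn, min_members=4)) == 1

    def test_bins_partition_reads(self):
        rng = np.random.default_rng(4)
        asn = [_wa(float(p), f"{k:08d}")
               for k, p in enumerate(rng.uniform(0, 30, 200))]
        out = windowed_clusters(asn, min_members=1)
        assert sum(w.n_unique for w in out) == len({a.v_sequence for a in asn})
        for w in out:
            lo, hi = w.interval
            assert hi - lo == 2

    def test_mixed_alleles_rejected(self):
        with pytest.raises(ValueError):
            windowed_clusters([_wa(0, "AAAA", name="V1"), _wa(0, "CCCC", name="V2")])


class TestSubsample:
    def test_small_input_identity(self):
        asn = [_wa(0, "AAAA")] * 500
        assert subsample(asn, 1000, seed=0) == asn

    def test_seed_determinism(self):
        asn = [_wa(float(i), f"{i:06d}") for i in range(50)]
        assert subsample(asn, 10, seed=7) == subsample(asn, 10, seed=7)

    def test_uniform_inclusion(self):
        # inclusion frequency of each element close to n/N over many seeds
        asn = [_wa(float(i), f"{i:04d}") for i in range(200)]
        counts = np.zeros(200)
        n_seeds = 100
        for s in range(n_seeds):
            for a in subsample(asn, 20, seed=s):
                counts[int(a.v_percent_difference)] += 1
        p = 20 / 200
        sd = np.sqrt(n_seeds * p * (1 - p))
        # 99% binomial band (~2.6 sd) with a small slack for 200 parallel tests
        assert np.all(np.abs(counts - n_seeds * p) <= 3.5 * sd)


class TestLevenshtein:
    def test_identity_and_single_ops(self):
        assert levenshtein("ACGT", "ACGT") == 0
        assert levenshtein("ACGT", "AGT") == 1
        assert levenshtein("", "ACG") == 3

    def test_matches_dp_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            a = "".join(BASES[i] for i in rng.integers(0, 4, rng.integers(0, 61)))
            b = "".join(BASES[i] for i in rng.integers(0, 4, rng.integers(0, 61)))
            assert levenshtein(a, b) == levenshtein_oracle(a, b)

    def test_metric_properties(self):
        rng = np.random.default_rng(37)
        seqs = ["".join(BASES[i] for i in rng.integers(0, 4, 30)) for _ in range(8)]
        for a, b, c in itertools.combinations(seqs, 3):
            assert levenshtein(a, b) == levenshtein(b, a)
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestUPGMA:
    def test_two_points(self):
        tree = upgma(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert tree.height == 3.0
        assert sorted(tree.leaves) == [0, 1]

    def test_three_points_closed_form(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma(d)
        inner = tree.left if not tree.left.is_leaf else tree.right
        assert inner.height == 2.0
        assert tree.height == 8.0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(41)
        for trial in range(100):
            n = int(rng.integers(3, 13))
            m = rng.uniform(0.1, 10, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma(d)
            heights = []

            def collect(node):
                if not node.is_leaf:
                    heights.append(node.height)
                    collect(node.left)
                    collect(node.right)

            collect(tree)
            assert np.allclose(sorted(heights), average_linkage_oracle(d))

    def test_monotone_heights(self):
        rng = np.random.default_rng(43)
        m = rng.uniform(0, 5, size=(15, 15))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)

        def check(node):
            if node.is_leaf:
                return
            for child in (node.left, node.right):
                assert child.height <= node.height + 1e-12
                check(child)

        check(upgma(d))


def _bundle_matrix(sizes, within, between):
    """Block matrix: tight bundles at distance ``within``, ``between`` across."""
    n = sum(sizes)
    d = np.full((n, n), float(between))
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestSubclusters:
    def test_two_tight_bundles_both_reported(self):
        # identical-ish bundles: internal heights <= 1 with an even tighter
        # pair inside each, joined at height 10
        d = _bundle_matrix([6, 6], within=1.0, between=10.0)
        d[0, 1] = d[1, 0] = 0.5
        d[6, 7] = d[7, 6] = 0.5
        tree = upgma(d)
        out = detect_subclusters(tree, min_size=5, ratio_threshold=0.8)
        leaf_sets = sorted(tuple(c.member_indices) for c in out)
        assert leaf_sets == [tuple(range(6)), tuple(range(6, 12))]

    def test_star_tree_no_subcluster(self):
        d = _bundle_matrix([10], within=5.0, between=5.0)
        tree = upgma(d)
        assert detect_subclusters(tree, min_size=5, ratio_threshold=0.8) == []

    def test_small_side_not_considered(self):
        # bundle of 4 + bundle of 6: the only separating node has a side < 5
        d = _bundle_matrix([4, 6], within=1.0, between=10.0)
        tree = upgma(d)
        out = detect_subclusters(tree, min_size=5, ratio_threshold=0.8)
        assert all(len(c.member_indices) >= 5 for c in out)
        assert tuple(range(4)) not in {tuple(c.member_indices) for c in out}

    def test_disjoint_leaf_sets(self):
        rng = np.random.default_rng(47)
        m = rng.uniform(0, 10, size=(30, 30))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        out = detect_subclusters(upgma(d), min_size=5, ratio_threshold=0.8)
        seen = set()
        for c in out:
            assert not (seen & set(c.member_indices))
            seen |= set(c.member_indices)


class TestConsensus:
    def test_identical_members(self):
        assert consensus(["ACGTACGT"] * 10) == "ACGTACGT"

    def test_sixty_percent_threshold_inclusive(self):
        members = ["A"] * 6 + ["G"] * 4
        assert consensus(members) == "A"

    def test_below_majority_gives_n(self):
        members = ["A"] * 5 + ["G"] * 5
        assert consensus(members) == "N"

    def test_counts_weight_votes(self):
        assert consensus(["A", "G"], counts=[6, 4]) == "A"
        assert consensus(["A", "G"], counts=[5, 5]) == "N"

    def test_matches_exhaustive_column_vote(self):
        # pre-aligned equal-length members: consensus must equal a direct
        # per-column tally
        rng = np.random.default_rng(53)
        base = "".join(BASES[i] for i in rng.integers(0, 4, 40))
        members = []
        for _ in range(20):
            s = list(base)
            for pos in rng.choice(40, size=2, replace=False):
                s[pos] = BASES[int(rng.integers(4))]
            members.append("".join(s))
        expected = []
        for col in range(40):
            tally = {}
            for m in members:
                tally[m[col]] = tally.get(m[col], 0) + 1
            base_b, w = max(sorted(tally.items()), key=lambda kv: kv[1])
            expected.append(base_b if w >= 0.6 * len(members) else "N")
        assert consensus(members) == "".join(expected)

    def test_single_allele_cluster_recovers_truth(self):
        # >= 20 members with <= 1% independent error each: consensus equals
        # the true sequence exactly, across seeds
        truth = "ACGT" * 25
        for seed in range(5):
            rng = np.random.default_rng(seed)
            members = []
            for _ in range(25):
                s = list(truth)
                for pos in range(len(s)):
                    if rng.random() < 0.01:
                        s[pos] = BASES[int(rng.integers(4))]
                members.append("".join(s))
            assert consensus(members) == truth

    def test_gap_majority_column_deleted(self):
        members = ["ACGT"] * 3 + ["ACGGT"] * 2  # minority insertion
        assert consensus(members) == "ACGT"

    def test_distance_matrix_symmetric_zero_diag(self):
        seqs = ["ACGT", "AGGT", "TTTT"]
        d = distance_matrix(seqs)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d[0, 1] == 1
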