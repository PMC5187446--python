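"""Preprocessing: merging, primer trimming, length filter, dereplication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vgerm.preprocess import (
    MergeFailure,
    PreprocessConfig,
    dereplicate,
    length_filter,
    merge_read_pair,
    preprocess,
    trim_primers,
)
from vgerm.records import SequenceRecord, reverse_complement

BASES = "ACGT"


def rec(seq, **kw):
    return SequenceRecord(id=kw.pop("id", "r"), sequence=seq, **kw)


def make_pair(amplicon: str, read_len: int, rng, error_rate: float = 0.0):
    """Cut a 2x``read_len`` pair from an amplicon, reverse read in sequencer
    orientation, with independent substitution errors."""
    def noisy(s):
        out = list(s)
        for i in range(len(out)):
            if rng.random() < error_rate:
                out[i] = BASES[(BASES.index(out[i]) + 1 + rng.integers(3)) % 4]
        return "".join(out)

    fwd = noisy(amplicon[:read_len])
    rev = noisy(reverse_complement(amplicon[-read_len:]))
    return rec(fwd, id="f"), rec(rev, id="rv")


class TestMerge:
    def test_exact_overlap(self):
        # fwd=ACGTACGT, reverse-complemented reverse=ACGTTTTT, overlap ACGT
        cfg = PreprocessConfig(min_overlap=4, max_overlap_mismatch_fraction=0.0)
        fwd = rec("ACGTACGT")
        rev = rec(reverse_complement("ACGTTTTT"))
        merged = merge_read_pair(fwd, rev, cfg)
        assert merged.sequence == "ACGTACGTTTTT"

    def test_no_overlap_fails(self):
        cfg = PreprocessConfig(min_overlap=8)
        with pytest.raises(MergeFailure):
            merge_read_pair(rec("AAAACCCC"), rec(reverse_complement("GGGGTTTT")), cfg)

    def test_quality_resolves_disagreement(self):
        cfg = PreprocessConfig(min_overlap=4, max_overlap_mismatch_fraction=0.3)
        fwd = rec("AACCGGTT", qualities=[10] * 8)
        # overlap GGTT vs GCTT, reverse base C has higher quality
        rev_seq = reverse_complement("GCTTACGT")
        rev = rec(rev_seq, qualities=[40] * 8)
        merged = merge_read_pair(fwd, rev, cfg)
        assert merged.sequence == "AACCGCTTACGT"

    def test_forward_wins_without_qualities(self):
        cfg = PreprocessConfig(min_overlap=4, max_overlap_mismatch_fraction=0.3)
        merged = merge_read_pair(
            rec("AACCGGTT"), rec(reverse_complement("GCTTACGT")), cfg
        )
        assert merged.sequence == "AACCGGTTACGT"

    def test_error_free_pairs_merge_exactly(self):
        rng = np.random.default_rng(11)
        cfg = PreprocessConfig(min_overlap=16)
        for _ in range(50):
            amplicon = "".join(BASES[i] for i in rng.integers(0, 4, 550))
            fwd, rev = make_pair(amplicon, 300, rng)
            assert merge_read_pair(fwd, rev, cfg).sequence == amplicon

    def test_simulated_pairs_recover_amplicons(self):
        # 500 pairs of 2x300 from 550 nt amplicons at 0.3% per-base error:
        # >= 99% merge, and merged sequences stay close to their truth
        # amplicons (a read carries ~1.7 errors on average, so a small
        # fraction legitimately exceeds edit distance 4)
        import edlib

        rng = np.random.default_rng(11)
        cfg = PreprocessConfig(min_overlap=16)
        n_ok = 0
        n_close = 0
        for _ in range(500):
            amplicon = "".join(BASES[i] for i in rng.integers(0, 4, 550))
            fwd, rev = make_pair(amplicon, 300, rng, error_rate=0.003)
            try:
                merged = merge_read_pair(fwd, rev, cfg)
            except MergeFailure:
                continue
            d = edlib.align(merged.sequence, amplicon, mode="NW",
                            task="distance")["editDistance"]
            assert d <= 10
            n_ok += 1
            n_close += d <= 4
        assert n_ok >= 495  # >= 99% merge rate
        # expected P(edit distance <= 4) ~ 0.975 for Poisson(1.65) errors
        assert n_close / n_ok >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        amplicon = "".join(BASES[i] for i in rng.integers(0, 4, 500))
        fwd, rev = make_pair(amplicon, 300, rng, error_rate=0.01)
        cfg = PreprocessConfig(min_overlap=16)
        a = merge_read_pair(fwd, rev, cfg)
        b = merge_read_pair(fwd, rev, cfg)
        assert a.sequence == b.sequence


class TestTrimPrimers:
    def test_exact_prefix_removed(self):
        cfg = PreprocessConfig(primers_5p=("ACGTACGT",))
        out = trim_primers(rec("ACGTACGT" + "TTTTGGGG"), cfg)
        assert out.sequence == "TTTTGGGG"

    def test_no_primers_identity(self):
        r = rec("ACGTACGTACGT")
        assert trim_primers(r, PreprocessConfig()) is r

    def test_one_mismatch_in_twenty_tolerated(self):
        primer = "ACGTACGTACGTACGTACGT"  # 20 nt -> 2 mismatches allowed
        mismatched = "TCGTACGTACGTACGTACGT"
        cfg = PreprocessConfig(primers_5p=(primer,))
        out = trim_primers(rec(mismatched + "GGGG"), cfg)
        assert out.sequence == "GGGG"

    def test_too_many_mismatches_left_alone(self):
        primer = "ACGTACGTAC"  # 10 nt -> 1 mismatch allowed
        seq = "TTGTACGTAC" + "GGGG"
        cfg = PreprocessConfig(primers_5p=(primer,))
        assert trim_primers(rec(seq), cfg).sequence == seq

    def test_3p_primer(self):
        cfg = PreprocessConfig(primers_3p=("CCCCAAAA",))
        out = trim_primers(rec("GGGG" + "CCCCAAAA"), cfg)
        assert out.sequence == "GGGG"


class TestLengthFilter:
    def test_threshold_300_inclusive(self):
        recs = [rec("A" * n, id=str(n)) for n in (299, 300, 301)]
        kept = length_filter(recs, PreprocessConfig(min_length=300))
        assert [r.id for r in kept] == ["300", "301"]

    def test_zero_is_identity(self):
        recs = [rec("A"), rec("AC")]
        assert length_filter(recs, PreprocessConfig(min_length=0)) == recs

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(7)
        recs = [rec("A" * int(n), id=str(i))
                for i, n in enumerate(rng.integers(250, 350, 1000))]
        kept = length_filter(recs, PreprocessConfig(min_length=300))
        assert len(kept) == sum(1 for r in recs if len(r.sequence) >= 300)


class TestDereplicate:
    def test_counts_and_order(self):
        out = dereplicate([rec("AAAA", id="a"), rec("AAAA", id="b"), rec("CCCC", id="c")])
        assert [(r.sequence, r.count, r.id) for r in out] == [
            ("AAAA", 2, "a"), ("CCCC", 1, "c")
        ]

    def test_all_unique_identity(self):
        recs = [rec("AAAA"), rec("CCCC"), rec("GGGG")]
        out = dereplicate(recs)
        assert [(r.sequence, r.count) for r in out] == [
            (r.sequence, 1) for r in recs
        ]

    def test_counts_match_hash_map(self):
        rng = np.random.default_rng(13)
        pool = ["".join(BASES[i] for i in rng.integers(0, 4, 20)) for _ in range(50)]
        seqs = [pool[i] for i in rng.integers(0, 50, 2000)]
        out = dereplicate([rec(s, id=str(i)) for i, s in enumerate(seqs)])
        expected = {}
        for s in seqs:
            expected[s] = expected.get(s, 0) + 1
        assert {r.sequence: r.count for r in out} == expected

    @given(st.lists(st.sampled_from(["AAAA", "CCCC", "GGGG", "TTTT"]),
                    min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_count_conservation(self, seqs):
        out = dereplicate([rec(s, id=str(i)) for i, s in enumerate(seqs)])
        assert sum(r.count for r in out) == len(seqs)

    def test_commutes_with_length_filter(self):
        rng = np.random.default_rng(3)
        pool = ["A" * int(n) for n in rng.integers(295, 305, 10)]
        recs = [rec(pool[i], id=str(k)) for k, i in enumerate(rng.integers(0, 10, 200))]
        cfg = PreprocessConfig(min_length=300)
        a = {(r.sequence, r.count)
             for r in length_filter(dereplicate(recs), cfg)}
        b = {(r.sequence, r.count)
             for r in dereplicate(length_filter(recs, cfg))}
        assert a == b


def test_pipeline_drops_n_rich_reads():
    good = rec("ACGT" * 80, id="good")
    bad = rec("N" * 40 + "ACGT" * 70, id="bad")  # 12.5% N
    out, log = preprocess(records=[good, bad],
                          config=PreprocessConfig(min_length=300))
    assert [r.id for r in out] == ["good"]
    assert log["n_filtered"] == 1
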