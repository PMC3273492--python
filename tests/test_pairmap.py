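"""Tests for the exact k-mer index and mate-pair mapping engine."""

import numpy as np
import pandas as pd
import pytest

from csbl import pairmap, tagsim
from csbl.pairmap import KmerHashIndex, build_index, map_all, map_pair
from csbl.tagsim import ReferenceGenome, RepeatFamily, SimConfig, revcomp
from conftest import brute_force_lookup, brute_force_pair_placements


class TestBuildIndex:
    def test_tiny_enumeration(self):
        ref = ReferenceGenome({"s": "ACGT"})
        idx = build_index(ref, 2)
        assert [h for h in idx.lookup("AC") if h[2] == "+"] == [("s", 0, "+")]
        assert [h for h in idx.lookup("CG") if h[2] == "+"] == [("s", 1, "+")]
        assert [h for h in idx.lookup("GT") if h[2] == "+"] == [("s", 2, "+")]

    def test_homopolymer_starts(self):
        ref = ReferenceGenome({"s": "AAAA"})
        idx = build_index(ref, 2)
        plus = [h for h in idx.lookup("AA") if h[2] == "+"]
        assert [s for _, s, _ in plus] == [0, 1, 2]

    def test_n_windows_excluded(self):
        ref = ReferenceGenome({"s": "ANGT"})
        idx = build_index(ref, 2)
        assert [h for h in idx.lookup("AN" if False else "GT") if h[2] == "+"] == [("s", 2, "+")]
        # windows containing the N are absent entirely
        assert len(idx.sorted_hashes) == 1

    def test_minus_strand_lookup(self):
        ref = ReferenceGenome({"s": "ACGTTT"})
        idx = build_index(ref, 3)
        hits = idx.lookup("AAA")  # revcomp TTT at start 3
        assert ("s", 3, "-") in hits

    def test_k_larger_than_all_sequences(self):
        with pytest.raises(ValueError, match="larger"):
            build_index(ReferenceGenome({"s": "ACGT"}), 5)

    def test_wrong_tag_length(self):
        idx = build_index(ReferenceGenome({"s": "ACGTACGT"}), 4)
        with pytest.raises(ValueError, match="length"):
            idx.lookup("ACGTA")

    def test_multi_sequence_no_spanning_windows(self):
        ref = ReferenceGenome({"a": "AAAA", "b": "CCCC"})
        idx = build_index(ref, 3)
        assert all(h[0] == "a" for h in idx.lookup("AAA") if h[2] == "+")
        assert all(h[0] == "b" for h in idx.lookup("CCC") if h[2] == "+")
        # nothing maps across the boundary
        assert [h for h in idx.lookup("AAC") if h[2] == "+"] == []


class TestLookupOracle:
    def test_matches_brute_force_scan(self):
        """Index lookups agree exactly with a sliding-window scan on random
        repeat-bearing genomes."""
        rng = np.random.default_rng(21)
        for trial in range(5):
            ref = tagsim.synth_genome(
                3000, 0.5, [RepeatFamily(4, 100)], seed=int(rng.integers(2**31))
            )
            idx = build_index(ref, 13)
            seq = ref.sequences["synth1"]
            for _ in range(100):
                s = int(rng.integers(0, len(seq) - 13))
                tag = seq[s:s + 13] if rng.random() < 0.5 else revcomp(seq[s:s + 13])
                assert sorted(idx.lookup(tag)) == brute_force_lookup(ref, tag)

    def test_absent_tag_empty(self):
        ref = ReferenceGenome({"s": "A" * 100})
        idx = build_index(ref, 13)
        assert idx.lookup("ACGTACGTACGTA") == []

    def test_planted_repeat_multiplicity(self):
        ref = tagsim.synth_genome(10_000, 0.5, [RepeatFamily(5, 500)], seed=22)
        seq = ref.sequences["synth1"]
        # find a 13-mer inside the planted repeat (occurs >= 5 times)
        from collections import Counter

        counts = Counter(seq[i:i + 500] for i in range(len(seq) - 499))
        rep, n = counts.most_common(1)[0]
        assert n >= 5
        idx = build_index(ref, 13)
        inner = rep[200:213]
        assert len(idx.lookup(inner)) >= 5


class TestMapPair:
    def test_unique_pair_recovers_truth(self):
        ref = tagsim.synth_genome(10_000, 0.5, None, seed=23)
        cfg = SimConfig(tag_length=13, seed=24)
        pairs = tagsim.sample_pairs(ref, "synth1", cfg, n_pairs=50)
        idx = build_index(ref, 13)
        for pair in pairs.itertuples():
            out = map_pair(idx, pair)
            assert out.status == "unique"
            p = out.placement
            assert (p.start1, p.start2, p.strand, p.separation) == (
                pair.start1, pair.start2, pair.strand, pair.separation
            )

    def test_pair_inside_long_exact_repeat_is_multi(self):
        # repeat longer than insert_max + 2 tags: both tags can sit in either copy
        ref = tagsim.synth_genome(20_000, 0.5, [RepeatFamily(2, 1000)], seed=25)
        seq = ref.sequences["synth1"]
        from collections import Counter

        counts = Counter(seq[i:i + 1000] for i in range(len(seq) - 999))
        rep, n = counts.most_common(1)[0]
        assert n == 2
        tag1, tag2 = rep[10:23], rep[410:423]

        class P:
            pair_id, tag1_, tag2_ = 0, tag1, tag2
        pair = type("pair", (), {"pair_id": 0, "tag1": tag1, "tag2": tag2})
        out = map_pair(build_index(ref, 13), pair, 300, 700)
        assert out.status == "multi"
        assert len(out.placements) >= 2

    def test_mutated_tag_unmapped(self):
        ref = tagsim.synth_genome(10_000, 0.5, None, seed=26)
        cfg = SimConfig(tag_length=13, seed=27)
        pair = tagsim.sample_pairs(ref, "synth1", cfg, n_pairs=1).iloc[0]
        absent = "ACGTACGTACGTA"
        idx = build_index(ref, 13)
        if not idx.lookup(absent):
            fake = type("pair", (), {"pair_id": 0, "tag1": pair.tag1, "tag2": absent})
            assert map_pair(idx, fake).status == "unmapped"

    def test_tag_level_mode_stricter(self):
        """A pair rescued by the joint insert constraint is unique at pair
        level but multi at tag level when one tag recurs."""
        ref = tagsim.synth_genome(20_000, 0.5, [RepeatFamily(3, 60)], seed=28)
        cfg = SimConfig(tag_length=13, seed=29)
        pairs = tagsim.sample_pairs(ref, "synth1", cfg, n_pairs=500)
        idx = build_index(ref, 13)
        n_pair_unique = n_tag_unique = 0
        for pair in pairs.itertuples():
            if map_pair(idx, pair, pair_level=True).status == "unique":
                n_pair_unique += 1
            if map_pair(idx, pair, pair_level=False).status == "unique":
                n_tag_unique += 1
        assert n_tag_unique <= n_pair_unique


class TestMapAll:
    def test_matches_per_pair_route_and_oracle(self):
        """The vectorized batch mapper agrees with map_pair and with the
        brute-force oracle on a repeat-bearing genome."""
        ref = tagsim.synth_genome(
            8000, 0.5, [RepeatFamily(2, 900), RepeatFamily(4, 80)], seed=30
        )
        cfg = SimConfig(tag_length=13, insert_min=300, insert_max=700, seed=31)
        pairs = tagsim.sample_pairs(ref, "synth1", cfg, n_pairs=400)
        idx = build_index(ref, 13)
        outcomes, summary = map_all(idx, pairs, 300, 700)
        assert summary["n"] == 400
        assert summary["fraction_unique"] + summary["fraction_multi"] + \
            summary["fraction_unmapped"] == pytest.approx(1.0)
        for row, pair in zip(outcomes.itertuples(), pairs.itertuples()):
            oracle = brute_force_pair_placements(ref, pair.tag1, pair.tag2, 300, 700)
            assert row.n_placements == len(oracle)
            single = map_pair(idx, pair, 300, 700)
            assert row.status == single.status
            if row.status == "unique":
                assert (oracle[0][1], oracle[0][2]) == (row.start1, row.start2)

    def test_error_free_pairs_never_unmapped(self):
        ref = tagsim.synth_genome(15_000, 0.5, [RepeatFamily(3, 800, 0.02)], seed=32)
        cfg = SimConfig(tag_length=14, seed=33)
        pairs = tagsim.sample_pairs(ref, "synth1", cfg, n_pairs=400)
        outcomes, summary = map_all(build_index(ref, 14), pairs)
        assert summary["fraction_unmapped"] == 0.0

    def test_empty_input(self):
        ref = tagsim.synth_genome(5000, 0.5, None, seed=34)
        idx = build_index(ref, 13)
        empty = pd.DataFrame(columns=["pair_id", "tag1", "tag2"])
        outcomes, summary = map_all(idx, empty)
        assert summary == {"n": 0, "fraction_unique": 0.0, "fraction_multi": 0.0,
                           "fraction_unmapped": 0.0}
        assert len(outcomes) == 0

    def test_nested_placement_subset_monotonicity(self):
        """Placement sets at L+1 are subsets of those at L, so unique pairs
        stay unique and fraction-unique never decreases (exact assertion)."""
        ref = tagsim.synth_genome(
            40_000, 0.5, [RepeatFamily(2, 1200, 0.03), RepeatFamily(3, 900, 0.02)],
            seed=35,
        )
        cfg = SimConfig(tag_length=13, nested=True, nested_max_length=20, seed=36)
        rng = np.random.default_rng(36)
        frags = tagsim.sample_fragments(ref, "synth1", 400, cfg, rng, anchor_length=20)
        prev_counts = None
        prev_frac = -1.0
        for L in range(13, 21):
            pairs = tagsim.pairs_from_fragments(ref, frags, L, anchor_length=20)
            outcomes, summary = map_all(build_index(ref, L), pairs)
            counts = outcomes["n_placements"].to_numpy()
            if prev_counts is not None:
                assert np.all(counts <= prev_counts)
            assert summary["fraction_unique"] >= prev_frac
            prev_counts, prev_frac = counts, summary["fraction_unique"]


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        ref = tagsim.synth_genome(5000, 0.5, None, seed=37)
        idx = build_index(ref, 13)
        path = tmp_path / "idx.npz"
        idx.save(str(path))
        back = KmerHashIndex.load(str(path), ref)
        tag = ref.sequences["synth1"][100:113]
        assert back.lookup(tag) == idx.lookup(tag)

    def test_digest_mismatch_detected(self, tmp_path):
        ref = tagsim.synth_genome(5000, 0.5, None, seed=38)
        other = tagsim.synth_genome(5000, 0.5, None, seed=39)
        idx = build_index(ref, 13)
        path = tmp_path / "idx.npz"
        idx.save(str(path))
        with pytest.raises(ValueError, match="digest"):
            KmerHashIndex.load(str(path), other)
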