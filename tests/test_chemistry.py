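"""Unit and property tests for the cSBL chemistry bookkeeping."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csbl import chemistry as ch
from conftest import bookkeeping_position, random_template

import numpy as np


class TestDesignAnchor:
    @pytest.mark.parametrize(
        "offset, expected",
        [
            (0, "ATCACCGACTGCCCATAGA"),
            (1, "TCACCGACTGCCCATAGA"),
            (2, "CACCGACTGCCCATAGA"),
            (3, "ACCGACTGCCCATAGA"),
        ],
    )
    def test_bench_anchor_series(self, paper_template, offset, expected):
        anchor = ch.design_anchor(paper_template, offset)
        assert anchor.sequence == expected
        assert anchor.phosphorylated_end == "5'"

    def test_single_base_template(self):
        t = ch.TemplateStrand("AC", known_len=1)
        assert ch.design_anchor(t, 0).sequence == "T"

    def test_offset_out_of_range(self, paper_template):
        with pytest.raises(ValueError, match="offset"):
            ch.design_anchor(paper_template, paper_template.known_len)
        with pytest.raises(ValueError, match="offset"):
            ch.design_anchor(paper_template, -1)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 18), st.integers(0, 2**31 - 1))
    def test_anchor_always_hybridizes_to_known_region(self, offset, seed):
        """The designed anchor is a perfect duplex with the template prefix."""
        t = random_template(np.random.default_rng(seed))
        anchor = ch.design_anchor(t, offset)
        assert ch.ligation_compatible(anchor.sequence, t, junction=1)


class TestCleave:
    def test_register_of_the_nine_mer(self):
        removed, retained = ch.cleave("NNiNNXNNN")
        assert (removed, retained) == ("NNiN", "NXNNN")
        assert removed + retained == "NNiNNXNNN"

    def test_nothing_past_cleavage_point(self):
        with pytest.raises(ch.InvalidGeometryError):
            ch.cleave("Ni")

    def test_no_inosine_means_no_cleavage(self):
        with pytest.raises(ch.NoCleavageSiteError):
            ch.cleave("NNNNNNNNN")

    def test_register_uniquely_fixed_by_printed_positions(self, standard):
        """Brute force over cleavage registers: only bond 2 reproduces the
        standard primer reading position 5 at cycle 0 and 10 after one cycle."""
        consistent = []
        for bond in range(1, 5):
            rule = ch.CleavageRule(bond_index=bond)
            p0 = ch.queried_position(0, 0, standard, rule)
            p1 = ch.queried_position(0, 1, standard, rule)
            if (p0, p1) == (5, 10):
                consistent.append(bond)
        assert consistent == [2]

    @settings(max_examples=100, derandomize=True)
    @given(
        st.integers(2, 12),
        st.integers(1, 11),
        st.integers(1, 10),
    )
    def test_conservation(self, length, ino_pos, bond):
        """removed + retained reconstitutes every cleavable query exactly."""
        if ino_pos > length:
            ino_pos = 1 + (ino_pos - 1) % length
        query = "".join(
            "i" if k == ino_pos - 1 else "ACGTN"[k % 5] for k in range(length)
        )
        rule = ch.CleavageRule(bond_index=bond)
        if ino_pos - 1 + bond >= length:
            with pytest.raises(ch.InvalidGeometryError):
                ch.cleave(query, rule)
        else:
            removed, retained = ch.cleave(query, rule)
            assert removed + retained == query
            assert "i" in removed and "i" not in retained
            assert len(retained) >= 1


class TestQueriedPosition:
    def test_inosine_pool_reads_fourth_base(self, exseq4):
        assert ch.queried_position(0, 0, exseq4) == 4

    def test_offset_three_reads_first_base(self, exseq4):
        assert ch.queried_position(3, 0, exseq4) == 1

    def test_standard_pool_fifth_then_tenth(self, standard):
        assert ch.queried_position(0, 0, standard) == 5
        assert ch.queried_position(0, 1, standard) == 10

    def test_probing_known_region_signalled(self, exseq4):
        with pytest.raises(ch.ProbesKnownRegionError):
            ch.queried_position(4, 0, exseq4)

    @settings(max_examples=80, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 5), st.booleans())
    def test_closed_form_matches_junction_bookkeeping(self, offset, cycle, use_std):
        """Scheduler arithmetic agrees with explicit junction bookkeeping on
        the template string for offsets 0-8, cycles 0-5."""
        t = random_template(np.random.default_rng(0), known_len=19, unknown_len=60)
        pool = ch.standard_pool_set() if use_std else ch.exseq4_pool_set()
        rule = ch.CleavageRule()
        expected = bookkeeping_position(t, offset, cycle, pool, rule)
        if expected < 1:
            with pytest.raises(ch.ProbesKnownRegionError):
                ch.queried_position(offset, cycle, pool, rule)
        else:
            assert ch.queried_position(offset, cycle, pool, rule) == expected


class TestEnumerateSchedule:
    def test_bench_protocol_interrogates_one_through_fourteen(self, paper_schedule):
        entries = ch.enumerate_schedule(paper_schedule)
        assert sorted({e.position for e in entries}) == list(range(1, 15))
        ino = [e for e in entries if e.pool_set.has_inosine]
        assert sorted(e.position for e in ino if e.anchor_offset == 0) == [4, 9, 14]
        # no duplicate positions among the inosine-pool interrogations
        positions = [e.position for e in ino]
        assert len(positions) == len(set(positions))

    def test_single_offset_single_cycle(self):
        sch = ch.ProtocolSchedule(anchor_offsets=(0,), n_cycles=1)
        entries = ch.enumerate_schedule(sch)
        assert [e.position for e in entries] == [4]

    def test_empty_offsets(self):
        sch = ch.ProtocolSchedule(anchor_offsets=(), n_cycles=1)
        assert ch.enumerate_schedule(sch) == []

    def test_schedule_json_roundtrip(self):
        text = '{"anchor_offsets": [0, 1], "n_cycles": 2, "standard_pool_at": [[0, 0]]}'
        sch = ch.ProtocolSchedule.from_json(text)
        entries = ch.enumerate_schedule(sch)
        assert sorted({e.position for e in entries}) == [3, 4, 5, 8, 9]


class TestLigationCompatible:
    def test_query_base_complements_template(self, paper_template):
        # template position 23 (unknown 4) is C; a query with G pairing it
        q = "NNNNNNNNG"  # 3' base pairs junction
        t = ch.TemplateStrand("AC" + "T" * 10, known_len=2)
        assert ch.ligation_compatible("NNNNNNNNA", t, junction=3)  # A:T
        assert not ch.ligation_compatible("NNNNNNNNC", t, junction=3)  # C:T mismatch

    def test_inosine_is_universal(self):
        for base in "ACGT":
            t = ch.TemplateStrand("A" + base * 9, known_len=1)
            assert ch.ligation_compatible("NNNNNNNNi", t, junction=2)

    def test_template_n_pairs_anything(self):
        t = ch.TemplateStrand("ANNNNNNNNN", known_len=1)
        assert ch.ligation_compatible("ACGTACGTA", t, junction=2)

    def test_overhang_is_incompatible(self):
        t = ch.TemplateStrand("ACGT", known_len=1)
        assert not ch.ligation_compatible("NNNNNNNNN", t, junction=2)


class TestMaxInformativeCycles:
    def test_native_direction_unbounded(self, exseq4):
        assert ch.max_informative_cycles("3'->5'", exseq4) == math.inf

    def test_reverse_direction_limited_to_two(self, exseq4):
        assert ch.max_informative_cycles("5'->3'", exseq4) == 2

    def test_no_inosine_single_ligation(self):
        pool = ch.QueryPrimerPool(name="plain", inosine_index=None, query_index=5,
                                  reported_base="A", channel="Cy3")
        assert ch.max_informative_cycles("3'->5'", pool) == 1

    def test_retained_fragment_is_inosine_free(self, exseq4):
        _, retained = ch.cleave(exseq4.geometry.degenerate_sequence())
        assert "i" not in retained


class TestTemplateStrand:
    def test_unknown_positions(self, paper_template):
        assert paper_template.unknown_base(1) == "A"
        assert paper_template.unknown_base(2) == "N"
        assert paper_template.unknown_length == 32
        assert paper_template.unknown_region.startswith("ANGCG")

    def test_invalid_known_len(self):
        with pytest.raises(ValueError):
            ch.TemplateStrand("ACGT", known_len=4)
        with pytest.raises(ValueError):
            ch.TemplateStrand("ACGT", known_len=0)

    def test_fasta_roundtrip(self, paper_template, tmp_path):
        path = tmp_path / "template.fasta"
        ch.write_fasta(path, [("test", paper_template.sequence)])
        back = ch.read_template_fasta(str(path), paper_template.known_len)
        assert back.sequence == paper_template.sequence
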