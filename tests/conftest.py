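"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from csbl import chemistry as ch
from csbl.tagsim import ReferenceGenome, revcomp


@pytest.fixture
def paper_template() -> ch.TemplateStrand:
    return ch.TemplateStrand.paper_template()


@pytest.fixture
def paper_schedule() -> ch.ProtocolSchedule:
    return ch.ProtocolSchedule.paper_schedule()


@pytest.fixture
def exseq4() -> ch.PoolSet:
    return ch.exseq4_pool_set()


@pytest.fixture
def standard() -> ch.PoolSet:
    return ch.standard_pool_set()


# ---------------------------------------------------------------------------
# Independent oracles

def bookkeeping_position(template: ch.TemplateStrand, offset: int, cycle: int,
                         pool: ch.PoolSet, rule: ch.CleavageRule) -> int:
    """Oracle for the scheduler: explicit junction bookkeeping.

    Walks the physical chemistry on the template string: the anchor covers
    template bases 1..known_len-offset; each preceding cycle ligates the
    cycling 9-mer and extends the anchor by the cleave()-retained fragment;
    the interrogated template index is (anchored end) + (query-base distance
    from the ligating end).  Returns the 1-based unknown-region position
    (may be < 1 when the query base pairs inside the known region).
    """
    anchored_end = template.known_len - offset  # template index of last paired base
    cycling = ch.exseq4_pool_set().geometry.degenerate_sequence()
    for _ in range(cycle):
        _, retained = ch.cleave(cycling, rule)
        anchored_end += len(retained)
    return anchored_end + pool.query_dist_from_3p - template.known_len


def brute_force_lookup(ref: ReferenceGenome, tag: str) -> list:
    """Oracle for the k-mer index: sliding-window scan on both strands."""
    hits = []
    rc = revcomp(tag)
    for name, seq in ref.sequences.items():
        for probe, strand in ((tag, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append((name, start, strand))
                start = seq.find(probe, start + 1)
    # palindromic tags hit the same site on both strands; keep both, like lookup()
    hits.sort()
    return hits


def brute_force_pair_placements(ref: ReferenceGenome, tag1: str, tag2: str,
                                insert_min: int, insert_max: int) -> list:
    """Oracle for pair mapping: join of brute-force per-tag scans."""
    placements = []
    for n1, s1, st1 in brute_force_lookup(ref, tag1):
        for n2, s2, st2 in brute_force_lookup(ref, tag2):
            if n1 != n2 or st1 != st2:
                continue
            sep = s2 - s1 if st1 == "+" else s1 - s2
            if insert_min <= sep <= insert_max:
                placements.append((n1, s1, s2, st1, sep))
    placements.sort()
    return placements


def random_template(rng: np.random.Generator, known_len: int = 19,
                    unknown_len: int = 32) -> ch.TemplateStrand:
    seq = "".join(rng.choice(list("ACGT"), size=known_len + unknown_len))
    return ch.TemplateStrand(seq, known_len)
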