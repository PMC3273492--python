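"""Synthetic reference genomes and error-free mate-paired short tags.

Models the simulation side of a mate-paired short-tag sequencing experiment:
pairs of fixed-length tags (13-20 nt) sampled from a reference, with
start-to-start separations uniform on [300, 700] nt, from either strand,
error-free, at a pair count chosen so total tag bases equal a target fold
coverage of the region.

Pair geometry and strand convention
-----------------------------------
A pair is anchored by a plus-strand fragment ``[s, s + sep + L)``:

* plus-strand pair: ``tag1 = ref[s : s+L]``, ``tag2 = ref[s+sep : s+sep+L]``;
* minus-strand pair: the same windows read on the reverse strand, reported
  5'->3' on that strand, with tag1 the fragment's minus-strand 5' tag
  (highest plus coordinates).

Both tags are reported on their source strand (forward-forward orientation on
that strand) and ``start1``/``start2`` are the plus-strand (0-based) starts of
the matched windows, so start-to-start separation equals ``sep`` on either
strand.  In *nested* mode, windows at tag length L are anchored so the tag at
L+1 is the one-base 3' extension of the tag at L from the identical fragment
— placement sets then shrink monotonically with L, which downstream code
exploits for exact monotonicity checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGenome",
    "RepeatFamily",
    "SimConfig",
    "MatePairTag",
    "synth_genome",
    "n_tags_for_coverage",
    "sample_fragments",
    "pairs_from_fragments",
    "sample_pairs",
    "verify_pairs",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ReferenceGenome:
    """Named DNA sequences (A/C/G/T/N), e.g. a synthetic genome or one
    chromosome plus decoys."""

    sequences: dict

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("a reference needs at least one sequence")
        for name, seq in self.sequences.items():
            self.sequences[name] = seq.upper()
            if len(seq) < 1:
                raise ValueError(f"sequence {name} is empty")

    @property
    def names(self) -> list:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str) -> None:
        from .chemistry import write_fasta

        write_fasta(path, self.sequences.items())


@dataclass(frozen=True)
class RepeatFamily:
    """``n_copies`` planted copies of a ``length``-nt repeat; ``divergence``
    is the per-base substitution rate applied independently to each copy
    (0 = exact copies)."""

    n_copies: int
    length: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.n_copies < 1 or self.length < 1:
            raise ValueError("repeat family needs n_copies >= 1 and length >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


@dataclass(frozen=True)
class MatePairTag:
    pair_id: int
    tag1: str
    tag2: str
    name: str
    start1: int
    start2: int
    strand: str
    separation: int


@dataclass
class SimConfig:
    """Tag-simulation parameters (defaults are the standard study conditions:
    13-20 nt tags, separations uniform on [300, 700], 10x coverage)."""

    tag_length: int = 13
    insert_min: int = 300
    insert_max: int = 700
    coverage_target: float = 10.0
    seed: int | None = None
    orientation: str = "forward-forward"
    nested: bool = False
    nested_max_length: int = 20

    def __post_init__(self) -> None:
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if self.coverage_target <= 0:
            raise ValueError("coverage_target must be > 0")
        if self.nested and self.nested_max_length < self.tag_length:
            raise ValueError("nested_max_length must be >= tag_length")

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def synth_genome(
    length: int,
    gc: float = 0.5,
    repeat_spec: Sequence[RepeatFamily] | None = None,
    seed: int | None = None,
    name: str = "synth1",
) -> ReferenceGenome:
    """Seeded random genome with planted repeats.

    Background bases are i.i.d. with the given GC fraction.  Each repeat
    family plants ``n_copies`` non-overlapping copies of one random
    consensus; per-copy substitutions at rate ``divergence`` emulate the
    inexactness of real repeat families (0 keeps copies exact).
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)

    repeat_spec = list(repeat_spec or [])
    total_repeat = sum(f.n_copies * f.length for f in repeat_spec)
    if total_repeat > 0.9 * length:
        raise ValueError("repeat_spec does not fit in the genome")

    occupied: list[tuple[int, int]] = []

    def place(rlen: int) -> int:
        for _ in range(10_000):
            s = int(rng.integers(0, length - rlen + 1))
            if all(s + rlen <= a or s >= b for a, b in occupied):
                occupied.append((s, s + rlen))
                return s
        raise ValueError("could not place repeat copies; repeat_spec infeasible")

    for fam in repeat_spec:
        consensus = rng.choice(4, size=fam.length, p=p)
        for _ in range(fam.n_copies):
            copy = consensus.copy()
            if fam.divergence > 0:
                mut = rng.random(fam.length) < fam.divergence
                # substitute with a uniformly different base
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            s = place(fam.length)
            codes[s:s + fam.length] = copy

    seq = _BASES[codes].tobytes().decode()
    return ReferenceGenome({name: seq})


def n_tags_for_coverage(region_length: int, tag_length: int, coverage_target: float) -> int:
    """Pairs needed so total tag bases = coverage_target x region_length:
    ``ceil(coverage x length / (2 x tag_length))``."""
    if region_length < 1 or tag_length < 1 or coverage_target <= 0:
        raise ValueError("arguments must be positive")
    return math.ceil(coverage_target * region_length / (2 * tag_length))


def sample_fragments(
    ref: ReferenceGenome,
    region: str,
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
    anchor_length: int | None = None,
) -> pd.DataFrame:
    """Sample pair-defining fragments ``(start, separation, strand)``.

    ``anchor_length`` is the tag length whose windows must be N-free and
    in-bounds (the nested maximum in nested mode); fragments are valid for
    every tag length <= anchor_length.  Fragments whose tag windows contain N
    are rejected and resampled.
    """
    L = anchor_length if anchor_length is not None else config.tag_length
    seq = ref.sequences[region]
    n = len(seq)
    is_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    ncum = np.concatenate([[0], np.cumsum(is_n)])

    def window_has_n(starts: np.ndarray) -> np.ndarray:
        return (ncum[starts + L] - ncum[starts]) > 0

    max_start_span = config.insert_max + L
    if n < max_start_span:
        raise ValueError("region shorter than insert_max + tag length")

    starts = np.empty(n_pairs, dtype=np.int64)
    seps = np.empty(n_pairs, dtype=np.int64)
    strands = np.where(rng.random(n_pairs) < 0.5, "+", "-")
    need = np.ones(n_pairs, dtype=bool)
    for _ in range(1000):
        k = int(need.sum())
        if k == 0:
            break
        sep_k = rng.integers(config.insert_min, config.insert_max + 1, size=k)
        hi = n - (sep_k + L)  # inclusive upper bound for start
        start_k = (rng.random(k) * (hi + 1)).astype(np.int64)
        ok = ~window_has_n(start_k) & ~window_has_n(start_k + sep_k)
        idx = np.flatnonzero(need)
        good = idx[ok]
        starts[good] = start_k[ok]
        seps[good] = sep_k[ok]
        need[good] = False
    else:
        raise ValueError("no valid N-free window found in region")

    return pd.DataFrame(
        {"start": starts, "separation": seps, "strand": strands, "name": region}
    )


def pairs_from_fragments(
    ref: ReferenceGenome,
    fragments: pd.DataFrame,
    tag_length: int,
    anchor_length: int | None = None,
) -> pd.DataFrame:
    """Extract tags of ``tag_length`` from fragments.

    ``anchor_length`` (>= tag_length) fixes the nested anchoring: minus-strand
    windows keep their right edge at the anchor-length window end, so the tag
    at L+1 extends the tag at L by one base at its 3' end on either strand.
    For plain (non-nested) sampling pass ``anchor_length=tag_length``.
    """
    L = tag_length
    A = anchor_length if anchor_length is not None else tag_length
    if L > A:
        raise ValueError("tag_length exceeds anchor_length")
    out = []
    for frag in fragments.itertuples():
        seq = ref.sequences[frag.name]
        s, sep = int(frag.start), int(frag.separation)
        if frag.strand == "+":
            s1, s2 = s, s + sep
            t1, t2 = seq[s1:s1 + L], seq[s2:s2 + L]
        else:
            e1, e2 = s + sep + A, s + A  # fixed right edges (nested anchoring)
            s1, s2 = e1 - L, e2 - L
            t1, t2 = revcomp(seq[s1:e1]), revcomp(seq[s2:e2])
        out.append((t1, t2, frag.name, s1, s2, frag.strand, sep))
    df = pd.DataFrame(
        out, columns=["tag1", "tag2", "name", "start1", "start2", "strand", "separation"]
    )
    df.insert(0, "pair_id", np.arange(len(df)))
    return df


def sample_pairs(
    ref: ReferenceGenome,
    region: str,
    config: SimConfig,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Sample error-free mate-paired tags from *region* of *ref*.

    Returns a DataFrame with one :class:`MatePairTag` per row (columns
    ``pair_id, tag1, tag2, name, start1, start2, strand, separation``).
    Deterministic given ``config.seed``; pair count defaults to the
    fold-coverage formula of :func:`n_tags_for_coverage`.
    """
    if n_pairs is None:
        n_pairs = n_tags_for_coverage(
            ref.length(region), config.tag_length, config.coverage_target
        )
    rng = np.random.default_rng(config.seed)
    anchor = config.nested_max_length if config.nested else config.tag_length
    frags = sample_fragments(ref, region, n_pairs, config, rng, anchor_length=anchor)
    return pairs_from_fragments(ref, frags, config.tag_length, anchor_length=anchor)


def verify_pairs(ref: ReferenceGenome, pairs: pd.DataFrame) -> bool:
    """Self-consistency: every tag matches its recorded source window/strand."""
    for row in pairs.itertuples():
        seq = ref.sequences[row.name]
        L = len(row.tag1)
        w1 = seq[row.start1:row.start1 + L]
        w2 = seq[row.start2:row.start2 + L]
        if row.strand == "+":
            if row.tag1 != w1 or row.tag2 != w2:
                return False
            if row.start2 - row.start1 != row.separation:
                return False
        else:
            if row.tag1 != revcomp(w1) or row.tag2 != revcomp(w2):
                return False
            if row.start1 - row.start2 != row.separation:
                return False
    return True


def pairs_to_tsv(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def pairs_from_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def pairs_to_fasta(pairs: pd.DataFrame, path: str) -> None:
    """Interleaved FASTA (pair_id/1, pair_id/2)."""
    with open(path, "w") as fh:
        for row in pairs.itertuples():
            fh.write(f">{row.pair_id}/1\n{row.tag1}\n>{row.pair_id}/2\n{row.tag2}\n")
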