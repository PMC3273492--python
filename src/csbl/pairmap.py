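"""Exact mapping of mate-paired short tags via a k-mer hash index.

The index stores every N-free k-mer start of the reference (k = tag length).
Internally k-mers are packed into 2-bit-per-base unsigned 64-bit keys kept in
a sorted array with their genomic starts, so a lookup is two binary searches
(one for the tag, one for its reverse complement) — an exact-retrieval
structure with hash-table semantics that also supports fast vectorized batch
queries.  Matching is exact only: a placement is a position where the tag (or
its reverse complement, for minus-strand hits) equals the reference k-mer.

A mate pair places at ``(start1, start2)`` when both tags match the same
sequence on a consistent strand with start-to-start separation inside the
configured insert range (forward-forward on the source strand: plus-strand
pairs have ``start2 - start1`` in range, minus-strand pairs ``start1 -
start2``).  Uniqueness is classified at the pair level by default — a pair is
``unique`` iff its joint placement count is exactly 1, ``multi`` for >= 2,
``unmapped`` for 0; multi and unmapped pairs carry no coverage downstream.  A
tag-level mode (each tag individually unique) is available behind a flag.
"""

from __future__ import annotations

import hashlib
import json

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tagsim import ReferenceGenome, revcomp

__all__ = [
    "KmerHashIndex",
    "PairPlacement",
    "MappingOutcome",
    "build_index",
    "lookup",
    "map_pair",
    "map_all",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c

MAX_K = 31  # 2 bits/base in a uint64 key


def _encode_seq(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid) over all windows of length k; invalid = contains N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | codes[j:j + n].astype(np.uint64)
    bad = (codes < 0).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return h, valid


def _hash_tags(tags: Sequence[str], k: int) -> np.ndarray:
    """Pack equal-length tags into uint64 keys (vectorized)."""
    if len(tags) == 0:
        return np.empty(0, dtype=np.uint64)
    flat = _CODE[np.frombuffer("".join(tags).encode(), dtype=np.uint8)]
    if np.any(flat < 0):
        raise ValueError("tags must be over A/C/G/T")
    mat = flat.reshape(len(tags), k).astype(np.uint64)
    h = np.zeros(len(tags), dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | mat[:, j]
    return h


def _rc_hash(h: np.ndarray, k: int) -> np.ndarray:
    """Key of the reverse complement, computed bitwise."""
    h = h.astype(np.uint64)
    out = np.zeros_like(h)
    x = ~h  # complement: A<->T (00<->11), C<->G (01<->10) is bitwise NOT per 2-bit code
    for _ in range(k):
        out = (out << np.uint64(2)) | (x & np.uint64(3))
        x = x >> np.uint64(2)
    return out


@dataclass(frozen=True)
class PairPlacement:
    name: str
    start1: int
    start2: int
    strand: str
    separation: int


@dataclass(frozen=True)
class MappingOutcome:
    pair_id: int
    status: str  # unique | multi | unmapped
    placements: tuple = ()

    @property
    def placement(self) -> PairPlacement | None:
        return self.placements[0] if self.status == "unique" else None


class KmerHashIndex:
    """Sorted-key exact k-mer index over a reference (see module docstring)."""

    def __init__(
        self,
        k: int,
        sorted_hashes: np.ndarray,
        sorted_starts: np.ndarray,
        seq_names: list,
        seq_offsets: np.ndarray,
        seq_lengths: np.ndarray,
        digest: str,
    ):
        self.k = k
        self.sorted_hashes = sorted_hashes
        self.sorted_starts = sorted_starts  # global (concatenated) coordinates
        self.seq_names = seq_names
        self.seq_offsets = seq_offsets
        self.seq_lengths = seq_lengths
        self.digest = digest

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, ref: ReferenceGenome, k: int) -> "KmerHashIndex":
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}")
        if k > max(len(s) for s in ref.sequences.values()):
            raise ValueError("k larger than every reference sequence")
        names = ref.names
        lengths = np.array([ref.length(n) for n in names], dtype=np.int64)
        # concatenate with k N's between sequences so no window spans two
        sep = "N" * k
        concat = sep.join(ref.sequences[n] for n in names)
        offsets = np.zeros(len(names), dtype=np.int64)
        pos = 0
        for i, n in enumerate(names):
            offsets[i] = pos
            pos += lengths[i] + k
        codes = _encode_seq(concat)
        h, valid = _window_hashes(codes, k)
        starts = np.flatnonzero(valid)
        keys = h[starts]
        order = np.argsort(keys, kind="stable")
        digest = hashlib.md5(
            ("\x00".join(names) + "\x01" + concat).encode()
        ).hexdigest()
        return cls(k, keys[order], starts[order], names, offsets, lengths, digest)

    # -- coordinate helpers --------------------------------------------------

    def _to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global concatenated position -> (seq index, local start)."""
        idx = np.searchsorted(self.seq_offsets, gpos, side="right") - 1
        return idx, gpos - self.seq_offsets[idx]

    # -- queries -------------------------------------------------------------

    def _range(self, key: np.uint64) -> tuple[int, int]:
        lo = int(np.searchsorted(self.sorted_hashes, key, side="left"))
        hi = int(np.searchsorted(self.sorted_hashes, key, side="right"))
        return lo, hi

    def _range_batch(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_hashes, keys, side="left")
        hi = np.searchsorted(self.sorted_hashes, keys, side="right")
        return lo, hi

    def lookup(self, tag: str) -> list:
        """All exact placements of *tag* on both strands, as
        ``(name, 0-based start, strand)`` tuples sorted by coordinate."""
        if len(tag) != self.k:
            raise ValueError(f"tag length {len(tag)} != index k {self.k}")
        out = []
        fwd = _hash_tags([tag], self.k)[0]
        for key, strand in ((fwd, "+"), (_rc_hash(np.array([fwd]), self.k)[0], "-")):
            lo, hi = self._range(key)
            idx, local = self._to_local(self.sorted_starts[lo:hi])
            for i, s in zip(idx, local):
                out.append((self.seq_names[int(i)], int(s), strand))
        out.sort()
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist as .npz (arrays) with a JSON metadata sidecar check."""
        meta = json.dumps(
            {"k": self.k, "digest": self.digest, "seq_names": self.seq_names}
        )
        np.savez_compressed(
            path,
            sorted_hashes=self.sorted_hashes,
            sorted_starts=self.sorted_starts,
            seq_offsets=self.seq_offsets,
            seq_lengths=self.seq_lengths,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path: str, ref: ReferenceGenome | None = None) -> "KmerHashIndex":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        idx = cls(
            int(meta["k"]), data["sorted_hashes"], data["sorted_starts"],
            list(meta["seq_names"]), data["seq_offsets"], data["seq_lengths"],
            meta["digest"],
        )
        if ref is not None:
            check = cls.build(ref, idx.k)
            if check.digest != idx.digest:
                raise ValueError("index digest does not match the supplied reference")
        return idx


def build_index(ref: ReferenceGenome, k: int) -> KmerHashIndex:
    """Build the exact k-mer index (every N-free k-mer start, both strands
    reachable at query time)."""
    return KmerHashIndex.build(ref, k)


def lookup(index: KmerHashIndex, tag: str) -> list:
    return index.lookup(tag)


def _join_placements(
    hits1: Iterable[tuple], hits2: Iterable[tuple],
    insert_min: int, insert_max: int,
    check_orientation: bool = True, check_insert: bool = True,
) -> list:
    """All joint placements of a pair from per-tag placement lists."""
    placements = []
    for n1, s1, st1 in hits1:
        for n2, s2, st2 in hits2:
            if n1 != n2:
                continue
            if check_orientation:
                if st1 != st2:
                    continue
                sep = s2 - s1 if st1 == "+" else s1 - s2
            else:
                sep = abs(s2 - s1)
            if check_insert and not insert_min <= sep <= insert_max:
                continue
            placements.append(PairPlacement(n1, s1, s2, st1 if st1 == st2 else ".", sep))
    return placements


def map_pair(
    index: KmerHashIndex,
    pair,
    insert_min: int = 300,
    insert_max: int = 700,
    pair_level: bool = True,
    check_orientation: bool = True,
    check_insert: bool = True,
) -> MappingOutcome:
    """Map one mate pair; *pair* is a :class:`~csbl.tagsim.MatePairTag` or any
    object with ``pair_id``, ``tag1``, ``tag2`` attributes."""
    hits1 = index.lookup(pair.tag1)
    hits2 = index.lookup(pair.tag2)
    placements = _join_placements(
        hits1, hits2, insert_min, insert_max, check_orientation, check_insert
    )
    if pair_level:
        n = len(placements)
    else:
        # tag-level: each tag must be individually unique; the single joint
        # candidate must still satisfy the pairing constraints
        if len(hits1) == 0 or len(hits2) == 0:
            n = 0
        elif len(hits1) > 1 or len(hits2) > 1:
            return MappingOutcome(int(pair.pair_id), "multi", tuple(placements))
        else:
            n = len(placements)
    status = "unmapped" if n == 0 else ("unique" if n == 1 else "multi")
    return MappingOutcome(int(pair.pair_id), status, tuple(placements))


def _map_all_general(index, pairs, insert_min, insert_max, pair_level,
                     check_orientation, check_insert) -> pd.DataFrame:
    rows = []
    for pair in pairs.itertuples():
        o = map_pair(index, pair, insert_min, insert_max, pair_level,
                     check_orientation, check_insert)
        p = o.placement
        rows.append((
            o.pair_id, o.status, len(o.placements),
            p.name if p else None, p.start1 if p else -1,
            p.start2 if p else -1, p.strand if p else ".",
            p.separation if p else -1,
        ))
    return pd.DataFrame(rows, columns=[
        "pair_id", "status", "n_placements", "name", "start1", "start2",
        "strand", "separation",
    ])


def map_all(
    index: KmerHashIndex,
    pairs: pd.DataFrame,
    insert_min: int = 300,
    insert_max: int = 700,
    pair_level: bool = True,
    check_orientation: bool = True,
    check_insert: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Map a table of pairs; returns ``(outcomes, summary)``.

    Outcomes carry one row per pair (order-independent classification) with
    the unique placement's coordinates where applicable.  Summary holds the
    unique/multi/unmapped fractions (0.0 with ``n = 0`` for empty input).
    The default configuration runs a vectorized fast path; non-default
    orientation/insert switches fall back to the per-pair route.
    """
    n_pairs = len(pairs)
    if n_pairs == 0:
        summary = {"n": 0, "fraction_unique": 0.0, "fraction_multi": 0.0,
                   "fraction_unmapped": 0.0}
        return _map_all_general(index, pairs, insert_min, insert_max, pair_level,
                                check_orientation, check_insert), summary

    if not (check_orientation and check_insert and pair_level):
        out = _map_all_general(index, pairs, insert_min, insert_max, pair_level,
                               check_orientation, check_insert)
        return out, _summarize_outcomes(out)

    k = index.k
    t1 = _hash_tags(list(pairs["tag1"]), k)
    t2 = _hash_tags(list(pairs["tag2"]), k)
    t1r = _rc_hash(t1, k)
    t2r = _rc_hash(t2, k)

    lo1p, hi1p = index._range_batch(t1)
    lo1m, hi1m = index._range_batch(t1r)
    lo2p, hi2p = index._range_batch(t2)
    lo2m, hi2m = index._range_batch(t2r)
    c1p, c1m = hi1p - lo1p, hi1m - lo1m
    c2p, c2m = hi2p - lo2p, hi2m - lo2m

    starts = index.sorted_starts
    offsets = index.seq_offsets

    def _gather(lo, cnt):
        if len(starts) == 0:
            return np.full(len(lo), -1, dtype=np.int64)
        safe = np.minimum(lo, len(starts) - 1)
        g = starts[safe]
        return np.where(cnt == 1, g, -1)

    simple = (c1p <= 1) & (c1m <= 1) & (c2p <= 1) & (c2m <= 1)

    g1p, g2p = _gather(lo1p, c1p), _gather(lo2p, c2p)
    g1m, g2m = _gather(lo1m, c1m), _gather(lo2m, c2m)

    def _same_seq(a, b):
        ia = np.searchsorted(offsets, a, side="right")
        ib = np.searchsorted(offsets, b, side="right")
        return ia == ib

    sep_p = g2p - g1p
    plus_ok = (c1p == 1) & (c2p == 1) & (sep_p >= insert_min) & (sep_p <= insert_max) \
        & _same_seq(g1p, g2p)
    sep_m = g1m - g2m
    minus_ok = (c1m == 1) & (c2m == 1) & (sep_m >= insert_min) & (sep_m <= insert_max) \
        & _same_seq(g1m, g2m)
    n_pl = np.where(simple, plus_ok.astype(np.int64) + minus_ok.astype(np.int64), -1)

    # general path for pairs with any multi-hit tag
    complex_idx = np.flatnonzero(~simple)
    pl_start1 = np.where(plus_ok, g1p, np.where(minus_ok, g1m, -1))
    pl_start2 = np.where(plus_ok, g2p, np.where(minus_ok, g2m, -1))
    pl_strand = np.where(plus_ok, "+", np.where(minus_ok, "-", "."))
    pl_sep = np.where(plus_ok, sep_p, np.where(minus_ok, sep_m, -1))

    n_pl = n_pl.copy()
    multi_seq = len(index.seq_names) > 1
    for i in complex_idx:
        n, placement = _count_joint(
            index,
            starts[lo1p[i]:hi1p[i]], starts[lo2p[i]:hi2p[i]],
            starts[lo1m[i]:hi1m[i]], starts[lo2m[i]:hi2m[i]],
            insert_min, insert_max, multi_seq,
        )
        n_pl[i] = n
        if placement is not None:
            g1, g2, strand, sep = placement
            pl_start1[i], pl_start2[i] = g1, g2
            pl_strand[i], pl_sep[i] = strand, sep
        else:
            pl_start1[i] = pl_start2[i] = -1
            pl_strand[i], pl_sep[i] = ".", -1

    status = np.where(n_pl == 0, "unmapped", np.where(n_pl == 1, "unique", "multi"))
    uniq = n_pl == 1
    # map global -> (name, local start) for unique placements
    name_arr = np.full(n_pairs, None, dtype=object)
    s1_local = np.full(n_pairs, -1, dtype=np.int64)
    s2_local = np.full(n_pairs, -1, dtype=np.int64)
    if uniq.any():
        i1, l1 = index._to_local(pl_start1[uniq])
        _i2, l2 = index._to_local(pl_start2[uniq])
        name_arr[uniq] = [index.seq_names[int(j)] for j in i1]
        s1_local[uniq] = l1
        s2_local[uniq] = l2

    out = pd.DataFrame({
        "pair_id": pairs["pair_id"].to_numpy(),
        "status": status,
        "n_placements": n_pl,
        "name": name_arr,
        "start1": s1_local,
        "start2": s2_local,
        "strand": np.where(uniq, pl_strand, "."),
        "separation": np.where(uniq, pl_sep, -1),
    })
    return out, _summarize_outcomes(out)


def _count_joint(index, p1p, p2p, p1m, p2m, insert_min, insert_max, multi_seq):
    """Joint placement count (and the placement itself when unique) for one
    pair from per-tag global-position arrays.

    Positions from the index are coordinate-sorted within a key, so each
    tag1 hit only needs a binary search into the tag2 array for its
    separation window: O((c1 + c2) log) rather than the c1 x c2 cross join.
    """
    count = 0
    placement = None
    for pa, pb, strand in ((p1p, p2p, "+"), (p1m, p2m, "-")):
        if len(pa) == 0 or len(pb) == 0:
            continue
        for x in pa:
            # plus: tag2 downstream of tag1; minus: tag2 upstream
            if strand == "+":
                lo = int(np.searchsorted(pb, x + insert_min, side="left"))
                hi = int(np.searchsorted(pb, x + insert_max, side="right"))
            else:
                lo = int(np.searchsorted(pb, x - insert_max, side="left"))
                hi = int(np.searchsorted(pb, x - insert_min, side="right"))
            for y in pb[lo:hi]:
                if multi_seq:
                    ia = np.searchsorted(index.seq_offsets, x, side="right")
                    ib = np.searchsorted(index.seq_offsets, y, side="right")
                    if ia != ib:
                        continue
                count += 1
                if count == 1:
                    sep = int(y - x) if strand == "+" else int(x - y)
                    placement = (int(x), int(y), strand, sep)
    return count, (placement if count == 1 else None)



def _summarize_outcomes(out: pd.DataFrame) -> dict:
    n = len(out)
    if n == 0:
        return {"n": 0, "fraction_unique": 0.0, "fraction_multi": 0.0,
                "fraction_unmapped": 0.0}
    counts = out["status"].value_counts()
    return {
        "n": n,
        "fraction_unique": float(counts.get("unique", 0)) / n,
        "fraction_multi": float(counts.get("multi", 0)) / n,
        "fraction_unmapped": float(counts.get("unmapped", 0)) / n,
    }
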