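"""Sequence-level model of cyclic sequencing-by-ligation (cSBL).

cSBL extends classic sequencing-by-ligation: a degenerate 9-mer query primer
carrying a deoxyinosine is ligated to an anchor primer hybridized to the known
region of an immobilized template, the fluorophore on the query's distal end
reports one template base, and Endonuclease V then nicks the query two
phosphodiester bonds 3' of the deoxyinosine.  The retained query fragment
stays ligated, lengthening the anchor so the next ligation interrogates a
position deeper into the unknown region.

This module owns the symbolic bookkeeping of that chemistry: anchor design,
the Endonuclease V cleavage register, ligation compatibility with universal
bases, and the scheduler that maps (anchor offset, cycle, primer pool) to the
1-based position of the unknown region that a given image reports.

Conventions
-----------
* All sequences are written 5'->3'.
* Deoxyinosine is encoded as a lowercase ``"i"`` (an extension of the IUPAC
  alphabet, since IUPAC has no inosine code); it pairs with every base.
* Unknown-region positions are 1-based: position ``p`` corresponds to the
  1-based template string index ``known_len + p``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "TemplateStrand",
    "AnchorPrimer",
    "QueryPrimerPool",
    "PoolSet",
    "CleavageRule",
    "ProtocolSchedule",
    "ScheduleEntry",
    "NoCleavageSiteError",
    "InvalidGeometryError",
    "ProbesKnownRegionError",
    "complement",
    "reverse_complement",
    "design_anchor",
    "cleave",
    "retained_length",
    "queried_position",
    "enumerate_schedule",
    "ligation_compatible",
    "max_informative_cycles",
    "TEST_TEMPLATE",
    "exseq4_pool_set",
    "standard_pool_set",
    "saturation_pool",
    "read_template_fasta",
    "write_fasta",
]

INOSINE = "i"
_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    # inosine is a universal base; its "complement" is left maximally
    # ambiguous rather than inventing a pairing partner
    INOSINE: "N",
}

#: Test template of the bench protocol: a 19-base anchor-complement region
#: followed by a 32-base unknown region (position 2 of the unknown region is
#: an ambiguous N in the synthesized oligo).
TEST_TEMPLATE = "TCTATGGGCAGTCGGTGATANGCGCTTGCAAGAGAATGAGGAAAACGAAGA"
TEST_TEMPLATE_KNOWN_LEN = 19


class NoCleavageSiteError(ValueError):
    """The query primer contains no deoxyinosine, so Endonuclease V is inert."""


class InvalidGeometryError(ValueError):
    """The cleavage point falls at or beyond the 3' end of the primer."""


class ProbesKnownRegionError(ValueError):
    """The scheduled read falls inside the anchor-complement (known) region."""


def complement(base: str) -> str:
    try:
        return _COMP[base]
    except KeyError:
        raise ValueError(f"not a valid base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


@dataclass(frozen=True)
class TemplateStrand:
    """An immobilized template: known 5' anchor-complement region + unknown tag.

    Parameters
    ----------
    sequence:
        Template 5'->3', alphabet A/C/G/T/N.
    known_len:
        Number of 5' bases complementary to the full-length anchor primer.
    """

    sequence: str
    known_len: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"template contains non-ACGTN characters: {sorted(bad)}")
        if not 1 <= self.known_len < len(seq):
            raise ValueError("known_len must satisfy 1 <= known_len < len(sequence)")

    @property
    def unknown_length(self) -> int:
        return len(self.sequence) - self.known_len

    def unknown_base(self, position: int) -> str:
        """Base at 1-based unknown-region *position* (position 1 abuts the anchor)."""
        if not 1 <= position <= self.unknown_length:
            raise IndexError(f"unknown position {position} outside 1..{self.unknown_length}")
        return self.sequence[self.known_len + position - 1]

    @property
    def unknown_region(self) -> str:
        return self.sequence[self.known_len:]

    @classmethod
    def paper_template(cls) -> "TemplateStrand":
        return cls(TEST_TEMPLATE, TEST_TEMPLATE_KNOWN_LEN)


@dataclass(frozen=True)
class AnchorPrimer:
    """Anchor primer for a given offset; its 5'-phosphate end sits at the junction."""

    offset: int
    sequence: str
    phosphorylated_end: str = "5'"


def design_anchor(template: TemplateStrand, offset: int) -> AnchorPrimer:
    """Reverse complement of template bases ``1..known_len - offset``.

    The full anchor (offset 0) hybridizes to the entire known region with its
    5' phosphate at the known/unknown junction; each successive offset removes
    one base from the junction end, shifting every scheduled read one base
    toward the anchor.
    """
    if not 0 <= offset < template.known_len:
        raise ValueError(
            f"invalid anchor offset {offset}: must be in 0..{template.known_len - 1}"
        )
    n = template.known_len - offset
    return AnchorPrimer(offset=offset, sequence=reverse_complement(template.sequence[:n]))


@dataclass(frozen=True)
class QueryPrimerPool:
    """One degenerate query-primer pool (a single fluorophore / reported base).

    ``inosine_index`` and ``query_index`` are 1-based from the labeled 5' end.
    The pool's single non-degenerate position is the query base; the base it
    *reports* on the template is carried in ``reported_base`` and tied to a
    fluorescence ``channel``.  The saturation pool is fully degenerate and
    unlabeled (``query_index is None``, ``labeled=False``).
    """

    name: str
    length: int = 9
    inosine_index: int | None = 3
    query_index: int | None = 6
    reported_base: str | None = None
    channel: str | None = None
    labeled: bool = True

    def __post_init__(self) -> None:
        if self.query_index is not None and not 1 <= self.query_index <= self.length:
            raise ValueError("query_index outside primer")
        if self.inosine_index is not None:
            if not 1 <= self.inosine_index <= self.length:
                raise ValueError("inosine_index outside primer")
            if self.inosine_index == self.query_index:
                raise ValueError("inosine cannot sit at the query position")
        if self.query_index is None and self.labeled:
            raise ValueError("a fully degenerate pool must be unlabeled")

    @property
    def has_inosine(self) -> bool:
        return self.inosine_index is not None

    @property
    def query_dist_from_3p(self) -> int:
        """Distance of the query base from the 3' (ligating) end, 3'-terminal base = 1."""
        if self.query_index is None:
            raise ValueError(f"pool {self.name} has no query base")
        return self.length - self.query_index + 1

    def degenerate_sequence(self) -> str:
        """The pool written 5'->3' with N at degenerate positions."""
        chars = ["N"] * self.length
        if self.inosine_index is not None:
            chars[self.inosine_index - 1] = INOSINE
        if self.query_index is not None and self.reported_base is not None:
            # the query base physically pairs the template base it reports
            chars[self.query_index - 1] = complement(self.reported_base)
        return "".join(chars)


@dataclass(frozen=True)
class PoolSet:
    """Four same-geometry pools (one per base) co-ligated in a single reaction."""

    name: str
    pools: tuple[QueryPrimerPool, ...]

    def __post_init__(self) -> None:
        geoms = {(p.length, p.inosine_index, p.query_index) for p in self.pools}
        if len(geoms) != 1:
            raise ValueError("all pools in a set must share geometry")
        bases = sorted(p.reported_base for p in self.pools)
        if bases != ["A", "C", "G", "T"]:
            raise ValueError("a pool set must report each of A/C/G/T exactly once")

    @property
    def geometry(self) -> QueryPrimerPool:
        return self.pools[0]

    @property
    def has_inosine(self) -> bool:
        return self.geometry.has_inosine

    @property
    def query_dist_from_3p(self) -> int:
        return self.geometry.query_dist_from_3p

    def pool_for_base(self, base: str) -> QueryPrimerPool:
        for p in self.pools:
            if p.reported_base == base:
                return p
        raise KeyError(base)

    def channel_for_base(self, base: str) -> str:
        return self.pool_for_base(base).channel


#: Default channel identifiers, in fixed order, and the base each reports.
CHANNELS = ("Cy3", "Cy5", "FITC", "TxRed")
CHANNEL_BASE_MAP = {"Cy3": "A", "Cy5": "T", "FITC": "C", "TxRed": "G"}


def exseq4_pool_set() -> PoolSet:
    """The cycling inosine pools: 9-mers, inosine 3rd from 5', query base 6th
    from 5' (4th from the ligating 3' end)."""
    pools = tuple(
        QueryPrimerPool(
            name=f"ExSeq4-{base}", inosine_index=3, query_index=6,
            reported_base=base, channel=channel,
        )
        for channel, base in CHANNEL_BASE_MAP.items()
    )
    return PoolSet("exseq4", pools)


def standard_pool_set() -> PoolSet:
    """The inosine-free standard pools with query base 5th from the 3' end."""
    pools = tuple(
        QueryPrimerPool(
            name=f"Std-{base}", inosine_index=None, query_index=5,
            reported_base=base, channel=channel,
        )
        for channel, base in CHANNEL_BASE_MAP.items()
    )
    return PoolSet("standard", pools)


def saturation_pool() -> QueryPrimerPool:
    """Unlabeled fully degenerate pool used to keep failed strands in phase."""
    return QueryPrimerPool(
        name="saturation", inosine_index=3, query_index=None,
        reported_base=None, channel=None, labeled=False,
    )


@dataclass(frozen=True)
class CleavageRule:
    """Endonuclease V cleavage register.

    ``bond_index`` counts phosphodiester bonds 3' of the deoxyinosine, the
    inosine-to-next-base bond being bond 1.  The enzymatic default of 2 cleaves
    between the 1st and 2nd nucleotides 3' of the inosine.
    """

    bond_index: int = 2

    def __post_init__(self) -> None:
        if self.bond_index < 1:
            raise ValueError("bond_index must be >= 1")


def cleave(query: str, rule: CleavageRule = CleavageRule()) -> tuple[str, str]:
    """Split *query* (5'->3', exactly one inosine) at the Endonuclease V nick.

    Returns ``(removed, retained)`` where ``removed`` is the 5' fragment
    carrying the label and the inosine, and ``retained`` is the 3' fragment
    left ligated to the anchor.  ``removed + retained == query`` always.
    """
    positions = [k for k, b in enumerate(query) if b in (INOSINE, "I")]
    if not positions:
        raise NoCleavageSiteError("query contains no deoxyinosine")
    if len(positions) > 1:
        raise ValueError("query contains more than one deoxyinosine")
    cut = positions[0] + rule.bond_index
    if cut >= len(query):
        raise InvalidGeometryError(
            f"cleavage point (after base {cut}) at or beyond the 3' end"
        )
    return query[:cut], query[cut:]


def retained_length(pool: QueryPrimerPool | PoolSet, rule: CleavageRule = CleavageRule()) -> int:
    """Length of the query fragment left on the anchor after digestion."""
    geom = pool.geometry if isinstance(pool, PoolSet) else pool
    if not geom.has_inosine:
        raise NoCleavageSiteError(f"pool {geom.name} has no deoxyinosine")
    kept = geom.length - (geom.inosine_index - 1 + rule.bond_index)
    if kept < 1:
        raise InvalidGeometryError("cleavage would leave no retained fragment")
    return kept


def _default_extension(rule: CleavageRule) -> int:
    """Anchor extension per cycle produced by the cycling inosine pools."""
    return retained_length(exseq4_pool_set(), rule)


def queried_position(
    anchor_offset: int,
    cycle: int,
    pool: QueryPrimerPool | PoolSet,
    rule: CleavageRule = CleavageRule(),
    extension_per_cycle: int | None = None,
) -> int:
    """Unknown-region position (1-based) read by *pool* at a given offset/cycle.

    Closed form: ``query_dist_from_3p - anchor_offset + extension * cycle``,
    where ``extension`` is the retained-fragment length of the cycling inosine
    pools (the standard inosine-free pool rides on the extension created by
    the preceding inosine cycles, so the same term applies).

    Raises
    ------
    ProbesKnownRegionError
        If the result is < 1, i.e. the query base pairs a base of the
        anchor-complement region and reports nothing new.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0 (cycle 0 = before any digestion)")
    geom = pool.geometry if isinstance(pool, PoolSet) else pool
    if extension_per_cycle is None:
        extension_per_cycle = (
            retained_length(geom, rule) if geom.has_inosine else _default_extension(rule)
        )
    pos = geom.query_dist_from_3p - anchor_offset + extension_per_cycle * cycle
    if pos < 1:
        raise ProbesKnownRegionError(
            f"offset {anchor_offset}, cycle {cycle}: position {pos} lies in the known region"
        )
    return pos


@dataclass(frozen=True)
class ScheduleEntry:
    anchor_offset: int
    cycle: int
    pool_set: PoolSet
    position: int


@dataclass(frozen=True)
class ProtocolSchedule:
    """A full cSBL run plan.

    ``cycling_pool_set`` is applied at every (offset, cycle); ``extras`` lists
    additional (offset, cycle, pool_set) interrogations — e.g. the standard
    inosine-free pools read with the full-length anchor at cycles 0 and 1.
    """

    anchor_offsets: tuple[int, ...]
    n_cycles: int
    cycling_pool_set: PoolSet = field(default_factory=exseq4_pool_set)
    extras: tuple[tuple[int, int, PoolSet], ...] = ()
    direction: str = "3'->5'"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        offs = tuple(self.anchor_offsets)
        if len(set(offs)) != len(offs) or any(o < 0 for o in offs):
            raise ValueError("anchor offsets must be distinct and >= 0")
        if self.direction not in ("3'->5'", "5'->3'"):
            raise ValueError("direction must be \"3'->5'\" or \"5'->3'\"")
        object.__setattr__(self, "anchor_offsets", offs)
        object.__setattr__(self, "extras", tuple(self.extras))

    @classmethod
    def paper_schedule(cls) -> "ProtocolSchedule":
        """Offsets 0-3, three cycles of the inosine pools, standard pools at
        cycles 0 and 1 with the full anchor: interrogates positions 1..14."""
        std = standard_pool_set()
        return cls(
            anchor_offsets=(0, 1, 2, 3),
            n_cycles=3,
            extras=((0, 0, std), (0, 1, std)),
        )

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSchedule":
        cfg = json.loads(text)
        extras = tuple(
            (int(o), int(c), standard_pool_set())
            for o, c in cfg.get("standard_pool_at", [])
        )
        return cls(
            anchor_offsets=tuple(cfg["anchor_offsets"]),
            n_cycles=int(cfg["n_cycles"]),
            extras=extras,
            direction=cfg.get("direction", "3'->5'"),
        )


def enumerate_schedule(
    schedule: ProtocolSchedule,
    rule: CleavageRule = CleavageRule(),
) -> list[ScheduleEntry]:
    """All (offset, cycle, pool set, position) interrogations of a schedule.

    Entries whose query base would pair inside the known region are dropped
    (they re-read anchor-complement bases and carry no new information).
    """
    entries: list[ScheduleEntry] = []
    todo: list[tuple[int, int, PoolSet]] = [
        (off, cyc, schedule.cycling_pool_set)
        for off in schedule.anchor_offsets
        for cyc in range(schedule.n_cycles)
    ]
    todo.extend(schedule.extras)
    for off, cyc, pool_set in todo:
        try:
            pos = queried_position(off, cyc, pool_set, rule)
        except ProbesKnownRegionError:
            continue
        entries.append(ScheduleEntry(off, cyc, pool_set, pos))
    entries.sort(key=lambda e: (e.position, e.anchor_offset, e.cycle, e.pool_set.name))
    return entries


def ligation_compatible(query_instance: str, template: TemplateStrand, junction: int) -> bool:
    """Does a concrete query 9-mer hybridize perfectly with its 3' end at *junction*?

    *junction* is the 1-based template index paired by the query's 3'-terminal
    base; the query runs antiparallel, toward the template 3' end.  N on either
    strand and inosine on the query pair with anything.  A query extending past
    the template 3' end is an overhang and is treated as incompatible.
    """
    if not 1 <= junction <= len(template.sequence):
        raise ValueError("junction outside template")
    if junction + len(query_instance) - 1 > len(template.sequence):
        return False  # overhang
    for d, qbase in enumerate(reversed(query_instance)):
        tbase = template.sequence[junction - 1 + d]
        if qbase in (INOSINE, "I") or qbase == "N" or tbase == "N":
            continue
        if complement(qbase.upper()) != tbase:
            return False
    return True


def max_informative_cycles(
    direction: str,
    pool: QueryPrimerPool | PoolSet,
    rule: CleavageRule = CleavageRule(),
    max_cycles: int = 64,
) -> int | float:
    """Number of informative ligation cycles a pool geometry supports.

    In the native 3'->5' orientation the removed fragment carries the inosine
    away with the label, the retained fragment is inosine-free, and cycling is
    unbounded (in practice limited only by signal-to-noise) — returns
    ``math.inf``.  In the 5'->3' orientation the retained fragment keeps the
    inosine inside the extended anchor; the simulation ligates and digests
    until a digestion would cleave at a previously retained inosine and
    destroy the newest extension, and returns the number of cycles completed
    by then.  A pool with no inosine supports a single ligation.
    """
    geom = pool.geometry if isinstance(pool, PoolSet) else pool
    if not geom.has_inosine:
        return 1
    if direction == "3'->5'":
        removed, retained = cleave(geom.degenerate_sequence(), rule)
        if INOSINE in retained or "I" in retained:
            # would only happen with multiple inosines; be conservative
            return 2
        return math.inf
    if direction != "5'->3'":
        raise ValueError("direction must be \"3'->5'\" or \"5'->3'\"")

    # 5'->3': the query ligates via its 5' end; "retained" is the 5' fragment
    # up to the nick, which necessarily contains the inosine.
    old_inosines: list[int] = []  # distances (nt) of kept inosines behind the junction
    cycles = 0
    for _ in range(max_cycles):
        cycles += 1  # ligation of a fresh query: one informative read
        if old_inosines:
            # Endonuclease V now also recognizes an inosine inside the anchor
            # extension; its nick (bond_index bonds 3' of it) falls at or past
            # the old junction, severing the new extension.
            if any(rule.bond_index >= back for back in old_inosines):
                return cycles
        kept = geom.inosine_index - 1 + rule.bond_index  # bases retained from the new query
        old_inosines = [back + kept for back in old_inosines]
        old_inosines.append(kept - (geom.inosine_index - 1))  # junction distance of new inosine
    return cycles


# ---------------------------------------------------------------------------
# FASTA I/O (templates and primers)

def read_template_fasta(path: str, known_len: int) -> TemplateStrand:
    """Read the first record of a FASTA file as a template strand."""
    from Bio import SeqIO

    record = next(SeqIO.parse(path, "fasta"))
    return TemplateStrand(str(record.seq).upper(), known_len)


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")
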