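"""Decode four-channel bead intensities into base calls and reads.

One image set per (bead, anchor offset, cycle, pool set) yields four channel
means; the brightest channel names the base and the ratio of the brightest
channel to the mean of the other three is the signal-to-noise ratio (S/N) of
the call.  Calls below an S/N threshold, or with a tied maximum, become
no-calls.  Calls are placed at the template position given by the protocol
scheduler, assembled into per-bead reads, and reduced to a consensus by
majority vote across beads.

Because real instruments re-tune camera gain per cycle, calling is built
entirely on within-image channel ratios: rescaling all four channels of an
image by a common positive factor changes neither the call nor its S/N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    CHANNEL_BASE_MAP,
    CHANNELS,
    CleavageRule,
    ProtocolSchedule,
    TemplateStrand,
    enumerate_schedule,
)
from .signal_synth import IntensityTable

__all__ = [
    "BaseCall",
    "DecodedRead",
    "DecodeResult",
    "average_pixels",
    "call_base",
    "decode_run",
    "error_profile",
    "GAP",
]

logger = logging.getLogger(__name__)

GAP = "-"
DEFAULT_SNR_THRESHOLD = 2.0


@dataclass(frozen=True)
class BaseCall:
    bead: int
    anchor_offset: int
    cycle: int
    position: int
    base: str | None  # None = no-call
    snr: float
    channel_means: tuple[float, float, float, float]
    pool: str = ""
    query_distance: int = 0


@dataclass
class DecodedRead:
    """Base string over unknown positions ``1..length`` with gaps, plus per
    position S/N."""

    length: int
    bases: list = field(default_factory=list)
    snr: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bases:
            self.bases = [None] * self.length
        if not self.snr:
            self.snr = [0.0] * self.length

    @property
    def sequence(self) -> str:
        return "".join(b if b is not None else GAP for b in self.bases)

    def set_call(self, position: int, base: str | None, snr: float) -> None:
        k = position - 1
        if self.bases[k] is not None and base is not None:
            if snr <= self.snr[k]:
                logger.warning(
                    "duplicate call at position %d: keeping earlier higher-S/N call", position
                )
                return
            logger.warning(
                "duplicate call at position %d: replacing with higher-S/N call", position
            )
        if base is not None:
            self.bases[k] = base
            self.snr[k] = snr

    def to_fastq(self, record_id: str) -> str:
        """FASTQ record; gaps become N with quality 0, called positions get
        ``Q = min(40, round(10 * log10(snr + 1)))`` (Phred+33)."""
        seq, quals = [], []
        for b, s in zip(self.bases, self.snr):
            if b is None:
                seq.append("N")
                quals.append(0)
            else:
                seq.append(b)
                q = 40 if math.isinf(s) else min(40, int(round(10 * math.log10(s + 1))))
                quals.append(q)
        qstr = "".join(chr(33 + q) for q in quals)
        return f"@{record_id}\n{''.join(seq)}\n+\n{qstr}\n"


def average_pixels(pixels: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of a pixel vector (the per-bead channel intensity)."""
    arr = np.asarray(pixels, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pixel vector")
    return float(arr.mean())


def call_base(
    channel_means: Sequence[float],
    channel_base_map: Mapping[str, str] | None = None,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    snr_mode: str = "others_mean",
) -> tuple[str | None, float]:
    """Call a base from four channel means.

    Returns ``(base, snr)`` with ``base is None`` for a no-call (S/N below
    threshold, or tied maximum).  ``snr_mode`` is either ``"others_mean"``
    (brightest / mean of the other three, the default) or ``"second_max"``.
    """
    if channel_base_map is None:
        channel_base_map = CHANNEL_BASE_MAP
    means = np.asarray(channel_means, dtype=float)
    if means.shape != (4,):
        raise ValueError("expected exactly 4 channel means")
    if np.any(means < 0):
        raise ValueError("channel means must be non-negative")
    order = np.argsort(means)
    top = int(order[-1])
    if means[top] == means[int(order[-2])]:
        return None, 1.0  # tie
    others = np.delete(means, top)
    denom = others.mean() if snr_mode == "others_mean" else others.max()
    snr = math.inf if denom == 0 else float(means[top] / denom)
    base = channel_base_map[CHANNELS[top]]
    if snr < snr_threshold:
        return None, snr
    return base, snr


@dataclass
class DecodeResult:
    calls: pd.DataFrame          # one row per (bead, offset, cycle, pool) image
    reads: dict                  # bead -> DecodedRead
    consensus: DecodedRead


def decode_run(
    table: IntensityTable,
    schedule: ProtocolSchedule,
    rule: CleavageRule = CleavageRule(),
    channel_base_map: Mapping[str, str] | None = None,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    snr_mode: str = "others_mean",
) -> DecodeResult:
    """Decode an intensity table against its protocol schedule.

    Every (bead, offset, cycle, pool) image becomes one :class:`BaseCall`
    placed at the scheduler's position for that combination; per-bead reads
    keep the higher-S/N call on duplicate positions, and the consensus is the
    across-bead majority at each position (ties -> gap).
    """
    entries = enumerate_schedule(schedule, rule)
    pos_of = {(e.anchor_offset, e.cycle, e.pool_set.name): e for e in entries}
    max_pos = max((e.position for e in entries), default=0)

    if len(table.df) == 0:
        empty = pd.DataFrame(
            columns=["bead", "anchor_offset", "cycle", "pool", "position",
                     "query_distance", "base", "snr"]
        )
        return DecodeResult(empty, {}, DecodedRead(max_pos))

    means = table.channel_means()
    wide = means.pivot_table(
        index=["bead", "anchor_offset", "cycle", "pool"],
        columns="channel",
        values="mean_intensity",
    )[list(CHANNELS)]

    records = []
    for (bead, offset, cycle, pool), row in wide.iterrows():
        key = (offset, cycle, pool)
        if key not in pos_of:
            logger.warning("image %s not in schedule; skipped", key)
            continue
        entry = pos_of[key]
        base, snr = call_base(row.to_numpy(), channel_base_map, snr_threshold, snr_mode)
        records.append(
            (bead, offset, cycle, pool, entry.position,
             entry.pool_set.query_dist_from_3p, base, snr)
        )
    calls = pd.DataFrame(
        records,
        columns=["bead", "anchor_offset", "cycle", "pool", "position",
                 "query_distance", "base", "snr"],
    )

    reads: dict[int, DecodedRead] = {}
    for bead, sub in calls.groupby("bead"):
        read = DecodedRead(max_pos)
        for row in sub.sort_values(["position", "snr"]).itertuples():
            read.set_call(row.position, row.base, row.snr)
        reads[bead] = read

    consensus = DecodedRead(max_pos)
    for pos in range(1, max_pos + 1):
        votes: dict[str, list[float]] = {}
        for read in reads.values():
            b = read.bases[pos - 1]
            if b is not None:
                votes.setdefault(b, []).append(read.snr[pos - 1])
        if not votes:
            continue
        counts = {b: len(v) for b, v in votes.items()}
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        if len(winners) > 1:
            continue  # tie across beads -> gap
        b = winners[0]
        consensus.set_call(pos, b, float(np.median(votes[b])))
    return DecodeResult(calls, reads, consensus)


def error_profile(
    calls: pd.DataFrame,
    truth: TemplateStrand,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position and per-junction-distance error counts for decoded calls.

    *calls* is the per-image call table of :func:`decode_run` (columns
    ``position``, ``query_distance``, ``base``).  *truth* is the concrete
    template; an ``N`` in the truth matches any call.  No-calls are excluded
    from the denominators.

    Returns ``(per_position, per_distance)`` DataFrames with columns
    ``n_calls``, ``n_errors`` and ``error_rate``.
    """
    made = calls[calls["base"].notna()].copy()
    if len(made) == 0:
        empty = pd.DataFrame(columns=["n_calls", "n_errors", "error_rate"])
        return empty, empty.copy()

    def is_error(row) -> bool:
        t = truth.unknown_base(int(row.position))
        return t != "N" and row.base != t

    made["error"] = [is_error(r) for r in made.itertuples()]

    def agg(group_col: str) -> pd.DataFrame:
        g = made.groupby(group_col)["error"].agg(n_calls="count", n_errors="sum")
        g["n_errors"] = g["n_errors"].astype(int)
        g["error_rate"] = g["n_errors"] / g["n_calls"]
        return g

    return agg("position"), agg("query_distance")
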