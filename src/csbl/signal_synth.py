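"""Synthetic four-channel fluorescence data for a cSBL run.

Turns a :class:`~csbl.chemistry.ProtocolSchedule` plus a noise model into
per-bead, per-channel pixel intensities emulating epifluorescence microscope
measurements of query-primer ligations on beads: 4 channels, a 14-bit camera
(integer intensities 1..16383), 100 pixels scored per bead and channel.

The noise model is deliberately minimal but has the right qualitative knobs:

* ``decay_per_cycle`` — multiplicative signal loss per ligation/digestion
  cycle (template loss, incomplete stripping, enzyme carry-over);
* ``ligation_efficiency`` — probability a strand is extended by a labeled
  query in a cycle; failures are either rescued by the unlabeled saturation
  pool (dark this cycle, back in phase the next) or start lagging one
  junction behind and thereafter emit at the previous position's channel;
* ``crosstalk`` — row-stochastic 4x4 channel bleed;
* ``background`` / ``pixel_sd`` — additive offset and per-pixel Gaussian
  spread;
* ``mismatch_slope`` / ``mismatch_onset`` — optional loss of ligation
  specificity with query-base distance from the junction, for reproducing
  position-dependent error profiles of non-cyclic protocols.

Because bench protocols re-tune camera gain every cycle, absolute intensities
across cycles are not comparable on a real instrument; the simulator reports
raw (uncalibrated) intensities and leaves any normalization to the caller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .chemistry import (
    CHANNELS,
    CleavageRule,
    PoolSet,
    ProbesKnownRegionError,
    ProtocolSchedule,
    ScheduleEntry,
    TemplateStrand,
    enumerate_schedule,
)

__all__ = [
    "NoiseModel",
    "BeadPopulation",
    "IntensityTable",
    "simulate_cycle",
    "render_pixels",
    "simulate_run",
    "INTENSITY_MIN",
    "INTENSITY_MAX",
]

INTENSITY_MIN = 1
INTENSITY_MAX = 16383  # 14-bit camera


def _default_crosstalk() -> np.ndarray:
    # 2% bleed into each off channel
    m = np.full((4, 4), 0.02)
    np.fill_diagonal(m, 0.94)
    return m


@dataclass
class NoiseModel:
    """Parameters of the synthetic signal generator (see module docstring)."""

    base_signal: float = 8000.0
    decay_per_cycle: float = 0.75
    ligation_efficiency: float = 0.9
    saturation_rescue: float = 0.9
    crosstalk: np.ndarray = field(default_factory=_default_crosstalk)
    background: float = 150.0
    pixel_sd: float = 120.0
    mismatch_onset: int = 6
    mismatch_slope: float = 0.0
    n_pixels: int = 100

    def __post_init__(self) -> None:
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        for name in ("ligation_efficiency", "saturation_rescue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.decay_per_cycle <= 1.0:
            raise ValueError("decay_per_cycle must be in (0, 1]")
        if self.crosstalk.shape != (4, 4) or not np.allclose(self.crosstalk.sum(axis=1), 1.0):
            raise ValueError("crosstalk must be a 4x4 row-stochastic matrix")
        if self.base_signal + self.background > INTENSITY_MAX:
            raise ValueError("base_signal + background exceeds the 14-bit range")

    @classmethod
    def noise_free(cls, base_signal: float = 8000.0, n_pixels: int = 100) -> "NoiseModel":
        """Degenerate model: no decay, perfect ligation, identity crosstalk,
        zero background and pixel spread."""
        return cls(
            base_signal=base_signal,
            decay_per_cycle=1.0,
            ligation_efficiency=1.0,
            saturation_rescue=1.0,
            crosstalk=np.eye(4),
            background=0.0,
            pixel_sd=0.0,
            n_pixels=n_pixels,
        )

    def mismatch_probability(self, query_distance: int) -> float:
        """Probability an extended strand reports a wrong base, as a function
        of the query base's distance from the ligation junction."""
        p = self.mismatch_slope * max(0, query_distance - self.mismatch_onset)
        return float(np.clip(p, 0.0, 0.75))

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "crosstalk"}
        d["crosstalk"] = self.crosstalk.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NoiseModel":
        return cls(**json.loads(text))


@dataclass
class BeadPopulation:
    """Clonal beads carrying one template, with per-population phase state.

    Phase fractions follow a deterministic expectation model shared by all
    beads of the population: ``in_phase`` strands sit at the current junction,
    ``lagging`` strands sit one junction behind and emit at the previous
    position's channel, and ``dark`` is the (transient) fraction saturated by
    the unlabeled pool this cycle — extended but unlabeled, hence dark now and
    in phase again next cycle.
    """

    template: TemplateStrand
    n_beads: int = 20
    in_phase: float = 1.0
    lagging: float = 0.0
    dark: float = 0.0
    prev_position: dict = field(default_factory=dict)

    def reset(self) -> None:
        """Fresh anchor hybridization (new offset): all strands in phase."""
        self.in_phase, self.lagging, self.dark = 1.0, 0.0, 0.0
        self.prev_position = {}

    def advance_phase(self, noise: "NoiseModel") -> None:
        eff, rescue = noise.ligation_efficiency, noise.saturation_rescue
        failed = self.in_phase * (1.0 - eff)
        self.dark = failed * rescue
        self.lagging = self.lagging + failed * (1.0 - rescue)
        self.in_phase = self.in_phase * eff + self.dark


def simulate_cycle(
    population: BeadPopulation,
    pool_set: PoolSet,
    position: int,
    cycle: int,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expected per-bead channel means for one (offset, cycle, pool set) image.

    *position* is the scheduled unknown-region position (from
    :func:`csbl.chemistry.queried_position`).  Returns an ``(n_beads, 4)``
    array ordered by :data:`csbl.chemistry.CHANNELS`.  Does **not** advance
    phase state; callers advance once per cycle via
    :meth:`BeadPopulation.advance_phase`.
    """
    n = population.n_beads
    tbase = population.template.unknown_base(position)
    sig = noise.base_signal * noise.decay_per_cycle**cycle * noise.ligation_efficiency
    emitted = np.zeros((n, 4))

    correct = CHANNELS.index(pool_set.channel_for_base(tbase))
    p_err = noise.mismatch_probability(pool_set.query_dist_from_3p)
    if p_err > 0.0 and rng is not None:
        # bead-level specificity failures: the in-phase signal of a bead goes
        # to a uniformly wrong channel
        wrong = rng.random(n) < p_err
        channels = np.full(n, correct)
        others = [c for c in range(4) if c != correct]
        channels[wrong] = rng.choice(others, size=int(wrong.sum()))
        emitted[np.arange(n), channels] += population.in_phase * sig
    else:
        emitted[:, correct] += population.in_phase * (1.0 - p_err) * sig
        if p_err > 0.0:
            emitted[:, [c for c in range(4) if c != correct]] += (
                population.in_phase * p_err / 3.0 * sig
            )

    prev = population.prev_position.get(pool_set.name)
    if population.lagging > 0.0 and prev is not None:
        lag_base = population.template.unknown_base(prev)
        lag_channel = CHANNELS.index(pool_set.channel_for_base(lag_base))
        emitted[:, lag_channel] += population.lagging * sig

    observed = emitted @ noise.crosstalk + noise.background
    population.prev_position[pool_set.name] = position
    return observed


def render_pixels(
    mean: float | np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer pixel vectors ~ round(Normal(mean, pixel_sd)) clipped to the
    14-bit range.  *mean* may be any array shape; one trailing axis of
    ``n_pixels`` is appended."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("channel means must be >= 0")
    px = rng.normal(mean[..., None], noise.pixel_sd, size=mean.shape + (noise.n_pixels,))
    return np.clip(np.rint(px), INTENSITY_MIN, INTENSITY_MAX).astype(np.int32)


class IntensityTable:
    """Per (bead, anchor offset, cycle, pool set, channel) pixel intensities.

    Backed by a tidy :class:`pandas.DataFrame` with identifier columns
    ``bead``, ``anchor_offset``, ``cycle``, ``pool`` and ``channel`` plus
    ``n_pixels`` pixel columns ``p000`` ....  The concrete template used for
    the simulation (ambiguity codes instantiated) travels with the table so
    decoders can be scored against truth.
    """

    def __init__(self, df: pd.DataFrame, template: TemplateStrand | None = None):
        self.df = df
        self.template = template

    @property
    def pixel_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("p") and c[1:].isdigit()]

    def channel_means(self) -> pd.DataFrame:
        """Collapse pixel vectors to their arithmetic mean (one row per image)."""
        out = self.df[["bead", "anchor_offset", "cycle", "pool", "channel"]].copy()
        out["mean_intensity"] = self.df[self.pixel_columns].mean(axis=1)
        return out

    def to_tsv(self, path: str, summary: bool = False) -> None:
        """Write as TSV; with ``summary=True`` write per-image mean/sd instead
        of the raw 100-pixel vectors."""
        if summary:
            out = self.df[["bead", "anchor_offset", "cycle", "pool", "channel"]].copy()
            px = self.df[self.pixel_columns]
            out["mean_intensity"] = px.mean(axis=1)
            out["sd_intensity"] = px.std(axis=1, ddof=0)
            out.to_csv(path, sep="\t", index=False)
        else:
            self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, template: TemplateStrand | None = None) -> "IntensityTable":
        return cls(pd.read_csv(path, sep="\t"), template)

    def __len__(self) -> int:
        return len(self.df)


def _instantiate_ns(template: TemplateStrand, rng: np.random.Generator) -> TemplateStrand:
    """Replace template N's with concrete bases (the synthesized oligo carries
    *some* base there; the caller keeps the concrete instance as truth)."""
    if "N" not in template.sequence:
        return template
    seq = list(template.sequence)
    for k, b in enumerate(seq):
        if b == "N":
            seq[k] = "ACGT"[rng.integers(4)]
    return TemplateStrand("".join(seq), template.known_len)


def simulate_run(
    template: TemplateStrand,
    schedule: ProtocolSchedule,
    noise: NoiseModel,
    seed: int | None = None,
    n_beads: int = 20,
) -> IntensityTable:
    """Simulate a full cSBL run and return the intensity table.

    Deterministic given *seed*.  Scheduled positions beyond the template's
    unknown region are dropped with a warning (truncation).  Phase state is
    reset at every anchor offset (the strand is stripped and a fresh anchor
    hybridized), and advances once per cycle.
    """
    rng = np.random.default_rng(seed)
    concrete = _instantiate_ns(template, rng)
    entries = enumerate_schedule(schedule)

    by_offset: dict[int, dict[int, list[ScheduleEntry]]] = {}
    for e in entries:
        by_offset.setdefault(e.anchor_offset, {}).setdefault(e.cycle, []).append(e)

    rows: list[tuple] = []
    pixel_blocks: list[np.ndarray] = []
    for offset in sorted(by_offset):
        pop = BeadPopulation(template=concrete, n_beads=n_beads)
        pop.reset()
        for cycle in sorted(by_offset[offset]):
            for entry in by_offset[offset][cycle]:
                if entry.position > concrete.unknown_length:
                    warnings.warn(
                        f"scheduled position {entry.position} beyond template "
                        f"unknown region ({concrete.unknown_length} nt); truncating",
                        stacklevel=2,
                    )
                    continue
                means = simulate_cycle(pop, entry.pool_set, entry.position, cycle, noise, rng)
                px = render_pixels(means, noise, rng)  # (n_beads, 4, n_pixels)
                for bead in range(n_beads):
                    for ch in range(4):
                        rows.append((bead, offset, cycle, entry.pool_set.name, CHANNELS[ch]))
                        pixel_blocks.append(px[bead, ch])
            pop.advance_phase(noise)

    ids = pd.DataFrame(rows, columns=["bead", "anchor_offset", "cycle", "pool", "channel"])
    if pixel_blocks:
        px_arr = np.stack(pixel_blocks)
        px_df = pd.DataFrame(px_arr, columns=[f"p{k:03d}" for k in range(px_arr.shape[1])])
        df = pd.concat([ids, px_df], axis=1)
    else:
        df = ids
    return IntensityTable(df, concrete)
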