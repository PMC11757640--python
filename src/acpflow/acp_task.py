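"""Active categorical perception (ACP) stimuli.

The task abstracts a block-catching scenario into classification: a block,
characterised by size (small/large), shade (bright/dark) and side
(left/right), is flashed onto a 4-pixel retina for two consecutive
timesteps within a 4-timestep episode.  The block may appear early
(t=0,1), at an intermediate time (t=1,2) or late (t=2,3); the other rows
are blank.  The network must report the block's category (one of eight)
after the final timestep, which forces it to retain the percept in its
recurrent state when the block appears early.

The stimulus space is fully enumerable: 8 block configurations x 3 temporal
placements = 24 episodes, 3 episodes per class.  ``generate_dataset`` is
deterministic and bit-exact across calls; episode order is configuration
major (class label 0..7), timing minor (early, intermediate, late).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator

import numpy as np
import pandas as pd

N_SENSORS = 4
N_TIMESTEPS = 4
N_CONFIGS = 8
N_TIMINGS = 3
N_EPISODES = N_CONFIGS * N_TIMINGS
N_CLASSES = 8

TIMINGS = ("early", "intermediate", "late")

#: first row index at which the block is shown, per timing
_TIMING_ONSET = {"early": 0, "intermediate": 1, "late": 2}


class Size(IntEnum):
    SMALL = 0
    LARGE = 1


class Shade(IntEnum):
    BRIGHT = 0
    DARK = 1


class Side(IntEnum):
    LEFT = 0
    RIGHT = 1


@dataclass(frozen=True)
class BlockConfig:
    """One of the eight block identities (size x shade x side)."""

    size: Size
    shade: Shade
    side: Side

    @property
    def label(self) -> int:
        return label_of(self)


@dataclass(frozen=True)
class Episode:
    """A single 4-timestep stimulus with its class label.

    ``frames`` is a [4 timesteps x 4 sensors] matrix with entries in
    {-1, 0, +1}: the block occupies two (small) or three (large) contiguous
    pixels, coded +1 for bright and -1 for dark, on exactly two consecutive
    rows determined by ``timing``.
    """

    frames: np.ndarray
    timing: str
    label: int
    config: BlockConfig

    def __post_init__(self) -> None:
        self.frames.setflags(write=False)


@dataclass
class EpisodeSet:
    """The ordered, complete collection of all 24 (config, timing) episodes."""

    episodes: list[Episode] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.episodes)

    @property
    def m(self) -> int:
        return N_CLASSES

    def __iter__(self) -> Iterator[Episode]:
        return iter(self.episodes)

    def __len__(self) -> int:
        return len(self.episodes)

    @property
    def frames(self) -> np.ndarray:
        """Stacked stimuli, shape [n, 4, 4]."""
        return np.stack([ep.frames for ep in self.episodes])

    @property
    def labels(self) -> np.ndarray:
        """Class labels, shape [n]."""
        return np.array([ep.label for ep in self.episodes], dtype=np.int64)

    def to_table(self) -> pd.DataFrame:
        """Long-format export: one row per (episode, timestep)."""
        rows = []
        for eid, ep in enumerate(self.episodes):
            for t in range(N_TIMESTEPS):
                rows.append(
                    {
                        "episode_id": eid,
                        "t": t,
                        **{f"s{k}": ep.frames[t, k] for k in range(N_SENSORS)},
                        "label": ep.label,
                        "timing": ep.timing,
                    }
                )
        return pd.DataFrame(rows)


def all_configs() -> list[BlockConfig]:
    """The eight configurations in label order (label 0 first)."""
    return [
        BlockConfig(Size(sz), Shade(sh), Side(sd))
        for sz in (0, 1)
        for sh in (0, 1)
        for sd in (0, 1)
    ]


def label_of(config: BlockConfig) -> int:
    """Bijection config -> class label: size*4 + shade*2 + side.

    small/bright/left are the zero bits, so (small, bright, left) -> 0 and
    (large, dark, right) -> 7.
    """
    return int(config.size) * 4 + int(config.shade) * 2 + int(config.side)


def render_block(config: BlockConfig) -> np.ndarray:
    """Project a block onto the 4-pixel retina.

    Small blocks occupy two contiguous pixels, large blocks three; left
    blocks are flush against column 0, right blocks flush against column 3.
    Bright pixels read +1, dark pixels -1, empty pixels 0.
    """
    width = 2 if config.size == Size.SMALL else 3
    value = 1.0 if config.shade == Shade.BRIGHT else -1.0
    row = np.zeros(N_SENSORS)
    if config.side == Side.LEFT:
        row[:width] = value
    else:
        row[N_SENSORS - width :] = value
    return row


def make_episode(config: BlockConfig, timing: str) -> Episode:
    """Place the rendered block on two consecutive rows per ``timing``."""
    if timing not in _TIMING_ONSET:
        raise ValueError(f"unknown timing {timing!r}; expected one of {TIMINGS}")
    onset = _TIMING_ONSET[timing]
    frames = np.zeros((N_TIMESTEPS, N_SENSORS))
    row = render_block(config)
    frames[onset] = row
    frames[onset + 1] = row
    return Episode(frames=frames, timing=timing, label=label_of(config), config=config)


def generate_dataset() -> EpisodeSet:
    """All 24 episodes: 8 configurations x 3 timings, deterministic order."""
    episodes = [
        make_episode(config, timing)
        for config in all_configs()
        for timing in TIMINGS
    ]
    return EpisodeSet(episodes=episodes)
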