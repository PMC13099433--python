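"""Task timelines for the naturalistic stimulation runs.

The study protocol has three passive-stimulation runs — emotional video
clips, movie scenes, and a musical piece — each laid out as fixation and
stimulus blocks played back-to-back.  This module builds those timelines
analytically (onsets, durations, condition labels), computes the number
of fMRI volumes required to cover a run at a given TR, and reads/writes
BIDS-style events tables.

Conventions: onsets are 0-based seconds and intervals are half-open
``[onset, onset + duration)``, so the total duration is exactly the sum
of event durations and events never overlap by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TaskTimeline",
    "build_run_timeline",
    "required_volumes",
    "write_events",
    "read_events",
    "CLIPS_BLOCKS",
    "MOVIE_BLOCKS",
    "MUSIC_BLOCKS",
]

# Printed block structure of the three runs.  The clips run interleaves
# 15-s fixations between four stimulation blocks (neutral clips split
# into two 55-s blocks, fear and joy 110 s each; the 1-s inter-clip
# fixations are part of the block durations).  Block order for the clips
# run varied between repetitions and does not affect totals.
CLIPS_BLOCK_DURATIONS = {
    "neutral_a": 55.0,
    "neutral_b": 55.0,
    "fear": 110.0,
    "joy": 110.0,
}
DEFAULT_CLIPS_ORDER = ("fear", "neutral_a", "joy", "neutral_b")

CLIPS_BLOCKS = None  # built on demand with a configurable order
MOVIE_BLOCKS = (
    ("fixation", 5.0),
    ("farewell", 501.0),
    ("fixation", 20.0),
    ("snakes", 321.0),
    ("fixation", 20.0),
)
MUSIC_BLOCKS = (
    ("fixation", 5.0),
    ("music", 423.0),
    ("fixation", 20.0),
)


@dataclass
class TaskTimeline:
    """Ordered, gap-free sequence of labelled events covering one run."""

    events: list  # of (onset_s, duration_s, condition)
    total_s: float
    name: str = ""

    def __post_init__(self) -> None:
        t = 0.0
        for onset, dur, _ in self.events:
            if dur <= 0:
                raise ValueError("event durations must be positive")
            if abs(onset - t) > 1e-9:
                raise ValueError("events must be contiguous and ascending")
            t = onset + dur
        if abs(t - self.total_s) > 1e-9:
            raise ValueError("total_s must equal the last event offset")

    def windows(self, condition: str) -> list[tuple[float, float]]:
        """[(start, end)] of every event with the given condition label."""
        return [(o, o + d) for o, d, c in self.events if c == condition]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, _, c in self.events:
            if c not in seen:
                seen.append(c)
        return seen


def _layout(blocks) -> TaskTimeline:
    events, t = [], 0.0
    for label, dur in blocks:
        events.append((t, float(dur), label))
        t += float(dur)
    return TaskTimeline(events=events, total_s=t)


def build_run_timeline(run_spec, block_order=None) -> TaskTimeline:
    """Build the timeline of one run.

    Parameters
    ----------
    run_spec : str or sequence of (label, duration_s)
        One of ``"clips"``, ``"movie"``, ``"music"`` for the three
        protocol runs, or an explicit ordered block list (including any
        fixation blocks) for a custom run.
    block_order : sequence of str, optional
        For the clips run only: order of the four stimulation blocks
        (keys of :data:`CLIPS_BLOCK_DURATIONS`).  Totals are invariant
        to the order.
    """
    if isinstance(run_spec, str):
        name = run_spec
        if run_spec == "clips":
            order = tuple(block_order) if block_order is not None else DEFAULT_CLIPS_ORDER
            if sorted(order) != sorted(CLIPS_BLOCK_DURATIONS):
                raise ValueError(f"clips block order must permute {sorted(CLIPS_BLOCK_DURATIONS)}")
            blocks = [("fixation", 5.0)]
            for i, key in enumerate(order):
                if i > 0:
                    blocks.append(("fixation", 15.0))
                blocks.append((key, CLIPS_BLOCK_DURATIONS[key]))
        elif run_spec == "movie":
            blocks = list(MOVIE_BLOCKS)
        elif run_spec == "music":
            blocks = list(MUSIC_BLOCKS)
        else:
            raise ValueError(f"unknown run name {run_spec!r}; pass an explicit block list")
    else:
        name = "custom"
        blocks = list(run_spec)
        if not blocks:
            raise ValueError("custom run needs at least one block")
    tl = _layout(blocks)
    tl.name = name
    return tl


def required_volumes(total_s: float, tr: float = 1.5) -> int:
    """Smallest number of TR-spaced volumes covering ``total_s`` seconds.

    The ceiling convention reproduces all three acquisition counts of
    the protocol (254, 578 and 299 volumes at TR = 1.5 s).
    """
    if total_s <= 0 or tr <= 0:
        raise ValueError("total_s and tr must be positive")
    # round first so that exact integer multiples of tr are not pushed
    # up by floating-point representation error
    return int(math.ceil(round(total_s / tr, 9)))


def write_events(timeline: TaskTimeline, path) -> None:
    """Write a BIDS-style events table (onset, duration, trial_type)."""
    df = pd.DataFrame(
        [(o, d, c) for o, d, c in timeline.events],
        columns=["onset", "duration", "trial_type"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path, name: str = "") -> TaskTimeline:
    df = pd.read_csv(path, sep="\t")
    events = [
        (float(r.onset), float(r.duration), str(r.trial_type)) for r in df.itertuples()
    ]
    total = events[-1][0] + events[-1][1] if events else 0.0
    tl = TaskTimeline(events=events, total_s=total, name=name)
    return tl
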