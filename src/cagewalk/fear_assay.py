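"""Freezing scoring from immobility traces.

The pipeline starts from a boolean immobility series (one observation per
video frame, e.g. 30 Hz), not from video: motion detection is the
recorder's job. An observation counts as *freezing* only if it belongs to
a maximal immobility run lasting at least 1 s (brief pauses are not fear).
Per conditioned-stimulus scores are percentages of freezing observations
in a 20-s window anchored, by default, at CS offset ("following" the tone);
onset anchoring is available for the alternative reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cagewalk.protocol import FearSchedule

__all__ = [
    "FreezingTrace",
    "FreezingScore",
    "score_freezing",
    "freezing_percentage",
    "session_freezing",
]


@dataclass(frozen=True)
class FreezingTrace:
    """Boolean immobility series for one animal over one session."""

    animal_id: str
    sample_rate_hz: float
    immobile: np.ndarray  # bool, one observation per sample
    schedule: FearSchedule | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        object.__setattr__(
            self, "immobile", np.asarray(self.immobile, dtype=bool)
        )

    @property
    def duration_s(self) -> float:
        return self.immobile.size / self.sample_rate_hz


@dataclass(frozen=True)
class FreezingScore:
    """Freezing percentage in one 20-s post-CS window."""

    animal_id: str
    cs_index: int
    window_start_s: float
    window_end_s: float
    pct_freezing: float


def score_freezing(trace: FreezingTrace, min_bout_s: float = 1.0) -> np.ndarray:
    """Boolean freezing series: immobility runs of at least ``min_bout_s``.

    A sample is freezing iff its maximal immobility run spans
    ``>= min_bout_s`` (inclusive threshold: a bout of exactly 1.0 s
    counts). Monotone in the threshold: raising ``min_bout_s`` never adds
    freezing samples.
    """
    if min_bout_s <= 0:
        raise ValueError("min_bout_s must be positive")
    imm = trace.immobile
    out = np.zeros_like(imm)
    if imm.size == 0:
        return out
    # run-length encode
    edges = np.flatnonzero(np.diff(imm.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [imm.size]])
    min_len = min_bout_s * trace.sample_rate_hz
    for s, e in zip(starts, ends):
        if imm[s] and (e - s) >= min_len - 1e-9:
            out[s:e] = True
    return out


def freezing_percentage(
    freezing: np.ndarray, sample_rate_hz: float, window: tuple[float, float]
) -> float:
    """Percent of freezing observations within ``window = [start_s, end_s)``.

    Sample ``i`` is attributed to time ``i / rate``; robust to sample rate
    up to one sample's discretization at the window edges.
    """
    start_s, end_s = window
    if not end_s > start_s:
        raise ValueError(f"empty window [{start_s}, {end_s})")
    i0 = int(math.ceil(start_s * sample_rate_hz - 1e-9))
    i1 = int(math.ceil(end_s * sample_rate_hz - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, freezing.size)
    if i1 <= i0:
        raise ValueError(f"window [{start_s}, {end_s}) outside trace span")
    seg = freezing[i0:i1]
    return 100.0 * float(seg.sum()) / seg.size


def session_freezing(
    trace: FreezingTrace,
    min_bout_s: float = 1.0,
    window_s: float = 20.0,
    anchor: str = "offset",
) -> tuple[list[FreezingScore], float]:
    """Per-CS freezing percentages for one session, plus the session mean.

    One ``window_s`` window per CS, anchored at CS offset (default) or CS
    onset. The trace must cover the whole scheduled session. Returns
    ``(scores, mean_pct)``.
    """
    if trace.schedule is None:
        raise ValueError("trace has no session schedule")
    if anchor not in ("offset", "onset"):
        raise ValueError(f"anchor must be 'offset' or 'onset', got {anchor!r}")
    gap = trace.schedule.duration_s - trace.duration_s
    if gap > 1.0 / trace.sample_rate_hz + 1e-9:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) shorter than schedule "
            f"({trace.schedule.duration_s:.1f} s); coverage gap {gap:.1f} s"
        )
    freezing = score_freezing(trace, min_bout_s)
    scores = []
    for i, cs in enumerate(trace.schedule.cs_events):
        w0 = cs.offset_s if anchor == "offset" else cs.onset_s
        w1 = w0 + window_s
        pct = freezing_percentage(freezing, trace.sample_rate_hz, (w0, w1))
        scores.append(FreezingScore(trace.animal_id, i, w0, w1, pct))
    mean = float(np.mean([s.pct_freezing for s in scores])) if scores else float("nan")
    return scores, mean
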