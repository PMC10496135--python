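"""Bout analytics: run-length structure of the per-frame module stream.

A bout (module sequence) is a maximal run of consecutive frames carrying the
same module label.  These analytics quantify the temporal grain of the
segmentation: the distribution of bout durations, the share of time spent in
very short bouts (putative transition frames), and frame-to-millisecond
conversion at the recording's frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import Seb3rError
from .io_dlc import DEFAULT_FPS


@dataclass
class Bout:
    """A maximal run of identical module labels within one session."""

    bm_id: int
    start_frame: int  # 1-based within the session
    length_frames: int


@dataclass
class BoutTable:
    """All bouts of one session, in order; they tile the session exactly."""

    subject_id: str
    session_label: str
    bouts: list[Bout]
    fps: float = DEFAULT_FPS

    @property
    def n_frames(self) -> int:
        return sum(b.length_frames for b in self.bouts)

    def decode(self) -> np.ndarray:
        """Reconstruct the per-frame label stream."""
        return np.repeat(
            [b.bm_id for b in self.bouts], [b.length_frames for b in self.bouts]
        )


def run_length_encode(
    labels: np.ndarray,
    subject_id: str = "",
    session_label: str = "",
    fps: float = DEFAULT_FPS,
) -> BoutTable:
    """Run-length encode a per-frame module stream into a bout table."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise Seb3rError("cannot encode an empty label stream")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    bouts = [
        Bout(bm_id=int(labels[s]), start_frame=int(s) + 1, length_frames=int(e - s))
        for s, e in zip(starts, ends)
    ]
    return BoutTable(
        subject_id=subject_id, session_label=session_label, bouts=bouts, fps=fps
    )


def frames_to_duration(n_frames: int, fps: float = DEFAULT_FPS) -> float:
    """Convert a frame count to milliseconds: each frame spans 1000/fps ms.

    At the default 25 fps one frame is 40 ms, so e.g. a 3-frame bout lasts
    120 ms.
    """
    if not fps > 0:
        raise Seb3rError(f"fps must be positive, got {fps}")
    if n_frames < 0:
        raise Seb3rError("frame count must be >= 0")
    return n_frames * 1000.0 / fps


def _behavioral_bouts(table: BoutTable, include_unassigned: bool) -> list[Bout]:
    if include_unassigned:
        return table.bouts
    return [b for b in table.bouts if b.bm_id != 0]


def short_bout_percentage(
    table: BoutTable,
    threshold_frames: int = 3,
    include_unassigned: bool = False,
) -> float:
    """Percent of frames lying in bouts shorter than ``threshold_frames``.

    With the default threshold of 3 this is the printed formula
    (frames in 1-frame bouts + frames in 2-frame bouts) * 100 / total frames.
    Unassigned (module 0) bouts are excluded from both numerator and
    denominator unless ``include_unassigned`` is set.
    """
    if threshold_frames < 1:
        raise Seb3rError("threshold must be >= 1 frame")
    bouts = _behavioral_bouts(table, include_unassigned)
    total = sum(b.length_frames for b in bouts)
    if total == 0:
        raise Seb3rError("no frames to evaluate")
    short = sum(b.length_frames for b in bouts if b.length_frames < threshold_frames)
    return short * 100.0 / total


def duration_distribution(
    tables: list[BoutTable],
    per_bm: bool = False,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Bout-length counts, medians and cumulative frequencies.

    Returns a tidy frame with one row per (group, length):
    ``bm_id`` (-1 = pooled), ``length_frames``, ``count``, ``cum_fraction``
    (fraction of the group's bouts with length <= L; reaches exactly 1 at the
    maximum length), ``median_frames`` (median bout length of the group,
    over bouts, repeated on every row), ``duration_ms`` of the length bin.
    """
    all_bouts: list[tuple[int, int, float]] = []
    for t in tables:
        for b in _behavioral_bouts(t, include_unassigned):
            all_bouts.append((b.bm_id, b.length_frames, t.fps))
    if not all_bouts:
        raise Seb3rError("no bouts to summarize")

    df = pd.DataFrame(all_bouts, columns=["bm_id", "length_frames", "fps"])
    groups = df.groupby("bm_id") if per_bm else [(-1, df)]
    out = []
    for bm, g in groups:
        lengths = np.sort(g["length_frames"].to_numpy())
        uniq, counts = np.unique(lengths, return_counts=True)
        cum = np.cumsum(counts) / counts.sum()
        med = float(np.median(lengths))
        fps = g["fps"].iloc[0]
        for L, c, cf in zip(uniq, counts, cum):
            out.append(
                {
                    "bm_id": int(bm),
                    "length_frames": int(L),
                    "count": int(c),
                    "cum_fraction": float(cf),
                    "median_frames": med,
                    "duration_ms": frames_to_duration(int(L), fps),
                }
            )
    return pd.DataFrame(out)
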