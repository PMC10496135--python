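"""Step 3: relabel every frame with its behavioral module and tally frequencies.

Takes the per-session posture labels from step 1 and the posture-to-module
map from step 2, stamps a module id on every frame, and writes one labeled
CSV per original tracking file plus a per-subject frequency table (rows =
modules, columns = sessions) of frames spent in each module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io_dlc
from .errors import Seb3rError
from .module_matching import ModuleMap
from .posture_extraction import ClusteredSession


@dataclass
class LabeledSession:
    """One session with a posture id and a module id per frame (0 = unassigned)."""

    subject_id: str
    session_label: str
    posture_ids: np.ndarray
    bm_ids: np.ndarray
    fps: float = io_dlc.DEFAULT_FPS

    @property
    def n_frames(self) -> int:
        return len(self.bm_ids)


@dataclass
class FrequencyTable:
    """Frames per (module, session) for one subject.

    ``counts[b, s]`` is the number of frames of session ``session_labels[s]``
    assigned to ``bm_ids[b]``; module id 0 collects unassigned (missing
    tracking) frames and is only present when such frames exist.
    """

    subject_id: str
    session_labels: list[str]
    bm_ids: list[int]
    counts: np.ndarray  # len(bm_ids) x len(session_labels), int

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def row(self, bm: int) -> np.ndarray:
        return self.counts[self.bm_ids.index(bm)]

    def total_frames(self, bm: int) -> int:
        """Total frames in a module across all sessions (0 if absent)."""
        return int(self.row(bm).sum()) if bm in self.bm_ids else 0


def assign_modules(
    clustered: list[ClusteredSession],
    module_map: ModuleMap,
    modules_dir: str | Path | None = None,
) -> list[LabeledSession]:
    """Map each frame's posture id to its module id, session by session.

    Frame order and count are preserved; the sentinel posture 0 (missing
    tracking) propagates to module 0.  A posture id missing from the map is
    an error naming the subject and posture.  When ``modules_dir`` is given,
    one labeled CSV per session is written there (the per-subject "Modules"
    folder).
    """
    labeled: list[LabeledSession] = []
    for c in clustered:
        bm = np.zeros(len(c.postures), dtype=int)
        for p in np.unique(c.postures):
            if p == 0:
                continue
            key = (c.subject_id, int(p))
            if key not in module_map.entries:
                raise Seb3rError(
                    f"posture {p} of subject {c.subject_id} missing from module map"
                )
            bm[c.postures == p] = module_map.entries[key]
        labeled.append(
            LabeledSession(
                subject_id=c.subject_id,
                session_label=c.session_label,
                posture_ids=c.postures.copy(),
                bm_ids=bm,
                fps=c.fps,
            )
        )
        if modules_dir is not None:
            d = Path(modules_dir)
            d.mkdir(parents=True, exist_ok=True)
            io_dlc.write_labeled(
                d / f"Mouse{c.subject_id}_{c.session_label}.csv",
                c.subject_id,
                c.z,
                c.postures,
                bm,
            )
    return labeled


def count_frequencies(
    labeled: list[LabeledSession],
    n_modules: int | None = None,
    out_path: str | Path | None = None,
) -> FrequencyTable:
    """Tally frames per (module, session) for one subject.

    Every module 1..n_modules gets a row even when empty, so frequency
    files are comparable across subjects; a module-0 row for unassigned
    frames is appended only when such frames exist.
    """
    if not labeled:
        raise Seb3rError("need at least one labeled session")
    subjects = {s.subject_id for s in labeled}
    if len(subjects) != 1:
        raise Seb3rError(f"sessions belong to different subjects: {sorted(subjects)}")
    subject_id = subjects.pop()
    if n_modules is None:
        n_modules = max((int(s.bm_ids.max()) for s in labeled), default=0)

    session_labels = [s.session_label for s in labeled]
    bm_ids = list(range(1, n_modules + 1))
    counts = np.zeros((n_modules, len(labeled)), dtype=int)
    unassigned = np.zeros(len(labeled), dtype=int)
    for s_idx, s in enumerate(labeled):
        binned = np.bincount(s.bm_ids, minlength=n_modules + 1)
        counts[:, s_idx] = binned[1 : n_modules + 1]
        unassigned[s_idx] = binned[0]
    if unassigned.any():
        bm_ids = bm_ids + [0]
        counts = np.vstack([counts, unassigned])

    table = FrequencyTable(
        subject_id=subject_id,
        session_labels=session_labels,
        bm_ids=bm_ids,
        counts=counts,
    )
    if out_path is not None:
        io_dlc.write_frequencies(
            Path(out_path),
            session_labels,
            {bm: counts[i].tolist() for i, bm in enumerate(bm_ids)},
        )
    return table
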