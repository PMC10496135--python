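"""Reading DeepLabCut-3D tracking CSVs and writing every pipeline output dialect.

The pipeline consumes only the vertical (z) coordinate of six tracked body
parts ("bodily hotspots"): nose, eyes, neck, mid back, lower back, tail
attachment.  This module owns the canonical hotspot order used everywhere
else, the cohort folder conventions (one subfolder per animal id inside a
"mother folder"), and the readers/writers for each intermediate CSV the
pipeline exchanges between its three steps.

Two input header dialects are auto-detected:

* the native DLC-3D three-row header (scorer / bodyparts / coords, with an
  x,y,z triplet per body part), and
* a simplified one-row header with one z column per hotspot (either the bare
  hotspot name or ``<name>_z``).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, LayoutError, MissingHotspotError

logger = logging.getLogger(__name__)

#: Canonical hotspot order.  Single source of truth for every module.
HOTSPOTS: tuple[str, ...] = (
    "nose",
    "eyes",
    "neck",
    "mid back",
    "lower back",
    "tail attachment",
)

N_HOTSPOTS = len(HOTSPOTS)

#: Default acquisition rate (frames per second) of the validation recordings.
DEFAULT_FPS = 25.0

#: Floating-point format used by every writer; round-trips doubles to
#: better than 1e-9 relative.
_FLOAT_FMT = "%.12g"


@dataclass
class TrackingSession:
    """One tracking file: the z-coordinate timeline of a single recording.

    Attributes
    ----------
    subject_id:
        Animal identification string.
    session_label:
        Ordinal/experimental label of the recording (e.g. habituation, SHAM,
        T1-T3); by default the source file stem.
    z:
        ``(frames, 6)`` float array of vertical coordinates, camera units,
        columns in :data:`HOTSPOTS` order.  Missing values are NaN.
    fps:
        Acquisition rate, frames per second.
    missing_mask:
        Boolean per-frame vector; True where any hotspot z is absent or
        unparsable.  Flagged frames stay in the timeline so frame indices
        remain aligned with the source video.
    """

    subject_id: str
    session_label: str
    z: np.ndarray
    fps: float = DEFAULT_FPS
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[1] != N_HOTSPOTS:
            raise FormatError(
                f"z must be (frames, {N_HOTSPOTS}), got shape {self.z.shape}"
            )
        if self.z.shape[0] < 1:
            raise FormatError("a tracking session must contain at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.z).all(axis=1)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (self.z.shape[0],):
                raise FormatError("missing_mask length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]


@dataclass
class CohortLayout:
    """Mother-folder inventory: one entry per animal subfolder.

    ``subjects`` maps each subject id to its ordered list of session file
    paths; ordering is deterministic (lexicographic after zero-padding runs
    of digits) so the session sequence is stable across platforms.
    """

    root_path: Path
    subjects: dict[str, list[Path]] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def n_sessions(self) -> int:
        counts = {len(v) for v in self.subjects.values()}
        if len(counts) > 1:
            raise LayoutError(
                f"subjects have unequal session counts: {sorted(counts)}"
            )
        return counts.pop() if counts else 0


@dataclass
class FrameCountReport:
    """Result of :func:`validate_frame_counts`."""

    ok: bool
    #: offending (subject_id, session_label, frame_count) triples
    mismatches: list[tuple[str, str, int]] = field(default_factory=list)
    #: consensus frame count per session ordinal (modal count)
    expected: list[int] = field(default_factory=list)


def _natural_key(name: str) -> str:
    """Zero-pad every digit run so lexicographic order equals numeric order."""
    return re.sub(r"\d+", lambda m: m.group(0).zfill(12), name)


#: Folder names under the mother folder that hold pipeline outputs or
#: fixture ground truth, never subjects.
RESERVED_DIRS = frozenset({"Mean Distances", "Modules", "ground_truth"})

#: File-name prefixes of pipeline outputs; skipped by discovery so a mother
#: folder that already holds results can be re-processed from the raw
#: tracking files.
RESERVED_PREFIXES = ("Clustered", "Mouse", "Frequencies", "truth_")


def _detect_dialect(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    head = first.split(",")[0].strip().lower()
    return "dlc3d" if head == "scorer" else "flat"


def _z_columns_dlc3d(path: Path) -> pd.DataFrame:
    # no index_col: with a 3-row header pandas would silently consume the
    # first data row as an index-name row, dropping frame 0
    df = pd.read_csv(path, header=[0, 1, 2], encoding="utf-8")
    # level 1 = bodyparts, level 2 = coords
    cols = {}
    for hotspot in HOTSPOTS:
        matches = [
            c
            for c in df.columns
            if str(c[1]).strip().lower() == hotspot and str(c[2]).strip().lower() == "z"
        ]
        if not matches:
            raise MissingHotspotError(hotspot, path)
        cols[hotspot] = df[matches[0]]
    return pd.DataFrame(cols)


def _z_columns_flat(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    lowered = {str(c).strip().lower(): c for c in df.columns}
    cols = {}
    for hotspot in HOTSPOTS:
        for candidate in (hotspot, f"{hotspot}_z", hotspot.replace(" ", "_"),
                          f"{hotspot.replace(' ', '_')}_z"):
            if candidate in lowered:
                cols[hotspot] = df[lowered[candidate]]
                break
        else:
            raise MissingHotspotError(hotspot, path)
    return pd.DataFrame(cols)


def read_tracking_csv(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    subject_id: str | None = None,
    session_label: str | None = None,
) -> TrackingSession:
    """Read one DLC-3D tracking CSV into a :class:`TrackingSession`.

    Only the z column of each required hotspot is retained, in canonical
    order.  Frames with any absent or unparsable z are flagged in
    ``missing_mask`` but never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _detect_dialect(path)
    try:
        frame = _z_columns_dlc3d(path) if dialect == "dlc3d" else _z_columns_flat(path)
    except MissingHotspotError:
        raise
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    z = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return TrackingSession(
        subject_id=subject_id if subject_id is not None else path.stem,
        session_label=session_label if session_label is not None else path.stem,
        z=z,
        fps=fps,
    )


def discover_layout(root: str | Path) -> CohortLayout:
    """Inventory a mother folder: one subfolder per animal id, CSVs inside.

    A session file must carry its folder's subject id in its name; anything
    else is excluded with a logged warning.  Session order is the
    deterministic natural sort of file names.
    """
    root = Path(root)
    if not root.is_dir():
        raise LayoutError(f"mother folder {root} does not exist")
    subdirs = sorted(
        (d for d in root.iterdir() if d.is_dir() and d.name not in RESERVED_DIRS),
        key=lambda d: _natural_key(d.name),
    )
    subjects: dict[str, list[Path]] = {}
    for sub in subdirs:
        files = []
        for f in sorted(sub.iterdir(), key=lambda p: _natural_key(p.name)):
            if not f.is_file() or f.suffix.lower() != ".csv":
                if f.is_file():
                    logger.warning("excluding non-CSV file %s from subject %s", f.name, sub.name)
                continue
            if f.name.startswith(RESERVED_PREFIXES):
                continue
            if sub.name not in f.name:
                logger.warning(
                    "excluding %s: name does not contain subject id %r", f.name, sub.name
                )
                continue
            files.append(f)
        if files:
            subjects[sub.name] = files
        else:
            logger.warning("subject folder %s contains no usable session files", sub.name)
    if not subjects:
        raise LayoutError(f"no subject folders with tracking CSVs under {root}")
    return CohortLayout(root_path=root, subjects=subjects)


def validate_frame_counts(
    layout: CohortLayout, sessions: dict[str, list[TrackingSession]]
) -> FrameCountReport:
    """Check that session k of every subject has the same frame count.

    The cross-subject module matching of step 2 assumes comparable session
    durations, so every subject's k-th tracking file must contain the same
    number of frames.  Returns a report rather than raising; the CLI turns a
    failing report into a nonzero exit.
    """
    n_sessions = max((len(v) for v in sessions.values()), default=0)
    mismatches: list[tuple[str, str, int]] = []
    expected: list[int] = []
    for ordinal in range(n_sessions):
        counts: dict[str, tuple[str, int]] = {}
        for subject, sess_list in sessions.items():
            if ordinal < len(sess_list):
                s = sess_list[ordinal]
                counts[subject] = (s.session_label, s.n_frames)
        values = [c for _, c in counts.values()]
        modal = max(set(values), key=values.count) if values else 0
        expected.append(modal)
        for subject, (label, count) in counts.items():
            if count != modal:
                mismatches.append((subject, label, count))
    return FrameCountReport(ok=not mismatches, mismatches=mismatches, expected=expected)


def load_cohort(
    layout: CohortLayout, fps: float = DEFAULT_FPS
) -> dict[str, list[TrackingSession]]:
    """Read every session file of every subject in layout order."""
    out: dict[str, list[TrackingSession]] = {}
    for subject, paths in layout.subjects.items():
        out[subject] = [
            read_tracking_csv(p, fps=fps, subject_id=subject, session_label=p.stem)
            for p in paths
        ]
    return out


# ---------------------------------------------------------------------------
# Output dialects.  All intermediate files are plain comma-separated UTF-8.
# Column layouts follow the pipeline's file conventions:
#   MouseIDDistMean : subject id | 15 mean distances | posture id   (17 cols)
#   Clustered       : subject id | 6 z coordinates  | posture id    (8 cols)
#   ModulesAssigned : subject id | posture id | module id           (3 cols)
#   MouseID         : Clustered + module id as column 9             (9 cols)
#   Frequencies     : header "BM,<session labels>"; one row per module
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_mean_distances(
    path: str | Path, subject_id: str, centroids: np.ndarray, posture_ids: np.ndarray
) -> None:
    """Write a MouseIDDistMean table: P rows x 17 columns, headerless."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 15:
        raise FormatError(f"centroids must be (P, 15), got {centroids.shape}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for row, pid in zip(centroids, posture_ids):
            w.writerow([subject_id, *(_fmt(v) for v in row), int(pid)])


def read_mean_distances(path: str | Path) -> tuple[str, np.ndarray, np.ndarray]:
    """Read a MouseIDDistMean table back: (subject_id, centroids, posture_ids)."""
    rows = _read_rows(path, expected_width=17)
    subject = rows[0][0]
    centroids = np.array([[float(v) for v in r[1:16]] for r in rows])
    posture_ids = np.array([int(r[16]) for r in rows], dtype=int)
    return subject, centroids, posture_ids


def write_clustered(
    path: str | Path, subject_id: str, z: np.ndarray, postures: np.ndarray
) -> None:
    """Write a Clustered table: one row per frame, 8 headerless columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for row, p in zip(np.asarray(z, dtype=float), postures):
            w.writerow([subject_id, *(_fmt(v) for v in row), int(p)])


def read_clustered(path: str | Path) -> tuple[str, np.ndarray, np.ndarray]:
    """Read a Clustered table back: (subject_id, z, posture labels)."""
    rows = _read_rows(path, expected_width=8)
    subject = rows[0][0]
    z = np.array([[_parse_float(v) for v in r[1:7]] for r in rows])
    postures = np.array([int(r[7]) for r in rows], dtype=int)
    return subject, z, postures


def write_modules_assigned(
    path: str | Path, entries: dict[tuple[str, int], int]
) -> None:
    """Write a ModulesAssigned table: subject id, posture id, module id."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for (subject, posture), bm in entries.items():
            w.writerow([subject, int(posture), int(bm)])


def read_modules_assigned(path: str | Path) -> dict[tuple[str, int], int]:
    rows = _read_rows(path, expected_width=3)
    entries: dict[tuple[str, int], int] = {}
    for subject, posture, bm in rows:
        key = (subject, int(posture))
        if key in entries:
            raise FormatError(f"{path}: duplicate (subject, posture) key {key}")
        entries[key] = int(bm)
    return entries


def write_labeled(
    path: str | Path,
    subject_id: str,
    z: np.ndarray,
    postures: np.ndarray,
    modules: np.ndarray,
) -> None:
    """Write a MouseID table: Clustered columns plus the module id as column 9."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for row, p, b in zip(np.asarray(z, dtype=float), postures, modules):
            w.writerow([subject_id, *(_fmt(v) for v in row), int(p), int(b)])


def read_labeled(path: str | Path) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    rows = _read_rows(path, expected_width=9)
    subject = rows[0][0]
    z = np.array([[_parse_float(v) for v in r[1:7]] for r in rows])
    postures = np.array([int(r[7]) for r in rows], dtype=int)
    modules = np.array([int(r[8]) for r in rows], dtype=int)
    return subject, z, postures, modules


def write_frequencies(
    path: str | Path,
    session_labels: list[str],
    counts: dict[int, list[int]],
) -> None:
    """Write a Frequencies table: rows = modules, columns = sessions.

    ``counts`` maps module id -> per-session frame counts; module id 0, if
    present, is written last with the row label "unassigned".
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["BM", *session_labels])
        for bm in sorted(k for k in counts if k != 0):
            w.writerow([bm, *(int(c) for c in counts[bm])])
        if 0 in counts and any(counts[0]):
            w.writerow(["unassigned", *(int(c) for c in counts[0])])


def read_frequencies(path: str | Path) -> tuple[list[str], dict[int, list[int]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    labels = rows[0][1:]
    counts: dict[int, list[int]] = {}
    for r in rows[1:]:
        bm = 0 if r[0] == "unassigned" else int(r[0])
        counts[bm] = [int(v) for v in r[1:]]
    return labels, counts


def _parse_float(token: str) -> float:
    token = token.strip()
    if not token or token.lower() in ("nan", "na"):
        return float("nan")
    return float(token)


def _read_rows(path: str | Path, expected_width: int) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise FormatError(f"{path}: empty file")
    for i, r in enumerate(rows):
        if len(r) != expected_width:
            raise FormatError(
                f"{path}: row {i + 1} has {len(r)} fields, expected {expected_width}"
            )
    return rows
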