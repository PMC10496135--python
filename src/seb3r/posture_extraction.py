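"""Step 1: per-subject posture discovery from z-coordinate geometry.

For one subject the z timelines of all sessions are concatenated, every
frame is converted to the 15 signed pairwise differences between hotspot
heights (all unordered pairs of the six hotspots), and the resulting
``N x 15`` feature matrix is clustered with k-means, choosing k by the elbow
criterion on within-cluster sum of squares.  The clusters are the subject's
"postures".

The pairwise subtraction removes any additive per-animal height offset (a
taller mouse shifts every hotspot equally), which is what makes posture
labels comparable across animals of different size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from . import io_dlc
from .errors import Seb3rError
from .io_dlc import HOTSPOTS, N_HOTSPOTS, TrackingSession

logger = logging.getLogger(__name__)

#: Canonical order of the 15 unordered hotspot pairs: (i, j) with i < j,
#: iterated with i outermost.  Column c of a feature matrix is
#: z[:, i] - z[:, j] for PAIR_INDEX[c] = (i, j).
PAIR_INDEX: tuple[tuple[int, int], ...] = tuple(combinations(range(N_HOTSPOTS), 2))

N_PAIRS = len(PAIR_INDEX)  # C(6, 2) = 15

PAIR_NAMES: tuple[str, ...] = tuple(
    f"{HOTSPOTS[i]} - {HOTSPOTS[j]}" for i, j in PAIR_INDEX
)


@dataclass
class ClusteringConfig:
    """Knobs of the elbow k-means engine (shared by steps 1 and 2).

    k_max:
        Largest cluster count the elbow search will consider.
    variance_cutoff:
        Smallest k whose explained-variance fraction
        V(k) = 1 - WCSS(k)/WCSS(1) reaches this value is chosen.
    replicates:
        k-means++ restarts per k; WCSS(k) is the best of these.
    seed:
        Seeds every restart; identical inputs + seed give identical output.
    max_iter:
        Lloyd iteration cap per restart.
    """

    k_max: int = 20
    variance_cutoff: float = 0.95
    replicates: int = 10
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self):
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not 0 < self.variance_cutoff < 1:
            raise ValueError("variance_cutoff must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class DistanceFeatureMatrix:
    """N x 15 matrix of signed pairwise z-differences for one subject."""

    values: np.ndarray
    pair_index: tuple[tuple[int, int], ...] = PAIR_INDEX
    #: (session_label, 1-based frame number) for each row
    frame_origin: list[tuple[str, int]] | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_PAIRS:
            raise Seb3rError(
                f"feature matrix must have {N_PAIRS} columns, got {self.values.shape}"
            )
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values).all(axis=1)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusteredSession:
    """Per-session slice of step-1 output: z plus a posture label per frame."""

    subject_id: str
    session_label: str
    z: np.ndarray
    postures: np.ndarray  # 1..P, 0 = unassigned (missing tracking)
    fps: float = io_dlc.DEFAULT_FPS


@dataclass
class PostureSummary:
    """Per-subject posture centroids: the input to cross-subject matching."""

    subject_id: str
    centroids: np.ndarray  # P x 15, mean feature vector of each posture
    posture_ids: np.ndarray  # 1..P
    counts: np.ndarray  # frames per posture

    @property
    def n_postures(self) -> int:
        return len(self.posture_ids)


def concat_sessions(
    sessions: list[TrackingSession],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Stack the z timelines of one subject's sessions in session order.

    Returns ``(z, missing_mask, frame_origin)`` where ``frame_origin[r]`` is
    the (session label, 1-based frame number) of combined row r, so step-3
    outputs can be split back into per-session files.
    """
    if not sessions:
        raise Seb3rError("need at least one session")
    subject_ids = {s.subject_id for s in sessions}
    if len(subject_ids) != 1:
        raise Seb3rError(f"sessions belong to different subjects: {sorted(subject_ids)}")
    z = np.vstack([s.z for s in sessions])
    mask = np.concatenate([s.missing_mask for s in sessions])
    origin = [
        (s.session_label, f + 1) for s in sessions for f in range(s.n_frames)
    ]
    return z, mask, origin


def pairwise_z_differences(
    z_timeline: np.ndarray,
    missing_mask: np.ndarray | None = None,
    frame_origin: list[tuple[str, int]] | None = None,
    absolute: bool = False,
) -> DistanceFeatureMatrix:
    """Convert an N x 6 z timeline into the N x 15 pairwise-difference matrix.

    Column c is ``z[:, i] - z[:, j]`` for ``PAIR_INDEX[c] = (i, j)``; the
    sign encodes which hotspot is higher (nose above vs below tail is a
    different posture).  ``absolute=True`` gives |differences| instead.
    """
    z = np.asarray(z_timeline, dtype=float)
    if z.ndim != 2 or z.shape[1] != N_HOTSPOTS:
        raise Seb3rError(f"z timeline must have {N_HOTSPOTS} columns, got {z.shape}")
    i_idx = np.array([i for i, _ in PAIR_INDEX])
    j_idx = np.array([j for _, j in PAIR_INDEX])
    values = z[:, i_idx] - z[:, j_idx]
    if absolute:
        values = np.abs(values)
    return DistanceFeatureMatrix(
        values=values, frame_origin=frame_origin, missing_mask=missing_mask
    )


def _wcss_k1(x: np.ndarray) -> float:
    return float(((x - x.mean(axis=0)) ** 2).sum())


def _fit_kmeans(x: np.ndarray, k: int, config: ClusteringConfig, salt: int) -> KMeans:
    # distinct stream per k, all derived from config.seed
    rs = np.random.SeedSequence([config.seed, salt]).generate_state(1)[0] % (2**31)
    km = KMeans(
        n_clusters=k,
        n_init=config.replicates,
        init="k-means++",
        max_iter=config.max_iter,
        random_state=int(rs),
    )
    km.fit(x)
    return km


def elbow_kmeans(
    features: DistanceFeatureMatrix | np.ndarray,
    config: ClusteringConfig | None = None,
    full_curve: bool = False,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Cluster feature rows with k-means, choosing k by the elbow criterion.

    For each k the within-cluster sum of squares WCSS(k) is the best of
    ``config.replicates`` seeded k-means++ restarts; the chosen k is the
    smallest one whose explained-variance fraction
    ``V(k) = 1 - WCSS(k)/WCSS(1)`` reaches ``config.variance_cutoff``
    (k = 1 when WCSS(1) = 0, i.e. all rows identical).  By default the
    search stops at that k; ``full_curve=True`` sweeps every k to k_max.

    Returns ``(labels, k, wcss)``: labels are 1..k for non-missing frames
    and 0 for missing ones, renumbered by descending cluster size; ``wcss``
    holds WCSS for k = 1 .. len(wcss).
    """
    if config is None:
        config = ClusteringConfig()
    if isinstance(features, DistanceFeatureMatrix):
        x_all, missing = features.values, features.missing_mask
    else:
        x_all = np.asarray(features, dtype=float)
        missing = ~np.isfinite(x_all).all(axis=1)
    x = x_all[~missing]
    if x.shape[0] == 0:
        raise Seb3rError("no non-missing frames to cluster")

    n_distinct = np.unique(x, axis=0).shape[0]
    k_max = config.k_max
    if k_max > n_distinct:
        logger.info("k_max %d clamped to %d distinct rows", k_max, n_distinct)
        k_max = n_distinct

    wcss1 = _wcss_k1(x)
    wcss = [wcss1]
    models: dict[int, KMeans] = {}
    chosen = 1
    if wcss1 > 0:
        chosen = 0
        for k in range(2, k_max + 1):
            km = _fit_kmeans(x, k, config, salt=k)
            models[k] = km
            wcss.append(float(km.inertia_))
            if chosen == 0 and 1 - km.inertia_ / wcss1 >= config.variance_cutoff:
                chosen = k
                if not full_curve:
                    break
        if chosen == 0:  # cutoff never reached within k_max
            logger.warning(
                "variance cutoff %.3f not reached by k_max=%d; using k_max",
                config.variance_cutoff,
                k_max,
            )
            chosen = k_max if k_max > 1 else 1

    raw = (
        models[chosen].labels_ if chosen > 1 else np.zeros(x.shape[0], dtype=int)
    )
    labels_nonmissing = _renumber_by_size(raw, chosen)
    labels = np.zeros(x_all.shape[0], dtype=int)
    labels[~missing] = labels_nonmissing
    return labels, chosen, np.asarray(wcss)


def _renumber_by_size(raw_labels: np.ndarray, k: int) -> np.ndarray:
    """Map raw cluster ids to 1..k ordered by descending frame count.

    Ties broken by the lower raw id, for determinism.
    """
    counts = np.bincount(raw_labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-counts[c], c))
    mapping = np.empty(k, dtype=int)
    for rank, raw in enumerate(order, start=1):
        mapping[raw] = rank
    return mapping[raw_labels]


def summarize_postures(
    subject_id: str, features: DistanceFeatureMatrix, labels: np.ndarray
) -> PostureSummary:
    """Mean feature vector and frame count per posture label (> 0)."""
    ids = np.array(sorted(set(labels[labels > 0])), dtype=int)
    if ids.size == 0:
        raise Seb3rError(f"subject {subject_id}: no assigned frames")
    centroids = np.vstack(
        [features.values[labels == p].mean(axis=0) for p in ids]
    )
    counts = np.array([(labels == p).sum() for p in ids], dtype=int)
    return PostureSummary(
        subject_id=subject_id, centroids=centroids, posture_ids=ids, counts=counts
    )


def extract_postures(
    sessions: list[TrackingSession],
    config: ClusteringConfig | None = None,
    absolute: bool = False,
    subject_dir: str | Path | None = None,
    mean_distances_dir: str | Path | None = None,
) -> tuple[PostureSummary, list[ClusteredSession], DistanceFeatureMatrix]:
    """Run the whole of step 1 for one subject.

    Concatenates sessions, builds the pairwise-difference features, clusters
    with the elbow criterion, and splits the frame labels back per session.
    When ``subject_dir`` is given, one Clustered CSV per session is written
    there; when ``mean_distances_dir`` is given, the MouseIDDistMean table
    is written there (the paper-style "Mean Distances" collection folder).
    """
    if config is None:
        config = ClusteringConfig()
    subject_id = sessions[0].subject_id
    z, mask, origin = concat_sessions(sessions)
    features = pairwise_z_differences(z, mask, origin, absolute=absolute)
    labels, k, _ = elbow_kmeans(features, config)
    summary = summarize_postures(subject_id, features, labels)

    clustered: list[ClusteredSession] = []
    offset = 0
    for s in sessions:
        lab = labels[offset : offset + s.n_frames]
        clustered.append(
            ClusteredSession(
                subject_id=subject_id,
                session_label=s.session_label,
                z=s.z,
                postures=lab.copy(),
                fps=s.fps,
            )
        )
        offset += s.n_frames

    if subject_dir is not None:
        subject_dir = Path(subject_dir)
        subject_dir.mkdir(parents=True, exist_ok=True)
        for c in clustered:
            io_dlc.write_clustered(
                subject_dir / f"Clustered_{c.session_label}.csv",
                subject_id,
                c.z,
                c.postures,
            )
    if mean_distances_dir is not None:
        mean_distances_dir = Path(mean_distances_dir)
        mean_distances_dir.mkdir(parents=True, exist_ok=True)
        io_dlc.write_mean_distances(
            mean_distances_dir / f"Mouse{subject_id}DistMean.csv",
            subject_id,
            summary.centroids,
            summary.posture_ids,
        )
    return summary, clustered, features
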