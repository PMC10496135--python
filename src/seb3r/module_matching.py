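"""Step 2: match postures across subjects into cohort-level behavioral modules.

Each subject's posture centroids (mean 15-dimensional distance vectors) are
pooled and clustered a second time with k-means at a fixed, user-chosen k.
Postures from different animals that land in the same cluster are declared
the same behavioral module (BM) — the cohort-level unit all downstream
analytics operate on.  The recommended k is ``min(per-subject posture
count) + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_dlc
from .errors import Seb3rError
from .posture_extraction import ClusteringConfig, PostureSummary, _fit_kmeans

logger = logging.getLogger(__name__)


@dataclass
class ModuleMap:
    """Mapping from (subject_id, posture_id) to behavioral-module id."""

    entries: dict[tuple[str, int], int]
    k: int

    def __post_init__(self):
        bms = set(self.entries.values())
        if not bms <= set(range(1, self.k + 1)):
            raise Seb3rError(f"module ids {sorted(bms)} outside 1..{self.k}")

    def __getitem__(self, key: tuple[str, int]) -> int:
        return self.entries[key]

    @property
    def n_modules(self) -> int:
        return len(set(self.entries.values()))


def recommend_k(posture_counts: list[int]) -> int:
    """Recommended module count: min(per-subject posture counts) + 1.

    One more cluster than the sparsest subject's posture repertoire gives
    every subject's postures room to separate while keeping modules
    replicated across most animals.
    """
    if not posture_counts:
        raise Seb3rError("posture_counts must be nonempty")
    if any(c < 1 for c in posture_counts):
        raise Seb3rError("posture counts must be positive")
    return min(posture_counts) + 1


def match_postures(
    summaries: list[PostureSummary],
    k: int,
    config: ClusteringConfig | None = None,
    weighted: bool = False,
    out_path: str | Path | None = None,
) -> ModuleMap:
    """Pool all subjects' posture centroids and k-means them at fixed k.

    Uses the same seeded k-means++ engine as step 1 but with no elbow
    search.  Module ids are renumbered by descending total frame count
    across the cohort.  Two postures of the same subject may share a module
    (they are merged downstream).  With ``weighted=True`` each centroid row
    is weighted by its posture's frame count.
    """
    if config is None:
        config = ClusteringConfig()
    if not summaries:
        raise Seb3rError("need at least one posture summary")
    if k < 1:
        raise Seb3rError("k must be >= 1")

    keys: list[tuple[str, int]] = []
    rows: list[np.ndarray] = []
    weights: list[int] = []
    for s in summaries:
        for row, pid, cnt in zip(s.centroids, s.posture_ids, s.counts):
            key = (s.subject_id, int(pid))
            if key in keys:
                raise Seb3rError(f"duplicate (subject, posture) key {key}")
            keys.append(key)
            rows.append(row)
            weights.append(int(cnt))
    x = np.vstack(rows)
    if k > x.shape[0]:
        raise Seb3rError(f"k={k} exceeds the {x.shape[0]} pooled posture centroids")

    if k == 1:
        raw = np.zeros(x.shape[0], dtype=int)
    else:
        from sklearn.cluster import KMeans

        rs = np.random.SeedSequence([config.seed, 0x5EB3]).generate_state(1)[0] % (2**31)
        km = KMeans(
            n_clusters=k,
            n_init=config.replicates,
            init="k-means++",
            max_iter=config.max_iter,
            random_state=int(rs),
        )
        km.fit(x, sample_weight=np.asarray(weights, float) if weighted else None)
        raw = km.labels_

    # renumber modules by descending total frames across the cohort
    totals = np.zeros(k, dtype=float)
    for lab, w in zip(raw, weights):
        totals[lab] += w
    order = sorted(range(k), key=lambda c: (-totals[c], c))
    rank = {raw_id: r for r, raw_id in enumerate(order, start=1)}
    entries = {key: rank[lab] for key, lab in zip(keys, raw)}

    merged = len(entries) - len(set(entries.values()))
    for subj in {s.subject_id for s in summaries}:
        own = [bm for (sid, _), bm in entries.items() if sid == subj]
        if len(own) != len(set(own)):
            logger.info("subject %s has postures merged into a shared module", subj)

    module_map = ModuleMap(entries=entries, k=k)
    if out_path is not None:
        io_dlc.write_modules_assigned(Path(out_path), entries)
    return module_map
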