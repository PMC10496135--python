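"""End-to-end orchestration of the three pipeline steps over a mother folder."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import io_dlc
from .errors import Seb3rError
from .frame_labeling import FrequencyTable, LabeledSession, assign_modules, count_frequencies
from .io_dlc import CohortLayout, TrackingSession
from .module_matching import ModuleMap, match_postures, recommend_k
from .posture_extraction import (
    ClusteredSession,
    ClusteringConfig,
    PostureSummary,
    extract_postures,
)


@dataclass
class PipelineResult:
    layout: CohortLayout
    sessions: dict[str, list[TrackingSession]]
    summaries: dict[str, PostureSummary]
    clustered: dict[str, list[ClusteredSession]]
    module_map: ModuleMap
    labeled: dict[str, list[LabeledSession]]
    frequencies: dict[str, FrequencyTable]
    k: int


def run_pipeline(
    root: str | Path,
    fps: float = io_dlc.DEFAULT_FPS,
    config: ClusteringConfig | None = None,
    k: int | str = "auto",
    absolute: bool = False,
    weighted: bool = False,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run posture extraction, module matching and frame labeling in order.

    ``k`` is the module count for the cross-subject matching; ``"auto"``
    applies the min(poses)+1 recommendation to the extracted per-subject
    posture counts.  With ``write_outputs`` the standard CSV products are
    written under the mother folder (Mean Distances, Clustered, ModulesAssigned,
    per-subject Modules folders, per-subject frequency files).
    """
    if config is None:
        config = ClusteringConfig()
    root = Path(root)
    layout = io_dlc.discover_layout(root)
    sessions = io_dlc.load_cohort(layout, fps=fps)
    report = io_dlc.validate_frame_counts(layout, sessions)
    if not report.ok:
        raise Seb3rError(
            "frame counts differ across subjects: "
            + "; ".join(f"{s}/{lab}={n}" for s, lab, n in report.mismatches)
        )

    mean_dir = root / "Mean Distances" if write_outputs else None
    summaries: dict[str, PostureSummary] = {}
    clustered: dict[str, list[ClusteredSession]] = {}
    for subject, sess in sessions.items():
        summary, clust, _ = extract_postures(
            sess,
            config=config,
            absolute=absolute,
            subject_dir=(root / subject) if write_outputs else None,
            mean_distances_dir=mean_dir,
        )
        summaries[subject] = summary
        clustered[subject] = clust

    counts = [s.n_postures for s in summaries.values()]
    k_final = recommend_k(counts) if k == "auto" else int(k)
    module_map = match_postures(
        list(summaries.values()),
        k_final,
        config=config,
        weighted=weighted,
        out_path=(root / "ModulesAssigned.csv") if write_outputs else None,
    )

    labeled: dict[str, list[LabeledSession]] = {}
    frequencies: dict[str, FrequencyTable] = {}
    for subject, clust in clustered.items():
        lab = assign_modules(
            clust,
            module_map,
            modules_dir=(root / subject / "Modules") if write_outputs else None,
        )
        labeled[subject] = lab
        frequencies[subject] = count_frequencies(
            lab,
            n_modules=k_final,
            out_path=(root / subject / f"FrequenciesMouse{subject}.csv")
            if write_outputs
            else None,
        )
    return PipelineResult(
        layout=layout,
        sessions=sessions,
        summaries=summaries,
        clustered=clustered,
        module_map=module_map,
        labeled=labeled,
        frequencies=frequencies,
        k=k_final,
    )
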