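"""Synthetic DLC-3D-style cohorts with planted posture archetypes.

The generator emulates what the pipeline's upstream tracking produces: per
frame, the heights of six bodily hotspots while a mouse switches between a
repertoire of discrete posture archetypes (rearing-like profiles with
nose/eyes high, a hunched profile with a mid-back apex, flat locomotion,
and so on).  Switching is semi-Markov with geometric dwell times, each
animal carries an additive body-size offset, tracking adds i.i.d. Gaussian
noise, and occasional frames go missing — so every pipeline stage can be
validated against known ground truth without any recordings.

The generated mother folder matches exactly what
:func:`seb3r.io_dlc.discover_layout` expects; ground-truth label files are
stored in a sibling ``ground_truth`` directory, never inside the subject
folders.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import Seb3rError
from .io_dlc import DEFAULT_FPS, HOTSPOTS, N_HOTSPOTS, TrackingSession
from .posture_extraction import PAIR_INDEX


@dataclass
class ArchetypeSet:
    """A x 6 matrix of hotspot-height profiles (arbitrary camera units)."""

    archetypes: np.ndarray
    names: list[str] | None = None

    def __post_init__(self):
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.archetypes.ndim != 2 or self.archetypes.shape[1] != N_HOTSPOTS:
            raise Seb3rError(f"archetypes must be (A, {N_HOTSPOTS})")
        if self.archetypes.shape[0] < 1:
            raise Seb3rError("need at least one archetype")
        if np.unique(self.archetypes, axis=0).shape[0] != self.archetypes.shape[0]:
            raise Seb3rError("archetype rows must be pairwise distinct")

    @property
    def n_archetypes(self) -> int:
        return self.archetypes.shape[0]


# Height profiles (units ~ cm above the floor), one per archetype, columns
# in canonical hotspot order.  Each profile keeps the qualitative character
# of the posture it is named after (rearing: nose high, tail low; hunched:
# mid-back apex; head-dip: nose lowest; climb: rear highest) but the set as
# a whole is uniformized so that every pair of archetypes is comparably far
# apart in the 15-dimensional pairwise-difference feature space (min
# separation 28 units, ~10x the within-cluster spread at the default
# tracking noise).  Without that uniformity the elbow criterion is
# ill-posed: two nearly coincident archetypes next to a few extreme ones
# would be merged at any fixed explained-variance cutoff.  Profiles are
# deliberately not translates of one another: a pure additive shift is
# invisible to the pairwise-difference features, exactly like a bigger
# animal.
_BASE_PROFILES: dict[str, tuple[float, ...]] = {
    "flat_walk": (2.44, 12.18, 8.43, 15.58, 11.66, 4.65),
    "unaided_rear": (14.43, 11.75, 8.37, 12.32, 7.57, 0.50),
    "aided_rear": (10.87, 13.97, 15.37, 6.42, 3.71, 4.61),
    "hunched": (8.37, 3.29, 11.14, 17.67, 8.63, 5.85),
    "stretch_attend": (1.64, 10.09, 5.08, 10.32, 12.87, 14.95),
    "head_dip": (0.92, 6.55, 15.30, 11.76, 9.44, 10.99),
    "groom": (5.20, 4.17, 9.19, 11.09, 17.85, 7.45),
    "vigilant_crouch": (17.41, 12.67, 6.78, 4.24, 5.80, 8.05),
    "climb": (7.50, 1.46, 8.91, 9.29, 11.11, 16.69),
}


def default_archetypes(n: int = 9, scale: float = 1.0) -> ArchetypeSet:
    """The bundled repertoire of up to 9 posture archetypes.

    ``scale`` multiplies every profile, widening the separation between
    archetypes in feature space without changing their shape.
    """
    if not 1 <= n <= len(_BASE_PROFILES):
        raise Seb3rError(f"n must be in 1..{len(_BASE_PROFILES)}")
    names = list(_BASE_PROFILES)[:n]
    return ArchetypeSet(
        archetypes=np.array([_BASE_PROFILES[k] for k in names]) * scale,
        names=names,
    )


def feature_separation(archetypes: ArchetypeSet) -> float:
    """Smallest pairwise Euclidean distance between archetypes in the
    15-dimensional pairwise-difference feature space."""
    a = archetypes.archetypes
    i_idx = np.array([i for i, _ in PAIR_INDEX])
    j_idx = np.array([j for _, j in PAIR_INDEX])
    feats = a[:, i_idx] - a[:, j_idx]
    d = np.sqrt(((feats[:, None, :] - feats[None, :, :]) ** 2).sum(-1))
    return float(d[np.triu_indices(len(a), k=1)].min())


@dataclass
class SimulationConfig:
    """Cohort generation parameters.

    Defaults mirror the validation-scale experiment: 12 animals, five
    3-min sessions at 25 fps (4500 frames each), each animal expressing at
    least 8 of 9 archetypes, geometric bout dwell with mean 10 frames,
    tracking noise of 0.5 camera units per hotspot, an additive per-animal
    body-size offset, and 1% missing frames.
    """

    n_subjects: int = 12
    n_sessions: int = 5
    frames_per_session: int = 4500
    mean_bout_frames: float = 10.0
    noise_sd: float = 0.5
    offset_sd: float = 1.0
    min_expressed: int = 8
    missing_prob: float = 0.01
    fps: float = DEFAULT_FPS
    seed: int = 0
    session_labels: list[str] = field(
        default_factory=lambda: ["habituation", "SHAM", "T1", "T2", "T3"]
    )

    def __post_init__(self):
        for name in ("n_subjects", "n_sessions", "frames_per_session"):
            if getattr(self, name) < 1:
                raise Seb3rError(f"{name} must be positive")
        if self.mean_bout_frames < 1:
            raise Seb3rError("mean_bout_frames must be >= 1")
        if not 0 <= self.missing_prob <= 1:
            raise Seb3rError("missing_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise Seb3rError("noise and offset s.d. must be >= 0")
        if len(self.session_labels) < self.n_sessions:
            self.session_labels = [
                f"S{i + 1}" for i in range(self.n_sessions)
            ]

    def labels(self) -> list[str]:
        return self.session_labels[: self.n_sessions]


def _simulate_state_stream(
    rng: np.random.Generator, states: np.ndarray, n_frames: int, mean_dwell: float
) -> np.ndarray:
    """Semi-Markov switching: geometric dwell, uniform jump to another state."""
    out = np.empty(n_frames, dtype=int)
    pos = 0
    current = int(rng.choice(states))
    p = 1.0 / mean_dwell
    while pos < n_frames:
        dwell = int(rng.geometric(p)) if len(states) > 1 else n_frames - pos
        dwell = min(dwell, n_frames - pos)
        out[pos : pos + dwell] = current
        pos += dwell
        if len(states) > 1:
            others = states[states != current]
            current = int(rng.choice(others))
    return out


def simulate_subject(
    archetypes: ArchetypeSet,
    config: SimulationConfig,
    subject_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrackingSession], list[np.ndarray]]:
    """Generate one animal's sessions plus per-frame ground-truth labels.

    Returns ``(sessions, truth)`` where ``truth[s][f]`` is the 1-based
    archetype index expressed at frame f of session s (the label is defined
    even for frames whose tracking is blanked as missing).
    """
    a = archetypes.n_archetypes
    if config.min_expressed > a:
        raise Seb3rError(
            f"min_expressed={config.min_expressed} exceeds {a} archetypes"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_expressed = int(rng.integers(config.min_expressed, a + 1))
    expressed = np.sort(rng.choice(a, size=n_expressed, replace=False))
    offset = rng.normal(0.0, config.offset_sd)

    sessions: list[TrackingSession] = []
    truth: list[np.ndarray] = []
    for label in config.labels():
        states = _simulate_state_stream(
            rng, expressed, config.frames_per_session, config.mean_bout_frames
        )
        z = archetypes.archetypes[states] + offset
        z = z + rng.normal(0.0, config.noise_sd, size=z.shape)
        missing = rng.random(config.frames_per_session) < config.missing_prob
        z[missing] = np.nan
        sessions.append(
            TrackingSession(
                subject_id=subject_id, session_label=label, z=z, fps=config.fps
            )
        )
        truth.append(states + 1)
    return sessions, truth


def write_dlc_csv(session: TrackingSession, path: str | Path) -> None:
    """Write a session in the native DLC-3D dialect (3-row header, x/y/z
    triplets per body part).  x and y are filled with zeros — the pipeline
    consumes only z.  Missing frames are written as empty cells."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + ["seb3r_synthetic"] * (3 * N_HOTSPOTS))
        w.writerow(["bodyparts"] + [h for h in HOTSPOTS for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "z"] * N_HOTSPOTS)
        for f in range(session.n_frames):
            row: list[str] = [str(f)]
            for h in range(N_HOTSPOTS):
                zv = session.z[f, h]
                if np.isfinite(zv):
                    row += ["0", "0", "%.12g" % zv]
                else:
                    row += ["", "", ""]
            w.writerow(row)


def simulate_cohort(
    archetypes: ArchetypeSet,
    config: SimulationConfig,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Write a full mother folder of DLC-3D CSVs plus ground-truth files.

    Layout: ``out_dir/<subject_id>/<subject_id>_<session>.csv`` for tracking
    and ``out_dir/ground_truth/truth_<subject_id>_<session>.csv`` for the
    planted per-frame archetype labels.  Returns the in-memory ground truth
    keyed by subject id then session label — key by label, not position,
    because folder discovery orders sessions by file name, which need not
    match generation order.  Bit-identical under a fixed seed.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise Seb3rError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    root_ss = np.random.SeedSequence(config.seed)
    subject_seeds = root_ss.spawn(config.n_subjects)
    truth_all: dict[str, dict[str, np.ndarray]] = {}
    for i in range(config.n_subjects):
        subject_id = str(101 + i)
        rng = np.random.default_rng(subject_seeds[i])
        sessions, truth = simulate_subject(archetypes, config, subject_id, rng)
        sub_dir = out_dir / subject_id
        sub_dir.mkdir(exist_ok=True)
        truth_all[subject_id] = {}
        for s, t in zip(sessions, truth):
            write_dlc_csv(s, sub_dir / f"{subject_id}_{s.session_label}.csv")
            np.savetxt(
                truth_dir / f"truth_{subject_id}_{s.session_label}.csv",
                t,
                fmt="%d",
                header="archetype",
                comments="",
            )
            truth_all[subject_id][s.session_label] = t
    return truth_all
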