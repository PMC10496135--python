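"""Session-level statistics on module frequencies.

Two analyses: (1) normalized change in time spent per module relative to a
reference session, the symmetric index (a - b)/(a + b) in [-1, 1], used with
either the habituation session (stimulus-independent vs stimulus-driven
change) or the SHAM session (whisker-independent vs whisker-dependent
behavior) as reference; (2) the Pearson correlation between per-subject time
spent in each module and manually scored ethogram categories (active/passive
avoidance, aided/unaided rearing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import Seb3rError
from .frame_labeling import FrequencyTable

ETHOGRAM_COLUMNS = ("subject_id", "category", "time")


def normalized_change(a: float, b: float) -> float:
    """(a - b) / (a + b), defined as 0 when both counts are zero."""
    if a < 0 or b < 0:
        raise Seb3rError("frame counts must be non-negative")
    if a == 0 and b == 0:
        return 0.0
    return (a - b) / (a + b)


def normalize_sessions(
    freq: FrequencyTable, reference: str
) -> pd.DataFrame:
    """Score each (module, non-reference session) against the reference.

    value = (test frames - reference frames)/(test frames + reference
    frames), one row per module per non-reference session.  Stored values
    are the [-1, 1] fraction; multiply by 100 for percent reporting.
    """
    if reference not in freq.session_labels:
        raise Seb3rError(
            f"reference session {reference!r} not in {freq.session_labels}"
        )
    ref_idx = freq.session_labels.index(reference)
    rows = []
    for b_idx, bm in enumerate(freq.bm_ids):
        if bm == 0:
            continue
        ref_count = freq.counts[b_idx, ref_idx]
        for s_idx, label in enumerate(freq.session_labels):
            if s_idx == ref_idx:
                continue
            rows.append(
                {
                    "subject_id": freq.subject_id,
                    "bm_id": bm,
                    "session_label": label,
                    "value": normalized_change(
                        float(freq.counts[b_idx, s_idx]), float(ref_count)
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "bm_id", "session_label", "value"])


def bm_time_matrix(
    freqs: list[FrequencyTable], sessions: list[str] | None = None
) -> pd.DataFrame:
    """Per-subject total frames in each module (rows subjects, cols modules).

    ``sessions`` restricts the tally to the named sessions (default: all).
    """
    if not freqs:
        raise Seb3rError("need at least one frequency table")
    bms = sorted({bm for f in freqs for bm in f.bm_ids if bm != 0})
    data = {}
    for f in freqs:
        if f.subject_id in data:
            raise Seb3rError(f"duplicate frequency table for subject {f.subject_id}")
        if sessions is None:
            s_idx = list(range(len(f.session_labels)))
        else:
            missing = [s for s in sessions if s not in f.session_labels]
            if missing:
                raise Seb3rError(f"subject {f.subject_id} lacks sessions {missing}")
            s_idx = [f.session_labels.index(s) for s in sessions]
        row = {}
        for bm in bms:
            if bm in f.bm_ids:
                row[bm] = int(f.counts[f.bm_ids.index(bm), s_idx].sum())
            else:
                row[bm] = 0
        data[f.subject_id] = row
    return pd.DataFrame.from_dict(data, orient="index")[bms]


def correlate_bm_ethogram(
    freqs: list[FrequencyTable],
    ethogram: pd.DataFrame,
    sessions: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r between time in each module and each ethogram category.

    ``ethogram`` is a tidy table with columns subject_id, category, time
    (frames or seconds — r is invariant to the unit at fixed fps).  Returns
    one row per (module, category) with r, the two-sided t-distribution p,
    n, and ``undefined`` = True where either vector is constant (r and p are
    NaN there, never silently 0).  Requires >= 3 matched subjects.
    """
    missing_cols = [c for c in ETHOGRAM_COLUMNS if c not in ethogram.columns]
    if missing_cols:
        raise Seb3rError(f"ethogram table lacks columns {missing_cols}")
    bm_time = bm_time_matrix(freqs, sessions=sessions)
    etho = ethogram.pivot_table(
        index="subject_id", columns="category", values="time", aggfunc="sum"
    )
    etho.index = etho.index.astype(str)
    bm_subjects = set(bm_time.index)
    et_subjects = set(etho.index)
    unmatched = sorted(bm_subjects ^ et_subjects)
    if unmatched:
        raise Seb3rError(f"subject ids not present on both sides: {unmatched}")
    order = sorted(bm_subjects)
    if len(order) < 3:
        raise Seb3rError(f"need >= 3 paired subjects, got {len(order)}")
    bm_time = bm_time.loc[order]
    etho = etho.loc[order]

    rows = []
    for bm in bm_time.columns:
        x = bm_time[bm].to_numpy(dtype=float)
        for cat in etho.columns:
            y = etho[cat].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p, undef = float("nan"), float("nan"), True
            else:
                res = stats.pearsonr(x, y)
                r, p, undef = float(res.statistic), float(res.pvalue), False
            rows.append(
                {
                    "bm_id": bm,
                    "category": cat,
                    "r": r,
                    "p": p,
                    "n": len(order),
                    "undefined": undef,
                }
            )
    return pd.DataFrame(rows)
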