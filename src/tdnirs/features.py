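"""Integral/centroid feature extraction and group-level statistics.

Each response curve is reduced to two scalars over the task window: the
*integral* (signed trapezoidal area of the deviation from the rest
reference; intensity of the response) and the *centroid* (absolute-
deviation-weighted mean time relative to task onset; timing of the
response).  For the two task-rest ratio families the twelve features carry
canonical names::

    F1  integral  activated     RHbO1     F7  integral  activated     RHbO2
    F2  centroid  activated     RHbO1     F8  centroid  activated     RHbO2
    F3  integral  suppressive   RHbO1     F9  integral  suppressive   RHbO2
    F4  centroid  suppressive   RHbO1     F10 centroid  suppressive   RHbO2
    F5  integral  channel_avg   RHbO1     F11 integral  channel_avg   RHbO2
    F6  centroid  channel_avg   RHbO1     F12 centroid  channel_avg   RHbO2

Per-gate ``dHbO`` families use descriptive column names
(``dHbO2_sup_integral`` etc.).  Group selection is a two-tailed Welch
t-test per feature at alpha = 0.05 with no multiplicity correction by
default (Benjamini-Hochberg available); test-retest comparison is a paired
t-test across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .physics import HbOSeries
from .protocol import TaskProtocol
from .responses import (
    ACTIVATED,
    SUPPRESSIVE,
    ChannelQuality,
    QualityThresholds,
    ResponseTriplet,
    build_response_triplet,
    reject_channels,
)

RESPONSES = (ACTIVATED, SUPPRESSIVE, "channel_avg")
VARIABLES = ("integral", "centroid")

#: canonical feature index for the task-rest ratio families
FEATURE_INDEX: dict[str, tuple[str, str, str]] = {}
for _fi, _fam in enumerate(("RHbO1", "RHbO2")):
    for _ri, _resp in enumerate(RESPONSES):
        for _vi, _var in enumerate(VARIABLES):
            FEATURE_INDEX[f"F{_fi * 6 + _ri * 2 + _vi + 1}"] = (_fam, _resp, _var)

RHBO_FEATURES = tuple(FEATURE_INDEX)


def feature_name(family: str, response: str, variable: str) -> str:
    """Canonical column name for a (family, response, variable) triple."""
    for name, key in FEATURE_INDEX.items():
        if key == (family, response, variable):
            return name
    short = {ACTIVATED: "act", SUPPRESSIVE: "sup", "channel_avg": "avg"}[response]
    return f"{family}_{short}_{variable}"


def integral_feature(
    curve: np.ndarray,
    protocol: TaskProtocol,
    reference: float,
) -> float:
    """Signed area of (curve - reference) over the task window.

    Trapezoidal rule on the available task-window frames; missing frames
    are dropped (pairwise-available integration, no interpolation).
    Suppressive responses therefore yield negative integrals.
    """
    t = np.arange(len(curve)) / protocol.fs_hz
    mask = protocol.task_mask(t) & np.isfinite(curve)
    if np.count_nonzero(mask) < 2:
        return np.nan
    return float(np.trapezoid(np.asarray(curve, float)[mask] - reference, t[mask]))


def centroid_feature(
    curve: np.ndarray,
    protocol: TaskProtocol,
    reference: float,
) -> float:
    """Absolute-deviation-weighted mean time, in s relative to task onset.

    ``t_c = sum(t * |x - ref|) / sum(|x - ref|)`` over task-window frames;
    the absolute weight gives suppressive responses a meaningful timing.
    Returns NaN when the total weight is zero.
    """
    t = np.arange(len(curve)) / protocol.fs_hz
    mask = protocol.task_mask(t) & np.isfinite(curve)
    if np.count_nonzero(mask) < 2:
        return np.nan
    w = np.abs(np.asarray(curve, float)[mask] - reference)
    total = w.sum()
    if total <= 0:
        return np.nan
    return float(np.sum((t[mask] - protocol.task_onset_s) * w) / total)


def triplet_features(
    triplet: ResponseTriplet, protocol: TaskProtocol, family: str
) -> dict[str, float]:
    """All six features of one family's response triplet."""
    out = {}
    for response in RESPONSES:
        curve = triplet.curve(response)
        empty = triplet.is_empty(response)
        for variable, fn in (("integral", integral_feature), ("centroid", centroid_feature)):
            name = feature_name(family, response, variable)
            out[name] = np.nan if empty else fn(curve, protocol, triplet.reference)
    return out


def sample_features(
    hbo: dict[str, HbOSeries],
    protocol: TaskProtocol,
    thresholds: QualityThresholds | None = None,
    quality: ChannelQuality | None = None,
) -> tuple[dict[str, float], list[dict]]:
    """Features for one recording across its hemoglobin families.

    ``quality`` may be supplied when rejection was already decided at the
    photon-count level (gated series); otherwise each family's series is
    screened independently.  Returns the feature dict and per-family
    quality summary rows.
    """
    feats: dict[str, float] = {}
    qrows: list[dict] = []
    for family, series in hbo.items():
        q = quality if quality is not None else reject_channels(series, thresholds, protocol)
        qrows.append(
            {
                "family": family,
                "n_channels": len(q.channel_ids),
                "n_rejected": q.n_rejected,
                "rejected_fraction": q.rejected_fraction,
            }
        )
        if q.all_rejected:
            for response in RESPONSES:
                for variable in VARIABLES:
                    feats[feature_name(family, response, variable)] = np.nan
            continue
        triplet = build_response_triplet(series, q, protocol)
        feats.update(triplet_features(triplet, protocol, family))
    return feats, qrows


def build_feature_table(
    samples,
    protocol: TaskProtocol,
    thresholds: QualityThresholds | None = None,
    hbo_getter=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the samples x features table for a cohort.

    ``samples`` is an iterable of objects with ``sample_id``,
    ``subject_id``, ``group``, ``session`` and an ``hbo`` mapping (or
    provide ``hbo_getter(sample) -> dict``).  Returns the feature table
    and a per-(sample, family) quality table.
    """
    rows, qrows = [], []
    for s in samples:
        hbo = hbo_getter(s) if hbo_getter is not None else s.hbo
        feats, quality = sample_features(hbo, protocol, thresholds)
        row = {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "group": s.group,
            "session": s.session,
        }
        row.update(feats)
        rows.append(row)
        for q in quality:
            qrows.append({"sample_id": s.sample_id, **q})
    return pd.DataFrame(rows), pd.DataFrame(qrows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"sample_id", "subject_id", "group", "session"}
    return [c for c in table.columns if c not in meta]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float, bool]:
    """Two-sample t with explicit handling of zero-variance degeneracy."""
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), False


def select_features(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("HC", "MDD"),
    alpha: float = 0.05,
    equal_var: bool = False,
    correction: str | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Two-tailed t-test per feature between the two groups.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled form).  ``correction="bh"`` applies Benjamini-Hochberg to the
    p-values before thresholding; the default applies none, selecting
    features at raw p <= alpha.
    """
    features = features or feature_columns(table)
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []
    for feat in features:
        a = ga[feat].dropna().to_numpy(float)
        b = gb[feat].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "feature": feat,
                    f"mean_{groups[0]}": np.nan,
                    f"mean_{groups[1]}": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "selected": False,
                    "degenerate": False,
                }
            )
            continue
        t, p, degenerate = _welch_t(a, b, equal_var)
        rows.append(
            {
                "feature": feat,
                f"mean_{groups[0]}": float(a.mean()),
                f"mean_{groups[1]}": float(b.mean()),
                "t": t,
                "p": p,
                "selected": False,
                "degenerate": degenerate,
            }
        )
    report = pd.DataFrame(rows).set_index("feature")
    pvals = report["p"].to_numpy(float)
    if correction == "bh":
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = stats.false_discovery_control(pvals[finite], method="bh")
        report["p_adjusted"] = adj
        report["selected"] = report["p_adjusted"] <= alpha
    else:
        report["selected"] = report["p"] <= alpha
    return report


def test_retest_compare(
    table: pd.DataFrame,
    features: list[str] | None = None,
    subject_col: str = "subject_id",
    session_col: str = "session",
    sessions: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Paired two-tailed t-test of session 1 vs session 2 per feature.

    Subjects missing either session are excluded.  Identical sessions
    (all-zero differences) report p = 1 by convention.
    """
    features = features or feature_columns(table)
    rows = []
    for feat in features:
        wide = table.pivot_table(
            index=subject_col, columns=session_col, values=feat, aggfunc="mean"
        )
        wide = wide.dropna(subset=list(sessions))
        a = wide[sessions[0]].to_numpy(float)
        b = wide[sessions[1]].to_numpy(float)
        if len(a) < 2:
            rows.append({"feature": feat, "n_subjects": len(a), "t": np.nan, "p": np.nan})
            continue
        diff = b - a
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append(
            {"feature": feat, "n_subjects": len(a), "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("feature")
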