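"""Channel quality rejection and activation/suppression response separation.

Poor optode-scalp coupling corrupts a substantial fraction of channels in
scalp-probe recordings of speech tasks; those channels must be excluded
before any group-level inference.  The retained channels of a recording
are then partitioned, per hemoglobin parameter family, into an *activated*
class (task-window mean above the rest reference) and a *suppressive*
class (at or below it), and summarized as three response curves: the
activated mean, the suppressive mean, and the channel-wise average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .physics import GatedSeries, HbOSeries
from .protocol import TaskProtocol

ACTIVATED = "activated"
SUPPRESSIVE = "suppressive"


@dataclass(frozen=True)
class QualityThresholds:
    """Channel-rejection thresholds; all configurable.

    min_median_counts applies to gated photon counts only.  Baseline CV,
    rest-shift (pre-task baseline vs. end-of-recording rest level,
    relative) and burst-fraction (frames whose second difference exceeds
    ``burst_z`` robust SDs) apply to both gated and ratio series;
    max_baseline_offset (distance of the baseline mean from the rest
    reference) applies to ratio series.
    """

    min_median_counts: float = 100.0
    max_baseline_cv: float = 0.15
    max_rest_shift: float = 0.15
    max_burst_fraction: float = 0.05
    burst_z: float = 5.0
    max_baseline_offset: float = 0.20
    max_missing_fraction: float = 0.5


@dataclass
class ChannelQuality:
    channel_ids: tuple[int, ...]
    retained: np.ndarray  # bool per channel
    reasons: dict[int, tuple[str, ...]]  # channel_id -> rejection reasons
    metrics: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(~self.retained))

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / len(self.channel_ids)

    @property
    def retained_ids(self) -> tuple[int, ...]:
        return tuple(np.array(self.channel_ids)[self.retained].tolist())

    @property
    def all_rejected(self) -> bool:
        return self.n_rejected == len(self.channel_ids)


def summarize_rejections(rejected_counts: np.ndarray, n_channels: int) -> dict:
    """Cohort-level rejection summary in reporting units.

    Returns the mean and SD of rejected channels per recording together
    with the mean rejected percentage rounded to a whole percent (e.g. a
    mean of 7.5 rejected channels out of 22 reports as 34%).
    """
    counts = np.asarray(rejected_counts, float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return {
        "mean_rejected": mean,
        "sd_rejected": sd,
        "n_channels": n_channels,
        "percent_rejected": int(round(100.0 * mean / n_channels)),
        "percent_sd": int(round(100.0 * sd / n_channels)),
    }


def _burst_fraction(x: np.ndarray, burst_z: float) -> float:
    """Fraction of frames with outlying second differences (robust z).

    Second differences suppress both slow hemodynamic transitions and
    linear drift, isolating spike artifacts.  The robust scale is floored
    at a small fraction of the signal's overall robust spread so that a
    noise-free smooth recording (zero difference MAD) is not flagged.
    """
    x = x[np.isfinite(x)]
    if x.size < 6:
        return 0.0
    d2 = np.diff(x, n=2)
    med = np.median(d2)
    mad = 1.4826 * np.median(np.abs(d2 - med))
    # floor on the overall signal spread: a smooth noise-free recording has
    # near-zero difference MAD but a finite task swing, and must not flag
    scale = max(mad, 0.02 * float(np.std(x)))
    if scale <= 0:
        return 0.0
    return float(np.count_nonzero(np.abs(d2 - med) > burst_z * scale) / d2.size)


def _masked_mean(x: np.ndarray, mask: np.ndarray) -> float:
    vals = x[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def reject_channels(
    series: GatedSeries | HbOSeries,
    thresholds: QualityThresholds | None = None,
    protocol: TaskProtocol | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> ChannelQuality:
    """Flag channels whose signal quality precludes hemodynamic analysis.

    Deterministic given thresholds; each rejected channel carries at least
    one named reason.  Accepts either gated photon counts (count-level
    checks plus stability checks) or a derived hemoglobin series
    (stability checks relative to the rest reference).
    """
    thr = thresholds or QualityThresholds()
    protocol = protocol or getattr(series, "protocol", None)
    if protocol is None and baseline_window is None:
        raise ValueError("a protocol or an explicit baseline window is required")
    times = series.frame_times_s
    if baseline_window is None:
        baseline_window = protocol.baseline_window()
    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    if protocol is not None:
        tail = protocol.tail_mask(times)
    else:
        tail = times >= times[-1] - (times[-1] - times[0]) * 0.15

    rows = []
    reasons: dict[int, tuple[str, ...]] = {}
    retained = np.ones(len(series.channel_ids), bool)

    if isinstance(series, GatedSeries):
        vals = series.values  # (ch, wl, gate, T)
        for c, ch_id in enumerate(series.channel_ids):
            why: list[str] = []
            total = np.nansum(vals[c], axis=(0, 1))  # per frame
            median_counts = float(np.nanmedian(total))
            if median_counts < thr.min_median_counts:
                why.append("low_counts")
            base_cv = 0.0
            shift = 0.0
            burst = 0.0
            for w in range(vals.shape[1]):
                for g in range(vals.shape[2]):
                    x = vals[c, w, g]
                    bm = _masked_mean(x, base)
                    if not np.isfinite(bm) or bm <= 0:
                        continue
                    bsd = float(np.nanstd(x[base]))
                    base_cv = max(base_cv, bsd / bm)
                    tm = _masked_mean(x, tail)
                    if np.isfinite(tm):
                        shift = max(shift, abs(tm - bm) / bm)
                    burst = max(burst, _burst_fraction(x, thr.burst_z))
            if median_counts >= thr.min_median_counts:
                # stability checks are meaningless on a dead channel
                if base_cv > thr.max_baseline_cv:
                    why.append("baseline_instability")
                if shift > thr.max_rest_shift:
                    why.append("drift")
                if burst > thr.max_burst_fraction:
                    why.append("burst")
            rows.append(
                {
                    "channel": ch_id,
                    "median_counts": median_counts,
                    "baseline_cv": base_cv,
                    "rest_shift": shift,
                    "burst_fraction": burst,
                }
            )
            if why:
                retained[c] = False
                reasons[ch_id] = tuple(why)
    else:
        ref = series.reference
        vals = series.values  # (ch, T)
        for c, ch_id in enumerate(series.channel_ids):
            why = []
            x = vals[c]
            missing = float(np.mean(~np.isfinite(x)))
            if ch_id in series.bad_channels or missing > thr.max_missing_fraction:
                why.append("unusable")
                rows.append(
                    {
                        "channel": ch_id,
                        "missing_fraction": missing,
                        "baseline_offset": np.nan,
                        "baseline_cv": np.nan,
                        "rest_shift": np.nan,
                        "burst_fraction": np.nan,
                    }
                )
                retained[c] = False
                reasons[ch_id] = tuple(why)
                continue
            bm = _masked_mean(x, base)
            scale = abs(ref) if ref != 0 else max(float(np.nanstd(x)), 1e-12)
            offset = abs(bm - ref) / scale if np.isfinite(bm) else np.inf
            bsd = float(np.nanstd(x[base]))
            base_cv = bsd / scale
            tm = _masked_mean(x, tail)
            shift = abs(tm - bm) / scale if np.isfinite(tm) else 0.0
            burst = _burst_fraction(x, thr.burst_z)
            if offset > thr.max_baseline_offset:
                why.append("baseline_offset")
            if base_cv > thr.max_baseline_cv:
                why.append("baseline_instability")
            if shift > thr.max_rest_shift:
                why.append("drift")
            if burst > thr.max_burst_fraction:
                why.append("burst")
            rows.append(
                {
                    "channel": ch_id,
                    "missing_fraction": missing,
                    "baseline_offset": offset,
                    "baseline_cv": base_cv,
                    "rest_shift": shift,
                    "burst_fraction": burst,
                }
            )
            if why:
                retained[c] = False
                reasons[ch_id] = tuple(why)

    return ChannelQuality(
        channel_ids=tuple(series.channel_ids),
        retained=retained,
        reasons=reasons,
        metrics=pd.DataFrame(rows),
    )


def classify_channel_response(
    values: np.ndarray,
    protocol: TaskProtocol,
    reference: float,
) -> str | None:
    """Classify one channel as activated or suppressive.

    Activated iff the task-window mean deviation from the reference is
    strictly positive; a tie counts as suppressive (a response that never
    rises above baseline is a non-positive deflection).  Returns None when
    more than half the task-window frames are missing.
    """
    task = protocol.task_mask(np.arange(len(values)) / protocol.fs_hz)
    x = np.asarray(values, float)[task]
    valid = np.isfinite(x)
    if valid.size == 0 or valid.mean() < 0.5:
        return None
    return ACTIVATED if float(np.mean(x[valid] - reference)) > 0.0 else SUPPRESSIVE


@dataclass
class ResponseTriplet:
    """Activated / suppressive / channel-average curves for one recording."""

    activated_mean: np.ndarray
    suppressive_mean: np.ndarray
    channel_avg: np.ndarray
    channel_class: dict[int, str]
    n_activated: int
    n_suppressive: int
    empty_activated: bool
    empty_suppressive: bool
    reference: float
    frame_times_s: np.ndarray

    def curve(self, response: str) -> np.ndarray:
        return {
            ACTIVATED: self.activated_mean,
            SUPPRESSIVE: self.suppressive_mean,
            "channel_avg": self.channel_avg,
        }[response]

    def is_empty(self, response: str) -> bool:
        return {
            ACTIVATED: self.empty_activated,
            SUPPRESSIVE: self.empty_suppressive,
            "channel_avg": self.n_activated + self.n_suppressive == 0,
        }[response]


def build_response_triplet(
    series: HbOSeries,
    quality: ChannelQuality,
    protocol: TaskProtocol | None = None,
) -> ResponseTriplet:
    """Separate a recording into class means and the channel average.

    Class means ignore missing frames pointwise; an empty class yields a
    constant curve at the reference with its empty flag set so downstream
    features can be emitted as missing rather than fabricated.
    """
    protocol = protocol or series.protocol
    if quality.retained.sum() == 0:
        raise ValueError("no retained channels; sample is invalid")
    ref = series.reference
    classes: dict[int, str] = {}
    act_rows, sup_rows = [], []
    for c, ch_id in enumerate(series.channel_ids):
        if not quality.retained[c]:
            continue
        klass = classify_channel_response(series.values[c], protocol, ref)
        if klass is None:
            continue
        classes[ch_id] = klass
        (act_rows if klass == ACTIVATED else sup_rows).append(series.values[c])

    n_frames = len(series.frame_times_s)

    def class_mean(rows: list[np.ndarray]) -> np.ndarray:
        if not rows:
            return np.full(n_frames, ref)
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.stack(rows), axis=0)

    all_rows = act_rows + sup_rows
    return ResponseTriplet(
        activated_mean=class_mean(act_rows),
        suppressive_mean=class_mean(sup_rows),
        channel_avg=class_mean(all_rows),
        channel_class=classes,
        n_activated=len(act_rows),
        n_suppressive=len(sup_rows),
        empty_activated=not act_rows,
        empty_suppressive=not sup_rows,
        reference=ref,
        frame_times_s=series.frame_times_s,
    )


def triplet_to_tidy(
    triplet: ResponseTriplet, sample_id: str, family: str
) -> pd.DataFrame:
    """Tidy long-format export of one triplet for plotting."""
    rows = []
    for response in (ACTIVATED, SUPPRESSIVE, "channel_avg"):
        curve = triplet.curve(response)
        for t, v in zip(triplet.frame_times_s, curve):
            rows.append(
                {
                    "sample_id": sample_id,
                    "family": family,
                    "response": response,
                    "frame_time_s": t,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)
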