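"""Calcium-trace analysis: baseline, dF/F0, smoothing, peak detection,
cross-ROI motion-artifact rejection and transient kinetics.

The pipeline operates on raw ROI fluorescence traces ``F(t)`` sampled at a
fixed frame interval.  For each trace a slowly varying baseline ``F0(t)`` is
estimated as the mean of the lowest ``fraction`` of samples in a causal
sliding window, the relative change ``dF/F0 = (F - F0)/F0`` is smoothed by a
short moving average, and candidate transients are local maxima that exceed
amplitude, prominence and width thresholds.  Because animal movement deflects
every ROI of a field simultaneously (with either sign), each candidate peak
is compared against the absolute signal of all *other* ROIs at the peak
frame: if the peak is small relative to ``(AVGo + STDo)/sensitivity2`` it is
flagged as a motion artifact.  Accepted transients are then characterised by
their 10%-to-peak rise time and peak-to-10% decay time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .errors import DegenerateBaselineError, InputError, ParameterError

ROI_KINDS = ("soma", "neurite")

#: Column order of the tidy event table (one row per candidate peak).
EVENT_COLUMNS = [
    "roi_id",
    "roi_kind",
    "peak_frame",
    "peak_time_s",
    "amplitude_dff",
    "prominence_dff",
    "rise_time_s",
    "decay_time_s",
    "duration_s",
    "rejected",
    "rejection_threshold_dff",
]


@dataclass
class TraceSet:
    """ROI x frame raw fluorescence matrix with acquisition metadata.

    Parameters
    ----------
    fluorescence
        2-D array, shape ``(n_rois, n_frames)``, raw fluorescence in a.u.
    frame_interval_s
        Time between frames in seconds (1 / frame rate).
    roi_kind
        Per-ROI label, ``"soma"`` or ``"neurite"``.
    roi_ids
        Per-ROI identifiers; defaults to ``roi0000 ...``.
    field_id
        Identifier grouping ROIs recorded simultaneously.
    """

    fluorescence: np.ndarray
    frame_interval_s: float
    roi_kind: np.ndarray
    roi_ids: list[str] = field(default_factory=list)
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise InputError("fluorescence must be a 2-D (ROI x frame) array")
        n_rois, n_frames = self.fluorescence.shape
        if n_rois < 1 or n_frames < 2:
            raise InputError("need at least 1 ROI and 2 frames")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InputError("fluorescence contains non-finite values")
        if not self.frame_interval_s > 0:
            raise ParameterError("frame_interval_s must be positive")
        self.roi_kind = np.asarray(self.roi_kind, dtype=object)
        if self.roi_kind.shape != (n_rois,):
            raise InputError("roi_kind must have one label per ROI")
        bad = set(self.roi_kind) - set(ROI_KINDS)
        if bad:
            raise InputError(f"unknown ROI kind label(s): {sorted(bad)}")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:04d}" for i in range(n_rois)]
        if len(self.roi_ids) != n_rois:
            raise InputError("roi_ids must have one entry per ROI")

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the detection pipeline.

    Defaults are the values used throughout the study: a 30 s / lowest-50%
    baseline window, 0.8 s moving average, 0.8 s minimum peak width and
    sensitivity factors 0.2 (detection) and 0.15 (artifact rejection).
    """

    baseline_window_s: float = 30.0
    baseline_fraction: float = 0.5
    smooth_window_s: float = 0.8
    min_width_s: float = 0.8
    sensitivity1: float = 0.2
    sensitivity2: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "baseline_window_s",
            "smooth_window_s",
            "min_width_s",
            "sensitivity1",
            "sensitivity2",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.baseline_fraction <= 1:
            raise ParameterError("baseline_fraction must be in (0, 1]")


@dataclass
class EventTable:
    """Detected calcium events plus per-ROI activity summary.

    ``events`` has one row per candidate peak (columns :data:`EVENT_COLUMNS`,
    sorted by ROI then peak frame); ``rois`` has one row per ROI with its
    kind, accepted-event count and an ``active`` flag.
    """

    events: pd.DataFrame
    rois: pd.DataFrame

    @property
    def accepted(self) -> pd.DataFrame:
        return self.events[~self.events["rejected"]]


def recording_duration_s(n_frames: int, frame_rate_hz: float) -> float:
    """Duration of a recording of ``n_frames`` at ``frame_rate_hz``."""
    if not frame_rate_hz > 0:
        raise ParameterError("frame_rate_hz must be positive")
    return n_frames / frame_rate_hz


def compute_baseline(
    trace: np.ndarray,
    dt: float,
    window_s: float = 30.0,
    fraction: float = 0.5,
) -> np.ndarray:
    """Sliding lowest-percentile baseline F0(t).

    For each frame t, F0 is the mean of the lowest ``ceil(fraction * k)``
    samples among the k samples in the causal window ``(t - window_s, t]``.
    Near the start of the trace the window expands from the first frame, so
    ``F0(0) = F(0)``.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("trace must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise InputError("trace contains non-finite values")
    if not dt > 0 or not window_s > 0:
        raise ParameterError("dt and window_s must be positive")
    w = max(1, int(round(window_s / dt)))
    n = x.size
    out = np.empty(n, dtype=float)
    head = min(w - 1, n)
    for t in range(head):
        k = t + 1
        m = ceil(fraction * k)
        out[t] = np.partition(x[: t + 1], m - 1)[:m].mean()
    if n >= w:
        m = ceil(fraction * w)
        windows = sliding_window_view(x, w)
        lowest = np.partition(windows, m - 1, axis=1)[:, :m]
        out[w - 1 :] = lowest.mean(axis=1)
    return out


def compute_dff(trace: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Relative fluorescence change ``(F - F0) / F0``."""
    f = np.asarray(trace, dtype=float)
    f0 = np.asarray(baseline, dtype=float)
    if f.shape != f0.shape:
        raise InputError("trace and baseline must have the same shape")
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"baseline is non-positive at frame {bad[0]} (F0={f0[bad[0]]:g})"
        )
    return (f - f0) / f0


def smooth_dff(dff: np.ndarray, dt: float, window_s: float = 0.8) -> np.ndarray:
    """Centered moving average over ``round(window_s / dt)`` frames.

    The window length is forced odd (rounding up) so the filter is centered;
    edges are averaged over the available sub-window, so a constant series is
    unchanged everywhere.
    """
    x = np.asarray(dff, dtype=float)
    if not dt > 0 or not window_s > 0:
        raise ParameterError("dt and window_s must be positive")
    w = max(1, int(round(window_s / dt)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_peaks(
    smoothed: np.ndarray, dt: float, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Candidate transient peaks of one smoothed dF/F0 trace.

    A local maximum is kept iff its width at half prominence exceeds
    ``min_width_s``, and both its value and its prominence exceed
    ``sd(smoothed) / sensitivity1`` (sample standard deviation of the whole
    smoothed trace).  Returns a frame-sorted DataFrame with columns
    ``peak_frame, amplitude_dff, prominence_dff``.
    """
    params = params or DetectionParams()
    x = np.asarray(smoothed, dtype=float)
    peaks, _ = find_peaks(x)
    if peaks.size == 0:
        return pd.DataFrame(
            columns=["peak_frame", "amplitude_dff", "prominence_dff"]
        ).astype({"peak_frame": int})
    threshold = np.std(x, ddof=1) / params.sensitivity1
    prom = peak_prominences(x, peaks)[0]
    with warnings.catch_warnings():
        # zero-width plateau peaks are legal here; they fail the width test
        warnings.simplefilter("ignore")
        widths_s = peak_widths(x, peaks, rel_height=0.5)[0] * dt
    keep = (x[peaks] > threshold) & (prom > threshold) & (widths_s > params.min_width_s)
    return pd.DataFrame(
        {
            "peak_frame": peaks[keep].astype(int),
            "amplitude_dff": x[peaks[keep]],
            "prominence_dff": prom[keep],
        }
    )


def reject_artifacts(
    candidates: pd.DataFrame,
    all_smoothed: np.ndarray,
    sensitivity2: float = 0.15,
) -> pd.DataFrame:
    """Cross-ROI consensus test flagging simultaneous (motion) deflections.

    ``candidates`` must carry ``roi_index`` (row into ``all_smoothed``),
    ``peak_frame`` and ``amplitude_dff``.  For each candidate, AVGo and STDo
    are the mean and sample standard deviation of the absolute smoothed
    signal of all *other* ROIs at the peak frame; the candidate is rejected
    iff its amplitude is below ``(AVGo + STDo) / sensitivity2``.  With a
    single-ROI field the test cannot be applied: candidates are kept and a
    warning is emitted.
    """
    if not sensitivity2 > 0:
        raise ParameterError("sensitivity2 must be positive")
    mat = np.asarray(all_smoothed, dtype=float)
    out = candidates.copy()
    n_rois = mat.shape[0]
    if n_rois < 2:
        warnings.warn(
            "single-ROI field: artifact rejection is undefined, keeping all "
            "candidates",
            stacklevel=2,
        )
        out["rejected"] = False
        out["rejection_threshold_dff"] = np.nan
        return out
    thresholds = np.empty(len(out))
    for i, (r, f) in enumerate(zip(out["roi_index"], out["peak_frame"])):
        others = np.abs(np.delete(mat[:, int(f)], int(r)))
        avgo = others.mean()
        stdo = others.std(ddof=1) if others.size > 1 else 0.0
        thresholds[i] = (avgo + stdo) / sensitivity2
    out["rejection_threshold_dff"] = thresholds
    out["rejected"] = out["amplitude_dff"].to_numpy() < thresholds
    return out


def measure_kinetics(
    smoothed: np.ndarray,
    peak_frame: int,
    dt: float,
    left_bound: int | None = None,
    right_bound: int | None = None,
    frac: float = 0.1,
) -> tuple[float, float, float]:
    """Rise, decay and duration of one accepted peak, in seconds.

    Rise time is the span from the last upward crossing of ``frac * peak``
    before the peak to the peak; decay time the span from the peak to the
    first downward crossing after it (crossings located by linear
    interpolation between frames).  A side whose crossing lies outside the
    recording, or beyond the adjacent detected peak (``left_bound`` /
    ``right_bound``, frame indices), is censored and returned as NaN;
    duration = rise + decay is censored with either side.
    """
    x = np.asarray(smoothed, dtype=float)
    p = int(peak_frame)
    peak_val = x[p]
    if not peak_val > 0:
        raise InputError("kinetics require a positive peak value")
    level = frac * peak_val
    lo = 0 if left_bound is None else max(0, int(left_bound))
    hi = x.size - 1 if right_bound is None else min(x.size - 1, int(right_bound))

    rise = np.nan
    for j in range(p - 1, lo - 1, -1):
        if x[j] < level:
            t_cross = (j + (level - x[j]) / (x[j + 1] - x[j])) * dt
            rise = p * dt - t_cross
            break

    decay = np.nan
    for j in range(p + 1, hi + 1):
        if x[j] < level:
            t_cross = (j - 1 + (x[j - 1] - level) / (x[j - 1] - x[j])) * dt
            decay = t_cross - p * dt
            break

    duration = rise + decay  # NaN-propagating
    return rise, decay, duration


def analyze_field(
    traces: TraceSet, params: DetectionParams | None = None
) -> EventTable:
    """Full per-field pipeline: baseline -> dF/F0 -> smooth -> detect ->
    cross-ROI artifact rejection -> kinetics.

    Deterministic for fixed input.  Kinetics are measured on accepted events
    only (the "remaining peaks"), bounded by the adjacent accepted peak of
    the same ROI.
    """
    params = params or DetectionParams()
    dt = traces.frame_interval_s
    n_rois, n_frames = traces.fluorescence.shape

    smoothed = np.empty_like(traces.fluorescence)
    per_roi_candidates = []
    for r in range(n_rois):
        f = traces.fluorescence[r]
        f0 = compute_baseline(f, dt, params.baseline_window_s, params.baseline_fraction)
        dff = compute_dff(f, f0)
        smoothed[r] = smooth_dff(dff, dt, params.smooth_window_s)
        cand = detect_peaks(smoothed[r], dt, params)
        cand.insert(0, "roi_index", r)
        per_roi_candidates.append(cand)

    candidates = pd.concat(per_roi_candidates, ignore_index=True)
    if len(candidates):
        candidates = reject_artifacts(candidates, smoothed, params.sensitivity2)
    else:
        candidates["rejected"] = pd.Series(dtype=bool)
        candidates["rejection_threshold_dff"] = pd.Series(dtype=float)

    rows = []
    for r in range(n_rois):
        sub = candidates[candidates["roi_index"] == r].sort_values("peak_frame")
        accepted_frames = sub.loc[~sub["rejected"], "peak_frame"].to_numpy()
        for _, c in sub.iterrows():
            rise = decay = duration = np.nan
            if not c["rejected"]:
                pf = int(c["peak_frame"])
                before = accepted_frames[accepted_frames < pf]
                after = accepted_frames[accepted_frames > pf]
                rise, decay, duration = measure_kinetics(
                    smoothed[r],
                    pf,
                    dt,
                    left_bound=int(before.max()) if before.size else None,
                    right_bound=int(after.min()) if after.size else None,
                )
            rows.append(
                {
                    "roi_id": traces.roi_ids[r],
                    "roi_kind": traces.roi_kind[r],
                    "peak_frame": int(c["peak_frame"]),
                    "peak_time_s": c["peak_frame"] * dt,
                    "amplitude_dff": c["amplitude_dff"],
                    "prominence_dff": c["prominence_dff"],
                    "rise_time_s": rise,
                    "decay_time_s": decay,
                    "duration_s": duration,
                    "rejected": bool(c["rejected"]),
                    "rejection_threshold_dff": c["rejection_threshold_dff"],
                }
            )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values(["roi_id", "peak_frame"]).reset_index(drop=True)

    n_accepted = (
        events[~events["rejected"]].groupby("roi_id").size()
        if len(events)
        else pd.Series(dtype=int)
    )
    rois = pd.DataFrame(
        {
            "roi_id": traces.roi_ids,
            "roi_kind": traces.roi_kind,
            "n_events": [int(n_accepted.get(rid, 0)) for rid in traces.roi_ids],
        }
    )
    rois["active"] = rois["n_events"] > 0
    return EventTable(events=events, rois=rois)


def summarize_events(
    tables: EventTable | Mapping[str, EventTable],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group, per-kind activity proportions and tidy event vectors.

    ``tables`` is one :class:`EventTable` (group label ``"all"``) or a
    mapping of timepoint label to table.  Returns ``(summary, events)``:
    ``summary`` has one row per (group, kind) with the proportion of ROIs
    showing >=1 accepted event; ``events`` lists accepted events with their
    group and kind, ready for external statistics.
    """
    if isinstance(tables, EventTable):
        tables = {"all": tables}
    summary_rows = []
    event_frames = []
    for group, table in tables.items():
        bad = set(table.rois["roi_kind"]) - set(ROI_KINDS)
        if bad:
            raise InputError(f"unknown ROI kind label(s): {sorted(bad)}")
        for kind in ROI_KINDS:
            sub = table.rois[table.rois["roi_kind"] == kind]
            if len(sub) == 0:
                continue
            summary_rows.append(
                {
                    "group": group,
                    "roi_kind": kind,
                    "n_rois": len(sub),
                    "n_active": int(sub["active"].sum()),
                    "proportion_active": sub["active"].mean(),
                }
            )
        acc = table.accepted.copy()
        acc.insert(0, "group", group)
        event_frames.append(acc)
    summary = pd.DataFrame(
        summary_rows,
        columns=["group", "roi_kind", "n_rois", "n_active", "proportion_active"],
    )
    events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["group", *EVENT_COLUMNS])
    )
    return summary, events
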