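"""Synthetic data generators with exported ground truth.

Every simulator emulates the study's acquisition conditions and returns a
truth record alongside the data, so each downstream quantification stage can
be validated without external data:

* :func:`simulate_trace_set` — GCaMP6f-like ROI traces at 30.33 Hz with
  seconds-scale double-exponential transients (dF/F0 amplitudes around 10),
  a drifting baseline, per-ROI Gaussian noise and simultaneous
  positive-or-negative movement artifacts shared by all ROIs of the field.
* :func:`simulate_label_stack` — a 20-plane multi-channel tilescan with a
  graft band over mouse cortex, Poisson-placed nuclei and per-compartment
  marker assignment probabilities (DAPI / STEM101 / Sox2 / GFP).
* :func:`simulate_puncta_image` — Gaussian synaptic puncta (Synapsin /
  Homer1) at requested per-compartment densities inside the human-cell
  (GFP) mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk

from .compartments import LabelStack
from .errors import ParameterError
from .traces import TraceSet

# ---------------------------------------------------------------------------
# transient kernel


def double_exp_kernel(
    t: np.ndarray, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Unit-peak indicator kernel ``(1 - exp(-t/rise)) * exp(-t/decay)``.

    Zero for t < 0; rescaled so its maximum is exactly 1.
    """
    if not rise_tau_s > 0 or not decay_tau_s > 0:
        raise ParameterError("kernel time constants must be positive")
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0, (1 - np.exp(-t / rise_tau_s)) * np.exp(-t / decay_tau_s), 0.0)
    return g / _kernel_peak_value(rise_tau_s, decay_tau_s)


def kernel_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Time of the kernel maximum: ``rise * ln((rise + decay) / rise)``."""
    return rise_tau_s * np.log((rise_tau_s + decay_tau_s) / rise_tau_s)


def _kernel_peak_value(rise_tau_s: float, decay_tau_s: float) -> float:
    tp = kernel_peak_time(rise_tau_s, decay_tau_s)
    return (1 - np.exp(-tp / rise_tau_s)) * np.exp(-tp / decay_tau_s)


def kernel_rise_decay_times(
    rise_tau_s: float, decay_tau_s: float, frac: float = 0.1
) -> tuple[float, float]:
    """Expected 10%-to-peak rise and peak-to-10% decay times of the kernel.

    Solves the two crossings of ``frac`` on the unit-peak kernel; used as
    the ground-truth kinetic values for recovery tests.
    """
    tp = kernel_peak_time(rise_tau_s, decay_tau_s)

    def g(t: float) -> float:
        return float(double_exp_kernel(np.array([t]), rise_tau_s, decay_tau_s)[0]) - frac

    t_rise = brentq(g, 1e-12, tp)
    t_hi = tp
    while g(t_hi) > 0:
        t_hi *= 2
    t_decay = brentq(g, tp, t_hi)
    return tp - t_rise, t_decay - tp


# ---------------------------------------------------------------------------
# trace simulation


@dataclass(frozen=True)
class TraceSimParams:
    """Conditions of a simulated two-photon field.

    Defaults mirror the study's recordings: 50 ROIs followed for 10,000
    frames at 30.33 Hz (~330 s), sparse transients (zero to two prominent
    peaks per trace, mean 0.5) of dF/F0 amplitude 10 with ~2 s rise and ~5 s decay constants,
    and movement artifacts shared across the field (~11 per movie, of either
    sign, dF/F0 magnitude comparable to the transients, 1 s long).  The
    artifact duty cycle is kept at a few percent of the recording — the
    validity domain of the lowest-percentile baseline, and consistent with
    "10 to 50" artifacts per ~300 s movie.
    """

    n_rois: int = 50
    n_frames: int = 10_000
    frame_rate_hz: float = 30.33
    baseline_level: float = 100.0
    baseline_drift_amp: float = 0.02
    noise_sd: float = 0.3
    events_per_roi_rate: float = 0.5
    amp_dff_mean: float = 10.0
    rise_tau_s: float = 2.0
    decay_tau_s: float = 5.0
    artifact_rate_per_min: float = 2.0
    artifact_amp_sd: float = 300.0
    artifact_duration_s: float = 1.0
    background_floor: float = 5.0
    soma_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.n_frames < 2:
            raise ParameterError("need at least 1 ROI and 2 frames")
        if not self.frame_rate_hz > 0:
            raise ParameterError("frame_rate_hz must be positive")
        if not self.baseline_level > 0:
            raise ParameterError("baseline_level must be positive")
        if not (self.rise_tau_s > 0 and self.decay_tau_s > 0):
            raise ParameterError("kernel time constants must be positive")
        for name in (
            "baseline_drift_amp",
            "noise_sd",
            "events_per_roi_rate",
            "amp_dff_mean",
            "artifact_rate_per_min",
            "artifact_amp_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.artifact_duration_s > 0:
            raise ParameterError("artifact_duration_s must be positive")
        if self.background_floor < 0 or self.background_floor >= self.baseline_level:
            raise ParameterError(
                "background_floor must be in [0, baseline_level)"
            )
        if not 0 <= self.soma_fraction <= 1:
            raise ParameterError("soma_fraction must be in [0, 1]")


@dataclass
class TraceTruth:
    """Everything the trace simulator injected.

    ``events``: one row per transient (roi_index, roi_id, onset_s,
    peak_time_s, amp_dff, rise_tau_s, decay_tau_s).  ``artifacts``: one row
    per shared movement artifact (onset_s, onset_frame, duration_s).
    ``artifact_amps``: (n_artifacts, n_rois) signed amplitudes in raw a.u. —
    every artifact hits every ROI.
    """

    events: pd.DataFrame
    artifacts: pd.DataFrame
    artifact_amps: np.ndarray


def simulate_trace_set(params: TraceSimParams) -> tuple[TraceSet, TraceTruth]:
    """Generate one field of raw fluorescence traces plus ground truth.

    ``F(t) = baseline * (1 + drift) + sum_events amp_dff * baseline * g(t)
    + artifacts + noise`` with ``g`` the unit-peak double-exponential kernel.
    Artifact deflections start at a common frame in every ROI with per-ROI
    random sign and magnitude.  Fluorescence is floored at
    ``background_floor`` — detector offset plus neuropil background, below
    which a real recording never falls even when movement drives the ROI off
    the cell.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.frame_rate_hz
    n_r, n_f = params.n_rois, params.n_frames
    t = np.arange(n_f) * dt
    total_s = n_f * dt

    phases = rng.uniform(0, 2 * np.pi, n_r)
    drift = params.baseline_drift_amp * np.sin(
        2 * np.pi * t[None, :] / total_s + phases[:, None]
    )
    f = params.baseline_level * (1.0 + drift)

    # transients complete within the recording: onset margin covers the rise
    # to peak plus the decay back to 10% (a truncated decay would lower the
    # peak's prominence and censor its kinetics)
    tp = kernel_peak_time(params.rise_tau_s, params.decay_tau_s)
    _, t_decay10 = kernel_rise_decay_times(params.rise_tau_s, params.decay_tau_s)
    margin = tp + t_decay10 + 2.0
    event_rows = []
    for r in range(n_r):
        n_ev = rng.poisson(params.events_per_roi_rate)
        onsets = np.sort(rng.uniform(0, max(total_s - margin, 0), n_ev))
        for onset in onsets:
            amp = params.amp_dff_mean
            f[r] += (
                amp
                * params.baseline_level
                * double_exp_kernel(t - onset, params.rise_tau_s, params.decay_tau_s)
            )
            event_rows.append(
                {
                    "roi_index": r,
                    "onset_s": onset,
                    "peak_time_s": onset + tp,
                    "amp_dff": amp,
                    "rise_tau_s": params.rise_tau_s,
                    "decay_tau_s": params.decay_tau_s,
                }
            )

    # shared movement artifacts: boxcar deflection, per-ROI sign & magnitude
    n_art = rng.poisson(params.artifact_rate_per_min * total_s / 60.0)
    art_onsets = np.sort(
        rng.uniform(0, max(total_s - params.artifact_duration_s, 0), n_art)
    )
    dur_frames = max(1, int(round(params.artifact_duration_s / dt)))
    art_amps = rng.normal(0.0, params.artifact_amp_sd, size=(n_art, n_r))
    art_frames = np.minimum((art_onsets / dt).astype(int), n_f - 1)
    for a in range(n_art):
        sl = slice(art_frames[a], min(art_frames[a] + dur_frames, n_f))
        f[:, sl] += art_amps[a][:, None]

    if params.noise_sd > 0:
        f += rng.normal(0.0, params.noise_sd, size=f.shape)
    np.clip(f, params.background_floor, None, out=f)

    n_soma = int(round(params.soma_fraction * n_r))
    kinds = np.array(["soma"] * n_soma + ["neurite"] * (n_r - n_soma), dtype=object)
    traces = TraceSet(
        fluorescence=f,
        frame_interval_s=dt,
        roi_kind=kinds,
        field_id=f"sim-seed{params.seed}",
    )
    events = pd.DataFrame(
        event_rows,
        columns=[
            "roi_index",
            "onset_s",
            "peak_time_s",
            "amp_dff",
            "rise_tau_s",
            "decay_tau_s",
        ],
    )
    if len(events):
        events["roi_id"] = [traces.roi_ids[int(r)] for r in events["roi_index"]]
    else:
        events["roi_id"] = pd.Series(dtype=object)
    artifacts = pd.DataFrame(
        {
            "onset_s": art_onsets,
            "onset_frame": art_frames,
            "duration_s": params.artifact_duration_s,
        }
    )
    return traces, TraceTruth(events=events, artifacts=artifacts, artifact_amps=art_amps)


# ---------------------------------------------------------------------------
# label-stack simulation


def _default_marker_probs() -> dict[str, dict[str, float]]:
    # Sox2 positivity ~2/3 of human (graft) cells vs ~1/3 of mouse cells, as
    # reported for the xenograft; GFP marks human cells only.
    return {
        "graft": {"STEM101": 0.95, "Sox2": 0.65, "GFP": 1.0},
        "mouse_cortex": {"STEM101": 0.0, "Sox2": 0.32, "GFP": 0.0},
    }


def _default_gains() -> dict[str, float]:
    return {"DAPI": 3000.0, "STEM101": 4000.0, "Sox2": 4000.0, "GFP": 6000.0}


@dataclass(frozen=True)
class StackSimParams:
    """Geometry and marker statistics of a simulated graft tilescan.

    The graft is a flat horizontal band at the top of the frame (pial side),
    mouse cortex below, imaged as 20 z planes 0.5 um apart.  Nuclei are a
    spatial Poisson process; each nucleus carries markers drawn from the
    per-compartment probabilities.
    """

    height_px: int = 512
    width_px: int = 512
    n_z: int = 20
    pixel_size_um: float = 0.5
    z_step_um: float = 0.5
    graft_thickness_um: float = 100.0
    nucleus_radius_um: float = 3.0
    nucleus_density_per_mm2: float = 2500.0
    p_marker_by_compartment: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_marker_probs
    )
    channel_gains: Mapping[str, float] = field(default_factory=_default_gains)
    background: float = 100.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1 or self.n_z < 1:
            raise ParameterError("image dimensions must be positive")
        if not self.pixel_size_um > 0 or not self.z_step_um > 0:
            raise ParameterError("pixel sizes must be positive")
        if self.graft_thickness_um < 0:
            raise ParameterError("graft_thickness_um must be >= 0")
        if self.graft_thickness_um > self.height_px * self.pixel_size_um:
            raise ParameterError("graft is thicker than the image")
        if not self.nucleus_radius_um > 0:
            raise ParameterError("nucleus_radius_um must be positive")
        if self.nucleus_density_per_mm2 < 0:
            raise ParameterError("nucleus_density_per_mm2 must be >= 0")
        for comp, probs in self.p_marker_by_compartment.items():
            for marker, p in probs.items():
                if not 0 <= p <= 1:
                    raise ParameterError(
                        f"p({marker}|{comp}) = {p} is not a probability"
                    )


@dataclass
class StackTruth:
    """Ground truth of a simulated label stack.

    ``nuclei``: one row per nucleus with center (row_px, col_px),
    compartment ("graft"/"mouse_cortex"), band ("below50"/"above50" for
    graft nuclei, from the center's distance to the graft/cortex interface),
    and one boolean column per marker.  ``graft_rows``: number of image rows
    covered by the graft band.
    """

    nuclei: pd.DataFrame
    graft_rows: int
    limit_um: float = 50.0


def simulate_label_stack(params: StackSimParams) -> tuple[LabelStack, StackTruth]:
    """Render a DAPI/STEM101/Sox2/GFP stack of a graft band over cortex."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    px = params.pixel_size_um
    graft_rows = int(round(params.graft_thickness_um / px))
    markers = sorted(
        {m for probs in params.p_marker_by_compartment.values() for m in probs}
    )
    roles = ["DAPI", *markers]

    rows_list = []
    compartment_rows = {
        "graft": (0.0, float(graft_rows)),
        "mouse_cortex": (float(graft_rows), float(h)),
    }
    for comp, (r0, r1) in compartment_rows.items():
        area_mm2 = (r1 - r0) * w * px**2 / 1e6
        n = rng.poisson(params.nucleus_density_per_mm2 * area_mm2)
        rr = rng.uniform(r0, r1, n)
        cc = rng.uniform(0, w, n)
        probs = params.p_marker_by_compartment.get(comp, {})
        for i in range(n):
            rec = {"row_px": rr[i], "col_px": cc[i], "compartment": comp}
            for m in markers:
                rec[m] = bool(rng.random() < probs.get(m, 0.0))
            rows_list.append(rec)
    nuclei = pd.DataFrame(rows_list, columns=["row_px", "col_px", "compartment", *markers])
    if len(nuclei):
        depth_um = (graft_rows - nuclei["row_px"]) * px
        nuclei["band"] = np.where(
            nuclei["compartment"] == "graft",
            np.where(depth_um <= 50.0, "below50", "above50"),
            "",
        )
    else:
        nuclei["band"] = pd.Series(dtype=object)

    r_px = params.nucleus_radius_um / px
    plane = np.zeros((len(roles), h, w), dtype=float)
    gains = dict(params.channel_gains)
    for _, nuc in nuclei.iterrows():
        rr, cc = disk((nuc["row_px"], nuc["col_px"]), r_px, shape=(h, w))
        plane[0, rr, cc] = gains.get("DAPI", 3000.0)
        for i, m in enumerate(markers, start=1):
            if nuc[m]:
                # GFP is cytoplasmic but rendered on the same footprint as
                # the nuclear markers so area ratios equal cell fractions
                plane[i, rr, cc] = gains.get(m, 4000.0)

    voxels = np.broadcast_to(plane[:, None], (len(roles), params.n_z, h, w)).astype(
        np.float32
    )
    voxels += np.float32(params.background)
    if params.noise_sd > 0:
        voxels += params.noise_sd * rng.standard_normal(voxels.shape, dtype=np.float32)
    voxels = np.clip(voxels, 0, 65535).astype(np.uint16)
    stack = LabelStack(
        voxels=voxels,
        pixel_size_um=px,
        z_step_um=params.z_step_um,
        channel_roles=tuple(roles),
    )
    return stack, StackTruth(nuclei=nuclei, graft_rows=graft_rows)


# ---------------------------------------------------------------------------
# puncta simulation


def _default_puncta_densities() -> dict[str, dict[str, float]]:
    # Synapsin roughly uniform; Homer1 lower inside the graft, lowest far
    # from the mouse cortex — the pattern reported for the xenograft.  The
    # absolute level keeps the mean nearest-neighbour spacing (~0.5/sqrt(rho))
    # a few-fold above the ~2 sigma resolution limit of single-scale spot
    # detection.
    return {
        "Synapsin": {"mouse_cortex": 0.15, "below50": 0.12, "above50": 0.10},
        "Homer1": {"mouse_cortex": 0.14, "below50": 0.08, "above50": 0.05},
    }


@dataclass(frozen=True)
class PunctaSimParams:
    """Synaptic-puncta image: Gaussian spots inside compartment ∩ human mask.

    The human-cell (GFP) channel is a bright band covering
    ``human_band_um = (top, bottom)`` rows; compartments follow the same
    flat-band graft geometry as :class:`StackSimParams`.  Per-channel,
    per-compartment densities are in puncta per um^2; the number of spots
    placed is ``round(density * area)``, positions uniform (optionally with
    a minimum separation).
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.25
    graft_thickness_um: float = 80.0
    human_band_um: tuple[float, float] | None = None  # None -> full frame
    puncta_density_per_um2: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_puncta_densities
    )
    punctum_sigma_um: float = 0.3
    punctum_peak: float = 3000.0
    background: float = 500.0
    gfp_level: float = 6000.0
    gfp_background: float = 1000.0
    noise_sd: float = 20.0
    min_separation_um: float = 0.0
    limit_um: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ParameterError("image dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be positive")
        if not self.punctum_sigma_um > 0:
            raise ParameterError("punctum_sigma_um must be positive")
        if self.graft_thickness_um > self.height_px * self.pixel_size_um:
            raise ParameterError("graft is thicker than the image")
        for ch, by_comp in self.puncta_density_per_um2.items():
            for comp, d in by_comp.items():
                if d < 0:
                    raise ParameterError(f"density({ch}|{comp}) must be >= 0")


@dataclass
class PunctaTruth:
    """Spot centers placed by the puncta simulator.

    ``spots``: one row per punctum (channel, row_px, col_px, compartment).
    ``human_mask``: the boolean human-cell band actually used.
    """

    spots: pd.DataFrame
    human_mask: np.ndarray
    graft_rows: int


def _place_spots(
    rng: np.random.Generator,
    n: int,
    row_range: tuple[float, float],
    col_range: tuple[float, float],
    min_sep_px: float,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 1000 * max(n, 1):
            raise ParameterError(
                "could not place spots with the requested minimum separation"
            )
        r = rng.uniform(*row_range)
        c = rng.uniform(*col_range)
        if min_sep_px > 0:
            ok = all(
                (r - pr) ** 2 + (c - pc) ** 2 >= min_sep_px**2
                for pr, pc in pts + existing
            )
            if not ok:
                continue
        pts.append((r, c))
    return pts


def simulate_puncta_image(params: PunctaSimParams) -> tuple[LabelStack, PunctaTruth]:
    """Render a GFP/Synapsin/Homer1 plane with ground-truth spot centers."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    px = params.pixel_size_um
    graft_rows = int(round(params.graft_thickness_um / px))
    limit_rows = int(round(params.limit_um / px))
    band_rows = {
        "above50": (0, max(graft_rows - limit_rows, 0)),
        "below50": (max(graft_rows - limit_rows, 0), graft_rows),
        "mouse_cortex": (graft_rows, h),
    }
    if params.human_band_um is None:
        hb0, hb1 = 0, h
    else:
        hb0 = int(round(params.human_band_um[0] / px))
        hb1 = int(round(params.human_band_um[1] / px))
    human_mask = np.zeros((h, w), dtype=bool)
    human_mask[hb0:hb1] = True

    sigma_px = params.punctum_sigma_um / px
    channels = sorted(params.puncta_density_per_um2)
    images = {ch: np.full((h, w), params.background, dtype=float) for ch in channels}
    spot_rows = []
    for ch in channels:
        placed: list[tuple[float, float]] = []
        for comp, (r0, r1) in band_rows.items():
            rr0, rr1 = max(r0, hb0), min(r1, hb1)
            if rr1 <= rr0:
                continue
            area_um2 = (rr1 - rr0) * w * px**2
            density = params.puncta_density_per_um2[ch].get(comp, 0.0)
            n = int(round(density * area_um2))
            # 1 px margin from region borders so each spot's center pixel
            # lies unambiguously inside the region
            pts = _place_spots(
                rng,
                n,
                (min(rr0 + 1.0, rr1), max(rr0, rr1 - 1.0)),
                (1.0, float(w) - 1.0),
                params.min_separation_um / px,
                placed,
            )
            placed.extend(pts)
            for r, c in pts:
                spot_rows.append(
                    {"channel": ch, "row_px": r, "col_px": c, "compartment": comp}
                )
                ext = int(np.ceil(4 * sigma_px))
                ri, ci = int(round(r)), int(round(c))
                r_lo, r_hi = max(ri - ext, 0), min(ri + ext + 1, h)
                c_lo, c_hi = max(ci - ext, 0), min(ci + ext + 1, w)
                yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
                images[ch][r_lo:r_hi, c_lo:c_hi] += params.punctum_peak * np.exp(
                    -((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma_px**2)
                )

    gfp = np.full((h, w), params.gfp_background, dtype=float)
    gfp[human_mask] = params.gfp_level
    planes = [gfp] + [images[ch] for ch in channels]
    voxels = np.stack(planes)[:, None]  # (C, 1, H, W)
    if params.noise_sd > 0:
        voxels = voxels + rng.normal(0, params.noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0, 65535)
    stack = LabelStack(
        voxels=voxels,
        pixel_size_um=px,
        z_step_um=1.0,
        channel_roles=("GFP", *channels),
    )
    spots = pd.DataFrame(
        spot_rows, columns=["channel", "row_px", "col_px", "compartment"]
    )
    return stack, PunctaTruth(spots=spots, human_mask=human_mask, graft_rows=graft_rows)
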