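"""Puncta detection and density arithmetic.

Covers the synaptic-marker quantification (human-cell mask at a fixed
intensity threshold, difference-of-Gaussians spot detection, per-compartment
puncta densities on the human-cell mask), the EM areal synapse density with
its truncated reporting convention, and dendritic spine density.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import trunc
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .errors import InputError, ParameterError

#: Columns of a spot list (sub-pixel centers plus detector response).
SPOT_COLUMNS = ["row_px", "col_px", "quality"]


@dataclass
class DensityRecord:
    """Puncta density of one channel in one compartment."""

    compartment: str
    channel: str
    n_spots: int
    area_um2: float
    density_per_um2: float


def human_cell_mask(green_channel: np.ndarray, threshold: float = 5000.0) -> np.ndarray:
    """Human-cell ROI: green-channel pixels at or above ``threshold``.

    The acquisition-scale default of 5,000 matches the study's convention.
    """
    return np.asarray(green_channel, dtype=float) >= threshold


def _subpixel_offset(vals: np.ndarray) -> float:
    """Quadratic 3-point peak interpolation; clamped to +-0.5 px."""
    left, center, right = vals
    denom = left - 2 * center + right
    if denom >= 0:  # not a strict local max along this axis
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def detect_puncta(
    channel: np.ndarray,
    sigma_um: float,
    pixel_size_um: float,
    min_quality: float,
) -> pd.DataFrame:
    """Difference-of-Gaussians blob detection at a single spatial scale.

    The image is band-passed with Gaussians of ``sigma/sqrt(2)`` and
    ``sigma*sqrt(2)`` (sigma in pixels); local maxima of the response above
    ``min_quality`` are returned with sub-pixel centers (per-axis quadratic
    interpolation).  ``quality`` is the DoG response at the peak.  Two spots
    closer than about 2 sigma may merge into one detection — the resolution
    limit of single-scale blob detection.
    """
    if not sigma_um > 0:
        raise ParameterError("sigma_um must be positive")
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be positive")
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise InputError("detect_puncta expects a single 2-D channel")
    sigma_px = sigma_um / pixel_size_um
    dog = gaussian_filter(img, sigma_px / np.sqrt(2)) - gaussian_filter(
        img, sigma_px * np.sqrt(2)
    )
    coords = peak_local_max(
        dog,
        min_distance=max(1, int(round(sigma_px))),
        threshold_abs=min_quality,
        exclude_border=False,
    )
    rows = []
    for r, c in coords:
        dr = dc = 0.0
        if 0 < r < dog.shape[0] - 1:
            dr = _subpixel_offset(dog[r - 1 : r + 2, c])
        if 0 < c < dog.shape[1] - 1:
            dc = _subpixel_offset(dog[r, c - 1 : c + 2])
        rows.append({"row_px": r + dr, "col_px": c + dc, "quality": dog[r, c]})
    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    return spots.sort_values("quality", ascending=False).reset_index(drop=True)


def merge_spots_across_planes(
    per_plane_spots: Sequence[pd.DataFrame],
    radius_px: float,
) -> pd.DataFrame:
    """Merge spots detected on adjacent z planes within ``radius_px``.

    A punctum spanning several planes of a thin confocal stack is counted
    once: spots are taken in decreasing quality order and any spot on an
    adjacent plane within the lateral radius of an already-kept spot is
    absorbed.  Returns the kept spots with a ``z`` column.
    """
    frames = []
    for z, df in enumerate(per_plane_spots):
        d = df.copy()
        d["z"] = z
        frames.append(d)
    allspots = pd.concat(frames, ignore_index=True)
    if not len(allspots):
        return allspots
    allspots = allspots.sort_values("quality", ascending=False).reset_index(drop=True)
    kept: list[int] = []
    for i in range(len(allspots)):
        ri, ci, zi = allspots.loc[i, ["row_px", "col_px", "z"]]
        absorbed = False
        for j in kept:
            rj, cj, zj = allspots.loc[j, ["row_px", "col_px", "z"]]
            if abs(zi - zj) <= 1 and (ri - rj) ** 2 + (ci - cj) ** 2 <= radius_px**2:
                absorbed = True
                break
        if not absorbed:
            kept.append(i)
    return allspots.loc[kept].reset_index(drop=True)


def puncta_density(
    spots: pd.DataFrame,
    region_mask: np.ndarray,
    human_mask: np.ndarray,
    pixel_size_um: float,
    compartment: str = "",
    channel: str = "",
) -> DensityRecord:
    """Spots per um^2 of ``region ∩ human`` mask.

    A spot belongs to the region if its center pixel (nearest pixel to the
    sub-pixel center) lies in the intersection; the area is the pixel count
    times the squared pixel size.  Zero intersection area yields a NaN
    density.
    """
    region = np.asarray(region_mask, dtype=bool)
    human = np.asarray(human_mask, dtype=bool)
    if region.shape != human.shape:
        raise InputError("region and human masks must have the same shape")
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be positive")
    inter = region & human
    area_um2 = float(np.count_nonzero(inter)) * pixel_size_um**2
    n = 0
    for _, s in spots.iterrows():
        r = int(np.clip(round(s["row_px"]), 0, region.shape[0] - 1))
        c = int(np.clip(round(s["col_px"]), 0, region.shape[1] - 1))
        if inter[r, c]:
            n += 1
    density = n / area_um2 if area_um2 > 0 else float("nan")
    return DensityRecord(
        compartment=compartment,
        channel=channel,
        n_spots=n,
        area_um2=area_um2,
        density_per_um2=density,
    )


def em_areal_density(
    n_profiles: int, field_area_um2: float
) -> tuple[float, int]:
    """Areal synapse density per 100 um^2 of an EM field.

    Returns ``(raw, reported)`` where raw = n / area * 100 and the reported
    integer truncates the raw value toward zero — the convention that
    reproduces both published worked examples (12 profiles / 258 um^2 -> 4,
    53 / 258 -> 20; conventional rounding would print 5 for the first).
    """
    if not field_area_um2 > 0:
        raise InputError("field_area_um2 must be positive")
    if n_profiles < 0:
        raise InputError("n_profiles must be >= 0")
    raw = n_profiles / field_area_um2 * 100.0
    return raw, trunc(raw)


def spine_density(
    spine_counts: Sequence[int], dendrite_lengths_um: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Per-dendrite spine densities (spines/um) and their unweighted mean."""
    counts = np.asarray(spine_counts, dtype=float)
    lengths = np.asarray(dendrite_lengths_um, dtype=float)
    if counts.shape != lengths.shape or counts.ndim != 1 or counts.size == 0:
        raise InputError("counts and lengths must be equal-length non-empty vectors")
    if np.any(counts < 0):
        raise InputError("spine counts must be >= 0")
    if np.any(lengths <= 0):
        raise InputError("dendrite lengths must be positive")
    per = counts / lengths
    return per, float(per.mean())
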