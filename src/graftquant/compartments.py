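"""Compartmentalized immunofluorescence quantification.

Implements the histology pipeline applied to graft tilescans: z-group
averaging (20 planes -> 5), interpolation of hand-drawn graft ROIs across z
via signed-distance blending, splitting the graft into "Below 50 um" /
"Above 50 um" bands by Euclidean distance to the graft/cortex interface,
channel thresholding (Otsu or fixed), DAPI background gating at the
connected-component level, and colocalization area fractions used as a
proxy for double-positive cell abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import GeometryError, InputError, ParameterError

CHANNEL_ROLES = ("DAPI", "STEM101", "Sox2", "GFP", "Synapsin", "Homer1", "other")

#: Compartments reported by the colocalization table.
COMPARTMENTS = ("mouse_cortex", "below50", "above50", "graft")


@dataclass
class LabelStack:
    """Multi-channel image stack with physical pixel size.

    ``voxels`` is channel x z x row x col; ``channel_roles`` names each
    channel (e.g. DAPI, STEM101, Sox2, GFP, Synapsin, Homer1).
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise InputError("voxels must be 4-D (channel, z, row, col)")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be positive")
        if not self.z_step_um > 0:
            raise ParameterError("z_step_um must be positive")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.voxels.shape[0]:
            raise InputError(
                f"{len(self.channel_roles)} roles declared for "
                f"{self.voxels.shape[0]} channels"
            )

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """The (z, row, col) intensity array of the channel with ``role``."""
        matches = [i for i, r in enumerate(self.channel_roles) if r == role]
        if not matches:
            raise InputError(f"no channel with role {role!r}")
        if len(matches) > 1:
            raise InputError(f"role {role!r} is not unique in this stack")
        return self.voxels[matches[0]]


@dataclass
class CompartmentMap:
    """Exclusive per-z-plane masks: graft, below50, above50, mouse_cortex.

    Invariants (checked): below50 and above50 partition the graft;
    mouse_cortex is disjoint from the graft.
    """

    graft: np.ndarray
    below50: np.ndarray
    above50: np.ndarray
    mouse_cortex: np.ndarray
    limit_um: float = 50.0

    def __post_init__(self) -> None:
        for name in ("graft", "below50", "above50", "mouse_cortex"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3:
                raise InputError(f"{name} mask must be 2-D or 3-D (z, row, col)")
            setattr(self, name, arr)
        if not (
            self.graft.shape
            == self.below50.shape
            == self.above50.shape
            == self.mouse_cortex.shape
        ):
            raise InputError("compartment masks must share a shape")
        if np.any(self.below50 & self.above50):
            raise GeometryError("below50 and above50 overlap")
        if not np.array_equal(self.below50 | self.above50, self.graft):
            raise GeometryError("below50 and above50 do not partition the graft")
        if np.any(self.graft & self.mouse_cortex):
            raise GeometryError("graft and mouse_cortex overlap")

    def mask(self, compartment: str) -> np.ndarray:
        if compartment not in COMPARTMENTS:
            raise InputError(f"unknown compartment {compartment!r}")
        return getattr(self, compartment)


def average_z_groups(stack: LabelStack, group_size: int) -> LabelStack:
    """Average the stack ``group_size``-by-``group_size`` along z.

    The study averages 20 acquired planes in groups of 4 to obtain 5 working
    z points; the z step is scaled accordingly.
    """
    if group_size < 1:
        raise ParameterError("group_size must be >= 1")
    n_z = stack.n_z
    if n_z % group_size:
        raise InputError(f"{n_z} z planes are not divisible by group size {group_size}")
    c, _, h, w = stack.voxels.shape
    grouped = stack.voxels.reshape(c, n_z // group_size, group_size, h, w)
    return LabelStack(
        voxels=grouped.mean(axis=2),
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um * group_size,
        channel_roles=stack.channel_roles,
    )


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside; large constants for the
    degenerate all-true / all-false masks (no boundary to measure from)."""
    big = float(sum(mask.shape))
    if not mask.any():
        return np.full(mask.shape, -big)
    if mask.all():
        return np.full(mask.shape, big)
    return distance_transform_edt(mask) - distance_transform_edt(~mask)


def interpolate_roi_masks(
    first: np.ndarray, last: np.ndarray, n_intermediate: int
) -> np.ndarray:
    """Intermediate ROI masks between two hand-drawn end masks.

    Linear blending of the signed Euclidean distance transforms of the end
    masks, thresholded at 0 — for concentric disks this interpolates the
    radius linearly.  Returns ``(n_intermediate, H, W)`` boolean masks (the
    ends are not included).
    """
    a = np.asarray(first, dtype=bool)
    b = np.asarray(last, dtype=bool)
    if a.shape != b.shape:
        raise InputError("end masks must have the same shape")
    if n_intermediate < 0:
        raise ParameterError("n_intermediate must be >= 0")
    sd_a = _signed_distance(a)
    sd_b = _signed_distance(b)
    out = np.empty((n_intermediate, *a.shape), dtype=bool)
    for i in range(n_intermediate):
        alpha = (i + 1) / (n_intermediate + 1)
        out[i] = (1 - alpha) * sd_a + alpha * sd_b > 0
    return out


def split_graft_compartments(
    graft_mask: np.ndarray,
    cortex_mask: np.ndarray,
    pixel_size_um: float,
    limit_um: float = 50.0,
) -> CompartmentMap:
    """Split the graft at ``limit_um`` from the graft/cortex interface.

    ``below50`` collects graft pixels whose Euclidean distance to the mouse
    cortex is at most ``limit_um``; ``above50`` is the remainder.  Masks may
    be 2-D (one plane) or 3-D (z, row, col); the split is per plane.
    """
    graft = np.asarray(graft_mask, dtype=bool)
    cortex = np.asarray(cortex_mask, dtype=bool)
    if graft.shape != cortex.shape:
        raise InputError("graft and cortex masks must have the same shape")
    if graft.ndim == 2:
        graft = graft[None]
        cortex = cortex[None]
    if np.any(graft & cortex):
        raise InputError("graft and cortex masks must be disjoint")
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be positive")
    below = np.zeros_like(graft)
    for z in range(graft.shape[0]):
        if graft[z].any():
            if not (binary_dilation(cortex[z]) & graft[z]).any():
                raise GeometryError(
                    f"graft and cortex share no interface in plane {z}"
                )
            dist_um = distance_transform_edt(~cortex[z]) * pixel_size_um
            below[z] = graft[z] & (dist_um <= limit_um)
    return CompartmentMap(
        graft=graft,
        below50=below,
        above50=graft & ~below,
        mouse_cortex=cortex,
        limit_um=limit_um,
    )


def threshold_channel(
    channel: np.ndarray, method: str | float = "otsu"
) -> tuple[np.ndarray, float]:
    """Threshold one channel to a boolean mask.

    ``method`` is either ``"otsu"`` or a fixed numeric threshold.  Returns
    ``(mask, threshold)``.  Fixed thresholds use ``>=`` (so a pixel exactly
    at the threshold is foreground); Otsu uses the conventional ``>``.  A
    constant image has no Otsu split and yields an empty mask.
    """
    img = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(img)):
        raise InputError("image contains non-finite values")
    if isinstance(method, str):
        if method != "otsu":
            raise ParameterError(f"unknown threshold method {method!r}")
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool), float(img.max())
        t = float(threshold_otsu(img))
        return img > t, t
    t = float(method)
    if t <= img.min():
        warnings.warn(
            f"fixed threshold {t:g} is at or below the image minimum "
            f"{img.min():g}: mask is all-true",
            stacklevel=2,
        )
    return img >= t, t


def apply_dapi_filter(mask: np.ndarray, dapi_mask: np.ndarray) -> np.ndarray:
    """Remove connected components of ``mask`` that do not touch DAPI.

    Detected fluorescence not overlapping the DAPI signal is treated as
    background; components that touch DAPI anywhere are kept whole (a
    pixelwise AND would bisect nuclear rims).
    """
    m = np.asarray(mask, dtype=bool)
    d = np.asarray(dapi_mask, dtype=bool)
    if m.shape != d.shape:
        raise InputError("mask and DAPI mask must have the same shape")
    labels = cc_label(m, connectivity=2)
    keep = np.unique(labels[d])
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def coloc_fractions(
    stack: LabelStack,
    masks: Mapping[str, np.ndarray],
    compartments: CompartmentMap,
    pairs: Sequence[tuple[str, str]] = (("Sox2", "GFP"),),
    which_compartments: Iterable[str] = ("mouse_cortex", "below50", "above50"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Colocalization areas per z-plane and compartment, two normalizations.

    For each pair ``(marker, denom)`` the numerator area is
    ``marker & denom & compartment``.  Two percentages are emitted per row
    group: relative to the DAPI area in the compartment, and relative to the
    denominator marker's area in the compartment (e.g. "% of GFP surface
    also expressing Sox2").  Zero-denominator percentages are NaN.

    Returns ``(per_z, averaged)``: the per-plane table and its average over
    z (percentages averaged across planes where they are defined).
    """
    if "DAPI" not in masks:
        raise InputError("a DAPI mask is required for normalization")
    for a, b in pairs:
        for role in (a, b):
            if role not in masks:
                raise InputError(f"missing mask for role {role!r}")
    px_area = stack.pixel_size_um**2
    n_z = compartments.graft.shape[0]

    def _area(m: np.ndarray) -> float:
        return float(np.count_nonzero(m)) * px_area

    rows = []
    for z in range(n_z):
        dapi_z = np.asarray(masks["DAPI"], dtype=bool)[z]
        for comp in which_compartments:
            comp_mask = compartments.mask(comp)[z]
            for a, b in pairs:
                inter = (
                    np.asarray(masks[a], bool)[z]
                    & np.asarray(masks[b], bool)[z]
                    & comp_mask
                )
                inter_area = _area(inter)
                for norm, denom_mask in (
                    ("DAPI", dapi_z & comp_mask),
                    (b, np.asarray(masks[b], bool)[z] & comp_mask),
                ):
                    denom_area = _area(denom_mask)
                    rows.append(
                        {
                            "z": z,
                            "compartment": comp,
                            "marker": a,
                            "partner": b,
                            "normalization": norm,
                            "intersection_area_um2": inter_area,
                            "denominator_area_um2": denom_area,
                            "percentage": (
                                100.0 * inter_area / denom_area
                                if denom_area > 0
                                else np.nan
                            ),
                        }
                    )
    per_z = pd.DataFrame(rows)
    keys = ["compartment", "marker", "partner", "normalization"]
    averaged = (
        per_z.groupby(keys, sort=False)
        .agg(
            intersection_area_um2=("intersection_area_um2", "mean"),
            denominator_area_um2=("denominator_area_um2", "mean"),
            percentage=("percentage", "mean"),
        )
        .reset_index()
    )
    return per_z, averaged


def quantify_graft_stack(
    stack: LabelStack,
    graft_mask_first: np.ndarray,
    graft_mask_last: np.ndarray,
    z_group_size: int = 4,
    limit_um: float = 50.0,
    thresholds: Mapping[str, str | float] | None = None,
    pairs: Sequence[tuple[str, str]] = (("Sox2", "GFP"),),
) -> tuple[pd.DataFrame, pd.DataFrame, CompartmentMap]:
    """End-to-end graft quantification on one acquired stack.

    Averages z groups, interpolates the graft ROI between the two hand-drawn
    end masks, splits compartments at ``limit_um`` (mouse cortex = everything
    outside the graft, assuming the frame top is the pial surface),
    thresholds each needed channel (Otsu by default, per-role overrides via
    ``thresholds``), gates non-DAPI masks on DAPI, and tabulates
    colocalization fractions.
    """
    work = average_z_groups(stack, z_group_size) if z_group_size > 1 else stack
    n_z = work.n_z
    if n_z < 2:
        raise InputError("need at least 2 working z planes")
    inter = interpolate_roi_masks(graft_mask_first, graft_mask_last, n_z - 2)
    graft = np.stack(
        [np.asarray(graft_mask_first, bool), *inter, np.asarray(graft_mask_last, bool)]
    )
    compartments = split_graft_compartments(
        graft, ~graft, work.pixel_size_um, limit_um
    )

    thresholds = dict(thresholds or {})
    roles_needed = {"DAPI"} | {r for pair in pairs for r in pair}
    masks: dict[str, np.ndarray] = {}
    for role in roles_needed:
        vol = work.channel(role)
        mask = np.empty(vol.shape, dtype=bool)
        for z in range(n_z):
            mask[z], _ = threshold_channel(vol[z], thresholds.get(role, "otsu"))
        masks[role] = mask
    for role in roles_needed - {"DAPI"}:
        for z in range(n_z):
            masks[role][z] = apply_dapi_filter(masks[role][z], masks["DAPI"][z])

    per_z, averaged = coloc_fractions(work, masks, compartments, pairs)
    return per_z, averaged, compartments
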