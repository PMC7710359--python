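"""Fluorescent-feature quantification.

Counts annotated objects inside an analysis region, converts to a density
per mm^2 using the pixel scale, aggregates per-object mean intensities,
and normalizes densities to a control group's mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Image2D, LabelMask, RegionMask

__all__ = ["FeatureQuant", "quantify", "normalize_to_control", "quants_to_frame"]


@dataclass
class FeatureQuant:
    """Per-image quantification of annotated fluorescent features."""

    image_id: str
    group: str
    roi_count: int
    density: float  # objects per mm^2 of analyzed region
    mean_intensity: float  # mean over counted objects of per-object mean intensity
    region_area_mm2: float
    normalized_density: float = math.nan


def quantify(
    mask: LabelMask,
    image: Image2D,
    region: RegionMask,
    group: str = "",
    pooled_pixels: bool = False,
) -> FeatureQuant:
    """Quantify one image.

    An object is counted when its centroid lies inside the region (objects
    straddling the border are thus counted exactly once).  The region area
    is ``pixel count / (px_per_um^2 * 1e6)`` mm^2.  ``mean_intensity``
    averages the per-object mean pixel intensities of the counted objects;
    ``pooled_pixels=True`` instead pools all counted objects' pixels.
    """
    if not (mask.shape == image.shape == region.shape):
        raise ValueError("mask, image and region must share a shape")
    if image.px_per_um is None:
        raise ValueError("px_per_um must be set for physical-area quantification")
    if region.area_px == 0:
        raise ValueError("empty analysis region")

    area_mm2 = region.area_px / (image.px_per_um**2 * 1e6)
    counted: list[int] = []
    if mask.n_objects:
        cents = np.round(mask.centroids()).astype(int)
        cents[:, 0] = np.clip(cents[:, 0], 0, region.shape[0] - 1)
        cents[:, 1] = np.clip(cents[:, 1], 0, region.shape[1] - 1)
        inside = region.mask[cents[:, 0], cents[:, 1]]
        counted = list(np.flatnonzero(inside) + 1)

    if counted:
        pix = image.pixels.astype(float)
        if pooled_pixels:
            sel = np.isin(mask.labels, counted)
            mean_int = float(pix[sel].mean())
        else:
            mean_int = float(
                np.mean([pix[mask.labels == k].mean() for k in counted])
            )
    else:
        mean_int = math.nan

    return FeatureQuant(
        image_id=image.id,
        group=group,
        roi_count=len(counted),
        density=len(counted) / area_mm2,
        mean_intensity=mean_int,
        region_area_mm2=area_mm2,
    )


def normalize_to_control(
    quants: list[FeatureQuant], control_group: str
) -> list[FeatureQuant]:
    """Divide every density by the control group's mean density.

    The control group's mean normalized density is exactly 1 afterwards.
    """
    control = [q.density for q in quants if q.group == control_group]
    if not control:
        raise ValueError(f"control group {control_group!r} is empty")
    mean = float(np.mean(control))
    if mean == 0:
        raise ValueError("control group mean density is zero")
    return [replace(q, normalized_density=q.density / mean) for q in quants]


def quants_to_frame(quants: list[FeatureQuant]) -> pd.DataFrame:
    """Tabulate quantifications (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "image_id": q.image_id,
                "group": q.group,
                "roi_count": q.roi_count,
                "density_per_mm2": q.density,
                "mean_intensity": q.mean_intensity,
                "region_area_mm2": q.region_area_mm2,
                "normalized_density": q.normalized_density,
            }
            for q in quants
        ]
    )
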