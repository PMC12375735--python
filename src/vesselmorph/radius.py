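"""Centerline radius estimation and radius/length stratification.

The local vessel radius at a centerline pixel is the Euclidean distance
from that pixel to the nearest background pixel (the vessel wall), read off
the exact Euclidean distance map (EDM) of the vessel mask and scaled to µm.
Branches are then summarised to a single radius, classified as
small-radius (<= 7 µm) or large-radius (> 7 µm), cross-classified by
length as short (<= 20 µm) or long (> 20 µm), and total centerline length
is accumulated per stratum.  Both thresholds are configurable defaults,
with inclusive `<=` on the small/short side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .skeleton import SkeletonGraph


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance map of a binary mask, in pixels.

    Each foreground pixel carries the distance from its center to the
    nearest background pixel *center* (so a single foreground pixel, or the
    centerline of a one-pixel-wide line, has value 1); background is 0.
    """
    return ndi.distance_transform_edt(np.asarray(mask, dtype=bool))


def centerline_radii(
    edm: np.ndarray, skeleton: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Radius field: EDM (pixels) x skeleton x pixel_size, in µm.

    Nonzero only on skeleton pixels; elsewhere zero.
    """
    edm = np.asarray(edm, dtype=float)
    skel = np.asarray(skeleton, dtype=bool)
    if edm.shape != skel.shape:
        raise ValueError(f"shape mismatch: EDM {edm.shape}, skeleton {skel.shape}")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    return edm * skel * pixel_size


@dataclass(frozen=True)
class StratifiedTotals:
    """Total centerline length (µm) per radius/length stratum."""

    small_total_um: float
    large_total_um: float
    large_short_total_um: float
    large_long_total_um: float
    small_short_total_um: float
    small_long_total_um: float

    @property
    def total_um(self) -> float:
        return self.small_total_um + self.large_total_um


def _branch_radius(
    branch_pixels: list[tuple[int, int]],
    radius_field: np.ndarray,
    junction_pixels: np.ndarray,
    statistic: str,
    junction_margin: int = 2,
) -> float:
    """Summary radius of one branch from its centerline pixels.

    The EDM is inflated where several vessels merge, so the ``junction_margin``
    pixels adjacent to a junction-cluster end of the branch are excluded from
    the summary; if nothing remains (very short inter-junction branches) the
    full path is used.
    """
    pix = branch_pixels
    keep = pix
    if junction_pixels is not None and len(pix) > 1:
        lo = 0
        hi = len(pix)
        if junction_pixels[pix[0]]:
            lo = 1 + junction_margin
        if junction_pixels[pix[-1]]:
            hi = len(pix) - 1 - junction_margin
        if lo < hi:
            keep = pix[lo:hi]
    vals = np.array([radius_field[p] for p in keep], dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        vals = np.array([radius_field[p] for p in pix], dtype=float)
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("branch has no centerline pixel with a radius value")
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "max":
        return float(vals.max())
    raise ValueError(f"unknown radius statistic {statistic!r}")


def summarize_and_classify(
    graph: SkeletonGraph,
    radius_field: np.ndarray,
    radius_threshold: float = 7.0,
    length_threshold: float = 20.0,
    statistic: str = "median",
) -> tuple[pd.DataFrame, StratifiedTotals]:
    """Per-branch radius summary, class labels and stratified length totals.

    Returns a branch table with columns ``branch_id, length_um, n_pixels,
    radius_um, radius_class, length_class`` and the per-stratum
    :class:`StratifiedTotals`.  ``radius_class`` is ``"small"`` iff the
    branch radius is <= ``radius_threshold`` (inclusive), ``length_class``
    ``"short"`` iff its length is <= ``length_threshold``.
    """
    rows = []
    for b in graph.branches:
        r = _branch_radius(b.pixels, radius_field, graph.junction_pixels, statistic)
        rows.append(
            {
                "branch_id": b.branch_id,
                "length_um": b.length_um,
                "n_pixels": b.n_pixels,
                "radius_um": r,
            }
        )
    table = pd.DataFrame(
        rows, columns=["branch_id", "length_um", "n_pixels", "radius_um"]
    )
    table["radius_class"] = np.where(
        table["radius_um"] <= radius_threshold, "small", "large"
    )
    table["length_class"] = np.where(
        table["length_um"] <= length_threshold, "short", "long"
    )

    def _total(sel) -> float:
        return float(table.loc[sel, "length_um"].sum())

    small = table["radius_class"] == "small"
    short = table["length_class"] == "short"
    totals = StratifiedTotals(
        small_total_um=_total(small),
        large_total_um=_total(~small),
        large_short_total_um=_total(~small & short),
        large_long_total_um=_total(~small & ~short),
        small_short_total_um=_total(small & short),
        small_long_total_um=_total(small & ~short),
    )
    return table, totals


def radius_class_overlay(
    skeleton: np.ndarray,
    radius_field: np.ndarray,
    radius_threshold: float = 7.0,
) -> np.ndarray:
    """QC overlay: RGB image with small-radius centerlines magenta and
    large-radius centerlines blue (per-pixel classification)."""
    skel = np.asarray(skeleton, dtype=bool)
    rgb = np.zeros(skel.shape + (3,), dtype=np.uint8)
    small = skel & (radius_field <= radius_threshold)
    large = skel & (radius_field > radius_threshold)
    rgb[small] = (255, 0, 255)
    rgb[large] = (0, 0, 255)
    return rgb
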