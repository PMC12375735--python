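"""Per-sample morphometry reports and auxiliary measurements.

Covers the branch-length histogram (the distribution the group ANOVA is
run on), the Cavalieri serial-section volume estimator for the lobe, and
object-based double-positive (colocalization) cell counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .skeleton import MorphoDensities
from .radius import StratifiedTotals

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class LengthHistogram:
    """Branch counts per length bin.

    ``edges`` are the finite interior edges in µm; bins are
    ``(0, e1], (e1, e2], ..., (ek, inf)`` — right-closed so that the short/long
    split at a threshold edge matches the inclusive `<=` branch classes.
    ``density`` holds the same counts normalised per 10,000 µm² of ROI.
    """

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    density: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def length_histogram(
    branch_table: pd.DataFrame,
    edges: tuple[float, ...] = (20.0, 40.0, 60.0),
    roi_area_um2: float | None = None,
) -> LengthHistogram:
    """Histogram branch lengths into right-closed bins ending in (last, inf).

    ``edges`` must be strictly increasing and positive.  Counts always
    partition the branch table; the per-area densities (per 10,000 µm²) are
    zero-filled when no ROI area is given.
    """
    e = np.asarray(edges, dtype=float)
    if e.size == 0 or np.any(np.diff(e) <= 0) or e[0] <= 0:
        raise ValueError("edges must be positive and strictly increasing")
    lengths = branch_table["length_um"].to_numpy(dtype=float)
    if np.any(lengths < 0):
        raise ValueError("negative branch length")
    full = np.concatenate([[-np.inf], e, [np.inf]])
    # right-closed bins: count lengths in (e_i, e_{i+1}]
    idx = np.searchsorted(full, lengths, side="left")
    counts = np.bincount(idx - 1, minlength=e.size + 1)[: e.size + 1]
    if roi_area_um2:
        dens = counts / roi_area_um2 * 1e4
    else:
        dens = np.zeros_like(counts, dtype=float)
    return LengthHistogram(tuple(e), tuple(int(c) for c in counts), tuple(dens))


def lobe_volume(areas_um2, interval_um: float = 180.0) -> float:
    """Cavalieri estimate of lobe volume from serial-section areas.

    ``volume = sum(section areas) * section interval``; areas in µm²,
    interval in µm (default 180 µm between adjacent sections on a slide),
    result in µm³.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one section")
    if np.any(areas < 0):
        raise ValueError("section areas must be >= 0")
    if not interval_um > 0:
        raise ValueError("section interval must be > 0")
    return float(areas.sum() * interval_um)


def double_positive_count(
    mask_a: np.ndarray, mask_b: np.ndarray, min_overlap_px: int = 1
) -> int:
    """Object-based colocalization count.

    Counts 8-connected objects of ``mask_a`` (e.g. nuclear-marker-positive
    cells) whose overlap with ``mask_b`` (e.g. the endothelial mask) is at
    least ``min_overlap_px`` pixels — the "double-positive" cells.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min_overlap_px < 1:
        raise ValueError("min_overlap_px must be >= 1")
    lab, n = ndi.label(a, structure=_EIGHT)
    if n == 0:
        return 0
    overlap = ndi.sum_labels(b.astype(int), lab, index=np.arange(1, n + 1))
    return int((overlap >= min_overlap_px).sum())


@dataclass
class MorphometryReport:
    """Everything measured on one sample, with the parameters that made it."""

    sample_id: str
    roi_area_um2: float
    densities: MorphoDensities
    histogram: LengthHistogram
    totals: StratifiedTotals
    n_branches: int
    n_branch_points: int
    n_endpoints: int
    total_length_um: float
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "MorphometryReport":
        d = dict(d)
        d["densities"] = MorphoDensities(**d["densities"])
        h = d["histogram"]
        d["histogram"] = LengthHistogram(
            tuple(h["edges"]), tuple(h["counts"]), tuple(h["density"])
        )
        d["totals"] = StratifiedTotals(**d["totals"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "MorphometryReport":
        return cls.from_dict(json.loads(text))
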