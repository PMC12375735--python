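"""Synthetic vascular networks with exact ground truth.

Vessels are modelled as *capsules*: straight centerline segments dilated by a
constant radius, with hemispherical (disc) caps.  A pixel belongs to the
ground-truth mask iff its center lies within ``radius`` of the segment's
centerline, which makes centerline length and local radius analytically exact
and usable as an oracle for the measurement pipeline.

Coordinates are physical, in µm, ordered ``(y, x)`` so they map directly onto
``(row, col)`` rasters; the pixel ``(i, j)`` center sits at
``(i * pixel_size, j * pixel_size)``.

Two generators are provided on top of the renderer:

* :func:`sample_tree` — a connected branching tree with radii tapering from
  the root, for topology-recovery tests.
* :func:`generate_study` — a two-group study of scattered, non-overlapping
  vessel segments whose branch-length and radius composition differs between
  groups, emulating a knockout-vs-control comparison in which the affected
  group has fewer short branches and fewer large-radius vessels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "VesselSegment",
    "NoiseModel",
    "VesselNetworkSpec",
    "GroundTruth",
    "StudyDesign",
    "StudySample",
    "render_network",
    "sample_tree",
    "generate_study",
    "population_metrics",
    "write_study",
]

#: default length-bin edges (µm) used for branch-length stratification
DEFAULT_BIN_EDGES = (20.0, 40.0, 60.0)


@dataclass(frozen=True)
class VesselSegment:
    """A constant-radius vessel segment (capsule) in physical coordinates.

    Parameters
    ----------
    start, end : tuple of float
        Centerline endpoints ``(y, x)`` in µm.
    radius : float
        Vessel radius in µm; must be positive.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"segment radius must be > 0, got {self.radius}")
        if tuple(self.start) == tuple(self.end):
            raise ValueError("segment start and end coincide")

    @property
    def length(self) -> float:
        """Euclidean centerline length in µm."""
        return math.dist(self.start, self.end)


@dataclass(frozen=True)
class NoiseModel:
    """Intensity noise applied after PSF blurring.

    kind: ``"none"``, ``"gaussian"`` (additive, ``sd`` in intensity units;
    ``sd=None`` means 5% of the foreground-background dynamic range) or
    ``"poisson"`` (shot noise; intensities are scaled by ``scale``, Poisson
    sampled and scaled back).
    """

    kind: str = "gaussian"
    sd: float | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class VesselNetworkSpec:
    """Everything needed to render one synthetic vessel image."""

    segments: tuple[VesselSegment, ...]
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    foreground_intensity: float = 200.0
    background_intensity: float = 20.0
    psf_sigma: float = 1.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.foreground_intensity > self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        ymax = (self.image_shape[0] - 1) * self.pixel_size
        xmax = (self.image_shape[1] - 1) * self.pixel_size
        for k, seg in enumerate(self.segments):
            for pt in (seg.start, seg.end):
                if not (
                    seg.radius <= pt[0] <= ymax - seg.radius
                    and seg.radius <= pt[1] <= xmax - seg.radius
                ):
                    raise ValueError(
                        f"segment {k} exceeds image bounds after dilation by its radius"
                    )


@dataclass
class GroundTruth:
    """Analytic ground truth for a rendered network.

    ``branches`` has one row per segment with exact ``length_um`` and
    ``radius_um``.  Junctions/endpoints are defined on the *specification*
    graph: a point where >= 3 segment ends meet is a junction, a point
    touched by exactly one segment end is an endpoint (points shared by
    exactly two ends are interior connectors, neither).
    """

    branches: pd.DataFrame
    n_junctions: int
    n_endpoints: int
    total_length_um: float
    area_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_fraction <= 1.0:
            raise ValueError("area fraction outside [0, 1]")


def _segment_point_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points ``p`` (N, 2) to segment ``a``–``b``."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def _paint_segment(mask: np.ndarray, seg: VesselSegment, pixel_size: float) -> None:
    r = seg.radius / pixel_size
    a = np.asarray(seg.start) / pixel_size
    b = np.asarray(seg.end) / pixel_size
    lo = np.maximum(np.floor(np.minimum(a, b) - r).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(a, b) + r).astype(int) + 1, mask.shape)
    yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1]]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d = _segment_point_distance(pts, a, b).reshape(yy.shape)
    mask[lo[0] : hi[0], lo[1] : hi[1]] |= d <= r


def _spec_topology(segments: tuple[VesselSegment, ...]) -> tuple[int, int]:
    """(junction count, endpoint count) from endpoint multiplicity."""
    counts: dict[tuple[float, float], int] = {}
    for seg in segments:
        for pt in (seg.start, seg.end):
            key = (round(pt[0], 6), round(pt[1], 6))
            counts[key] = counts.get(key, 0) + 1
    n_junction = sum(1 for c in counts.values() if c >= 3)
    n_endpoint = sum(1 for c in counts.values() if c == 1)
    return n_junction, n_endpoint


def render_network(
    spec: VesselNetworkSpec, roi: np.ndarray | None = None
) -> tuple["CalibratedImage", np.ndarray, GroundTruth]:
    """Render a network spec into an intensity image, mask and ground truth.

    Returns ``(image, mask, truth)`` where ``image`` is a
    :class:`~vesselmorph.io.CalibratedImage`, ``mask`` the exact boolean
    vessel mask, and ``truth`` the analytic :class:`GroundTruth`.  The mask
    is independent of PSF and noise, which affect only the intensity image.
    """
    from .io import CalibratedImage  # local import to avoid a cycle

    mask = np.zeros(spec.image_shape, dtype=bool)
    for seg in spec.segments:
        _paint_segment(mask, seg, spec.pixel_size)

    img = np.where(mask, spec.foreground_intensity, spec.background_intensity).astype(
        float
    )
    if spec.psf_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=spec.psf_sigma / spec.pixel_size)

    nm = spec.noise_model
    rng = np.random.default_rng(spec.seed)
    if nm.kind == "gaussian":
        sd = nm.sd
        if sd is None:
            sd = 0.05 * (spec.foreground_intensity - spec.background_intensity)
        img = img + rng.normal(0.0, sd, size=img.shape)
    elif nm.kind == "poisson":
        img = rng.poisson(np.maximum(img, 0.0) * nm.scale) / nm.scale
    img = np.clip(img, 0.0, None)

    branches = pd.DataFrame(
        {
            "length_um": [s.length for s in spec.segments],
            "radius_um": [s.radius for s in spec.segments],
        }
    )
    n_junction, n_endpoint = _spec_topology(spec.segments)
    roi_px = int(roi.sum()) if roi is not None else mask.size
    vessel_px = int((mask & roi).sum()) if roi is not None else int(mask.sum())
    truth = GroundTruth(
        branches=branches,
        n_junctions=n_junction,
        n_endpoints=n_endpoint,
        total_length_um=float(branches["length_um"].sum()),
        area_fraction=vessel_px / roi_px if roi_px else 0.0,
    )
    return CalibratedImage(img, spec.pixel_size), mask, truth


# ---------------------------------------------------------------------------
# branching trees


def _tree_self_clear(segments: list[VesselSegment], clearance: float = 3.0) -> bool:
    """True iff no two segments that do not share an endpoint approach within
    the sum of their radii plus ``clearance`` (µm).

    Trees violating this would create raster junctions or fused branches that
    the specification-graph ground truth does not describe, so they are
    rejected and resampled.
    """
    def _key(pt):
        return (round(pt[0], 6), round(pt[1], 6))

    for i, a in enumerate(segments):
        a_keys = {_key(a.start), _key(a.end)}
        for b in segments[i + 1 :]:
            if a_keys & {_key(b.start), _key(b.end)}:
                continue
            d = _segments_distance(
                np.asarray(a.start), np.asarray(a.end),
                np.asarray(b.start), np.asarray(b.end),
            )
            if d < a.radius + b.radius + clearance:
                return False
    return True


def sample_tree(
    depth: int = 3,
    root_radius: float = 2.5,
    taper: float = 0.9,
    length_range: tuple[float, float] = (60.0, 100.0),
    branch_angle_range: tuple[float, float] = (0.8, 1.3),
    image_shape: tuple[int, int] = (576, 576),
    pixel_size: float = 1.0,
    seed: int = 0,
    max_tries: int = 200,
    **spec_kwargs,
) -> VesselNetworkSpec:
    """Sample a connected binary vessel tree as a :class:`VesselNetworkSpec`.

    A root segment is placed near the image center with a random
    orientation; every non-leaf segment spawns two children deflected by a
    random angle on either side, with radii tapering geometrically by
    ``taper`` per generation (depth 1 is a single segment).  Sampling is
    deterministic for a fixed ``seed``; trees that would leave the image, or
    whose non-adjacent limbs would touch (which would create raster
    junctions absent from the specification-graph ground truth), are
    re-drawn up to ``max_tries`` times before an error is raised.

    The defaults emulate a thin (capillary-scale) tree with branches much
    longer than the vessel radius and wide branching angles — the regime in
    which skeleton morphometry recovers the generative topology exactly and
    branch lengths to within a few percent (see the package methods note).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 < taper <= 1:
        raise ValueError("taper must be in (0, 1]")
    if length_range[0] <= 0:
        raise ValueError("branch lengths must be positive")
    rng = np.random.default_rng(seed)
    ymax = (image_shape[0] - 1) * pixel_size
    xmax = (image_shape[1] - 1) * pixel_size

    for _ in range(max_tries):
        segments: list[VesselSegment] = []
        cy = rng.uniform(0.35 * ymax, 0.65 * ymax)
        cx = rng.uniform(0.35 * xmax, 0.65 * xmax)
        theta0 = rng.uniform(0, 2 * math.pi)
        ok = True

        def grow(p: tuple[float, float], theta: float, level: int) -> bool:
            nonlocal ok
            radius = root_radius * taper ** (level - 1)
            length = rng.uniform(*length_range)
            q = (p[0] + length * math.sin(theta), p[1] + length * math.cos(theta))
            for pt in (p, q):
                if not (
                    radius <= pt[0] <= ymax - radius
                    and radius <= pt[1] <= xmax - radius
                ):
                    return False
            segments.append(VesselSegment(p, q, radius))
            if level < depth:
                for sign in (+1.0, -1.0):
                    dtheta = rng.uniform(*branch_angle_range)
                    if not grow(q, theta + sign * dtheta, level + 1):
                        return False
            return True

        if grow((cy, cx), theta0, 1) and ok and _tree_self_clear(segments):
            return VesselNetworkSpec(
                segments=tuple(segments),
                image_shape=image_shape,
                pixel_size=pixel_size,
                seed=int(rng.integers(2**31)),
                **spec_kwargs,
            )
    raise RuntimeError(
        f"could not fit a depth-{depth} tree inside {image_shape} after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# two-group studies


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic two-group vascular study.

    Each sample is a field of scattered, mutually non-overlapping vessel
    segments.  Branch counts per length bin are Poisson with intensities
    ``bin_lambdas`` (short-branch dominated, as in capillary beds); a branch
    is a large-radius vessel (radius drawn from ``large_radius_range``,
    otherwise ``small_radius_range``) with probability ``p_large``.

    ``group_effects`` maps each group label to a pair of multipliers
    ``(short_branch, large_radius)``: the first scales the expected count of
    short branches (first length bin, <= 20 µm), the second the probability —
    hence the expected total length — of large-radius vessels.
    """

    n_per_group: int = 5
    group_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (1.0, 1.0), "KO": (0.3, 0.3)}
    )
    bin_lambdas: tuple[float, ...] = (32.0, 24.0, 16.0, 8.0)
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    min_length: float = 6.0
    max_length: float = 110.0
    # probability that an eligible (long-enough) branch is a large-calibre
    # vessel; with the default length mix this yields ~15 large vessels per
    # control sample
    p_large: float = 0.5
    small_radius_range: tuple[float, float] = (2.0, 5.0)
    large_radius_range: tuple[float, float] = (8.0, 9.5)
    # only branches at least this long can carry a large calibre: an isolated
    # capsule shorter than ~2 diameters is a blob, not a tube, and lies
    # outside the validity domain of ridge-based segmentation
    large_min_length_um: float = 35.0
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    # wall-to-wall clearance between placed segments; at least twice the
    # tubeness scale (sigma 4 px) so the analysis chain can resolve
    # neighbouring vessels as distinct objects
    min_gap: float = 8.0
    psf_sigma: float = 1.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g, (ms, ml) in self.group_effects.items():
            if ms < 0 or ml < 0:
                raise ValueError(f"multipliers for group {g!r} must be >= 0")
        if len(self.bin_lambdas) != len(self.bin_edges) + 1:
            raise ValueError("need len(bin_lambdas) == len(bin_edges) + 1")


@dataclass
class StudySample:
    """One synthetic sample: its group, ground-truth branches and (optionally)
    the placed, renderable network spec."""

    sample_id: str
    group: str
    branches: pd.DataFrame
    spec: VesselNetworkSpec | None = None


def _sample_population(design: StudyDesign, effects, rng) -> pd.DataFrame:
    m_short, m_large = effects
    edges = (design.min_length,) + tuple(design.bin_edges) + (design.max_length,)
    lengths: list[float] = []
    for b, lam in enumerate(design.bin_lambdas):
        if b == 0:
            lam = lam * m_short
        n = rng.poisson(lam)
        lengths.extend(rng.uniform(edges[b], edges[b + 1], size=n))
    lengths_arr = np.asarray(lengths)
    p = min(design.p_large * m_large, 1.0)
    eligible = lengths_arr >= design.large_min_length_um
    is_large = eligible & (rng.random(lengths_arr.size) < p)
    radii = np.where(
        is_large,
        rng.uniform(*design.large_radius_range, size=lengths_arr.size),
        rng.uniform(*design.small_radius_range, size=lengths_arr.size),
    )
    df = pd.DataFrame({"length_um": lengths_arr, "radius_um": radii})
    return df.sort_values("radius_um", ascending=False, ignore_index=True)


def _segments_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments."""
    pts_a = np.linspace(a0, a1, 24)
    d1 = _segment_point_distance(pts_a, np.asarray(b0), np.asarray(b1)).min()
    pts_b = np.linspace(b0, b1, 24)
    d2 = _segment_point_distance(pts_b, np.asarray(a0), np.asarray(a1)).min()
    return float(min(d1, d2))


def _place_segments(
    branches: pd.DataFrame, design: StudyDesign, rng, tries_per_branch: int = 400
) -> tuple[VesselSegment, ...]:
    ymax = (design.image_shape[0] - 1) * design.pixel_size
    xmax = (design.image_shape[1] - 1) * design.pixel_size
    placed: list[VesselSegment] = []
    for row in branches.itertuples():
        L, r = row.length_um, row.radius_um
        for _ in range(tries_per_branch):
            theta = rng.uniform(0, 2 * math.pi)
            dy, dx = 0.5 * L * math.sin(theta), 0.5 * L * math.cos(theta)
            margin_y = abs(dy) + r
            margin_x = abs(dx) + r
            if 2 * margin_y >= ymax or 2 * margin_x >= xmax:
                continue
            cy = rng.uniform(margin_y, ymax - margin_y)
            cx = rng.uniform(margin_x, xmax - margin_x)
            p, q = (cy - dy, cx - dx), (cy + dy, cx + dx)
            clearance = r + design.min_gap
            if all(
                _segments_distance(np.asarray(p), np.asarray(q), s.start, s.end)
                >= clearance + s.radius
                for s in placed
            ):
                placed.append(VesselSegment(p, q, r))
                break
        else:
            raise RuntimeError(
                f"could not place a segment of length {L:.1f} µm without overlap; "
                "reduce branch counts or enlarge the image"
            )
    return tuple(placed)


def generate_study(design: StudyDesign, place: bool = True) -> list[StudySample]:
    """Generate a two-group synthetic study.

    Returns one :class:`StudySample` per animal.  Ground-truth branch tables
    (``branches``) are always produced; with ``place=True`` each sample also
    carries a renderable :class:`VesselNetworkSpec` in which the segments are
    laid out without mutual overlap (so that every generated branch remains
    an individual branch of the rendered network).  The ground truth for a
    given seed is identical whether or not placement is requested.
    """
    root = np.random.SeedSequence(design.seed)
    groups = list(design.group_effects)
    sample_seeds = root.spawn(len(groups) * design.n_per_group)
    samples: list[StudySample] = []
    k = 0
    for group in groups:
        effects = design.group_effects[group]
        for i in range(design.n_per_group):
            pop_ss, place_ss, noise_ss = sample_seeds[k].spawn(3)
            k += 1
            branches = _sample_population(
                design, effects, np.random.default_rng(pop_ss)
            )
            spec = None
            if place:
                segments = _place_segments(
                    branches, design, np.random.default_rng(place_ss)
                )
                spec = VesselNetworkSpec(
                    segments=segments,
                    image_shape=design.image_shape,
                    pixel_size=design.pixel_size,
                    psf_sigma=design.psf_sigma,
                    noise_model=design.noise_model,
                    seed=int(np.random.default_rng(noise_ss).integers(2**31)),
                )
            samples.append(
                StudySample(
                    sample_id=f"{group}_{i + 1:02d}", group=group,
                    branches=branches, spec=spec,
                )
            )
    return samples


def spec_to_yaml(spec: VesselNetworkSpec, path) -> None:
    """Serialize a network spec to YAML (segments, geometry, render settings)."""
    import yaml

    payload = {
        "segments": [
            {"start": list(s.start), "end": list(s.end), "radius": s.radius}
            for s in spec.segments
        ],
        "image_shape": list(spec.image_shape),
        "pixel_size": spec.pixel_size,
        "foreground_intensity": spec.foreground_intensity,
        "background_intensity": spec.background_intensity,
        "psf_sigma": spec.psf_sigma,
        "noise_model": {"kind": spec.noise_model.kind, "sd": spec.noise_model.sd,
                        "scale": spec.noise_model.scale},
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> VesselNetworkSpec:
    """Load a network spec written by :func:`spec_to_yaml`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return VesselNetworkSpec(
        segments=tuple(
            VesselSegment(tuple(s["start"]), tuple(s["end"]), s["radius"])
            for s in raw["segments"]
        ),
        image_shape=tuple(raw["image_shape"]),
        pixel_size=raw["pixel_size"],
        foreground_intensity=raw["foreground_intensity"],
        background_intensity=raw["background_intensity"],
        psf_sigma=raw["psf_sigma"],
        noise_model=NoiseModel(**raw["noise_model"]),
        seed=raw["seed"],
    )


def match_branches(graph, spec: VesselNetworkSpec) -> pd.DataFrame:
    """Match measured skeleton branches to the true segments of a spec.

    Graph nodes (junction-cluster centroids and endpoints) are assigned to
    the nearest true network node (segment endpoints, in pixel units); a
    measured branch then corresponds to the true segment joining its two
    node assignments.  Returns a frame with ``branch_id, length_um,
    true_length_um, true_radius_um`` for every branch whose node pair maps
    onto a true segment (all of them, when topology is recovered exactly).
    """
    from scipy import ndimage as ndi

    ps = spec.pixel_size
    jlab, nj = ndi.label(graph.junction_pixels, structure=np.ones((3, 3), int))
    centroids = {
        lab: np.array(np.nonzero(jlab == lab)).mean(axis=1) for lab in range(1, nj + 1)
    }
    node_pos = {}
    for nid, (kind, rep) in graph.nodes.items():
        node_pos[nid] = (
            centroids[jlab[rep]] if kind == "junction" else np.array(rep, float)
        )

    true_nodes: dict[tuple[float, float], np.ndarray] = {}
    for seg in spec.segments:
        for pt in (seg.start, seg.end):
            true_nodes[(round(pt[0], 6), round(pt[1], 6))] = np.asarray(pt) / ps
    tkeys = list(true_nodes)
    tpos = np.array([true_nodes[k] for k in tkeys])
    seg_by_pair = {}
    for i, seg in enumerate(spec.segments):
        a = (round(seg.start[0], 6), round(seg.start[1], 6))
        b = (round(seg.end[0], 6), round(seg.end[1], 6))
        seg_by_pair[frozenset((a, b))] = i

    rows = []
    for b in graph.branches:
        if b.node_a < 0 or b.node_b < 0:
            continue
        pa, pb = node_pos[b.node_a], node_pos[b.node_b]
        ka = tkeys[int(np.argmin(np.linalg.norm(tpos - pa, axis=1)))]
        kb = tkeys[int(np.argmin(np.linalg.norm(tpos - pb, axis=1)))]
        i = seg_by_pair.get(frozenset((ka, kb)))
        if i is None:
            continue
        rows.append(
            {
                "branch_id": b.branch_id,
                "length_um": b.length_um,
                "true_length_um": spec.segments[i].length,
                "true_radius_um": spec.segments[i].radius,
            }
        )
    return pd.DataFrame(rows)


def population_metrics(
    branches: pd.DataFrame,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    radius_threshold: float = 7.0,
    length_threshold: float = 20.0,
) -> dict:
    """Ground-truth summary metrics for one sample's branch population."""
    L = branches["length_um"].to_numpy()
    r = branches["radius_um"].to_numpy()
    edges = np.concatenate([[0.0], bin_edges, [np.inf]])
    counts, _ = np.histogram(L, bins=edges)
    large = r > radius_threshold
    short = L <= length_threshold
    return {
        "n_branches": int(L.size),
        "total_length_um": float(L.sum()),
        "n_short_branches": int(short.sum()),
        "large_radius_total_length_um": float(L[large].sum()),
        "small_radius_total_length_um": float(L[~large].sum()),
        "bin_counts": counts.astype(int).tolist(),
    }


def write_study(samples: list[StudySample], out_dir) -> pd.DataFrame:
    """Render a placed study to TIFF images + ROI masks and write the manifest.

    Creates ``<sample>.tif`` (intensity image), ``<sample>_roi.tif``
    (all-ones ROI), per-sample ground-truth branch tables, and
    ``manifest.csv`` with columns ``sample,group,image,roi``.  Returns the
    manifest as a DataFrame.
    """
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    gt_rows = []
    for s in samples:
        if s.spec is None:
            raise ValueError("study was generated without placement; cannot render")
        image, mask, truth = render_network(s.spec)
        img_path = out / f"{s.sample_id}.tif"
        roi_path = out / f"{s.sample_id}_roi.tif"
        tifffile.imwrite(
            img_path,
            image.pixels.astype(np.float32),
            resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size),
            metadata={"unit": "um"},
        )
        tifffile.imwrite(roi_path, np.ones(image.pixels.shape, dtype=np.uint8))
        rows.append(
            {"sample": s.sample_id, "group": s.group,
             "image": img_path.name, "roi": roi_path.name}
        )
        gt = s.branches.assign(sample=s.sample_id, group=s.group)
        gt_rows.append(gt)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.concat(gt_rows, ignore_index=True).to_csv(
        out / "ground_truth_branches.csv", index=False
    )
    return manifest
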