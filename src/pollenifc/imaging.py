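"""Synthetic stained-pollen micrographs and a rule-based dye-exclusion count.

The microscopy validation arm emulates acid-fuchsine dye exclusion in
bright-field imaging: dead grains stain dark, viable grains stay bright and
large (maximum Feret diameter ~38 ± 4 μm), dead grains are slightly smaller
(~34 ± 3 μm) and sterile grains are small (~27 ± 3 μm), unstained and
subtriangular.  Micrographs are rendered as 8-bit grayscale ("dark pink"
becomes low intensity: dye exclusion is a one-channel contrast decision),
with non-overlapping objects so segmentation recall is exact by
construction.

Classification is a transparent two-rule surrogate for a trained
classifier: stain intensity first (dark → dead), then size (small → sterile,
else viable).  The rules *are* the features that matter for this assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import draw as skdraw
from skimage.filters import threshold_otsu
from skimage.measure import label as sklabel
from skimage.measure import regionprops

from .impedance import RegressionFit, fit_linear

__all__ = [
    "RenderConfig",
    "SyntheticMicrograph",
    "render_micrograph",
    "segment",
    "max_feret",
    "classify_objects",
    "image_viability_percent",
    "simulate_image_arm",
    "method_agreement",
]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters of the synthetic micrographs.

    Sizes are maximum Feret diameters in μm (mean, sd) per class; the pixel
    scale defaults to 0.5 μm/px (4× objective regime).  Intensities are
    8-bit gray levels; background sits between the dark (stained dead) and
    bright (unstained) classes, at least 30 levels from each.
    """

    scale_um_per_px: float = 0.5
    background: int = 128
    intensities: dict = field(
        default_factory=lambda: {"viable": 200.0, "dead": 60.0, "sterile": 195.0}
    )
    feret_um: dict = field(
        default_factory=lambda: {"viable": (38.0, 4.0), "dead": (34.0, 3.0), "sterile": (27.0, 3.0)}
    )
    intensity_jitter: float = 4.0
    pixel_noise_sd: float = 3.0
    fill_fraction: float = 0.25
    margin_px: float = 3.0
    #: smallest rendered grain; smaller objects would be debris-filtered
    floor_feret_um: float = 21.0
    max_retries: int = 2000


@dataclass(frozen=True)
class SyntheticMicrograph:
    """Rendered image plus the ground truth used to draw it."""

    pixels: np.ndarray  # uint8, (rows, cols)
    scale_um_per_px: float
    truth: pd.DataFrame  # columns: row_px, col_px, true_label, feret_um


def _object_pixels(
    cls: str, feret_um: float, center: tuple[float, float], cfg: RenderConfig, rng: np.random.Generator
):
    """Pixel coordinates of one rendered grain (ellipse or triangle)."""
    r0, c0 = center
    f_px = feret_um / cfg.scale_um_per_px
    if cls == "sterile":
        # subtriangular outline: vertices of a rotated equilateral triangle
        # whose maximum vertex distance (the side) equals the Feret diameter
        circ_r = f_px / np.sqrt(3.0)
        angles = rng.uniform(0, 2 * np.pi) + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        rows = r0 + circ_r * np.sin(angles)
        cols = c0 + circ_r * np.cos(angles)
        return skdraw.polygon(rows, cols)
    a = f_px / 2.0
    b = a * rng.uniform(0.85, 1.0)
    rot = rng.uniform(0, np.pi)
    return skdraw.ellipse(r0, c0, a, b, rotation=rot)


def render_micrograph(
    n_objects: int,
    class_fractions: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    config: RenderConfig | None = None,
) -> SyntheticMicrograph:
    """Render a synthetic stained-pollen micrograph with known truth.

    Objects are placed by rejection sampling with non-overlap enforced on
    bounding circles (plus a margin), so rendered grains never touch; the
    image side is sized so the bounding circles fill at most
    ``config.fill_fraction`` of the area.  Deterministic under a fixed
    seed.  Raises if an object cannot be placed within ``max_retries``
    (density too high).
    """
    cfg = config or RenderConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = class_fractions or {"viable": 1.0}
    labels = list(fractions)
    probs = np.array([fractions[c] for c in labels], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("class fractions must be non-negative and not all zero")
    probs = probs / probs.sum()

    if n_objects == 0:
        img = np.full((64, 64), cfg.background, dtype=np.uint8)
        truth = pd.DataFrame(columns=["row_px", "col_px", "true_label", "feret_um"])
        return SyntheticMicrograph(img, cfg.scale_um_per_px, truth)

    classes = rng.choice(len(labels), size=n_objects, p=probs)
    ferets = np.empty(n_objects)
    for i, ci in enumerate(classes):
        mean, sd = cfg.feret_um[labels[ci]]
        ferets[i] = max(rng.normal(mean, sd), cfg.floor_feret_um)
    # collision radius = drawn extent from the centre (triangles reach their
    # circumradius feret/sqrt(3), ellipses feret/2) plus a separation margin
    extent = np.where(
        np.array([labels[ci] == "sterile" for ci in classes]),
        ferets / np.sqrt(3.0),
        ferets / 2.0,
    )
    radii_px = extent / cfg.scale_um_per_px + cfg.margin_px
    side = int(np.ceil(np.sqrt(np.pi * np.sum(radii_px**2) / cfg.fill_fraction)))
    side = max(side, int(2 * radii_px.max() + 4))

    # grid-accelerated non-overlap rejection sampling on bounding circles
    cell = max(2.0 * radii_px.max(), 1.0)
    n_cells = int(np.ceil(side / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.empty((n_objects, 2))
    for i in range(n_objects):
        r = radii_px[i]
        for attempt in range(cfg.max_retries):
            pos = rng.uniform(r, side - r, size=2)
            gi, gj = int(pos[0] // cell), int(pos[1] // cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for j in grid.get((gi + di, gj + dj), ()):
                        if np.hypot(*(pos - centers[j])) < r + radii_px[j]:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[i] = pos
                grid.setdefault((gi, gj), []).append(i)
                break
        else:
            raise RuntimeError(
                f"could not place object {i} after {cfg.max_retries} retries; "
                "lower the object density or fill_fraction"
            )

    img = np.full((side, side), float(cfg.background), dtype=np.float32)
    records = []
    for i in range(n_objects):
        cls = labels[classes[i]]
        rr, cc = _object_pixels(cls, ferets[i], tuple(centers[i]), cfg, rng)
        keep = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        intensity = np.clip(
            cfg.intensities[cls] + rng.normal(0.0, cfg.intensity_jitter), 0, 255
        )
        img[rr[keep], cc[keep]] = intensity
        records.append(
            {
                "row_px": centers[i][0],
                "col_px": centers[i][1],
                "true_label": cls,
                "feret_um": ferets[i],
            }
        )
    img += cfg.pixel_noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticMicrograph(pixels, cfg.scale_um_per_px, pd.DataFrame(records))


def max_feret(coords: np.ndarray, scale_um_per_px: float = 1.0) -> float:
    """Maximum Feret (caliper) diameter of a pixel region, in μm.

    Each pixel is treated as a unit square; the diameter is the maximum
    pairwise distance over the convex hull of all pixel corners (computed
    as the hull of the pixel-center hull's corners, which is identical by
    the Minkowski-sum identity).  A 10×4-pixel rectangle at scale 1 thus
    measures √(10² + 4²) ≈ 10.77, corner to corner.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 2) array of pixel positions")
    if coords.shape[0] >= 3:
        try:
            hull = ConvexHull(coords)
            base = coords[hull.vertices]
        except QhullError:  # collinear pixel set
            base = coords
    else:
        base = coords
    offsets = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
    corners = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except QhullError:
        warnings.warn("degenerate object; falling back to equivalent-box diagonal", stacklevel=2)
        pts = corners
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max()) * scale_um_per_px


def segment(
    image: np.ndarray,
    scale_um_per_px: float = 0.5,
    background: float | None = None,
    min_diameter_um: float = 15.0,
) -> pd.DataFrame:
    """Detect pollen objects in an 8-bit grayscale micrograph.

    Pipeline: subtract the background level (median if not given), Otsu
    threshold on the absolute deviation (so both dark-stained and bright
    unstained grains segment), 8-connected components, and a minimum-area
    filter at the area of a ``min_diameter_um`` circle.  Returns one row per
    object: id, row/col centroid (px), area_um2, feret_um, mean_intensity.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    bg = float(np.median(img)) if background is None else float(background)
    mag = np.abs(img.astype(np.float32) - bg)
    if mag.max() == 0:
        return pd.DataFrame(
            columns=["id", "row_px", "col_px", "area_um2", "feret_um", "mean_intensity"]
        )
    thr = threshold_otsu(mag)
    mask = mag > thr
    if not mask.any():
        return pd.DataFrame(
            columns=["id", "row_px", "col_px", "area_um2", "feret_um", "mean_intensity"]
        )
    labelled = sklabel(mask, connectivity=2)
    px_area_um2 = scale_um_per_px**2
    min_area_px = np.pi * (min_diameter_um / 2.0) ** 2 / px_area_um2
    rows = []
    for region in regionprops(labelled, intensity_image=img):
        if region.area < min_area_px:
            continue
        rows.append(
            {
                "id": region.label,
                "row_px": region.centroid[0],
                "col_px": region.centroid[1],
                "area_um2": region.area * px_area_um2,
                "feret_um": max_feret(region.coords, scale_um_per_px),
                "mean_intensity": float(region.intensity_mean),
            }
        )
    return pd.DataFrame(rows)


def classify_objects(
    objects: pd.DataFrame,
    intensity_cut: float = 130.0,
    feret_cut_um: float = 31.0,
) -> np.ndarray:
    """Two-rule dye-exclusion classification of segmented objects.

    Stained (mean intensity below ``intensity_cut``) → dead; otherwise
    small (max Feret below ``feret_cut_um``, default 31 μm — the midpoint
    of the sterile 27 μm and viable/dead 34–38 μm size regimes) → sterile;
    otherwise viable.
    """
    intensity = objects["mean_intensity"].to_numpy(dtype=float)
    feret = objects["feret_um"].to_numpy(dtype=float)
    labels = np.where(
        intensity < intensity_cut,
        "dead",
        np.where(feret < feret_cut_um, "sterile", "viable"),
    )
    return labels.astype(object)


def image_viability_percent(labels, exclude_sterile: bool = True) -> float:
    """Viable percentage from image-based class labels."""
    labels = np.asarray(labels)
    v = int((labels == "viable").sum())
    d = int((labels == "dead").sum())
    s = int((labels == "sterile").sum())
    denom = v + d if exclude_sterile else v + d + s
    if denom == 0:
        return float("nan")
    return 100.0 * v / denom


def simulate_image_arm(
    ratios=((1, 0), (3, 1), (1, 1), (1, 3), (0, 1)),
    samples: int = 2,
    replicas: int = 3,
    objects_per_replica: int = 4000,
    untreated_viability: float = 0.95,
    sterile_fraction: float = 0.30,
    seed: int = 0,
    config: RenderConfig | None = None,
) -> pd.DataFrame:
    """Run the microscopy arm of the mixing-series validation.

    For each (ratio, sample, replica) a micrograph is rendered from the
    same ground-truth class fractions as the IFC arm, segmented, measured
    and classified; sterile-excluded viability is computed per replica.
    Returns a frame with ratio weights, nominal viability and
    ``image_viability_pct``.
    """
    cfg = config or RenderConfig()
    units = [
        (u, t, si, ri)
        for (u, t) in ratios
        for si in range(1, samples + 1)
        for ri in range(1, replicas + 1)
    ]
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(len(units))]
    rows = []
    for (u, t, si, ri), rng in zip(units, streams):
        r = u / (u + t)
        fractions = {
            "sterile": sterile_fraction,
            "viable": (1 - sterile_fraction) * r * untreated_viability,
            "dead": (1 - sterile_fraction) * (1 - r * untreated_viability),
        }
        micro = render_micrograph(objects_per_replica, fractions, rng, cfg)
        objs = segment(micro.pixels, cfg.scale_um_per_px, background=cfg.background)
        labels = classify_objects(objs)
        rows.append(
            {
                "ratio_untreated": float(u),
                "ratio_treated": float(t),
                "sample": f"S{si}",
                "replica": ri,
                "nominal_viability_pct": 100.0 * r * untreated_viability,
                "n_objects": len(objs),
                "image_viability_pct": image_viability_percent(labels),
            }
        )
    return pd.DataFrame(rows)


def method_agreement(ifc_viability, image_viability) -> RegressionFit:
    """Regression agreement between IFC and image viability series.

    Both arms must be paired (same replicas, sterile excluded) and
    non-constant; returns the OLS fit of the image arm on the IFC arm.
    """
    ifc = np.asarray(ifc_viability, dtype=float)
    img = np.asarray(image_viability, dtype=float)
    if ifc.size != img.size:
        raise ValueError("paired series differ in length")
    if np.ptp(ifc) == 0 or np.ptp(img) == 0:
        raise ValueError("constant viability arm; agreement undefined")
    return fit_linear(ifc, img)
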