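"""Synthetic plants and trait tables with exact known ground truth.

Two generators back the whole test surface of this package:

* :func:`render_plant` rasterises a stylised rice shoot (leaves radiating
  from a stem point, drawn as filled quadrilaterals) into an 8-bit RGB
  image together with a :class:`GroundTruth` record whose geometry is
  recomputed by brute force from the noise-free foreground mask.  Realism
  is explicitly not a goal; exact, independently-computed geometry is.
* :func:`simulate_trait_table` draws a balanced genotype x treatment x
  replicate trait table from the two-way model
  ``Y = mu + g_i + c_j + gc_ij + e_ijk`` with user-set variance
  components, the simulation inverse of the ANOVA fitted downstream.

The brute-force geometry oracles (:func:`brute_force_calliper`,
:func:`brute_force_mec`) are deliberately naive — max over all pairwise
distances, exhaustive search over pair/triple circumcircles — so they can
serve as independent references for the rotating-calipers and Welzl
implementations in :mod:`phenoscreen.image_traits`.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

VIEWS = ("top", "front", "back")

#: Hue (degrees) window that the default segmentation recovers; foreground
#: hues outside it would break the end-to-end contract.
GREEN_HUE_WINDOW = (60.0, 180.0)


class RenderError(ValueError):
    """A plant element does not fit inside the requested canvas."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafSpec:
    """One leaf: physical size plus orientation.

    ``inclination_deg`` is measured from the upward vertical (0 = erect,
    90 = horizontal); ``azimuth_deg`` is the compass direction of the leaf
    in the top view (0 = image up, clockwise).
    """

    length_mm: float
    width_mm: float
    inclination_deg: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("leaf length and width must be positive")
        if not 0.0 <= self.inclination_deg <= 90.0:
            raise ValueError("inclination must lie in [0, 90] degrees")
        if not 0.0 <= self.azimuth_deg < 360.0:
            raise ValueError("azimuth must lie in [0, 360) degrees")


@dataclass
class SyntheticPlantSpec:
    """Parameters of one synthetic plant and its imaging setup."""

    leaves: list[LeafSpec]
    stem_height_mm: float = 150.0
    n_tillers: int = 1
    foreground_hue_deg: float = 120.0
    background_color: tuple[int, int, int] = (245, 245, 245)
    scale_mm_per_px: float = 1.0
    image_size_px: tuple[int, int] = (480, 480)
    noise_sd: float = 0.0
    calib_length_mm: float = 50.0
    #: optional filled disk (radius, mm) at the stem point in the top view,
    #: emulating a dense rosette; used for radially-symmetric fixtures.
    rosette_radius_mm: float | None = None

    def __post_init__(self) -> None:
        self.leaves = [
            leaf if isinstance(leaf, LeafSpec) else LeafSpec(*leaf) for leaf in self.leaves
        ]
        if self.n_tillers < 1:
            raise ValueError("n_tillers must be >= 1")
        if self.stem_height_mm <= 0:
            raise ValueError("stem_height_mm must be positive")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not GREEN_HUE_WINDOW[0] <= self.foreground_hue_deg <= GREEN_HUE_WINDOW[1]:
            raise ValueError(
                "foreground hue must fall inside the default green segmentation "
                f"window {GREEN_HUE_WINDOW}"
            )
        if not self.leaves and self.rosette_radius_mm is None:
            raise ValueError("spec must define at least one leaf or a rosette disk")


@dataclass
class GroundTruth:
    """Exact geometry of the rendered noise-free foreground.

    Hull, calliper and MEC fields are populated for the top view; leaf
    angles for the side views.  All linear quantities are in mm using the
    spec's scale.
    """

    foreground_pixel_count: int
    projected_area_mm2: float
    hull_area_mm2: float | None = None
    calliper_length_mm: float | None = None
    mec_diameter_mm: float | None = None
    eccentricity: float | None = None
    leaf_angles_deg: list[float] = field(default_factory=list)
    #: float (row, col) landmark pairs [lamina_joint, blade_point] per leaf,
    #: side views only; exact, not pixel-rounded.
    leaf_landmarks: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )


# ---------------------------------------------------------------------------
# brute-force geometry oracles
# ---------------------------------------------------------------------------


def hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a 2-D point set, counter-clockwise.

    Collinear or degenerate sets raise :class:`scipy.spatial.QhullError`.
    """
    points = np.asarray(points, dtype=float)
    hull = ConvexHull(points)
    return points[hull.vertices]


def brute_force_calliper(points: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance, by exhaustive search."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def _circumcircles(triples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circumcenters and radii for an (m, 3, 2) stack of triangles.

    Near-collinear triangles are flagged invalid rather than producing
    huge unstable circles.
    """
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    span = np.ptp(triples.reshape(len(triples), -1), axis=1) + 1.0
    valid = np.abs(d) > 1e-12 * span**2
    d = np.where(valid, d, 1.0)
    a2 = (a**2).sum(axis=1)
    b2 = (b**2).sum(axis=1)
    c2 = (c**2).sum(axis=1)
    ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
    uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    centers = np.stack([ux, uy], axis=1)
    radii = np.linalg.norm(centers - a, axis=1)
    return centers, radii, valid


def brute_force_mec(
    points: np.ndarray, max_vertices: int = 200
) -> tuple[np.ndarray, float]:
    """Minimum enclosing circle by exhaustive pair/triple search.

    Considers every circle having two points as a diameter and every
    circumcircle of three hull vertices, keeping the smallest that
    contains all points.  Intended as an oracle; complexity is O(h^3)
    in the hull vertex count h, which must not exceed ``max_vertices``.

    Returns ``(center, radius)`` with center as ``(row, col)``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("cannot enclose an empty point set")
    if len(points) == 1:
        return points[0].copy(), 0.0
    try:
        verts = hull_vertices(points)
    except (QhullError, ValueError):
        verts = np.unique(points, axis=0)
    if len(verts) > max_vertices:
        raise ValueError(
            f"exhaustive MEC limited to {max_vertices} hull vertices, got {len(verts)}"
        )
    scale = float(np.ptp(verts)) + 1.0
    tol = 1e-9 * scale
    best_center, best_radius = None, np.inf

    def consider(centers: np.ndarray, radii: np.ndarray) -> None:
        nonlocal best_center, best_radius
        # containment of all hull vertices implies containment of all points
        dists = np.linalg.norm(verts[None, :, :] - centers[:, None, :], axis=2)
        ok = dists.max(axis=1) <= radii + tol
        if ok.any():
            i = np.argmin(np.where(ok, radii, np.inf))
            if radii[i] < best_radius:
                best_radius = float(radii[i])
                best_center = centers[i].copy()

    n = len(verts)
    ii, jj = np.triu_indices(n, k=1)
    consider((verts[ii] + verts[jj]) / 2.0, np.linalg.norm(verts[ii] - verts[jj], axis=1) / 2.0)

    if n >= 3:
        from itertools import combinations

        combos = np.array(list(combinations(range(n), 3)))
        for start in range(0, len(combos), 20000):
            batch = combos[start : start + 20000]
            centers, radii, valid = _circumcircles(verts[batch])
            consider(centers[valid], radii[valid])

    assert best_center is not None
    return best_center, best_radius


def _moment_eccentricity(points: np.ndarray) -> float:
    """Closed-form moment-ellipse eccentricity of a point cloud."""
    if len(points) < 2:
        return 0.0
    centered = points - points.mean(axis=0)
    mu20 = float((centered[:, 0] ** 2).mean())
    mu02 = float((centered[:, 1] ** 2).mean())
    mu11 = float((centered[:, 0] * centered[:, 1]).mean())
    disc = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    lam1 = (mu20 + mu02 + disc) / 2.0
    lam2 = (mu20 + mu02 - disc) / 2.0
    if lam1 <= 0.0:
        return 0.0
    return math.sqrt(max(0.0, 1.0 - lam2 / lam1))


def ground_truth_from_mask(
    mask: np.ndarray,
    scale_mm_per_px: float,
    leaf_angles_deg: Sequence[float] = (),
    leaf_landmarks: Sequence[tuple[tuple[float, float], tuple[float, float]]] = (),
    top_view: bool = True,
) -> GroundTruth:
    """Brute-force geometric ground truth of a binary foreground mask."""
    count = int(mask.sum())
    gt = GroundTruth(
        foreground_pixel_count=count,
        projected_area_mm2=count * scale_mm_per_px**2,
        leaf_angles_deg=list(leaf_angles_deg),
        leaf_landmarks=list(leaf_landmarks),
    )
    if not top_view or count == 0:
        return gt
    pts = np.argwhere(mask).astype(float)
    try:
        verts = hull_vertices(pts)
        area = ConvexHull(pts).volume  # scipy's own shoelace, independent path
    except (QhullError, ValueError):
        verts, area = pts, 0.0
    gt.hull_area_mm2 = float(area) * scale_mm_per_px**2
    gt.calliper_length_mm = brute_force_calliper(verts) * scale_mm_per_px
    _, radius = brute_force_mec(pts)
    gt.mec_diameter_mm = 2.0 * radius * scale_mm_per_px
    gt.eccentricity = _moment_eccentricity(pts)
    return gt


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _hue_to_rgb(hue_deg: float) -> tuple[int, int, int]:
    """Saturated mid-brightness RGB for a hue, kept inside the default
    segmentation window in saturation/brightness."""
    import colorsys

    r, g, b = colorsys.hsv_to_rgb(hue_deg / 360.0, 0.85, 0.65)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def _leaf_membership(
    rr: np.ndarray,
    cc: np.ndarray,
    origin: tuple[float, float],
    direction: tuple[float, float],
    length_px: float,
    width_px: float,
) -> np.ndarray:
    """Half-open oriented-box membership of pixel centers.

    Along the leaf axis the box covers ``[0, length)``; across it
    ``[-width/2, width/2)``.  With integer origins and axis-aligned
    leaves this gives exactly ``length * width`` pixels.
    """
    dr, dc = direction
    t = (rr - origin[0]) * dr + (cc - origin[1]) * dc
    s = -(rr - origin[0]) * dc + (cc - origin[1]) * dr
    eps = 1e-9
    return (t >= -eps) & (t < length_px - eps) & (s >= -width_px / 2 - eps) & (
        s < width_px / 2 - eps
    )


def _tiller_origins(center: tuple[float, float], n_tillers: int) -> list[tuple[float, float]]:
    if n_tillers == 1:
        return [center]
    origins = []
    for t in range(n_tillers):
        ang = 2.0 * math.pi * t / n_tillers
        origins.append((center[0] - 3.0 * math.cos(ang), center[1] + 3.0 * math.sin(ang)))
    return origins


def _render_mask(spec: SyntheticPlantSpec, view: str) -> tuple[np.ndarray, GroundTruth]:
    rows, cols = spec.image_size_px
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    mask = np.zeros((rows, cols), dtype=bool)
    px = 1.0 / spec.scale_mm_per_px

    def check_bounds(corners: np.ndarray, what: str) -> None:
        if (
            corners[:, 0].min() < 0
            or corners[:, 0].max() > rows - 1
            or corners[:, 1].min() < 0
            or corners[:, 1].max() > cols - 1
        ):
            raise RenderError(f"{what} exceeds the {rows}x{cols} px canvas")

    angles: list[float] = []
    landmarks: list[tuple[tuple[float, float], tuple[float, float]]] = []

    if view == "top":
        center = (float(rows // 2), float(cols // 2))
        origins = _tiller_origins(center, spec.n_tillers)
        if spec.rosette_radius_mm is not None:
            radius_px = spec.rosette_radius_mm * px
            check_bounds(
                np.array(
                    [
                        [center[0] - radius_px, center[1] - radius_px],
                        [center[0] + radius_px, center[1] + radius_px],
                    ]
                ),
                "rosette disk",
            )
            mask |= (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
        for k, leaf in enumerate(spec.leaves):
            origin = origins[k % len(origins)]
            az = math.radians(leaf.azimuth_deg)
            direction = (-math.cos(az), math.sin(az))
            # top view sees the horizontal projection of the inclined blade
            length_px = leaf.length_mm * math.sin(math.radians(leaf.inclination_deg)) * px
            width_px = leaf.width_mm * px
            if length_px < 1.0:
                continue  # an erect leaf projects to (almost) nothing from above
            corners = _box_corners(origin, direction, length_px, width_px)
            check_bounds(corners, f"leaf {k + 1} (azimuth {leaf.azimuth_deg:g} deg)")
            mask |= _leaf_membership(rr, cc, origin, direction, length_px, width_px)
    else:
        stem_px = spec.stem_height_mm * px
        base = (float(rows - 20), float(cols // 2))
        top = (base[0] - stem_px, base[1])
        check_bounds(np.array([base, top]), "stem")
        stem_w = max(2.0, 2.0 * px)
        mask |= _leaf_membership(rr, cc, top, (1.0, 0.0), stem_px + 1.0, stem_w)
        n = len(spec.leaves)
        for k, leaf in enumerate(spec.leaves):
            # first-formed leaf attaches lowest on the stem
            joint_r = base[0] - stem_px * (k + 1) / (n + 1)
            joint = (joint_r, base[1])
            incl = math.radians(leaf.inclination_deg)
            # side views show leaves to the camera's left or right of the stem
            side = 1.0 if leaf.azimuth_deg < 180.0 else -1.0
            if view == "back":
                side = -side
            direction = (-math.cos(incl), side * math.sin(incl))
            length_px = leaf.length_mm * px
            width_px = max(leaf.width_mm * px, 1.0)
            corners = _box_corners(joint, direction, length_px, width_px)
            check_bounds(corners, f"leaf {k + 1} (length {leaf.length_mm:g} mm)")
            mask |= _leaf_membership(rr, cc, joint, direction, length_px, width_px)
            blade = (
                joint[0] + direction[0] * 0.6 * length_px,
                joint[1] + direction[1] * 0.6 * length_px,
            )
            angles.append(leaf.inclination_deg)
            landmarks.append((joint, blade))

    gt = ground_truth_from_mask(
        mask,
        spec.scale_mm_per_px,
        leaf_angles_deg=angles,
        leaf_landmarks=landmarks,
        top_view=(view == "top"),
    )
    return mask, gt


def _box_corners(
    origin: tuple[float, float],
    direction: tuple[float, float],
    length_px: float,
    width_px: float,
) -> np.ndarray:
    dr, dc = direction
    u = np.array([dr, dc])
    v = np.array([-dc, dr])
    o = np.array(origin)
    return np.array(
        [
            o - v * width_px / 2,
            o + v * width_px / 2,
            o + u * length_px - v * width_px / 2,
            o + u * length_px + v * width_px / 2,
        ]
    )


def _calibration_line(spec: SyntheticPlantSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    rows, cols = spec.image_size_px
    length_px = spec.calib_length_mm / spec.scale_mm_per_px
    if length_px > cols - 20:
        raise RenderError("calibration line exceeds the canvas width")
    r = float(rows - 8)
    return (r, 10.0), (r, 10.0 + length_px)


def render_plant(
    spec: SyntheticPlantSpec, view: str, seed: int = 0
) -> tuple[np.ndarray, GroundTruth, dict]:
    """Render one plant view.

    Returns ``(image, ground_truth, metadata)`` where ``image`` is an
    (rows, cols, 3) uint8 array, ``ground_truth`` describes the
    noise-free foreground exactly, and ``metadata`` is the JSON-ready
    sidecar (view, scale, calibration line endpoints and physical
    length, leaf landmarks).  Identical ``(spec, view, seed)`` produce
    byte-identical images.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    mask, gt = _render_mask(spec, view)
    rows, cols = spec.image_size_px
    img = np.empty((rows, cols, 3), dtype=float)
    img[:] = np.asarray(spec.background_color, dtype=float)
    img[mask] = np.asarray(_hue_to_rgb(spec.foreground_hue_deg), dtype=float)

    (r0, c0), (r1, c1) = _calibration_line(spec)
    row_i = int(round(r0))
    img[row_i, int(math.ceil(c0)) : int(math.floor(c1)) + 1] = (255.0, 0.0, 0.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    metadata = {
        "view": view,
        "scale_mm_per_px": spec.scale_mm_per_px,
        "calib_line": [[r0, c0], [r1, c1]],
        "calib_mm": spec.calib_length_mm,
        "leaf_landmarks": [
            [[float(a) for a in p], [float(b) for b in q]] for p, q in gt.leaf_landmarks
        ],
    }
    return img, gt, metadata


def write_plant_image(path, img: np.ndarray, metadata: dict) -> None:
    """Write a rendered view as PNG plus its JSON sidecar (same stem)."""
    from pathlib import Path

    path = Path(path)
    buf = io.BytesIO()
    Image.fromarray(img).save(buf, format="PNG")
    path.write_bytes(buf.getvalue())
    path.with_suffix(".json").write_text(json.dumps(metadata, indent=1))


# ---------------------------------------------------------------------------
# trait-table simulation
# ---------------------------------------------------------------------------

TREATMENTS = ("control", "deficient")


@dataclass
class SimModel:
    """Generative two-way model for a balanced genotype x treatment table.

    ``conc_effect`` is the additive shift applied to the deficient arm;
    genotype effects are N(0, sigma2_g), genotype-by-concentration
    interactions N(0, sigma2_gc) and residuals N(0, sigma2_e).
    """

    n_genotypes: int
    n_reps: int
    mu: float = 10.0
    sigma2_g: float = 1.0
    sigma2_gc: float = 0.0
    conc_effect: float = -2.0
    sigma2_e: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_gc, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (heritability needs replication)")
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")


def simulate_trait_table(model: SimModel, traits: Sequence[str] = ("trait",)):
    """Draw a balanced trait table plus the realized effects.

    Returns ``(table, truth)``: a tidy DataFrame with columns
    ``genotype, treatment, rep, <trait...>`` (n_genotypes x 2 treatments
    x n_reps rows) and a dict mapping each trait name to its realized
    ``genotype_effects`` (Series) and ``interaction_effects`` (DataFrame
    genotype x treatment).
    """
    import pandas as pd

    rng = np.random.default_rng(model.seed)
    genos = [f"G{i + 1:03d}" for i in range(model.n_genotypes)]
    idx = pd.MultiIndex.from_product(
        [genos, TREATMENTS, range(1, model.n_reps + 1)],
        names=["genotype", "treatment", "rep"],
    )
    table = pd.DataFrame(index=idx).reset_index()
    truth: dict[str, dict] = {}
    g_idx = table["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    t_idx = (table["treatment"] == "deficient").to_numpy().astype(int)
    for trait in traits:
        g_eff = rng.normal(0.0, math.sqrt(model.sigma2_g), size=model.n_genotypes)
        gc_eff = rng.normal(0.0, math.sqrt(model.sigma2_gc), size=(model.n_genotypes, 2))
        errors = rng.normal(0.0, math.sqrt(model.sigma2_e), size=len(table))
        values = (
            model.mu
            + g_eff[g_idx]
            + model.conc_effect * t_idx
            + gc_eff[g_idx, t_idx]
            + errors
        )
        table[trait] = values
        truth[trait] = {
            "genotype_effects": pd.Series(g_eff, index=genos, name=trait),
            "interaction_effects": pd.DataFrame(
                gc_eff, index=genos, columns=list(TREATMENTS)
            ),
        }
    return table, truth


def default_demo_spec(seed: int = 0) -> SyntheticPlantSpec:
    """A representative multi-leaf shoot used by the demo pipeline."""
    rng = np.random.default_rng(seed)
    leaves = []
    for k in range(5):
        leaves.append(
            LeafSpec(
                length_mm=float(rng.uniform(60, 140)),
                width_mm=float(rng.uniform(6, 14)),
                inclination_deg=float(rng.uniform(25, 80)),
                azimuth_deg=float(k * 72.0 + rng.uniform(-20, 20)) % 360.0,
            )
        )
    return SyntheticPlantSpec(leaves=leaves, n_tillers=2, image_size_px=(420, 420))
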