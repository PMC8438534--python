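"""Plant segmentation and top-view geometric traits from RGB images.

The measurement chain mirrors the common ImageJ workflow for shoot
phenotyping: threshold the plant in HSB colour space, convert pixels to
millimetres with a calibration line of known physical length, then
summarise the top-view silhouette by projected area, convex hull
area/perimeter, calliper length (maximum Feret diameter, by rotating
calipers), minimum enclosing circle (Welzl's algorithm) and
moment-ellipse eccentricity.  Whole plant area (WPA) is the sum of the
projected areas of the top and the two side views.

Geometric conventions (documented because they decide exact values):

* coordinates are (row, col), origin top-left, 0-based; "vertical" for
  leaf angles is the decreasing-row direction;
* all geometry operates on foreground *pixel centers* — a single pixel
  has zero hull area but a projected area of one pixel.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.color import rgb2hsv


class NoPlantDetectedError(ValueError):
    """Segmentation found no foreground pixel; carries the thresholds used."""

    def __init__(self, thresholds: "HSBThresholds"):
        self.thresholds = thresholds
        super().__init__(f"no plant detected with thresholds {thresholds}")


class EmptyMaskError(ValueError):
    pass


@dataclass(frozen=True)
class HSBThresholds:
    """Inclusive HSB windows defining "plant" pixels.

    Hue is in degrees; a window with lo > hi wraps around 360.  Defaults
    capture green foliage on light backgrounds.
    """

    hue_deg: tuple[float, float] = (60.0, 180.0)
    saturation: tuple[float, float] = (0.25, 1.0)
    brightness: tuple[float, float] = (0.20, 1.0)


DEFAULT_THRESHOLDS = HSBThresholds()


@dataclass(frozen=True)
class ScaleCalibration:
    mm_per_px: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValueError("mm_per_px must be finite and positive")


@dataclass
class GeometricTraits:
    """Top-view geometry of one plant, in physical units."""

    projected_area_mm2: float
    hull_area_mm2: float
    hull_perimeter_mm: float
    calliper_length_mm: float
    mec_center_px: tuple[float, float]
    mec_diameter_mm: float
    eccentricity: float
    view: str = "top"

    def as_row(self) -> dict:
        return {
            "view": self.view,
            "projected_area_mm2": self.projected_area_mm2,
            "hull_area_mm2": self.hull_area_mm2,
            "hull_perimeter_mm": self.hull_perimeter_mm,
            "calliper_length_mm": self.calliper_length_mm,
            "mec_diameter_mm": self.mec_diameter_mm,
            "eccentricity": self.eccentricity,
        }


# ---------------------------------------------------------------------------
# segmentation and calibration
# ---------------------------------------------------------------------------


def segment_plant(
    image: np.ndarray,
    thresholds: HSBThresholds = DEFAULT_THRESHOLDS,
    keep_largest_component: bool = True,
) -> np.ndarray:
    """Binary foreground mask of the plant.

    A pixel is foreground iff its hue, saturation and brightness all lie
    in the configured windows.  With ``keep_largest_component`` (on by
    default) only the largest 8-connected blob is kept, suppressing
    colour speckle.

    Raises :class:`NoPlantDetectedError` when nothing passes the windows.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    lo, hi = thresholds.hue_deg
    if lo <= hi:
        mask = (hue >= lo) & (hue <= hi)
    else:  # wrap-around window, e.g. reds
        mask = (hue >= lo) | (hue <= hi)
    mask &= (hsv[..., 1] >= thresholds.saturation[0]) & (
        hsv[..., 1] <= thresholds.saturation[1]
    )
    mask &= (hsv[..., 2] >= thresholds.brightness[0]) & (
        hsv[..., 2] <= thresholds.brightness[1]
    )
    if not mask.any():
        raise NoPlantDetectedError(thresholds)
    if keep_largest_component:
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return mask


def calibrate(
    line_endpoints: tuple[tuple[float, float], tuple[float, float]],
    known_length_mm: float,
) -> ScaleCalibration:
    """mm-per-pixel scale from a drawn line of known physical length."""
    (r0, c0), (r1, c1) = line_endpoints
    dist = math.hypot(r1 - r0, c1 - c0)
    if dist == 0:
        raise ValueError("calibration endpoints must be distinct")
    if known_length_mm <= 0:
        raise ValueError("known_length_mm must be positive")
    return ScaleCalibration(mm_per_px=known_length_mm / dist)


def projected_area(mask: np.ndarray, cal: ScaleCalibration) -> float:
    """Foreground pixel count converted to mm^2."""
    count = int(np.asarray(mask, dtype=bool).sum())
    if count == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return count * cal.mm_per_px**2


def whole_plant_area(top: float, front: float, back: float) -> float:
    """WPA: summed projected area of the top and two side views (mm^2)."""
    areas = (top, front, back)
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    return float(sum(areas))


# ---------------------------------------------------------------------------
# convex-hull geometry
# ---------------------------------------------------------------------------


def _shoelace_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _perimeter(verts: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1).sum())


def rotating_calipers_calliper(verts: np.ndarray) -> float:
    """Maximum Feret diameter of a convex polygon via antipodal pairs.

    ``verts`` must be the hull vertices in (counter)clockwise order.
    Runs in O(h) after the hull; equals the brute-force maximum pairwise
    distance.
    """
    verts = np.asarray(verts, dtype=float)
    h = len(verts)
    if h < 2:
        return 0.0
    if h == 2:
        return float(np.linalg.norm(verts[1] - verts[0]))

    def cross_mag(o, a, b) -> float:
        return abs((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))

    best = 0.0
    j = 1
    for i in range(h):
        ni = (i + 1) % h
        while cross_mag(verts[i], verts[ni], verts[(j + 1) % h]) > cross_mag(
            verts[i], verts[ni], verts[j]
        ):
            j = (j + 1) % h
        best = max(
            best,
            float(np.linalg.norm(verts[j] - verts[i])),
            float(np.linalg.norm(verts[j] - verts[ni])),
        )
    return best


def _circle_two(p, q):
    center = ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)
    return center, math.dist(p, q) / 2.0


def _circle_three(a, b, c):
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14 * (1.0 + abs(a[0]) + abs(b[0]) + abs(c[0])) ** 2:
        return None
    a2, b2, c2 = a[0] ** 2 + a[1] ** 2, b[0] ** 2 + b[1] ** 2, c[0] ** 2 + c[1] ** 2
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    center = (ux, uy)
    return center, math.dist(center, a)


def _in_circle(p, circle, tol) -> bool:
    center, r = circle
    return math.dist(p, center) <= r + tol


def welzl_mec(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Minimum enclosing circle by Welzl's randomized incremental algorithm.

    Expected O(n) over the input point order; the order is shuffled with
    a fixed seed so results are deterministic.  Returns
    ``((row, col), radius)`` in pixel units.
    """
    pts = [tuple(map(float, p)) for p in np.asarray(points, dtype=float)]
    if not pts:
        raise EmptyMaskError("cannot enclose an empty point set")
    span = max(
        max(p[0] for p in pts) - min(p[0] for p in pts),
        max(p[1] for p in pts) - min(p[1] for p in pts),
    )
    tol = 1e-10 * (span + 1.0)
    random.Random(0x5EED).shuffle(pts)

    def circle_with(boundary):
        if len(boundary) == 0:
            return (pts[0], 0.0) if len(pts) == 1 else None
        if len(boundary) == 1:
            return boundary[0], 0.0
        if len(boundary) == 2:
            return _circle_two(*boundary)
        circ = _circle_three(*boundary)
        if circ is None:  # collinear support: largest two-point circle
            best = None
            for i in range(3):
                for j in range(i + 1, 3):
                    c = _circle_two(boundary[i], boundary[j])
                    if all(_in_circle(p, c, tol) for p in boundary):
                        if best is None or c[1] < best[1]:
                            best = c
            return best
        return circ

    # iterative move-to-front formulation of Welzl's recursion
    circle = None
    for i, p in enumerate(pts):
        if circle is not None and _in_circle(p, circle, tol):
            continue
        circle = (p, 0.0)
        for j in range(i):
            q = pts[j]
            if _in_circle(q, circle, tol):
                continue
            circle = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if _in_circle(s, circle, tol):
                    continue
                circle = circle_with([p, q, s])
    if circle is None:
        circle = (pts[0], 0.0)
    return circle


def moment_eccentricity(points: np.ndarray) -> float:
    """Eccentricity sqrt(1 - l2/l1) of the second-central-moment ellipse.

    0 for a radially symmetric cloud, approaching 1 for an elongated
    one; degenerate single-pixel input gives 0, exactly collinear input
    gives 1.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    lam2, lam1 = np.linalg.eigvalsh(cov)
    if lam1 <= 0:
        return 0.0
    return float(math.sqrt(max(0.0, 1.0 - lam2 / lam1)))


def top_view_geometry(
    mask: np.ndarray, cal: ScaleCalibration, view: str = "top"
) -> GeometricTraits:
    """All top-view geometric traits of a segmented plant.

    Hull area by the shoelace formula over the convex hull of foreground
    pixel centers, perimeter by hull edge sum, calliper by rotating
    calipers, MEC by Welzl's algorithm on hull vertices, eccentricity
    from second central moments of the full foreground.  Collinear-only
    foregrounds get zero hull area (with a warning); other fields stay
    defined.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    s = cal.mm_per_px
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
        hull_area = _shoelace_area(verts)
        hull_perim = _perimeter(verts)
    except (QhullError, ValueError):
        warnings.warn("foreground is collinear; hull area set to 0", stacklevel=2)
        # degenerate hull: keep only the two extreme points of the segment
        u = np.unique(pts, axis=0)
        d = np.linalg.norm(u[:, None] - u[None, :], axis=2)
        i, j = np.unravel_index(d.argmax(), d.shape)
        verts = u[[i, j]] if len(u) > 1 else u
        hull_area = 0.0
        hull_perim = 2.0 * float(d.max())
    calliper = (
        rotating_calipers_calliper(verts)
        if len(verts) > 2
        else (float(np.linalg.norm(verts[1] - verts[0])) if len(verts) == 2 else 0.0)
    )
    center, radius = welzl_mec(verts)
    return GeometricTraits(
        projected_area_mm2=len(pts) * s**2,
        hull_area_mm2=hull_area * s**2,
        hull_perimeter_mm=hull_perim * s,
        calliper_length_mm=calliper * s,
        mec_center_px=(float(center[0]), float(center[1])),
        mec_diameter_mm=2.0 * radius * s,
        eccentricity=moment_eccentricity(pts),
        view=view,
    )


def leaf_angle(
    stem_axis_point: tuple[float, float],
    lamina_joint: tuple[float, float],
    blade_point: tuple[float, float],
) -> float:
    """Leaf inclination: angle (degrees, in [0, 180]) between the upward
    image vertical and the lamina-joint -> blade vector.

    ``stem_axis_point`` anchors the vertical reference (the stem is the
    vertical axis); the angle itself depends only on joint and blade.
    """
    del stem_axis_point
    dr = blade_point[0] - lamina_joint[0]
    dc = blade_point[1] - lamina_joint[1]
    norm = math.hypot(dr, dc)
    if norm == 0:
        raise ValueError("blade point and lamina joint must be distinct")
    # upward vertical is (-1, 0) in (row, col) coordinates
    cosang = max(-1.0, min(1.0, -dr / norm))
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# batch extraction
# ---------------------------------------------------------------------------


def extract_image(
    image: np.ndarray,
    cal: ScaleCalibration,
    thresholds: HSBThresholds = DEFAULT_THRESHOLDS,
    view: str = "top",
) -> GeometricTraits:
    """Segment one image and measure its geometry at the given scale."""
    mask = segment_plant(image, thresholds)
    return top_view_geometry(mask, cal, view=view)


def extract_directory(images_dir, thresholds: HSBThresholds = DEFAULT_THRESHOLDS):
    """Measure every PNG/TIFF in a directory; one row per image.

    Each image must have a JSON sidecar (same stem) carrying
    ``scale_mm_per_px`` or a calibration line + physical length, as
    written by :func:`phenoscreen.synthetic_data.write_plant_image`.
    Returns a DataFrame with columns image_id, view and the geometric
    traits.
    """
    import json
    from pathlib import Path

    import pandas as pd
    from PIL import Image as PILImage

    rows = []
    images_dir = Path(images_dir)
    paths = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images found in {images_dir}")
    for path in paths:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing calibration sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        if "calib_line" in meta and "calib_mm" in meta:
            cal = calibrate(
                (tuple(meta["calib_line"][0]), tuple(meta["calib_line"][1])),
                meta["calib_mm"],
            )
        else:
            cal = ScaleCalibration(mm_per_px=float(meta["scale_mm_per_px"]))
        img = np.asarray(PILImage.open(path).convert("RGB"))
        traits = extract_image(img, cal, thresholds, view=meta.get("view", "top"))
        rows.append({"image_id": path.stem, **traits.as_row()})
    return pd.DataFrame(rows)
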