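"""Synthetic aortic anatomy and the centerline-based measurement apparatus.

The aorta is modeled as a tube lofted along a planar "candy-cane" centerline:
a straight ascending limb, a circular apex arc, and a straight descending
limb, with circular cross-sections whose diameter interpolates the four
clinical measurement levels (annulus, sinus of Valsalva, sino-tubular
junction, mid-ascending aorta).  The arch angle -- defined by the tangent at
the highest centerline point and the two intersections of the centerline
with that tangent displaced inward by one diameter -- is controlled by the
slope of the two limbs, which is solved numerically so the measured angle
matches the requested one.

All geometry is in cm internally; diameters cross the measurement interface
in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq, minimize_scalar
from scipy.spatial import cKDTree

__all__ = [
    "Centerline",
    "AortaSurface",
    "SlicePlane",
    "WallRegion",
    "PhenotypeParams",
    "GROUP_MEDIAN_PARAMS",
    "build_synthetic_aorta",
    "extract_planes",
    "define_wall_regions",
    "measure_arch_angle",
    "measure_levels",
    "straight_tube",
    "loft_surface",
]

MM_PER_CM = 10.0

PLANE_LABELS = ("plane0", "plane1", "plane2", "plane3", "plane4")
REGION_LABELS = ("root", "proximal_AA", "distal_AA", "arch", "descending")

# apex rounding-arc radius as a fraction of the apex lumen diameter; must be
# above 0.5 so the inner wall of the bend does not fold on itself
_APEX_ARC_RATIO = 0.62
# branch ostia sit this far (cm) off the ends of the apex arc
_OSTIUM_OFFSET = 0.5
# "just before/after" an ostium, as a fraction of the local diameter
_JUST_FRACTION = 0.05


@dataclass
class Centerline:
    """Ordered lumen centerline with arclength, tangents and local diameter.

    points : (n, 3) float array, cm
    arclength : (n,) cumulative distance, cm, strictly increasing
    tangent : (n, 3) unit vectors
    local_diameter : (n,) cm, positive
    """

    points: np.ndarray
    arclength: np.ndarray
    tangent: np.ndarray
    local_diameter: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        self.local_diameter = np.asarray(self.local_diameter, dtype=float)
        n = len(self.points)
        if n < 50:
            raise ValueError("centerline needs at least 50 points")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")
        if not np.allclose(np.linalg.norm(self.tangent, axis=1), 1.0, atol=1e-6):
            raise ValueError("tangents must be unit-norm")
        if np.any(self.local_diameter <= 0):
            raise ValueError("local_diameter must be positive everywhere")

    @classmethod
    def from_points(cls, points: np.ndarray, local_diameter) -> "Centerline":
        """Build a centerline from ordered points, deriving arclength/tangents."""
        points = np.asarray(points, dtype=float)
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        tan = np.gradient(points, s, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        d = np.broadcast_to(np.asarray(local_diameter, dtype=float), (len(points),)).copy()
        return cls(points, s, tan, d)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def diameter_at(self, s) -> np.ndarray:
        return np.interp(s, self.arclength, self.local_diameter)

    def point_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.stack([np.interp(s, self.arclength, self.points[:, k]) for k in range(3)], axis=-1)
        return out[0] if out.shape[0] == 1 else out

    def tangent_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.stack([np.interp(s, self.arclength, self.tangent[:, k]) for k in range(3)], axis=-1)
        out /= np.linalg.norm(out, axis=-1, keepdims=True)
        return out[0] if out.shape[0] == 1 else out


@dataclass
class AortaSurface:
    """Triangulated lumen wall, open at the inlet/outlet caps.

    landmarks maps names ('annulus', 'sinus', 'stj', 'mid_ascending',
    'brachiocephalic', 'left_carotid', 'left_subclavian') to centerline
    arclength positions in cm.  Branch ostia are landmark points only; the
    surface carries no branch tubes.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    landmarks: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def outward_normals(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)


@dataclass
class SlicePlane:
    """Cross-sectional analysis plane, perpendicular to the centerline."""

    label: str
    origin: np.ndarray
    normal: np.ndarray
    diameter: float
    arclength: float

    def __post_init__(self) -> None:
        if self.label not in PLANE_LABELS:
            raise ValueError(f"unknown plane label {self.label!r}")
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("plane normal must be unit-norm")

    def in_plane_axes(self) -> Tuple[np.ndarray, np.ndarray]:
        """Two orthonormal vectors spanning the plane."""
        n = self.normal
        a = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(a, n)) > 0.9:
            a = np.array([1.0, 0.0, 0.0])
        e1 = a - np.dot(a, n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass
class WallRegion:
    """Named subset of wall triangles used for regional WSS averaging."""

    label: str
    triangle_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        self.triangle_ids = np.asarray(self.triangle_ids, dtype=int)
        if self.triangle_ids.size == 0:
            raise ValueError(f"wall region {self.label!r} is empty")


@dataclass
class PhenotypeParams:
    """Per-subject geometric phenotype.

    Diameters are in mm (clinical convention); arch angle in degrees;
    recirculation_strength is the dimensionless peak reverse-flow fraction
    used by the flow-field generator (0 for normal anatomy).
    """

    group: str
    arch_angle_deg: float
    annulus_d: float
    sinus_d: float
    stj_d: float
    midAA_d: float
    recirculation_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("A_severe", "B_mild", "C_normal"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 < self.arch_angle_deg < 180.0:
            raise ValueError("arch angle must lie in (0, 180) degrees")
        for name in ("annulus_d", "sinus_d", "stj_d", "midAA_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recirculation_strength < 0:
            raise ValueError("recirculation_strength must be >= 0")
        if self.group == "C_normal" and self.recirculation_strength != 0:
            raise ValueError("normal phenotype cannot carry a recirculation zone")


# Cohort median phenotypes: level diameters and arch angles are the printed
# group medians (annulus / sinus / STJ / mid-ascending, mm; angle, degrees).
GROUP_MEDIAN_PARAMS: Dict[str, PhenotypeParams] = {
    "A_severe": PhenotypeParams("A_severe", 72.3, 29.6, 38.7, 29.8, 25.0, 0.6),
    "B_mild": PhenotypeParams("B_mild", 76.6, 24.5, 28.4, 23.3, 23.9, 0.15),
    "C_normal": PhenotypeParams("C_normal", 97.3, 22.1, 30.2, 26.0, 24.2, 0.0),
}


# ---------------------------------------------------------------------------
# centerline construction


def _measured_half_width(alpha: float, arc_radius: float, depth: float) -> float:
    """Horizontal half-distance from the apex to the centerline at `depth`
    below it, for limbs inclined `alpha` rad from vertical joined by an apex
    arc of `arc_radius`."""
    phi0 = np.pi / 2 - alpha
    h_arc = arc_radius * (1.0 - np.cos(phi0))
    if depth <= h_arc:  # intersection on the apex arc itself
        return float(np.sqrt(max(2 * arc_radius * depth - depth**2, 0.0)))
    return float(arc_radius * np.sin(phi0) + (depth - h_arc) * np.tan(alpha))


def _solve_limb_angle(target_deg: float, arc_radius: float, depth: float) -> float:
    """Limb inclination (rad from vertical) whose tangent-offset arch angle
    equals target_deg."""

    def f(alpha: float) -> float:
        x = _measured_half_width(alpha, arc_radius, depth)
        return 2.0 * np.degrees(np.arctan2(x, depth)) - target_deg

    lo, hi = 1e-4, np.radians(80.0)
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"arch angle {target_deg:.1f} deg is not reachable with apex arc "
            f"radius {arc_radius:.2f} cm and offset {depth:.2f} cm"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def _arch_centerline_points(
    arch_angle_deg: float,
    apex_diameter: float,
    limb_length: float,
    n_points: int,
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Planar (x-z) centerline: ascending limb, apex arc, descending limb.

    Returns the sampled points and the arclengths of the geometric stations
    (arc start/end, apex) needed to place landmarks.
    """
    arc_radius = _APEX_ARC_RATIO * apex_diameter
    alpha = _solve_limb_angle(arch_angle_deg, arc_radius, apex_diameter)
    phi0 = np.pi / 2 - alpha

    arc_len = 2.0 * arc_radius * phi0
    total = 2.0 * limb_length + arc_len
    s = np.linspace(0.0, total, n_points)

    s_arc0 = limb_length
    s_arc1 = limb_length + arc_len
    z_apex = limb_length * np.cos(alpha) + arc_radius * (1 - np.cos(phi0))

    # ascending limb runs up-right toward the arc start on the -x side
    u_asc = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
    u_desc = np.array([np.sin(alpha), 0.0, -np.cos(alpha)])
    arc_center = np.array([0.0, 0.0, z_apex - arc_radius])
    p_arc0 = arc_center + arc_radius * np.array([-np.sin(phi0), 0.0, np.cos(phi0)])
    p_start = p_arc0 - limb_length * u_asc

    pts = np.empty((n_points, 3))
    for i, si in enumerate(s):
        if si <= s_arc0:
            pts[i] = p_start + si * u_asc
        elif si <= s_arc1:
            phi = -phi0 + (si - s_arc0) / arc_radius
            pts[i] = arc_center + arc_radius * np.array([np.sin(phi), 0.0, np.cos(phi)])
        else:
            phi_end = phi0
            p_arc1 = arc_center + arc_radius * np.array(
                [np.sin(phi_end), 0.0, np.cos(phi_end)]
            )
            pts[i] = p_arc1 + (si - s_arc1) * u_desc
    stations = {
        "arc_start": s_arc0,
        "apex": 0.5 * (s_arc0 + s_arc1),
        "arc_end": s_arc1,
        "total": total,
    }
    return pts, stations


def _diameter_profile(
    total_length: float,
    s_levels: Dict[str, float],
    d_levels_cm: Dict[str, float],
) -> PchipInterpolator:
    """Shape-preserving diameter-vs-arclength profile through the four
    measurement levels, constant beyond the mid-ascending aorta."""
    s_ctrl = [
        0.0,
        s_levels["annulus"],
        s_levels["sinus"],
        s_levels["stj"],
        s_levels["mid_ascending"],
        total_length,
    ]
    d_ctrl = [
        d_levels_cm["annulus"],
        d_levels_cm["annulus"],
        d_levels_cm["sinus"],
        d_levels_cm["stj"],
        d_levels_cm["mid_ascending"],
        d_levels_cm["mid_ascending"],
    ]
    return PchipInterpolator(s_ctrl, d_ctrl)


def loft_surface(
    cl: Centerline,
    n_theta: int = 48,
    jitter: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Loft a circular-section tube along a (planar) centerline.

    Returns (vertices, triangles) with consistent outward orientation and
    open inlet/outlet ends.  `jitter` adds a seeded fractional radial
    perturbation to every vertex (surface-roughness realism).
    """
    rng = np.random.default_rng(seed)
    n = len(cl.points)
    e_y = np.array([0.0, 1.0, 0.0])
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts = np.empty((n * n_theta, 3))
    for i in range(n):
        t = cl.tangent[i]
        e1 = np.cross(e_y, t)
        nrm = np.linalg.norm(e1)
        if nrm < 1e-9:
            raise ValueError("centerline tangent parallel to loft frame axis")
        e1 /= nrm
        e2 = np.cross(t, e1)
        r = 0.5 * cl.local_diameter[i]
        if jitter > 0:
            r = r * (1.0 + jitter * rng.standard_normal(n_theta))
        ring = (
            cl.points[i]
            + np.outer(np.atleast_1d(r) * np.cos(theta), e1)
            + np.outer(np.atleast_1d(r) * np.sin(theta), e2)
        )
        verts[i * n_theta : (i + 1) * n_theta] = ring

    faces: List[Tuple[int, int, int]] = []
    for i in range(n - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    tris = np.asarray(faces, dtype=int)

    # orient outward: flip if normals point toward the local centerline
    v = verts[tris]
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    centroids = v.mean(axis=1)
    ring_idx = np.minimum(tris[:, 0] // n_theta, n - 1)
    outward = centroids - cl.points[ring_idx]
    if np.median(np.einsum("ij,ij->i", normals, outward)) < 0:
        tris = tris[:, [0, 2, 1]]
    return verts, tris


def build_synthetic_aorta(
    params: PhenotypeParams,
    seed: int = 0,
    n_points: int = 400,
    n_theta: int = 48,
    limb_length: float = 8.0,
    jitter: float = 5e-4,
) -> Tuple[Centerline, AortaSurface]:
    """Construct a phenotype-specific synthetic aorta.

    The measured arch angle (tangent-offset construction with the local
    apex diameter as offset) matches ``params.arch_angle_deg``; the lumen
    cross-section interpolates the four level diameters with a smooth sinus
    bulge.  Deterministic for a fixed seed.
    """
    d_mm = {
        "annulus": params.annulus_d,
        "sinus": params.sinus_d,
        "stj": params.stj_d,
        "mid_ascending": params.midAA_d,
    }
    d_cm = {k: v / MM_PER_CM for k, v in d_mm.items()}
    apex_d = d_cm["mid_ascending"]

    pts, st = _arch_centerline_points(
        params.arch_angle_deg, apex_d, limb_length, n_points
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])

    s_ann = 0.6
    s_levels = {
        "annulus": s_ann,
        "sinus": s_ann + 1.0,
        "stj": s_ann + 2.0,
        "mid_ascending": 0.5 * (s_ann + 2.0 + st["arc_start"]),
    }
    profile = _diameter_profile(total, s_levels, d_cm)
    local_d = profile(s)

    tan = np.gradient(pts, s, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    cl = Centerline(pts, s, tan, local_d)

    verts, tris = loft_surface(cl, n_theta=n_theta, jitter=jitter, seed=seed)
    landmarks = dict(s_levels)
    landmarks["brachiocephalic"] = st["arc_start"] - _OSTIUM_OFFSET
    landmarks["left_carotid"] = st["apex"]
    landmarks["left_subclavian"] = st["arc_end"] + _OSTIUM_OFFSET
    surf = AortaSurface(verts, tris, landmarks)
    return cl, surf


def straight_tube(
    length: float,
    diameter: float,
    n_points: int = 200,
    n_theta: int = 64,
    landmarks: Optional[Dict[str, float]] = None,
) -> Tuple[Centerline, AortaSurface]:
    """Straight constant- (or varying-) diameter tube along +z; the basic
    oracle geometry for Poiseuille-flow checks."""
    z = np.linspace(0.0, length, n_points)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    cl = Centerline.from_points(pts, diameter)
    verts, tris = loft_surface(cl, n_theta=n_theta)
    return cl, AortaSurface(verts, tris, landmarks or {})


# ---------------------------------------------------------------------------
# measurements


def measure_arch_angle(cl: Centerline, offset_diameter: float) -> float:
    """Arch angle (degrees) by the tangent-offset construction.

    A is the highest centerline point (height = in-plane projection of the
    global vertical); the tangent at A is displaced by `offset_diameter`
    toward the centerline centroid, and B, C are the first intersections of
    the centerline with the displaced line on either side of A.  Returns the
    angle BAC.
    """
    if offset_diameter <= 0:
        raise ValueError("offset_diameter must be positive")
    pts = cl.points
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # best-fit plane: normal = least-variance principal direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    plane_normal = vt[2]
    z = np.array([0.0, 0.0, 1.0])
    up = z - np.dot(z, plane_normal) * plane_normal
    if np.linalg.norm(up) < 1e-6:
        raise ValueError("centerline plane is horizontal; no height axis")
    up /= np.linalg.norm(up)

    h = pts @ up
    i_max = int(np.argmax(h))
    if i_max in (0, len(h) - 1):
        raise ValueError("height maximum at centerline endpoint; no arch apex")
    # ambiguity: another near-equal local maximum away from the apex
    scale = h.max() - h.min()
    near = np.where(h > h[i_max] - 1e-6 * max(scale, 1.0))[0]
    if near.max() - near.min() > max(5, len(h) // 50):
        raise ValueError("ambiguous height maximum on centerline")

    spline = CubicSpline(cl.arclength, pts, axis=0)
    s_lo = cl.arclength[max(i_max - 2, 0)]
    s_hi = cl.arclength[min(i_max + 2, len(h) - 1)]
    res = minimize_scalar(
        lambda t: -float(spline(t) @ up), bounds=(s_lo, s_hi), method="bounded",
        options={"xatol": 1e-10},
    )
    s_apex = float(res.x)
    A = np.asarray(spline(s_apex))
    tang = np.asarray(spline(s_apex, 1))
    tang /= np.linalg.norm(tang)

    down = np.cross(plane_normal, tang)
    if np.dot(down, centroid - A) < 0:
        down = -down
    down /= np.linalg.norm(down)

    def depth(t: float) -> float:
        return float((np.asarray(spline(t)) - A) @ down) - offset_diameter

    def first_crossing(direction: int) -> np.ndarray:
        s_grid = cl.arclength
        i0 = np.searchsorted(s_grid, s_apex)
        rng = range(i0, len(s_grid)) if direction > 0 else range(i0 - 1, -1, -1)
        prev_s = s_apex
        prev_f = depth(prev_s)
        for i in rng:
            si = s_grid[i]
            fi = depth(si)
            if prev_f < 0 <= fi:
                s_cross = brentq(depth, min(prev_s, si), max(prev_s, si), xtol=1e-10)
                return np.asarray(spline(s_cross))
            prev_s, prev_f = si, fi
        raise ValueError(
            "displaced tangent line does not intersect the centerline on "
            f"the {'distal' if direction > 0 else 'proximal'} side"
        )

    B = first_crossing(-1)
    C = first_crossing(+1)
    v1 = B - A
    v2 = C - A
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _section_polygon(
    surf: AortaSurface, cl: Centerline, s: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed cross-section contour at arclength s, as 2-D coordinates in
    the slice plane (plus the plane basis)."""
    origin = cl.point_at(s)
    normal = cl.tangent_at(s)
    mesh = surf.as_trimesh()
    section = mesh.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        raise ValueError(f"no cross-section found at arclength {s:.2f} cm")
    planar, to_3d = section.to_2D()
    # choose the closed loop nearest the slice origin
    best = None
    best_dist = np.inf
    for poly in planar.polygons_closed:
        if poly is None:
            continue
        c2 = np.array(poly.centroid.coords[0])
        c3 = trimesh.transform_points(np.array([[c2[0], c2[1], 0.0]]), to_3d)[0]
        dist = np.linalg.norm(c3 - origin)
        if dist < best_dist:
            best_dist = dist
            best = poly
    if best is None:
        raise ValueError(f"cross-section contour at s={s:.2f} cm is not closed")
    xy = np.array(best.exterior.coords)
    return xy, origin, normal


def measure_levels(surf: AortaSurface, cl: Centerline) -> Dict[str, float]:
    """Lumen diameters (mm) at the four measurement levels.

    Annulus, sinus and STJ use the equivalent-circle diameter 2*sqrt(A/pi)
    of the cross-section; the mid-ascending level uses the mean of the
    minimum and maximum caliper diameters of the section.
    """
    from shapely.geometry import Polygon

    required = ("annulus", "sinus", "stj", "mid_ascending")
    for name in required:
        if name not in surf.landmarks:
            raise ValueError(f"missing landmark {name!r}")
    out: Dict[str, float] = {}
    for name in required:
        xy, _, _ = _section_polygon(surf, cl, surf.landmarks[name])
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"invalid cross-section contour at level {name!r}")
        if name == "mid_ascending":
            hull = poly.convex_hull
            hx = np.array(hull.exterior.coords)
            d2 = ((hx[:, None, :] - hx[None, :, :]) ** 2).sum(-1)
            d_max = float(np.sqrt(d2.max()))
            rect = hull.minimum_rotated_rectangle
            rx = np.array(rect.exterior.coords)
            sides = np.linalg.norm(np.diff(rx, axis=0), axis=1)
            d_min = float(sides.min())
            out[name] = 0.5 * (d_min + d_max) * MM_PER_CM
        else:
            out[name] = 2.0 * np.sqrt(poly.area / np.pi) * MM_PER_CM
    return out


def extract_planes(cl: Centerline, surf: AortaSurface) -> List[SlicePlane]:
    """The five analysis planes along the centerline.

    plane0: one local diameter distal to the annulus slice; plane1: one
    local diameter proximal to the brachiocephalic ostium; plane2: just
    before that ostium; plane3: just after the left-subclavian ostium;
    plane4: two local diameters beyond plane3.
    """
    lm = surf.landmarks
    for name in ("annulus", "brachiocephalic", "left_subclavian"):
        if name not in lm:
            raise ValueError(f"missing landmark {name!r}")
    s_ann, s_bca, s_lsa = lm["annulus"], lm["brachiocephalic"], lm["left_subclavian"]
    if "left_carotid" in lm:
        if not (s_bca < lm["left_carotid"] < s_lsa):
            raise ValueError("branch ostia landmarks out of order along arclength")
    if not s_ann < s_bca < s_lsa:
        raise ValueError("landmarks out of order along arclength")

    s0 = s_ann + cl.diameter_at(s_ann)
    s1 = s_bca - cl.diameter_at(s_bca)
    s2 = s_bca - _JUST_FRACTION * cl.diameter_at(s_bca)
    s3 = s_lsa + _JUST_FRACTION * cl.diameter_at(s_lsa)
    s4 = s3 + 2.0 * cl.diameter_at(s3)
    s_list = [s0, s1, s2, s3, s4]
    if np.any(np.diff(s_list) <= 0):
        raise ValueError("plane arclengths are not strictly increasing")
    if s4 > cl.length:
        raise ValueError("plane4 falls beyond the end of the centerline")
    planes = []
    for label, s in zip(PLANE_LABELS, s_list):
        planes.append(
            SlicePlane(
                label=label,
                origin=cl.point_at(s),
                normal=cl.tangent_at(s),
                diameter=float(cl.diameter_at(s)),
                arclength=float(s),
            )
        )
    return planes


def define_wall_regions(
    surf: AortaSurface, cl: Centerline, planes: Sequence[SlicePlane]
) -> List[WallRegion]:
    """Five wall regions for regional WSS averaging.

    root: arclength band one local diameter proximal of the STJ; the other
    four: bands of +-0.5 local diameter around planes 1-4.  Triangles in
    overlapping bands go to the nearest band center.
    """
    if "stj" not in surf.landmarks:
        raise ValueError("missing landmark 'stj'")
    s_stj = surf.landmarks["stj"]
    d_stj = float(cl.diameter_at(s_stj))
    by_label = {p.label: p for p in planes}
    for lbl in ("plane1", "plane2", "plane3", "plane4"):
        if lbl not in by_label:
            raise ValueError(f"missing {lbl}")

    centers = [s_stj - 0.5 * d_stj]
    halfwidths = [0.5 * d_stj]
    for lbl in ("plane1", "plane2", "plane3", "plane4"):
        p = by_label[lbl]
        centers.append(p.arclength)
        halfwidths.append(0.5 * p.diameter)
    centers = np.asarray(centers)
    halfwidths = np.asarray(halfwidths)

    tree = cKDTree(cl.points)
    cent = surf.triangle_centroids()
    _, idx = tree.query(cent)
    s_tri = cl.arclength[idx]

    dist = np.abs(s_tri[:, None] - centers[None, :])
    inside = dist <= halfwidths[None, :]
    assigned = np.where(inside.any(axis=1), np.argmin(np.where(inside, dist, np.inf), axis=1), -1)

    regions = []
    for k, label in enumerate(REGION_LABELS):
        ids = np.where(assigned == k)[0]
        if ids.size == 0:
            raise ValueError(f"wall region {label!r} is empty")
        regions.append(WallRegion(label, ids))
    return regions
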