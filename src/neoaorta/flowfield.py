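"""Constructed time-periodic velocity fields on the synthetic geometry.

The field stands in for a finite-element flow solution: the axial component
follows a generalized power-law profile

    u_ax(s, r, t) = U(s, t) * (m+2)/m * (1 - (r/R)^m)

along the local centerline tangent, rescaled each instant so the
cross-sectional flux equals the inlet waveform Q(t) at every station.  The
bluntness exponent m(s) defaults to 2 (exact Poiseuille) on plain tubes; on
geometries with branch landmarks it rises toward the distal ascending aorta
(entrance-flow sharpening of the wall gradient) and relaxes along the arch,
which is what gives normal anatomies their root-minimum / distal-ascending-
maximum wall-shear pattern.

A phenotype-controlled recirculation bubble can be superposed between the
distal-ascending and arch planes: an axial deficit concentrated near the
outer-curvature wall (calibrated so the peak reverse velocity is `strength`
times the local mean forward velocity) plus a tangential swirl.  Both are
flux-neutral: each slice still integrates to Q(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .anatomy import AortaSurface, Centerline, SlicePlane
from .windkessel import InflowWaveform

__all__ = [
    "RecirculationSpec",
    "VelocityField",
    "SampledPlane",
    "generate_field",
    "sample_on_plane",
    "sample_near_wall",
]

# deficit radial shape q(r) = r^4 (1 - r^2), normalized to peak 1
_Q_PEAK = 4.0 / 27.0
# area mean of the normalized deficit (including the (1+cos)/2 azimuthal
# factor): <q>/2 with <q> = (1/12)/(4/27)
_DEFICIT_AREA_MEAN = 0.5 * (1.0 / 12.0) / _Q_PEAK
# swirl radial shape r (1 - r^2), normalized to peak 1
_SIGMA_PEAK = 2.0 / (3.0 * np.sqrt(3.0))


def _q_shape(r: np.ndarray) -> np.ndarray:
    return r**4 * (1.0 - r**2) / _Q_PEAK


def _sigma_shape(r: np.ndarray) -> np.ndarray:
    return r * (1.0 - r**2) / _SIGMA_PEAK


@dataclass
class RecirculationSpec:
    """Recirculation bubble between two arclength stations (cm).

    strength: peak reverse axial velocity as a fraction of the local mean
    forward velocity (0 disables the bubble); swirl: tangential velocity
    amplitude fraction.  The axial deficit is supported strictly inside
    (s_start, s_end); the swirl tail extends into the arch.
    """

    s_start: float
    s_end: float
    strength: float
    swirl: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.s_end <= self.s_start:
            raise ValueError("need s_end > s_start")
        if self.swirl is None:
            self.swirl = 1.2 * self.strength


class _CenterlineFrame:
    """Maps arbitrary points to tube coordinates (s, r, azimuth) with the
    local tangent / outward / binormal triad."""

    def __init__(self, cl: Centerline):
        self.cl = cl
        self.tree = cKDTree(cl.points)
        self.length = cl.length
        centroid = cl.points.mean(axis=0)
        e_y = np.array([0.0, 1.0, 0.0])
        out = np.cross(cl.tangent, e_y)
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        nrm[nrm < 1e-12] = 1.0
        out = out / nrm
        sign = np.sign(np.einsum("ij,ij->i", out, cl.points - centroid))
        sign[sign == 0] = 1.0
        self.outward = out * sign[:, None]

    def decompose(self, points: np.ndarray):
        points = np.atleast_2d(points)
        _, idx = self.tree.query(points)
        p0 = self.cl.points[idx]
        t = self.cl.tangent[idx]
        dp = points - p0
        ds = np.einsum("ij,ij->i", dp, t)
        s = np.clip(self.cl.arclength[idx] + ds, 0.0, self.length)
        radial = dp - ds[:, None] * t
        r = np.linalg.norm(radial, axis=1)
        rhat = np.where(r[:, None] > 1e-12, radial / np.maximum(r, 1e-12)[:, None], 0.0)
        e_out = self.outward[idx]
        e_bin = np.cross(t, e_out)
        cosphi = np.einsum("ij,ij->i", rhat, e_out)
        sinphi = np.einsum("ij,ij->i", rhat, e_bin)
        return s, r, rhat, t, cosphi, sinphi


def _default_bluntness(
    cl: Centerline, surf: AortaSurface, m_peak: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Bluntness exponent profile m(s): 2 at the root, peaking at the
    pre-bifurcation station, decaying to 2 by two diameters past the last
    branch; flat 2 when branch landmarks are absent."""
    lm = surf.landmarks
    if not {"stj", "brachiocephalic", "left_subclavian"} <= set(lm):
        return lambda s: np.full_like(np.asarray(s, dtype=float), 2.0)
    s0 = lm["stj"]
    s_pk = lm["brachiocephalic"] - 0.05 * cl.diameter_at(lm["brachiocephalic"])
    s_end = lm["left_subclavian"] + 2.0 * cl.diameter_at(lm["left_subclavian"])
    s_end = min(s_end, cl.length)

    def m_of_s(s):
        s = np.asarray(s, dtype=float)
        b = np.zeros_like(s)
        rise = (s > s0) & (s <= s_pk)
        b[rise] = np.sin(0.5 * np.pi * (s[rise] - s0) / (s_pk - s0)) ** 2
        fall = (s > s_pk) & (s < s_end)
        b[fall] = np.cos(0.5 * np.pi * (s[fall] - s_pk) / (s_end - s_pk)) ** 2
        return 2.0 + (m_peak - 2.0) * b

    return m_of_s


def _calibrate_deficit(strength: float, m_center: float) -> float:
    """Deficit amplitude beta such that the minimum axial velocity at the
    bubble center equals -strength * local mean velocity."""
    if strength == 0:
        return 0.0
    r = np.linspace(0.0, 1.0, 2001)
    prof = (m_center + 2.0) / m_center * (1.0 - r**m_center)
    q = _q_shape(r)

    def worst(beta: float) -> float:
        a = 1.0 + beta * _DEFICIT_AREA_MEAN
        return float(np.min(a * prof - beta * q)) + strength

    hi = 2.0
    while worst(hi) > 0 and hi < 1e3:
        hi *= 2.0
    return brentq(worst, 0.0, hi, xtol=1e-10)


class VelocityField:
    """Time-periodic lumen velocity field, sampleable at arbitrary points.

    Implements the evaluator protocol used by the metrics module:
    ``velocity(points, t)``, ``contains(points)``, ``period``,
    ``peak_systole_time``, plus geometry access for near-wall and
    volumetric sampling.
    """

    def __init__(
        self,
        cl: Centerline,
        surf: AortaSurface,
        waveform: InflowWaveform,
        recirc: Optional[RecirculationSpec] = None,
        n_frames: int = 40,
        bluntness: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        m_peak: float = 4.0,
        seed: int = 0,
    ):
        self.centerline = cl
        self.surface = surf
        self.waveform = waveform
        self.n_frames = int(n_frames)
        self.seed = seed
        self._frame = _CenterlineFrame(cl)
        self._m = bluntness or _default_bluntness(cl, surf, m_peak)
        self.recirc = recirc

        rng = np.random.default_rng(seed)
        # seeded anatomical variability of the bubble: azimuthal offset of
        # its outer-wall center and a slight axial shift
        self._phi0 = float(rng.normal(0.0, 0.15))
        self._shift = float(rng.normal(0.0, 0.05))

        if recirc is not None and recirc.strength > 0:
            if not (0.0 <= recirc.s_start < recirc.s_end <= cl.length):
                raise ValueError("recirculation interval outside the geometry")
            s_c = 0.5 * (recirc.s_start + recirc.s_end) + self._shift
            m_c = float(self._m(np.array([s_c]))[0])
            self._beta = _calibrate_deficit(recirc.strength, m_c)
            self._swirl_end = min(
                recirc.s_end + 1.5 * float(cl.diameter_at(recirc.s_end)), cl.length
            )
        else:
            self._beta = 0.0
            self._swirl_end = 0.0

    # -- protocol -----------------------------------------------------------

    @property
    def period(self) -> float:
        return self.waveform.period

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.period / self.n_frames

    @property
    def peak_systole_time(self) -> float:
        q = self.waveform.at(self.frame_times)
        return float(self.frame_times[int(np.argmax(q))])

    def contains(self, points: np.ndarray) -> np.ndarray:
        s, r, *_ = self._frame.decompose(points)
        R = 0.5 * self.centerline.diameter_at(s)
        return (r <= R) & (s > 0) & (s < self._frame.length)

    def radius_at(self, s) -> np.ndarray:
        return 0.5 * self.centerline.diameter_at(s)

    def axial_tangent(self, points: np.ndarray) -> np.ndarray:
        _, _, _, t, _, _ = self._frame.decompose(points)
        return t

    def _deficit_bump(self, s: np.ndarray) -> np.ndarray:
        rc = self.recirc
        g = np.zeros_like(s)
        lo, hi = rc.s_start + self._shift, rc.s_end + self._shift
        inside = (s > lo) & (s < hi)
        g[inside] = np.sin(np.pi * (s[inside] - lo) / (hi - lo)) ** 2
        return g

    def _swirl_bump(self, s: np.ndarray) -> np.ndarray:
        rc = self.recirc
        g = np.zeros_like(s)
        lo, hi = rc.s_start + self._shift, self._swirl_end
        inside = (s > lo) & (s < hi)
        g[inside] = np.sin(np.pi * (s[inside] - lo) / (hi - lo)) ** 2
        return g

    def velocity(self, points: np.ndarray, t: float) -> np.ndarray:
        """Velocity vectors (cm/s) at points (N, 3) and time t (s)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        s, r, rhat, tang, cosphi, sinphi = self._frame.decompose(points)
        R = 0.5 * self.centerline.diameter_at(s)
        rt = np.minimum(r / R, 1.0)
        q_t = float(self.waveform.at(t))
        u_mean = q_t / (np.pi * R**2)
        m = self._m(s)
        axial = (m + 2.0) / m * (1.0 - rt**m)

        v = np.zeros_like(points)
        if self._beta > 0:
            g_d = self._deficit_bump(s)
            a = 1.0 + self._beta * g_d * _DEFICIT_AREA_MEAN
            cos_off = cosphi * np.cos(self._phi0) + sinphi * np.sin(self._phi0)
            deficit = self._beta * g_d * _q_shape(rt) * 0.5 * (1.0 + cos_off)
            # deficit tracks forward flow: only act while flow is forward
            if q_t <= 0:
                deficit = 0.0 * deficit
                a = np.ones_like(a)
            u_ax = u_mean * (a * axial - deficit)
            g_s = self._swirl_bump(s)
            if np.any(g_s > 0) and q_t > 0:
                e_phi = np.cross(tang, rhat)
                u_phi = self.recirc.swirl * np.abs(u_mean) * g_s * _sigma_shape(rt)
                v += u_phi[:, None] * e_phi
        else:
            u_ax = u_mean * axial

        v += u_ax[:, None] * tang
        outside = (r > R) | (s <= 0) | (s >= self._frame.length)
        v[outside] = 0.0
        return v

    __call__ = velocity


def generate_field(
    geom: Tuple[Centerline, AortaSurface],
    w: InflowWaveform,
    recirc: Optional[RecirculationSpec] = None,
    seed: int = 0,
    n_frames: int = 40,
    **kwargs,
) -> VelocityField:
    """Build a velocity field on a (centerline, surface) geometry driven by
    the inflow waveform, with an optional recirculation bubble."""
    cl, surf = geom
    return VelocityField(cl, surf, w, recirc=recirc, n_frames=n_frames, seed=seed, **kwargs)


@dataclass
class SampledPlane:
    """Regular in-plane velocity grid masked to the lumen cross-section."""

    points: np.ndarray  # (n, n, 3)
    velocity: np.ndarray  # (n, n, 3)
    mask: np.ndarray  # (n, n) bool
    spacing: float  # cm
    e1: np.ndarray
    e2: np.ndarray
    normal: np.ndarray

    def flux(self) -> float:
        """Grid quadrature of the normal flux over the masked section."""
        un = self.velocity @ self.normal
        return float(un[self.mask].sum() * self.spacing**2)


def sample_on_plane(
    field: VelocityField, plane: SlicePlane, n_grid: int, t: float = 0.0
) -> SampledPlane:
    """Sample the field on an n_grid x n_grid grid covering the slice."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    e1, e2 = plane.in_plane_axes()
    half = 0.6 * plane.diameter
    coords = np.linspace(-half, half, n_grid)
    spacing = coords[1] - coords[0]
    u, v = np.meshgrid(coords, coords, indexing="ij")
    pts = (
        plane.origin[None, None, :]
        + u[..., None] * e1[None, None, :]
        + v[..., None] * e2[None, None, :]
    )
    flat = pts.reshape(-1, 3)
    mask = field.contains(flat).reshape(n_grid, n_grid)
    if not mask.any():
        raise ValueError("plane lies outside the lumen")
    vel = field.velocity(flat, t).reshape(n_grid, n_grid, 3)
    return SampledPlane(pts, vel, mask, float(spacing), e1, e2, plane.normal)


def sample_near_wall(
    field: VelocityField,
    surf: AortaSurface,
    eps: float,
    t: float = 0.0,
    triangle_ids: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Tangential velocity at wall-offset points, one per surface triangle.

    Samples the field at eps inward of the wall along the triangle's
    inward normal and projects onto the wall tangent plane.  The offset is
    measured from the analytic lumen boundary (the no-slip surface of the
    field): triangle centroids of a faceted mesh sit slightly inside the
    true wall, and that gap is compensated so eps = 0 lands exactly on the
    wall.  Offset points falling outside the lumen get NaN; the boolean
    inside-mask is the second return so callers can report the skip count.
    """
    if eps < 0:
        raise ValueError("offset eps must be >= 0")
    centroids = surf.triangle_centroids()
    normals = surf.outward_normals()
    if triangle_ids is not None:
        centroids = centroids[triangle_ids]
        normals = normals[triangle_ids]
    if eps == 0.0:
        return np.zeros_like(centroids), np.ones(len(centroids), dtype=bool)
    s, r, *_ = field._frame.decompose(centroids)
    gap = field.radius_at(s) - r  # centroid depth below the analytic wall
    pts = centroids - (eps - gap)[:, None] * normals
    inside = field.contains(pts)
    vel = field.velocity(pts, t)
    tangential = vel - np.einsum("ij,ij->i", vel, normals)[:, None] * normals
    tangential[~inside] = np.nan
    return tangential, inside
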