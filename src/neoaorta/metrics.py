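"""Hemodynamic post-processing metrics.

Wall shear stress (WSS) is the viscous stress of blood acting tangentially
on the vessel wall.  It is estimated from the constructed velocity field by
a one-sided second-order finite difference anchored at the no-slip wall:
with tangential speeds u(eps) and u(eps/2) at wall offsets eps and eps/2,

    WSS = mu * (4 u(eps/2) - u(eps)) / eps

which is exact for velocity profiles quadratic in wall distance (the
Poiseuille case).  TAWSS time-averages this over one cardiac cycle and
area-averages
over a wall region.  Slice vorticity takes the full 3-D curl by central
differences on a masked in-plane grid and averages |curl u| over the
section, then over the cycle.  Recirculation is quantified as the fraction
of volumetric sample points between the distal-ascending and arch planes
whose tangent-projected velocity is negative at peak systole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Optional, Tuple

import numpy as np

from .anatomy import SlicePlane, WallRegion, REGION_LABELS
from .flowfield import VelocityField, sample_near_wall
from .windkessel import FluidProperties

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsRecord",
    "wss_instant",
    "tawss",
    "poiseuille_wss",
    "vorticity_slice",
    "vorticity_metric",
    "recirculation_fraction",
    "wss_pattern",
]

RECIRC_FLAG_THRESHOLD = 0.02


@dataclass
class MetricsRecord:
    """Per-subject bundle of the reported hemodynamic quantities."""

    subject_id: str
    group: str
    tawss: Dict[str, float]  # dyn/cm^2 per wall region
    vorticity: Dict[str, float]  # 1/s per plane
    arch_angle: float  # degrees
    recirc_fraction: float
    recirc_present: bool
    reynolds: float
    pattern: str  # distal_AA_peak | arch_peak | other
    zscores: Dict[str, float] = dataclass_field(default_factory=dict)
    dilation_class: str = ""
    extras: Dict[str, float] = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.tawss.values()):
            raise ValueError("TAWSS must be non-negative")
        if any(v < 0 for v in self.vorticity.values()):
            raise ValueError("vorticity magnitude must be non-negative")
        if not 0.0 <= self.recirc_fraction <= 1.0:
            raise ValueError("recirculation fraction must lie in [0, 1]")


def poiseuille_wss(mu: float, Q: float, D: float) -> float:
    """Analytic wall shear stress of steady pipe flow: 32 mu Q / (pi D^3)."""
    if mu <= 0 or D <= 0:
        raise ValueError("viscosity and diameter must be positive")
    return 32.0 * mu * Q / (np.pi * D**3)


def wss_instant(
    field: VelocityField,
    region: WallRegion,
    fluid: FluidProperties = FluidProperties(),
    eps: Optional[float] = None,
    t: float = 0.0,
) -> Tuple[np.ndarray, int]:
    """Per-triangle WSS (dyn/cm^2) over a wall region at one instant.

    Returns (wss values aligned with region.triangle_ids, skip count of
    offset points that fell outside the lumen).
    """
    surf = field.surface
    if eps is None:
        eps = _default_eps(field, region)
    v1, in1 = sample_near_wall(field, surf, eps, t=t, triangle_ids=region.triangle_ids)
    v2, in2 = sample_near_wall(field, surf, 0.5 * eps, t=t, triangle_ids=region.triangle_ids)
    ok = in1 & in2
    u1 = np.linalg.norm(v1, axis=1)
    u2 = np.linalg.norm(v2, axis=1)
    wss = fluid.dynamic_viscosity * (4.0 * u2 - u1) / eps
    wss = np.where(ok, np.maximum(wss, 0.0), np.nan)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("wss_instant: skipped %d offset points outside lumen", n_skip)
    return wss, n_skip


def _default_eps(field: VelocityField, region: WallRegion) -> float:
    """Wall offset: 1/20 of the smallest local radius in the region."""
    cent = field.surface.triangle_centroids()[region.triangle_ids]
    s, *_ = field._frame.decompose(cent)
    return float(0.05 * field.radius_at(s).min())


def tawss(
    field: VelocityField,
    region: WallRegion,
    fluid: FluidProperties = FluidProperties(),
    eps: Optional[float] = None,
    n_frames: Optional[int] = None,
) -> float:
    """Time-averaged, area-averaged WSS (dyn/cm^2) over a wall region."""
    if region.triangle_ids.size == 0:
        raise ValueError("empty wall region")
    if eps is None:
        eps = _default_eps(field, region)
    n_frames = n_frames or field.n_frames
    times = np.arange(n_frames) * field.period / n_frames
    areas = field.surface.triangle_areas()[region.triangle_ids]
    acc = np.zeros(len(region.triangle_ids))
    for t in times:
        w, _ = wss_instant(field, region, fluid=fluid, eps=eps, t=t)
        acc += np.nan_to_num(w)
    mean_w = acc / n_frames
    return float(np.sum(mean_w * areas) / areas.sum())


def vorticity_slice(
    field: VelocityField,
    plane: SlicePlane,
    t: float = 0.0,
    n_grid: int = 48,
    streamwise_only: bool = False,
) -> float:
    """Slice-averaged vorticity magnitude (1/s) at one instant.

    Central-difference curl of the full 3-D velocity on a masked in-plane
    grid; only grid points whose entire stencil lies inside the lumen
    contribute.  With streamwise_only, averages |omega . normal| instead of
    the full magnitude.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    e1, e2 = plane.in_plane_axes()
    n_hat = plane.normal
    half = 0.6 * plane.diameter
    coords = np.linspace(-half, half, n_grid)
    spacing = coords[1] - coords[0]
    h = 0.25 * spacing  # stencil step, decoupled from the grid pitch
    u, v = np.meshgrid(coords, coords, indexing="ij")
    pts = (
        plane.origin[None, None, :]
        + u[..., None] * e1[None, None, :]
        + v[..., None] * e2[None, None, :]
    ).reshape(-1, 3)

    offsets = [h * e1, -h * e1, h * e2, -h * e2, h * n_hat, -h * n_hat]
    in_section = u.reshape(-1) ** 2 + v.reshape(-1) ** 2 <= (0.5 * plane.diameter) ** 2
    inside = field.contains(pts) & in_section
    samples = []
    for off in offsets:
        p = pts + off
        inside &= field.contains(p)
        samples.append(p)
    if int(inside.sum()) < 16:
        raise ValueError("grid too coarse: fewer than 16 lumen cells on the slice")

    keep = np.where(inside)[0]
    dv = []
    for k in range(0, 6, 2):
        vp = field.velocity(samples[k][keep], t)
        vm = field.velocity(samples[k + 1][keep], t)
        dv.append((vp - vm) / (2.0 * h))
    d1, d2, dn = dv  # dv/de1, dv/de2, dv/dn in the orthonormal frame

    # curl in the (e1, e2, n) frame, then back to Cartesian magnitude
    v1 = np.stack([d1 @ e1, d1 @ e2, d1 @ n_hat], axis=1)
    v2_ = np.stack([d2 @ e1, d2 @ e2, d2 @ n_hat], axis=1)
    vn = np.stack([dn @ e1, dn @ e2, dn @ n_hat], axis=1)
    w1 = v2_[:, 2] - vn[:, 1]
    w2 = vn[:, 0] - v1[:, 2]
    w3 = v1[:, 1] - v2_[:, 0]
    if streamwise_only:
        mag = np.abs(w3)
    else:
        mag = np.sqrt(w1**2 + w2**2 + w3**2)
    return float(mag.mean())


def vorticity_metric(
    field: VelocityField,
    plane: SlicePlane,
    n_grid: int = 48,
    n_frames: Optional[int] = None,
    streamwise_only: bool = False,
) -> float:
    """Cycle-averaged slice vorticity (1/s)."""
    n_frames = n_frames or field.n_frames
    times = np.arange(n_frames) * field.period / n_frames
    vals = [
        vorticity_slice(field, plane, t=t, n_grid=n_grid, streamwise_only=streamwise_only)
        for t in times
    ]
    return float(np.mean(vals))


def recirculation_fraction(
    field: VelocityField,
    interval: Tuple[float, float],
    t: Optional[float] = None,
    n_stations: int = 40,
    n_radial: int = 12,
    n_azimuthal: int = 24,
    flag_threshold: float = RECIRC_FLAG_THRESHOLD,
) -> Tuple[float, bool]:
    """Fraction of volumetric sample points in the arclength interval with
    negative tangent-projected velocity at peak systole (or time t).

    Sampling is a deterministic station x radius x azimuth lattice with
    area-uniform radii, volume-weighted by the local cross-section area.
    """
    s_lo, s_hi = interval
    cl = field.centerline
    if not 0.0 <= s_lo < s_hi <= cl.length:
        raise ValueError("interval outside the geometry")
    if t is None:
        t = field.peak_systole_time

    s_vals = np.linspace(s_lo, s_hi, n_stations)
    r_frac = np.sqrt((np.arange(n_radial) + 0.5) / n_radial)
    phi = np.linspace(0.0, 2 * np.pi, n_azimuthal, endpoint=False)

    e_y = np.array([0.0, 1.0, 0.0])
    pts = []
    weights = []
    for s in s_vals:
        p0 = cl.point_at(s)
        tan = cl.tangent_at(s)
        e1 = np.cross(e_y, tan)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(tan, e1)
        R = 0.95 * float(cl.diameter_at(s)) / 2.0  # stay off the wall
        ring_r = (r_frac * R)[:, None]
        x = ring_r * np.cos(phi)[None, :]
        y = ring_r * np.sin(phi)[None, :]
        block = p0[None, None, :] + x[..., None] * e1 + y[..., None] * e2
        pts.append(block.reshape(-1, 3))
        weights.append(np.full(n_radial * n_azimuthal, R**2))
    pts = np.concatenate(pts)
    weights = np.concatenate(weights)
    if pts.size == 0:
        raise ValueError("empty sample set")

    vel = field.velocity(pts, t)
    tang = field.axial_tangent(pts)
    axial = np.einsum("ij,ij->i", vel, tang)
    frac = float(np.sum(weights * (axial < 0)) / weights.sum())
    return frac, frac > flag_threshold


def wss_pattern(tawss_by_region: Dict[str, float]) -> str:
    """Classify the regional TAWSS profile by its argmax region.

    distal_AA -> 'distal_AA_peak'; arch -> 'arch_peak'; anything else ->
    'other'.  Ties break toward the more distal region (logged).
    """
    missing = set(REGION_LABELS) - set(tawss_by_region)
    if missing:
        raise ValueError(f"missing regions: {sorted(missing)}")
    vals = [tawss_by_region[r] for r in REGION_LABELS]
    vmax = max(vals)
    winners = [i for i, v in enumerate(vals) if v == vmax]
    if len(winners) > 1:
        logger.info("wss_pattern: tie among %s, taking most distal",
                    [REGION_LABELS[i] for i in winners])
    region = REGION_LABELS[winners[-1]]
    if region == "distal_AA":
        return "distal_AA_peak"
    if region == "arch":
        return "arch_peak"
    return "other"
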