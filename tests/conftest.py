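import numpy as np
import pytest

from neoaorta import anatomy, flowfield, windkessel as wk


@pytest.fixture(scope="session")
def steady_tube():
    """Straight tube D=2 cm carrying steady Q=83.33 cm^3/s (~5 L/min)."""
    D, L, Q = 2.0, 12.0, 83.33
    cl, surf = anatomy.straight_tube(L, D, n_points=200, n_theta=64)
    w = wk.InflowWaveform(np.linspace(0.0, 0.8, 50), np.full(50, Q))
    field = flowfield.generate_field((cl, surf), w)
    return dict(cl=cl, surf=surf, field=field, Q=Q, D=D, L=L)


@pytest.fixture(scope="session")
def pulsatile_waveform():
    return wk.scale_waveform(wk.default_inflow_waveform(), 5.0)


def _mid_band_region(surf, z_center=6.0, half=2.0):
    ids = np.where(np.abs(surf.triangle_centroids()[:, 2] - z_center) < half)[0]
    return anatomy.WallRegion("distal_AA", ids)


@pytest.fixture(scope="session")
def mid_band_region(steady_tube):
    return _mid_band_region(steady_tube["surf"])


@pytest.fixture(scope="session")
def group_geometries():
    """Median-phenotype geometry bundle per group (built once)."""
    out = {}
    for group, params in anatomy.GROUP_MEDIAN_PARAMS.items():
        cl, surf = anatomy.build_synthetic_aorta(params, seed=7)
        planes = anatomy.extract_planes(cl, surf)
        regions = anatomy.define_wall_regions(surf, cl, planes)
        out[group] = dict(params=params, cl=cl, surf=surf, planes=planes, regions=regions)
    return out


class UniformField:
    """Constant-velocity test field defined on all of space."""

    def __init__(self, v, period=1.0):
        self.v = np.asarray(v, dtype=float)
        self.period = period
        self.n_frames = 4
        self.peak_systole_time = 0.0

    def contains(self, points):
        return np.ones(len(np.atleast_2d(points)), dtype=bool)

    def velocity(self, points, t):
        points = np.atleast_2d(points)
        return np.tile(self.v, (len(points), 1))


class SolidBodyField:
    """Rigid rotation at rate omega (rad/s) about an axis through a point."""

    def __init__(self, omega, axis=(0.0, 0.0, 1.0), center=(0.0, 0.0, 0.0)):
        self.omega = omega
        self.axis = np.asarray(axis, dtype=float)
        self.axis /= np.linalg.norm(self.axis)
        self.center = np.asarray(center, dtype=float)
        self.period = 1.0
        self.n_frames = 4
        self.peak_systole_time = 0.0

    def contains(self, points):
        return np.ones(len(np.atleast_2d(points)), dtype=bool)

    def velocity(self, points, t):
        rel = np.atleast_2d(points) - self.center
        return self.omega * np.cross(self.axis, rel)
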