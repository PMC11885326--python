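"""Open-loop 0-D lumped-parameter hemodynamics.

Each outlet carries a 3-element Windkessel (proximal resistance Rp in series
with a parallel capacitance C / distal resistance Rd, venous reference
pressure 0).  Inlet flow splits among outlets by modified Murray's law with
exponent 2 (fractions proportional to diameter squared), an idealized
junction standing in for the 3-D domain.  Per outlet,

    P_i = Q_i Rp_i + P_c,i,      C_i dP_c,i/dt = Q_i - P_c,i / Rd_i

integrated with the exact exponential update of the single-state capacitor
equation (unconditionally stable at dt = 0.001 s).  Whole cardiac cycles
are integrated until systolic and diastolic root pressure change by no more
than `cycle_tol` versus the previous cycle, with a minimum of eight cycles;
only the final cycle is reported.

Units: flow cm^3/s, pressure dyn/cm^2 internally and mmHg at the interface,
resistance dyn.s/cm^5, capacitance cm^5/dyn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MMHG",
    "FluidProperties",
    "InflowWaveform",
    "RCR",
    "NetworkResult",
    "TuneResult",
    "default_inflow_waveform",
    "scale_waveform",
    "murray_split",
    "simulate_network",
    "tune_rcr",
    "reynolds",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg
CM3S_PER_LMIN = 1000.0 / 60.0

# proximal:distal resistance split of each Windkessel (conventional
# large-artery characteristic-impedance fraction); configurable in tune_rcr
DEFAULT_RP_RD_RATIO = 0.09


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: dynamic viscosity (poise) and density (g/cm^3)."""

    dynamic_viscosity: float = 0.04
    density: float = 1.06

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass
class InflowWaveform:
    """One period of the inlet flow waveform: time (s) vs flow (cm^3/s)."""

    time: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.time[0] != 0.0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must start at 0 and increase strictly")
        if not np.isclose(self.flow[0], self.flow[-1], atol=1e-9 * max(1.0, np.abs(self.flow).max())):
            raise ValueError("waveform must be periodic (first flow == last flow)")
        if self.mean_flow <= 0:
            raise ValueError("mean flow must be positive")

    @property
    def period(self) -> float:
        return float(self.time[-1])

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.flow, self.time) / self.time[-1])

    @property
    def cardiac_output(self) -> float:
        """L/min."""
        return self.mean_flow / CM3S_PER_LMIN

    def at(self, t) -> np.ndarray:
        """Periodic evaluation at arbitrary times."""
        return np.interp(np.mod(t, self.period), self.time, self.flow)


def default_inflow_waveform(period: float = 0.8, n: int = 400) -> InflowWaveform:
    """Bundled analytic aortic pulse: systolic half-sine of duration T/3
    followed by a small reverse lobe (valve closure) and diastolic zero
    flow.  Replace via CSV for measured waveforms."""
    if not 0.5 <= period <= 1.5:
        raise ValueError("period must lie in [0.5, 1.5] s")
    t = np.linspace(0.0, period, n)
    ts = period / 3.0
    td = 0.12 * period
    q = np.where(t < ts, np.sin(np.pi * t / ts), 0.0)
    lobe = (t >= ts) & (t < ts + td)
    q = np.where(lobe, -0.08 * np.sin(np.pi * (t - ts) / td), q)
    q[-1] = q[0]
    return InflowWaveform(t, q)


def scale_waveform(w: InflowWaveform, cardiac_output: float) -> InflowWaveform:
    """Uniformly rescale flows so the cycle mean equals `cardiac_output`
    (L/min); shape and period are unchanged."""
    if cardiac_output <= 0:
        raise ValueError("cardiac output must be positive")
    mean = w.mean_flow
    if mean == 0:
        raise ValueError("cannot scale a zero-mean waveform")
    factor = cardiac_output * CM3S_PER_LMIN / mean
    return InflowWaveform(w.time.copy(), w.flow * factor)


def murray_split(outlet_diameters: Sequence[float], exponent: float = 2.0) -> np.ndarray:
    """Flow fractions by modified Murray's law: d_i^k / sum d_j^k."""
    d = np.asarray(outlet_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("at least one outlet is required")
    if np.any(d <= 0):
        raise ValueError("outlet diameters must be positive")
    w = d**exponent
    return w / w.sum()


@dataclass(frozen=True)
class RCR:
    """3-element Windkessel parameters of one outlet."""

    Rp: float  # dyn.s/cm^5
    C: float  # cm^5/dyn
    Rd: float  # dyn.s/cm^5

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.C <= 0 or self.Rd <= 0:
            raise ValueError("RCR elements must be strictly positive")


@dataclass
class NetworkResult:
    """Final-cycle traces and convergence bookkeeping of one simulation."""

    time: np.ndarray  # s, final cycle, starting at 0
    root_pressure: np.ndarray  # mmHg
    outlet_pressures: np.ndarray  # (n_outlets, n_steps) mmHg
    outlet_flows: np.ndarray  # (n_outlets, n_steps) cm^3/s
    inlet_flow: np.ndarray  # cm^3/s
    systolic: float  # mmHg
    diastolic: float  # mmHg
    n_cycles: int
    converged: bool
    cycle_residual: float  # relative change of sys/dia vs previous cycle
    cycle_history: List[Tuple[float, float]] = field(default_factory=list)
    # (systolic, diastolic) mmHg per simulated cycle

    @property
    def mean_pressure(self) -> float:
        return float(np.mean(self.root_pressure))

    @property
    def pulse_pressure(self) -> float:
        return self.systolic - self.diastolic


def simulate_network(
    w: InflowWaveform,
    outlets: Sequence[Tuple[float, RCR]],
    dt: float = 0.001,
    max_cycles: int = 30,
    cycle_tol: float = 0.01,
    min_cycles: int = 8,
    murray_exponent: float = 2.0,
) -> NetworkResult:
    """Integrate the outlet Windkessels over whole cardiac cycles.

    Inlet flow is divided by Murray fractions each instant (mass is
    conserved exactly); root pressure is the flow-fraction-weighted mean of
    outlet proximal pressures.  Stops when systolic and diastolic root
    pressure change <= cycle_tol versus the previous cycle (minimum
    `min_cycles` cycles); a run that hits max_cycles unconverged is flagged,
    not silently accepted.
    """
    if not outlets:
        raise ValueError("at least one outlet is required")
    T = w.period
    n_steps = int(round(T / dt))
    if n_steps < 2 or abs(n_steps * dt - T) > dt:
        raise ValueError("dt must divide the period to within one sample")
    dt_eff = T / n_steps

    diam = np.array([d for d, _ in outlets], dtype=float)
    frac = murray_split(diam, murray_exponent)
    Rp = np.array([o.Rp for _, o in outlets])
    C = np.array([o.C for _, o in outlets])
    Rd = np.array([o.Rd for _, o in outlets])
    tau = Rd * C
    decay = np.exp(-dt_eff / tau)

    t_grid = np.arange(n_steps) * dt_eff
    q_in = w.at(t_grid)
    q_mid = w.at(t_grid + 0.5 * dt_eff)  # midpoint flow for the exact update
    q_out = frac[:, None] * q_in[None, :]

    # start each capacitor at its cycle-mean steady state to suppress the
    # initial transient
    p_c = frac * w.mean_flow * Rd

    prev_sys = prev_dia = None
    residual = np.inf
    converged = False
    n_cycles = 0
    history: List[Tuple[float, float]] = []
    root_trace = np.empty(n_steps)
    outlet_p = np.empty((len(outlets), n_steps))

    for cycle in range(1, max_cycles + 1):
        for k in range(n_steps):
            p_now = q_out[:, k] * Rp + p_c
            outlet_p[:, k] = p_now
            root_trace[k] = float(frac @ p_now)
            q_k = frac * q_mid[k]
            p_c = p_c * decay + q_k * Rd * (1.0 - decay)
        sys_p = root_trace.max()
        dia_p = root_trace.min()
        history.append((sys_p / MMHG, dia_p / MMHG))
        n_cycles = cycle
        if prev_sys is not None:
            residual = max(
                abs(sys_p - prev_sys) / abs(prev_sys),
                abs(dia_p - prev_dia) / abs(prev_dia),
            )
            if cycle >= min_cycles and residual <= cycle_tol:
                converged = True
                break
        prev_sys, prev_dia = sys_p, dia_p
    if not converged:
        logger.warning(
            "network simulation unconverged after %d cycles (residual %.3g)",
            n_cycles, residual,
        )

    return NetworkResult(
        time=t_grid.copy(),
        root_pressure=root_trace / MMHG,
        outlet_pressures=outlet_p / MMHG,
        outlet_flows=q_out.copy(),
        inlet_flow=q_in.copy(),
        systolic=float(root_trace.max() / MMHG),
        diastolic=float(root_trace.min() / MMHG),
        n_cycles=n_cycles,
        converged=converged,
        cycle_residual=float(residual),
        cycle_history=history,
    )


@dataclass
class TuneResult:
    outlets: List[Tuple[float, RCR]]
    achieved_systolic: float  # mmHg
    achieved_diastolic: float  # mmHg
    n_iter: int
    converged: bool
    result: NetworkResult
    history: List[Tuple[float, float]] = field(default_factory=list)


def _distribute(
    diam: np.ndarray, r_total: float, c_total: float, rp_rd_ratio: float,
    murray_exponent: float,
) -> List[RCR]:
    """Split network totals over outlets: resistances inversely proportional
    and capacitances proportional to the Murray fraction, fixed Rp:Rd."""
    frac = murray_split(diam, murray_exponent)
    rcrs = []
    for f in frac:
        r_i = r_total / f
        rd = r_i / (1.0 + rp_rd_ratio)
        rp = r_i - rd
        rcrs.append(RCR(Rp=rp, C=c_total * f, Rd=rd))
    return rcrs


def tune_rcr(
    w: InflowWaveform,
    outlet_diameters: Sequence[float],
    systolic_target: float,
    diastolic_target: float,
    tol: float = 0.01,
    max_iter: int = 40,
    rp_rd_ratio: float = DEFAULT_RP_RD_RATIO,
    murray_exponent: float = 2.0,
    dt: float = 0.001,
    initial_tau: float = 1.2,
) -> TuneResult:
    """Tune outlet RCRs to patient systolic/diastolic pressure targets.

    Fixed-point iteration with the standard two-knob decoupling: total
    resistance is scaled by the target/achieved mean-pressure ratio and
    total capacitance by the achieved/target pulse-pressure ratio, then
    redistributed to outlets.  Stops when both |sys - target|/target and
    |dia - target|/target <= tol; exceeding max_iter returns the best
    candidate found, flagged unconverged.
    """
    if not systolic_target > diastolic_target > 0:
        raise ValueError("need systolic > diastolic > 0 mmHg")
    diam = np.asarray(outlet_diameters, dtype=float)
    q_mean = w.mean_flow
    sys_t = systolic_target * MMHG
    dia_t = diastolic_target * MMHG

    r_total = 0.5 * (sys_t + dia_t) / q_mean
    c_total = initial_tau * (1.0 + rp_rd_ratio) / r_total

    best: Optional[TuneResult] = None
    best_err = np.inf
    history: List[Tuple[float, float]] = []
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        rcrs = _distribute(diam, r_total, c_total, rp_rd_ratio, murray_exponent)
        outlets = list(zip(diam, rcrs))
        res = simulate_network(w, outlets, dt=dt, murray_exponent=murray_exponent)
        sys_s, dia_s = res.systolic * MMHG, res.diastolic * MMHG
        history.append((res.systolic, res.diastolic))
        err_sys = abs(sys_s - sys_t) / sys_t
        err_dia = abs(dia_s - dia_t) / dia_t
        err = max(err_sys, err_dia)
        n_done = it
        if err < best_err:
            best_err = err
            best = TuneResult(
                outlets=outlets,
                achieved_systolic=res.systolic,
                achieved_diastolic=res.diastolic,
                n_iter=it,
                converged=False,
                result=res,
                history=history,
            )
        if err <= tol:
            converged = True
            break
        fac_r = np.clip((sys_t + dia_t) / (sys_s + dia_s), 0.3, 3.0)
        fac_c = np.clip((sys_s - dia_s) / (sys_t - dia_t), 0.3, 3.0)
        r_total *= fac_r
        c_total *= fac_c

    assert best is not None
    best.converged = converged
    best.n_iter = n_done
    best.history = history
    return best


def reynolds(
    cardiac_output: float,
    inlet_diameter: float,
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Reynolds number Re = U d / nu with U the mean inlet velocity from
    the cardiac output (L/min) and inlet diameter (cm)."""
    if cardiac_output <= 0 or inlet_diameter <= 0:
        raise ValueError("cardiac output and diameter must be positive")
    q = cardiac_output * CM3S_PER_LMIN
    u = q / (np.pi * inlet_diameter**2 / 4.0)
    return float(u * inlet_diameter / fluid.kinematic_viscosity)
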