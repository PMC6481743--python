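"""Three-element (RCR) Windkessel outlet model.

A proximal resistance Rp in series with a parallel compliance C / distal
resistance Rd pair relates outlet flow Q(t) to outlet pressure P(t) via

    P + Rd C dP/dt = (Rp + Rd) Q + Rp Rd C dQ/dt.

The ODE is integrated with an implicit trapezoidal step (A-stable, second
order) over repeated cardiac cycles until the pressure trace becomes
periodic; the final cycle is returned.  The frequency response
Z(w) = Rp + Rd / (1 + i w Rd C) serves as the analytic oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import FlowWaveform


@dataclass(frozen=True)
class WindkesselParams:
    """RCR parameters: resistances in Pa s/m3, compliance in m3/Pa.

    Defaults approximate a healthy systemic circulation seen from the
    aortic root: total resistance ~1.5e8 Pa s/m3 (mean pressure ~95 mmHg at
    5 l/min) with ~5% of it proximal, and a total arterial compliance of
    1e-8 m3/Pa (~1.3 ml/mmHg).
    """

    rp: float = 8.0e6
    c: float = 1.0e-8
    rd: float = 1.4e8

    def __post_init__(self) -> None:
        if self.rp <= 0 or self.c <= 0 or self.rd <= 0:
            raise ValueError("Windkessel parameters must be strictly positive")


@dataclass
class PressureTrace:
    times: np.ndarray
    pressure: np.ndarray  # Pa
    periodicity_residual: float  # Pa, max-norm change between last two cycles
    n_cycles: int
    converged: bool

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.pressure, self.times) / (self.times[-1] - self.times[0]))


def impedance(params: WindkesselParams, omega) -> np.ndarray:
    """Complex input impedance Z(w) = Rp + Rd / (1 + i w Rd C)."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("angular frequency must be non-negative")
    return params.rp + params.rd / (1.0 + 1j * w * params.rd * params.c)


def simulate_windkessel(
    params: WindkesselParams,
    waveform: FlowWaveform,
    cycles: int = 50,
    dt: float | None = None,
    p0: float = 0.0,
    tolerance: float = 1.0,
) -> PressureTrace:
    """Integrate the RCR model to a periodic pressure solution.

    Runs up to ``cycles`` cardiac cycles of implicit-trapezoid steps of size
    ``dt`` (default: the waveform sample spacing refined to at least 1000
    steps/cycle) from initial pressure ``p0``, stopping once the max-norm
    pressure change between consecutive cycles drops below ``tolerance``
    (Pa).  Returns the final cycle with its periodicity residual; warns on
    non-convergence.
    """
    if cycles < 1:
        raise ValueError("at least one cycle is required")
    T = waveform.period
    if dt is None:
        n = max(1000, 4 * len(waveform.times))
    else:
        n = int(round(T / dt))
        if not np.isclose(n * dt, T, rtol=1e-9):
            raise ValueError("dt must divide the cardiac period")
    dt = T / n
    t_grid = np.arange(n + 1) * dt

    tau = params.rd * params.c
    # g(t) = (Rp + Rd) Q + Rp Rd C dQ/dt ; P' = (g - P) / tau
    g = (params.rp + params.rd) * waveform.q_at(t_grid) \
        + params.rp * params.rd * params.c * waveform.dqdt_at(t_grid)

    a = 1.0 + dt / (2.0 * tau)
    b = 1.0 - dt / (2.0 * tau)
    p_prev_cycle = None
    p = p0
    residual = np.inf
    k_cycle = 0
    for k_cycle in range(1, cycles + 1):
        trace = np.empty(n + 1)
        trace[0] = p
        for i in range(n):
            p = (b * p + dt / (2.0 * tau) * (g[i] + g[i + 1])) / a
            trace[i + 1] = p
        if p_prev_cycle is not None:
            residual = float(np.max(np.abs(trace - p_prev_cycle)))
            if residual < tolerance:
                return PressureTrace(times=t_grid, pressure=trace,
                                     periodicity_residual=residual,
                                     n_cycles=k_cycle, converged=True)
        p_prev_cycle = trace
    warnings.warn(
        f"Windkessel did not reach a periodic solution within {cycles} cycles "
        f"(residual {residual:.3g} Pa)"
    )
    return PressureTrace(times=t_grid, pressure=p_prev_cycle,
                         periodicity_residual=residual,
                         n_cycles=k_cycle, converged=False)
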