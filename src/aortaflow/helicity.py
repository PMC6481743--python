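"""Eulerian and Lagrangian helical-flow descriptors.

Helical structure is quantified two ways:

* Eulerian — helicity density Hk = v . (curl v) (m/s^2), a pseudoscalar
  whose sign encodes rotation handedness, with its normalized counterpart
  LNH = Hk / (|v| |curl v|) in [-1, 1]; regions of strong helicity are
  quantified as volume fractions above a threshold (|Hk| >= theta, each
  sign separately).
* Lagrangian — the helicity flow index (HFI): massless particles are
  released from the inlet at the four systolic instants T1..T4, advected by
  4th-order Runge-Kutta through the time-periodic velocity field, and HFI
  is the mean of |LNH| along each trace, averaged over particles and then
  over release times; HFI lies in [0, 1].

Vorticity uses the same least-squares gradient reconstruction as the
wall-shear module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._gradients import node_gradient_operators, node_velocity_gradients
from .fields import AnalyticVelocity, TimeVaryingField
from .mesh import REGIONS, TubeMesh
from .wallshear import percent_diff

_DEGENERATE = 1e-12


@dataclass
class HelicityField:
    """Per-node vorticity, helicity density and LNH over the cycle."""

    mesh: TubeMesh
    times: np.ndarray
    period: float
    vorticity: np.ndarray  # (T, N, 3), 1/s
    hk: np.ndarray         # (T, N), m/s^2
    lnh: np.ndarray        # (T, N), dimensionless


def compute_helicity(fld: TimeVaryingField) -> HelicityField:
    """Vorticity, Hk and LNH at every node and phase.

    LNH is set to 0 (by convention) wherever velocity or vorticity
    vanishes.
    """
    mesh = fld.mesh
    stencils, ops = node_gradient_operators(mesh)
    grad = node_velocity_gradients(fld.velocity, stencils, ops)  # (T, N, 3, 3)
    omega = np.stack(
        [grad[..., 1, 2] - grad[..., 2, 1],
         grad[..., 2, 0] - grad[..., 0, 2],
         grad[..., 0, 1] - grad[..., 1, 0]],
        axis=-1,
    )
    hk = np.einsum("tnc,tnc->tn", fld.velocity, omega)
    vmag = np.linalg.norm(fld.velocity, axis=2)
    wmag = np.linalg.norm(omega, axis=2)
    denom = vmag * wmag
    lnh = np.where(denom > _DEGENERATE, hk / np.maximum(denom, _DEGENERATE), 0.0)
    lnh = np.clip(lnh, -1.0, 1.0)
    return HelicityField(mesh=mesh, times=fld.times.copy(), period=fld.period,
                         vorticity=omega, hk=hk, lnh=lnh)


def threshold_volumes(hel: HelicityField, theta: float = 200.0):
    """Volume fractions with Hk >= theta and Hk <= -theta, per region and phase.

    Fractions are node-volume weighted within each region (theta in m/s^2;
    200 is the conventional display threshold for strong helical flow).
    Returns a tidy DataFrame with columns (t_s, region, frac_pos, frac_neg).
    """
    import pandas as pd

    if theta <= 0:
        raise ValueError("threshold must be positive")
    w = hel.mesh.node_volume_weights
    rows = []
    for r in REGIONS + ("whole",):
        m = np.ones(hel.mesh.n_nodes, bool) if r == "whole" else hel.mesh.region_labels == r
        wtot = w[m].sum()
        for it, t in enumerate(hel.times):
            hk = hel.hk[it, m]
            rows.append({
                "t_s": t, "region": r,
                "frac_pos": float(w[m][hk >= theta].sum() / wtot),
                "frac_neg": float(w[m][hk <= -theta].sum() / wtot),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Lagrangian particle tracing
# --------------------------------------------------------------------------

@dataclass
class ParticleTrace:
    release_time: float
    times: np.ndarray
    positions: np.ndarray  # (n_steps + 1, 3)
    lnh: np.ndarray        # samples at accepted steps
    termination: str       # "exited" | "cycle_cap"


def lnh_interpolant(hel: HelicityField):
    """Space-time interpolant of LNH built from a helicity field.

    Packs LNH into the first component of a vector field to reuse the
    structured trilinear/periodic-linear interpolation machinery.
    """
    packed = np.zeros(hel.lnh.shape + (3,))
    packed[..., 0] = hel.lnh
    carrier = TimeVaryingField(mesh=hel.mesh, times=hel.times, velocity=packed,
                               period=hel.period)

    def sample(points, t):
        return carrier.velocity_at(points, t)[:, 0]

    return sample


def inlet_disc_seeds(mesh: TubeMesh, n: int = 500, radius_fraction: float = 0.9,
                     z_offset_fraction: float = 0.02) -> np.ndarray:
    """~n seed points on a uniform grid over the inlet disc.

    Seeds sit slightly inside the domain (z = z_offset_fraction * L) and
    within radius_fraction * R so that none starts on a boundary face.
    """
    st = mesh.require_structure()
    rmax = radius_fraction * st.radius
    m = max(2, int(np.ceil(np.sqrt(4 * n / np.pi))))
    x = np.linspace(-rmax, rmax, m)
    X, Y = np.meshgrid(x, x)
    keep = X**2 + Y**2 <= rmax**2
    pts = np.stack([X[keep], Y[keep],
                    np.full(keep.sum(), z_offset_fraction * st.length)], axis=1)
    return pts


def trace_particles(
    fld,
    seeds: np.ndarray,
    t_release: float,
    dt: float,
    max_cycles: int = 3,
    t_end: float | None = None,
    lnh_sampler=None,
    min_steps: int = 10,
) -> list[ParticleTrace]:
    """Advect massless particles through a time-periodic velocity field.

    Classic 4th-order Runge-Kutta with constant step ``dt``, velocities
    sampled trilinearly in space and periodic-linearly in time (or from a
    closed form when ``fld`` is an :class:`AnalyticVelocity`).  A particle
    terminates when it leaves the domain ("exited") or when the horizon
    ``t_end`` (default ``t_release + max_cycles * T``) is reached
    ("cycle_cap").  LNH is sampled at every accepted step; traces shorter
    than ``min_steps`` steps are dropped from HFI statistics by the caller.

    Seeds outside the domain are skipped with a warning count in the
    result (they produce zero-length traces that are filtered out).
    """
    import warnings

    if dt <= 0:
        raise ValueError("dt must be positive")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    inside0 = fld.inside(seeds)
    if not np.all(inside0):
        warnings.warn(f"{int((~inside0).sum())} seed(s) outside the domain were skipped")
    seeds = seeds[inside0]
    if seeds.shape[0] == 0:
        return []

    if lnh_sampler is None:
        if isinstance(fld, AnalyticVelocity):
            lnh_sampler = fld.lnh_fn or (lambda p, t: np.zeros(len(np.atleast_2d(p))))
        else:
            lnh_sampler = lnh_interpolant(compute_helicity(fld))

    period = getattr(fld, "period", np.inf)
    if t_end is None:
        if not np.isfinite(period):
            raise ValueError("t_end is required for aperiodic analytic fields")
        t_end = t_release + max_cycles * period
    n_steps = int(np.ceil((t_end - t_release) / dt - 1e-12))

    P = seeds.shape[0]
    pos = seeds.copy()
    active = np.ones(P, dtype=bool)
    history = np.full((n_steps + 1, P, 3), np.nan)
    lnh_hist = np.full((n_steps + 1, P), np.nan)
    history[0] = pos
    lnh_hist[0] = lnh_sampler(pos, t_release)
    steps_taken = np.zeros(P, dtype=int)

    t = t_release
    for i in range(n_steps):
        if not np.any(active):
            break
        p = pos[active]
        k1 = fld.velocity_at(p, t)
        k2 = fld.velocity_at(p + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = fld.velocity_at(p + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = fld.velocity_at(p + dt * k3, t + dt)
        newp = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        still = fld.inside(newp)
        idx_active = np.where(active)[0]
        accepted = idx_active[still]
        pos[accepted] = newp[still]
        history[i + 1, accepted] = newp[still]
        if len(accepted):
            lnh_hist[i + 1, accepted] = lnh_sampler(pos[accepted], t + dt)
        steps_taken[accepted] = i + 1
        active[idx_active[~still]] = False
        t += dt

    traces = []
    for p in range(P):
        ns = steps_taken[p]
        term = "cycle_cap" if ns == n_steps else "exited"
        traces.append(ParticleTrace(
            release_time=t_release,
            times=t_release + dt * np.arange(ns + 1),
            positions=history[: ns + 1, p],
            lnh=lnh_hist[: ns + 1, p],
            termination=term,
        ))
    return traces


@dataclass
class HFIResult:
    """Helicity flow index per systolic release time and its average."""

    release_times: np.ndarray
    hfi: np.ndarray          # per release time, in [0, 1]
    particle_counts: np.ndarray
    label: str = ""

    @property
    def average(self) -> float:
        return float(np.mean(self.hfi))


def compute_hfi(traces_by_release: dict, min_steps: int = 10, signed: bool = False,
                label: str = "") -> HFIResult:
    """HFI from particle traces grouped by release time.

    Per release time: mean over particles of the along-trace mean of |LNH|
    (or signed LNH when ``signed``); the headline value is the arithmetic
    mean over the release times.  Traces with fewer than ``min_steps``
    accepted steps do not count.  Raises when a release time has no
    surviving trace.
    """
    rel = np.array(sorted(traces_by_release.keys()))
    hfi = np.empty(len(rel))
    counts = np.empty(len(rel), dtype=int)
    for i, tr in enumerate(rel):
        vals = []
        for trace in traces_by_release[tr]:
            if len(trace.lnh) - 1 < min_steps:
                continue
            lnh = trace.lnh[np.isfinite(trace.lnh)]
            vals.append(np.mean(lnh if signed else np.abs(lnh)))
        if not vals:
            raise ValueError(f"no surviving particle trace for release time t={tr:g} s")
        hfi[i] = np.mean(vals)
        counts[i] = len(vals)
    return HFIResult(release_times=rel, hfi=hfi, particle_counts=counts, label=label)


def hfi_percent_diff(reference: HFIResult, other: HFIResult) -> dict:
    """Signed percent differences vs the reference, per release time and
    for the average; undefined entries (zero reference) come back as NaN."""
    if not np.allclose(reference.release_times, other.release_times):
        raise ValueError("HFI results use different release schedules")
    out = {f"T{i+1}": percent_diff(o, r)
           for i, (o, r) in enumerate(zip(other.hfi, reference.hfi))}
    out["Avg"] = percent_diff(other.average, reference.average)
    return out
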