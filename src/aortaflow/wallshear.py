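"""Wall shear stress and its cycle-integrated indices.

The WSS vector is the tangential part of the viscous traction
``mu (grad v + grad v^T) n`` evaluated at wall-face centroids, with the
velocity gradient reconstructed by weighted least squares over adjacent
cell nodes.  From the per-face time series the module derives

* TAWSS  = (1/T) integral |tau_w| dt,
* OSI    = 0.5 (1 - |integral tau_w dt| / integral |tau_w| dt),
* area-weighted surface means (whole wall and per AAo/AA/DAo region),
* the area-weighted 99th-percentile TAWSS (robust maximum, excluding
  spurious spikes), and
* unwrapped circumference-vs-time |WSS| maps at analysis planes.

Time integrals use the periodic trapezoid rule over the stored phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._gradients import face_velocity_gradients, wall_face_gradient_operators
from .fields import TimeVaryingField, _periodic_trapezoid_weights
from .mesh import REGIONS, FluidProperties, TubeMesh


@dataclass
class WSSField:
    """Per-wall-face WSS vectors over one cycle: tau has shape (T, F, 3)."""

    centroids: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    regions: np.ndarray
    times: np.ndarray
    period: float
    tau: np.ndarray
    valid: np.ndarray = None  # faces with a usable gradient stencil

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.areas.shape[0], dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)


def compute_wss(fld: TimeVaryingField, fluid: FluidProperties) -> WSSField:
    """Viscous wall traction at every wall face and phase.

    tau_w = tangential part of mu (grad v + grad v^T) n-hat, gradient by
    least squares over the face's adjacent cell nodes.  Faces whose stencil
    holds fewer than 4 usable nodes are flagged invalid and excluded from
    percentile statistics downstream.
    """
    mesh = fld.mesh
    stencils, ops = wall_face_gradient_operators(mesh)
    valid = np.array([len(nb) >= 4 for nb in stencils])
    grad = face_velocity_gradients(fld.velocity, stencils, ops)  # (T, F, 3, 3)
    n = mesh.wall_normals  # (F, 3)
    mu = fluid.dynamic_viscosity
    # traction_c = mu * sum_g (grad[g,c] + grad[c,g]) n_g
    traction = mu * (np.einsum("tfgc,fg->tfc", grad, n)
                     + np.einsum("tfcg,fg->tfc", grad, n))
    tau = traction - np.einsum("tfc,fc->tf", traction, n)[..., None] * n[None, :, :]
    return WSSField(
        centroids=mesh.wall_face_centroids,
        normals=n,
        areas=mesh.wall_face_areas,
        regions=mesh.wall_face_regions,
        times=fld.times.copy(),
        period=fld.period,
        tau=tau,
        valid=valid,
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Interpolated weighted quantile (area weighting for surface fields)."""
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(q, p, v))


@dataclass
class WSSIndices:
    """Cycle-integrated WSS indices on the wall surface."""

    tawss: np.ndarray       # (F,) Pa
    osi: np.ndarray         # (F,) dimensionless
    areas: np.ndarray
    regions: np.ndarray
    valid: np.ndarray
    mean_tawss: float
    tawss_p99: float
    mean_osi: float
    regional_mean_tawss: dict
    regional_mean_osi: dict

    def summary_row(self) -> dict:
        """Mean / 99th prc / AAo / AA / DAo layout for TAWSS plus OSI mean."""
        row = {"TAWSS_mean": self.mean_tawss, "TAWSS_p99": self.tawss_p99}
        for r in REGIONS:
            row[f"TAWSS_{r}"] = self.regional_mean_tawss[r]
        row["OSI_mean"] = self.mean_osi
        return row


def compute_indices(wss: WSSField, period: float | None = None) -> WSSIndices:
    """TAWSS, OSI and their area-weighted surface aggregates.

    OSI is defined as 0 on faces where the shear magnitude integral
    vanishes.  Regional means are area-weighted and exactly consistent with
    the whole-surface mean.
    """
    if len(wss.times) < 2:
        raise ValueError("at least two phases over the cycle are required")
    T = wss.period if period is None else period
    if period is not None and not np.isclose(period, wss.period):
        raise ValueError("requested period does not match the stored phases")
    w = _periodic_trapezoid_weights(wss.times, T)
    mag_int = np.einsum("t,tf->f", w, wss.magnitude)
    vec_int = np.einsum("t,tfc->fc", w, wss.tau)
    tawss = mag_int / T
    denom = np.maximum(mag_int, 1e-300)
    osi = 0.5 * (1.0 - np.linalg.norm(vec_int, axis=1) / denom)
    osi[mag_int <= 1e-300] = 0.0
    osi = np.clip(osi, 0.0, 0.5)

    a = wss.areas
    mean_tawss = float(a @ tawss / a.sum())
    mean_osi = float(a @ osi / a.sum())
    ok = wss.valid
    p99 = weighted_quantile(tawss[ok], a[ok], 0.99)
    reg_t, reg_o = {}, {}
    for r in REGIONS:
        m = wss.regions == r
        reg_t[r] = float(a[m] @ tawss[m] / a[m].sum()) if np.any(m) else np.nan
        reg_o[r] = float(a[m] @ osi[m] / a[m].sum()) if np.any(m) else np.nan
    return WSSIndices(tawss=tawss, osi=osi, areas=a, regions=wss.regions,
                      valid=ok, mean_tawss=mean_tawss, tawss_p99=p99,
                      mean_osi=mean_osi, regional_mean_tawss=reg_t,
                      regional_mean_osi=reg_o)


def percent_diff(other: float, ref: float, eps: float = 1e-300) -> float:
    """Signed percent difference 100 (other - ref)/ref.

    Exactly zero when the values agree within machine noise; NaN (flagged,
    never silently dropped) when the reference vanishes but the values
    differ.
    """
    if np.isnan(ref) or np.isnan(other):
        # both undefined (e.g. an empty region on both sides) compares equal
        return 0.0 if np.isnan(ref) and np.isnan(other) else np.nan
    if abs(ref) < 1e-12 * max(abs(other), 1.0) + eps:
        return 0.0 if abs(other - ref) < 1e-12 * max(abs(other), 1.0) + eps else np.nan
    return 100.0 * (other - ref) / ref


@dataclass
class WSSDiff:
    """Per-face absolute differences and regional percent differences of
    WSS indices between one BC variant and the 3D reference."""

    d_tawss: np.ndarray   # per-face |difference|, Pa
    d_osi: np.ndarray
    percent_tawss: dict   # region (+ "whole", "p99") -> signed %
    percent_osi: dict


def diff_maps(reference: WSSIndices, other: WSSIndices) -> WSSDiff:
    """Absolute-difference maps and regional percent differences vs reference."""
    if reference.tawss.shape != other.tawss.shape or not np.array_equal(
        reference.regions, other.regions
    ):
        raise ValueError("WSS indices are defined on different meshes")
    pt = {"whole": percent_diff(other.mean_tawss, reference.mean_tawss),
          "p99": percent_diff(other.tawss_p99, reference.tawss_p99)}
    po = {"whole": percent_diff(other.mean_osi, reference.mean_osi)}
    for r in REGIONS:
        pt[r] = percent_diff(other.regional_mean_tawss[r], reference.regional_mean_tawss[r])
        po[r] = percent_diff(other.regional_mean_osi[r], reference.regional_mean_osi[r])
    return WSSDiff(
        d_tawss=np.abs(other.tawss - reference.tawss),
        d_osi=np.abs(other.osi - reference.osi),
        percent_tawss=pt,
        percent_osi=po,
    )


@dataclass
class SpatioTemporalMap:
    """Unwrapped |WSS| along a wall contour (rows) over the cycle (columns).

    ``coordinate`` is the normalized arc length in [0, 1) around the closed
    contour cut by the analysis plane.
    """

    coordinate: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_contour_faces, n_times), Pa
    plane_s: float


def spatiotemporal_map(wss: WSSField, plane_s: float, mesh: TubeMesh | None = None) -> SpatioTemporalMap:
    """|WSS| sampled around the wall contour cut by the plane s = plane_s.

    Faces intersected by the plane are ordered by angle about the contour
    centroid; the coordinate is their cumulative arc length normalized to
    [0, 1).  Raises if the plane misses the wall or the cut faces do not
    form a single closed contour.
    """
    cz = wss.centroids[:, 2]
    # face axial extent on the structured tube: uniform spacing
    zs = np.unique(np.round(cz, 12))
    dz = np.min(np.diff(zs)) if len(zs) > 1 else np.inf
    sel = np.abs(cz - plane_s) <= dz / 2 + 1e-12
    if not np.any(sel):
        raise ValueError("analysis plane does not intersect the wall")
    idx = np.where(sel)[0]
    # keep the single closest axial ring
    ring_z = cz[idx][np.argmin(np.abs(cz[idx] - plane_s))]
    idx = idx[np.isclose(cz[idx], ring_z)]
    pts = wss.centroids[idx]
    ctr = pts.mean(axis=0)
    ang = np.mod(np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0]), 2 * np.pi)
    order = np.argsort(ang)
    idx = idx[order]
    pts = pts[order]
    gaps = np.diff(np.concatenate([ang[order], [ang[order][0] + 2 * np.pi]]))
    if len(idx) < 3 or np.max(gaps) > 4 * (2 * np.pi / len(idx)):
        raise ValueError(
            "cut faces do not form a single closed contour (plane may cut a "
            "branch or lie outside the tubular wall)"
        )
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    coord = arc / (arc[-1] + seg[-1])
    return SpatioTemporalMap(coordinate=coord, times=wss.times.copy(),
                             values=wss.magnitude[:, idx].T, plane_s=float(plane_s))
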