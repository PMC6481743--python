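"""Weighted least-squares gradient reconstruction on structured tube meshes.

Both the wall-shear and helicity modules need spatial velocity gradients.
They are reconstructed by fitting a local linear model over a stencil of
neighbouring nodes with inverse-square-distance weights; because the fit is
linear in the nodal values, each stencil reduces to a precomputed operator
matrix that is applied to every time step and vector component at once.
"""

from __future__ import annotations

import numpy as np

from .mesh import TubeMesh


def _lsq_operator(dx: np.ndarray, with_constant: bool) -> np.ndarray:
    """Gradient rows of the weighted LSQ pseudo-inverse for offsets ``dx``.

    Returns G (3, m) such that grad = G @ values (values relative to the
    centre value when ``with_constant`` is False).
    """
    d = np.linalg.norm(dx, axis=1)
    w = 1.0 / np.maximum(d, 1e-300) ** 2
    sw = np.sqrt(w)
    if with_constant:
        A = np.column_stack([np.ones(len(dx)), dx]) * sw[:, None]
        pinv = np.linalg.pinv(A, rcond=1e-10)
        return pinv[1:, :] * sw[None, :]
    A = dx * sw[:, None]
    pinv = np.linalg.pinv(A, rcond=1e-10)
    return pinv * sw[None, :]


def node_gradient_operators(mesh: TubeMesh):
    """Per-node LSQ gradient operators over index-space neighbours.

    Returns (stencils, ops): for node n, ``grad f(n) = ops[n] @ (f[stencils[n]]
    - f[n])`` — the constant term is pinned to the nodal value.
    """
    st = mesh.require_structure()
    pos = mesh.node_positions
    nr, nc, nz = st.n_radial, st.n_circ, st.n_axial
    stencils, ops = [], []
    for k in range(nz + 1):
        ks = [kk for kk in (k - 1, k, k + 1) if 0 <= kk <= nz]
        # axis node: neighbours = full first ring (this and adjacent slices)
        nb = [int(st.node_index(0, 0, kk)) for kk in ks if kk != k]
        nb += [int(st.node_index(1, j, kk)) for kk in ks for j in range(nc)]
        stencils.append(np.array(nb, dtype=int))
        for i in range(1, nr + 1):
            for j in range(nc):
                nb = []
                for kk in ks:
                    for ii in (i - 1, i, i + 1):
                        if ii < 0 or ii > nr:
                            continue
                        if ii == 0:
                            nb.append(int(st.node_index(0, 0, kk)))
                        else:
                            for jj in (j - 1, j, j + 1):
                                if ii == i and jj == j and kk == k:
                                    continue
                                nb.append(int(st.node_index(ii, jj, kk)))
                stencils.append(np.unique(np.array(nb, dtype=int)))
    for n, nb in enumerate(stencils):
        ops.append(_lsq_operator(pos[nb] - pos[n], with_constant=False))
    return stencils, ops


def wall_face_gradient_operators(mesh: TubeMesh):
    """Per-wall-face LSQ gradient operators.

    The stencil is the owner hexahedron of the face (its two outermost
    radial rings over the face's azimuthal and axial extent); keeping the
    stencil compact matters on the curved wall, where a wide azimuthal
    spread would fold wall curvature into the linear fit.  The constant
    term is a free parameter since the face centroid is not a node.
    Returns (stencils, ops) with ``grad f(face) = ops[f] @ f[stencils[f]]``.
    """
    st = mesh.require_structure()
    pos = mesh.node_positions
    nr, nc, nz = st.n_radial, st.n_circ, st.n_axial
    stencils, ops = [], []
    for f in range(mesh.wall_faces.shape[0]):
        k = f // nc
        j = f % nc
        nb = []
        for kk in (k, k + 1):
            for ii in (nr - 1, nr):
                for jj in (j, j + 1):
                    nb.append(int(st.node_index(ii, jj, kk)))
        nb = np.unique(np.array(nb, dtype=int))
        stencils.append(nb)
        ops.append(_lsq_operator(pos[nb] - mesh.wall_face_centroids[f], with_constant=True))
    return stencils, ops


def node_velocity_gradients(values: np.ndarray, stencils, ops) -> np.ndarray:
    """Velocity-gradient tensors at every node.

    values : (T, N, 3) nodal velocities.  Returns (T, N, 3, 3) with
    ``grad[t, n, g, c] = d v_c / d x_g`` at node n.
    """
    T, N, _ = values.shape
    out = np.empty((T, N, 3, 3))
    for n, (nb, G) in enumerate(zip(stencils, ops)):
        diff = values[:, nb, :] - values[:, n : n + 1, :]  # (T, m, 3)
        out[:, n] = np.einsum("gm,tmc->tgc", G, diff)
    return out


def face_velocity_gradients(values: np.ndarray, stencils, ops) -> np.ndarray:
    """Velocity-gradient tensors at wall-face centroids: (T, F, 3, 3)."""
    T = values.shape[0]
    F = len(stencils)
    out = np.empty((T, F, 3, 3))
    for f, (nb, G) in enumerate(zip(stencils, ops)):
        out[:, f] = np.einsum("gm,tmc->tgc", G, values[:, nb, :])
    return out
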