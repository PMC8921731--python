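"""JIT-compiled forward-kinematics / Jacobian kernel.

The inverse-kinematics solver evaluates marker positions and their Jacobian
thousands of times per Monte Carlo run; this module holds a numba version of
the recursion in :meth:`KinematicModel.marker_jacobian`.  The pure-numpy
implementation in ``model.py`` remains the reference; a test asserts both
paths agree to machine precision.  Joint type codes: 0 free6, 1 ball3,
2 hinge1, 3 locked0.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@njit(cache=False, fastmath=False)
def fk_marker_jac(parent_idx, jtype, dof_start, R_jp, o_jp, R_jci, o_jci,
                  q, marker_seg, marker_local, dm_idx, dm_off, dof_is_rot,
                  want_jac):  # pragma: no cover - exercised via python wrapper
    n = parent_idx.shape[0]
    ndof = q.shape[0]
    nm = marker_seg.shape[0]
    R = np.empty((n, 3, 3))
    p = np.empty((n, 3))
    axis = np.zeros((ndof, 3))
    point = np.zeros((ndof, 3))
    for i in range(n):
        par = parent_idx[i]
        if par < 0:
            Rp = np.eye(3)
            pp = np.zeros(3)
        else:
            Rp = R[par]
            pp = p[par]
        W = Rp @ R_jp[i]
        ow = pp + Rp @ o_jp[i]
        jt = jtype[i]
        s = dof_start[i]
        Rq = np.eye(3)
        if jt == 0:  # free6: tx ty tz rx ry rz
            ow = ow + W @ q[s:s + 3]
            cx, sx = np.cos(q[s + 3]), np.sin(q[s + 3])
            cy, sy = np.cos(q[s + 4]), np.sin(q[s + 4])
            cz, sz = np.cos(q[s + 5]), np.sin(q[s + 5])
            Rx = np.array(((1.0, 0.0, 0.0), (0.0, cx, -sx), (0.0, sx, cx)))
            Ry = np.array(((cy, 0.0, sy), (0.0, 1.0, 0.0), (-sy, 0.0, cy)))
            Rz = np.array(((cz, -sz, 0.0), (sz, cz, 0.0), (0.0, 0.0, 1.0)))
            Rq = Rx @ Ry @ Rz
            if want_jac:
                for k in range(3):
                    axis[s + k] = W[:, k]
                WRx = W @ Rx
                axis[s + 3] = W[:, 0]
                axis[s + 4] = WRx[:, 1]
                axis[s + 5] = (WRx @ Ry)[:, 2]
                for k in range(3):
                    point[s + 3 + k] = ow
        elif jt == 1:  # ball3: intrinsic x-y-z
            cx, sx = np.cos(q[s]), np.sin(q[s])
            cy, sy = np.cos(q[s + 1]), np.sin(q[s + 1])
            cz, sz = np.cos(q[s + 2]), np.sin(q[s + 2])
            Rx = np.array(((1.0, 0.0, 0.0), (0.0, cx, -sx), (0.0, sx, cx)))
            Ry = np.array(((cy, 0.0, sy), (0.0, 1.0, 0.0), (-sy, 0.0, cy)))
            Rz = np.array(((cz, -sz, 0.0), (sz, cz, 0.0), (0.0, 0.0, 1.0)))
            Rq = Rx @ Ry @ Rz
            if want_jac:
                WRx = W @ Rx
                axis[s] = W[:, 0]
                axis[s + 1] = WRx[:, 1]
                axis[s + 2] = (WRx @ Ry)[:, 2]
                for k in range(3):
                    point[s + k] = ow
        elif jt == 2:  # hinge1 about z
            cz, sz = np.cos(q[s]), np.sin(q[s])
            Rq = np.array(((cz, -sz, 0.0), (sz, cz, 0.0), (0.0, 0.0, 1.0)))
            if want_jac:
                axis[s] = W[:, 2]
                point[s] = ow
        Rj = W @ Rq
        R[i] = Rj @ R_jci[i]
        p[i] = ow + Rj @ o_jci[i]

    mk = np.empty((nm, 3))
    for m in range(nm):
        sidx = marker_seg[m]
        mk[m] = p[sidx] + R[sidx] @ marker_local[m]
    J = np.zeros((3 * nm, ndof))
    if want_jac:
        for d in range(ndof):
            a0, a1, a2 = axis[d, 0], axis[d, 1], axis[d, 2]
            if dof_is_rot[d]:
                for j in range(dm_off[d], dm_off[d + 1]):
                    m = dm_idx[j]
                    r0 = mk[m, 0] - point[d, 0]
                    r1 = mk[m, 1] - point[d, 1]
                    r2 = mk[m, 2] - point[d, 2]
                    J[3 * m, d] = a1 * r2 - a2 * r1
                    J[3 * m + 1, d] = a2 * r0 - a0 * r2
                    J[3 * m + 2, d] = a0 * r1 - a1 * r0
            else:
                for j in range(dm_off[d], dm_off[d + 1]):
                    m = dm_idx[j]
                    J[3 * m, d] = a0
                    J[3 * m + 1, d] = a1
                    J[3 * m + 2, d] = a2
    return R, p, mk, J
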