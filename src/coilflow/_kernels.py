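"""Numba-accelerated spatial kernels for the non-periodic solver path.

Each kernel replicates the vectorised numpy implementation in
:mod:`coilflow.solver` exactly (same stencils, same edge clamping); the
numpy versions remain the reference and serve the streamwise-periodic mode.
If numba is unavailable the solver falls back to numpy transparently.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def advect_kernel(u, v, dx):
    """Second-order upwind advection terms for both velocity components
    (first order on the boundary ring via index clamping)."""
    nxu, ny = u.shape
    nx = v.shape[0]
    nyv = v.shape[1]
    adv_u = np.empty_like(u)
    adv_v = np.empty_like(v)
    dx2 = 2.0 * dx

    for i in range(nxu):
        im = i - 1 if i - 1 >= 0 else 0
        ip = i if i <= nx - 1 else nx - 1
        for j in range(ny):
            vbar = 0.25 * (v[im, j] + v[ip, j] + v[im, j + 1] + v[ip, j + 1])
            a = u[i, j]
            if a > 0:
                c1 = i - 1 if i - 1 >= 0 else 0
                c2 = i - 2 if i - 2 >= 0 else 0
                dudx = (3.0 * u[i, j] - 4.0 * u[c1, j] + u[c2, j]) / dx2
            else:
                c1 = i + 1 if i + 1 <= nxu - 1 else nxu - 1
                c2 = i + 2 if i + 2 <= nxu - 1 else nxu - 1
                dudx = (-3.0 * u[i, j] + 4.0 * u[c1, j] - u[c2, j]) / dx2
            if vbar > 0:
                c1 = j - 1 if j - 1 >= 0 else 0
                c2 = j - 2 if j - 2 >= 0 else 0
                dudy = (3.0 * u[i, j] - 4.0 * u[i, c1] + u[i, c2]) / dx2
            else:
                c1 = j + 1 if j + 1 <= ny - 1 else ny - 1
                c2 = j + 2 if j + 2 <= ny - 1 else ny - 1
                dudy = (-3.0 * u[i, j] + 4.0 * u[i, c1] - u[i, c2]) / dx2
            adv_u[i, j] = a * dudx + vbar * dudy

    for i in range(nx):
        for j in range(nyv):
            jm = j - 1 if j - 1 >= 0 else 0
            jp = j if j <= ny - 1 else ny - 1
            ubar = 0.25 * (u[i, jm] + u[i + 1, jm] + u[i, jp] + u[i + 1, jp])
            if ubar > 0:
                c1 = i - 1 if i - 1 >= 0 else 0
                c2 = i - 2 if i - 2 >= 0 else 0
                dvdx = (3.0 * v[i, j] - 4.0 * v[c1, j] + v[c2, j]) / dx2
            else:
                c1 = i + 1 if i + 1 <= nx - 1 else nx - 1
                c2 = i + 2 if i + 2 <= nx - 1 else nx - 1
                dvdx = (-3.0 * v[i, j] + 4.0 * v[c1, j] - v[c2, j]) / dx2
            a = v[i, j]
            if a > 0:
                c1 = j - 1 if j - 1 >= 0 else 0
                c2 = j - 2 if j - 2 >= 0 else 0
                dvdy = (3.0 * v[i, j] - 4.0 * v[i, c1] + v[i, c2]) / dx2
            else:
                c1 = j + 1 if j + 1 <= nyv - 1 else nyv - 1
                c2 = j + 2 if j + 2 <= nyv - 1 else nyv - 1
                dvdy = (-3.0 * v[i, j] + 4.0 * v[i, c1] - v[i, c2]) / dx2
            adv_v[i, j] = ubar * dvdx + a * dvdy

    return adv_u, adv_v


@njit(cache=True)
def diffuse_kernel(u, v, mu_c, dx, rho):
    """Divergence of the full variable-viscosity stress tensor at u and v
    faces (no-slip ghosts in y; inlet reflect / outlet copy ghosts in x)."""
    nxu, ny = u.shape
    nx = mu_c.shape[0]
    nyv = v.shape[1]
    dif_u = np.empty_like(u)
    dif_v = np.empty_like(v)
    inv2 = 1.0 / dx**2

    # strain du/dy + dv/dx and viscosity at nodes
    S = np.empty((nxu, ny + 1))
    mu_n = np.empty((nxu, ny + 1))
    for i in range(nxu):
        il = i - 1 if i - 1 >= 0 else 0
        ir = i if i <= nx - 1 else nx - 1
        for k in range(ny + 1):
            if k == 0:
                dudy = 2.0 * u[i, 0] / dx
            elif k == ny:
                dudy = -2.0 * u[i, ny - 1] / dx
            else:
                dudy = (u[i, k] - u[i, k - 1]) / dx
            if i == 0:
                dvdx = 2.0 * v[0, k] / dx
            elif i == nxu - 1:
                dvdx = 0.0
            else:
                dvdx = (v[i, k] - v[i - 1, k]) / dx
            S[i, k] = dudy + dvdx
            kb = k - 1 if k - 1 >= 0 else 0
            kt = k if k <= ny - 1 else ny - 1
            mu_n[i, k] = 0.25 * (mu_c[il, kb] + mu_c[ir, kb] + mu_c[il, kt] + mu_c[ir, kt])

    for i in range(nxu):
        il = i - 1 if i - 1 >= 0 else 0
        ir = i if i <= nx - 1 else nx - 1
        i_m = i - 1 if i - 1 >= 0 else 0
        i_p = i + 1 if i + 1 <= nxu - 1 else nxu - 1
        for j in range(ny):
            t1 = 2.0 * (mu_c[ir, j] * (u[i_p, j] - u[i, j])
                        - mu_c[il, j] * (u[i, j] - u[i_m, j])) * inv2
            t2 = (mu_n[i, j + 1] * S[i, j + 1] - mu_n[i, j] * S[i, j]) / dx
            dif_u[i, j] = (t1 + t2) / rho

    for i in range(nx):
        for j in range(nyv):
            jb = j - 1 if j - 1 >= 0 else 0
            jt = j if j <= ny - 1 else ny - 1
            j_m = j - 1 if j - 1 >= 0 else 0
            j_p = j + 1 if j + 1 <= nyv - 1 else nyv - 1
            t1 = 2.0 * (mu_c[i, jt] * (v[i, j_p] - v[i, j])
                        - mu_c[i, jb] * (v[i, j] - v[i, j_m])) * inv2
            t2 = (mu_n[i + 1, j] * S[i + 1, j] - mu_n[i, j] * S[i, j]) / dx
            dif_v[i, j] = (t1 + t2) / rho

    return dif_u, dif_v


@njit(cache=True)
def shear_rate_kernel(u, v, dx):
    """Shear-rate magnitude sqrt(2 D:D) at cell centres (central
    differences, one-sided at domain edges, matching numpy.gradient)."""
    nx, ny = u.shape[0] - 1, u.shape[1]
    gam = np.empty((nx, ny))
    uc = np.empty((nx, ny))
    vc = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            uc[i, j] = 0.5 * (u[i, j] + u[i + 1, j])
            vc[i, j] = 0.5 * (v[i, j] + v[i, j + 1])
    for i in range(nx):
        for j in range(ny):
            dudx = (u[i + 1, j] - u[i, j]) / dx
            dvdy = (v[i, j + 1] - v[i, j]) / dx
            if j == 0:
                dudy = (uc[i, 1] - uc[i, 0]) / dx
            elif j == ny - 1:
                dudy = (uc[i, ny - 1] - uc[i, ny - 2]) / dx
            else:
                dudy = (uc[i, j + 1] - uc[i, j - 1]) / (2.0 * dx)
            if i == 0:
                dvdx = (vc[1, j] - vc[0, j]) / dx
            elif i == nx - 1:
                dvdx = (vc[nx - 1, j] - vc[nx - 2, j]) / dx
            else:
                dvdx = (vc[i + 1, j] - vc[i - 1, j]) / (2.0 * dx)
            gam[i, j] = np.sqrt(2.0 * (dudx * dudx + dvdy * dvdy)
                                + (dudy + dvdx) ** 2)
    return gam
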