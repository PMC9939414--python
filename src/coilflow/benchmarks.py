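"""Analytic channel benchmarks for the flow solver.

Each benchmark runs the full 2D solver in a configuration with a closed-form
solution and reports the measured value, the analytic value and the relative
error:

* ``poiseuille`` — steady Newtonian plane channel, inlet/outlet driven;
  centerline velocity 1.5*U and wall shear 6*mu*U/h.
* ``womersley`` — oscillatory body-force-driven flow in a streamwise-periodic
  channel at Womersley number alpha; centerline amplitude against the exact
  complex solution.
* ``darcy`` — periodic channel entirely filled with coil; bulk velocity
  against Darcy's law (K/mu)|dp/dx|.
* ``casson-channel`` — steady body-force-driven channel with the regularised
  Casson viscosity; centerline/bulk velocity against a shear-stress-inversion
  quadrature oracle.

The periodic benchmarks use a body force instead of an inlet so the
comparison is free of entrance-length effects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .geometry import GeometryParams, build_geometry
from .indices import WallProbe, _BilinearSampler
from .rheology import RheologyParams, casson_viscosity
from .solver import CoilModel, Solver, SolverConfig

__all__ = [
    "channel_geometry",
    "poiseuille_benchmark",
    "womersley_benchmark",
    "darcy_benchmark",
    "casson_channel_benchmark",
    "casson_channel_oracle",
    "run_benchmarks",
]


def channel_geometry(width: float = 4.0e-3, ny_gap: int = 64, nx: int = 8):
    """Straight (dome-free) channel geometry spanning the full grid height."""
    dx = width / ny_gap
    length = nx * dx
    params = GeometryParams(
        channel_width=width,
        channel_length=length,
        neck_width=min(width / 4, 0.4 * length),
        dome1_radius=0.0,
        dome2_radius=0.0,
        dome_offset=1.0e-3,
        grid_nx=nx,
        grid_ny=ny_gap,
        dx=dx,
    )
    return build_geometry(params)


_NEWTONIAN = RheologyParams(H=0.0, newtonian=True)


def poiseuille_benchmark(ny_gap: int = 64, u_mean: float = 0.3, t_run: float = 0.15):
    """Steady plane Poiseuille flow, inlet-driven.

    The run is initialised from the analytic parabola and integrated to a
    steady state; the reported errors measure how far the discrete steady
    solution drifts from the exact one.
    """
    width = 4.0e-3
    geo = channel_geometry(width=width, ny_gap=ny_gap, nx=2 * ny_gap)
    cfg = SolverConfig()
    solver = Solver(geo, _NEWTONIAN, config=cfg, inflow=lambda t: u_mean)
    solver.u[:] = solver.inlet_profile[None, :] * u_mean
    dt = solver.stable_dt()
    n = int(np.ceil(t_run / dt))
    for _ in range(n):
        solver.step(dt)

    lx = geo.nx * geo.dx
    pt = np.array([[0.6 * lx, width / 2.0]])
    uc, _ = solver.state.cell_velocity()
    u_center = _BilinearSampler(pt, geo.dx, geo.nx, geo.ny)(uc).item()
    u_exact = 1.5 * u_mean

    probe = WallProbe(geo, _NEWTONIAN)
    tau, _ = probe.evaluate(solver.state)
    sel = probe.valid & (geo.wall_xy[:, 0] > 0.3 * lx) & (geo.wall_xy[:, 0] < 0.85 * lx)
    tau_meas = float(np.mean(np.abs(tau[sel])))
    tau_exact = 6.0 * _NEWTONIAN.mu_inf * u_mean / width

    return {
        "centerline": {
            "measured": u_center,
            "analytic": u_exact,
            "rel_err": abs(u_center - u_exact) / u_exact,
        },
        "wall_shear": {
            "measured": tau_meas,
            "analytic": tau_exact,
            "rel_err": abs(tau_meas - tau_exact) / tau_exact,
        },
        "max_divergence": float(np.max(np.abs(solver.divergence()))),
        "max_solid_speed": solver.max_solid_speed(),
    }


def womersley_analytic_centerline(g0: float, omega: float, nu: float, h: float) -> float:
    """Centerline amplitude of oscillatory channel flow driven by the body
    force g0*cos(omega*t): |(g0/(i omega)) (1 - 1/cosh(lambda h))|."""
    lam = np.sqrt(1j * omega / nu)
    return float(np.abs(g0 / (1j * omega) * (1.0 - 1.0 / np.cosh(lam * h))))


def womersley_benchmark(alpha: float = 3.0, ny_gap: int = 64, n_periods: int = 5):
    """Oscillatory flow at Womersley number alpha in a periodic channel."""
    width = 4.0e-3
    h = width / 2.0
    nu = _NEWTONIAN.mu_inf / _NEWTONIAN.rho
    omega = alpha**2 * nu / h**2
    period = 2.0 * np.pi / omega
    # The analytic comparison is linear in the forcing amplitude; a modest
    # g0 keeps the advective CFL small at the coarse time step set by the
    # oscillation period.
    g0 = 0.2  # m/s^2, sets a ~0.03 m/s centerline amplitude

    geo = channel_geometry(width=width, ny_gap=ny_gap, nx=4)
    solver = Solver(
        geo, _NEWTONIAN, config=SolverConfig(), periodic_x=True,
        body_force=lambda t: g0 * np.cos(omega * t),
    )
    dt = period / 1500.0
    n_per = int(round(period / dt))
    pt = np.array([[2.0 * geo.dx, width / 2.0]])
    sampler = _BilinearSampler(pt, geo.dx, geo.nx, geo.ny)
    amp = 0.0
    for k in range(n_periods * n_per):
        solver.step(dt)
        if k >= (n_periods - 1) * n_per:
            uc, _ = solver.state.cell_velocity()
            amp = max(amp, abs(sampler(uc).item()))
    exact = womersley_analytic_centerline(g0, omega, nu, h)
    return {
        "alpha": alpha,
        "centerline_amplitude": {
            "measured": amp,
            "analytic": exact,
            "rel_err": abs(amp - exact) / exact,
        },
    }


def darcy_benchmark(porosity: float = 0.79, d_w: float = 2.5e-4,
                    dpdx: float = 900.0, ny_gap: int = 64):
    """Darcy-limit porous channel: bulk velocity = (K/mu)|dp/dx|.

    The channel is filled with coil across its full section; the bulk is
    measured over the core region away from the thin Brinkman wall layers.
    """
    width = 8.0e-3
    geo = channel_geometry(width=width, ny_gap=ny_gap, nx=4)
    geo = dataclasses.replace(geo, coil_mask=geo.lumen_mask.copy())
    coil = CoilModel(porosity=porosity, wire_diameter=d_w)
    g = dpdx / _NEWTONIAN.rho
    solver = Solver(
        geo, _NEWTONIAN, coil=coil, config=SolverConfig(), periodic_x=True,
        body_force=lambda t: g,
    )
    dt = 5.0e-4
    for _ in range(800):
        solver.step(dt)
    uc, _ = solver.state.cell_velocity()
    yc = geo.y_centers
    core = np.abs(yc - width / 2.0) < 0.25 * width
    u_bulk = float(np.mean(uc[:, core]))
    u_exact = coil.K * dpdx / _NEWTONIAN.mu_inf
    return {
        "K": coil.K,
        "bulk_velocity": {
            "measured": u_bulk,
            "analytic": u_exact,
            "rel_err": abs(u_bulk - u_exact) / u_exact,
        },
    }


def casson_channel_oracle(rheology: RheologyParams, dpdx: float, width: float,
                          n: int = 2000):
    """Steady Casson channel flow by shear-stress inversion.

    In a plane channel the shear stress varies linearly, tau(y') = G*y' with
    y' the distance from the centerline.  The local shear rate solves
    ``mu(gdot)*gdot = tau`` (monotone, bracketed root) and the velocity is
    its quadrature from the no-slip wall.  Returns (y, u, u_center, u_bulk).
    """
    h = width / 2.0
    yp = np.linspace(0.0, h, n)  # distance from centerline
    gdot = np.zeros(n)
    for i, y in enumerate(yp):
        tau = dpdx * y
        if tau <= 0:
            continue
        f = lambda g: casson_viscosity(g, rheology) * g - tau
        hi = max(tau / rheology.mu_inf * 2.0, 1.0)
        gdot[i] = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-13)
    # u(y') = int_{y'}^{h} gdot dy''  (wall at y' = h)
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(gdot, yp, initial=0.0)
    u = cum[-1] - cum
    u_bulk = float(np.trapezoid(u, yp) / h)
    return yp, u, float(u[0]), u_bulk


def casson_channel_benchmark(H: float = 0.45, dpdx: float = 30.0,
                             ny_gap: int = 64, t_run: float = 3.0):
    """Steady Casson channel flow against the stress-inversion oracle."""
    width = 4.0e-3
    rheo = RheologyParams(H=H)
    geo = channel_geometry(width=width, ny_gap=ny_gap, nx=4)
    solver = Solver(
        geo, rheo, config=SolverConfig(), periodic_x=True,
        body_force=lambda t: dpdx / rheo.rho,
    )
    dt = 1.0e-3
    for _ in range(int(t_run / dt)):
        solver.step(dt)
    uc, _ = solver.state.cell_velocity()
    prof = uc.mean(axis=0)
    pt = np.array([[2.0 * geo.dx, width / 2.0]])
    u_center = _BilinearSampler(pt, geo.dx, geo.nx, geo.ny)(uc).item()
    u_bulk = float(np.mean(prof))
    _, _, uc_exact, ub_exact = casson_channel_oracle(rheo, dpdx, width)
    return {
        "centerline": {
            "measured": u_center,
            "analytic": uc_exact,
            "rel_err": abs(u_center - uc_exact) / uc_exact,
        },
        "bulk": {
            "measured": u_bulk,
            "analytic": ub_exact,
            "rel_err": abs(u_bulk - ub_exact) / ub_exact,
        },
    }


def run_benchmarks(which: str = "all") -> dict:
    """Run the named benchmark(s); returns a dict of result dicts."""
    table = {
        "poiseuille": poiseuille_benchmark,
        "womersley": womersley_benchmark,
        "darcy": darcy_benchmark,
        "casson-channel": casson_channel_benchmark,
    }
    if which != "all":
        if which not in table:
            raise ValueError(f"unknown benchmark {which!r}; choose from {sorted(table)}")
        return {which: table[which]()}
    return {name: fn() for name, fn in table.items()}
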