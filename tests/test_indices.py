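"""Wall indices: OSI/TAWSS quadrature, probes, comparisons."""

import numpy as np
import pytest

from coilflow import (
    ComparisonReport,
    FlowState,
    IndexReport,
    RheologyParams,
    WallProbe,
    WallSeries,
    compare_conditions,
    export_wall_loads,
    neck_plane_average_velocity,
    osi,
    osi_windowed,
    tawss,
)
from coilflow.indices import PHASE_NAMES


def brute_force_cycle_mean(tau, t, period):
    """Independent periodic trapezoid: explicit loop over wrap-closed segments."""
    n = len(t)
    total = np.zeros(tau.shape[1])
    for k in range(n):
        k2 = (k + 1) % n
        dt = (t[k2] - t[k]) % period
        total += 0.5 * dt * (tau[k] + tau[k2])
    return total / period


def make_series(tau, t=None, period=1.0, **kw):
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:
        tau = tau.reshape(-1, 1)
    if t is None:
        t = np.arange(tau.shape[0]) * period / tau.shape[0]
    s = np.arange(tau.shape[1]) * 1e-3
    return WallSeries(s=s, t=t, tau_w=tau, p_w=np.zeros_like(tau), period=period, **kw)


class TestOsi:
    def test_steady_series_is_zero(self):
        ser = make_series(np.full((16, 1), 2.5))
        assert osi(ser)[0] == 0.0

    def test_zero_mean_sinusoid_is_half(self):
        t = np.arange(32) / 32
        ser = make_series(np.sin(2 * np.pi * t).reshape(-1, 1), t=t)
        assert osi(ser)[0] == pytest.approx(0.5, abs=1e-12)

    def test_worked_three_sample_series(self):
        # {1, 1, -1} Pa at uniform spacing with periodic closure:
        # |mean| = 1/3, mean |tau| = 1, OSI = 0.5*(1 - 1/3) = 1/3
        ser = make_series([1.0, 1.0, -1.0])
        assert osi(ser, min_samples=3)[0] == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert tawss(ser, min_samples=3)[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_series_assigned_zero(self):
        ser = make_series(np.zeros((16, 2)))
        assert np.all(osi(ser) == 0.0)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="16 samples"):
            osi(make_series(np.ones((8, 1))))

    def test_bounds_and_oracle_on_random_series(self, rng):
        # 1000 random wall series, including jittered sampling, against the
        # brute-force quadrature
        for _ in range(1000):
            n = rng.integers(16, 40)
            m = rng.integers(1, 4)
            t = np.sort(rng.uniform(0, 1, n))
            t[0] = 0.0
            tau = rng.normal(scale=rng.uniform(0.1, 5), size=(n, m))
            ser = make_series(tau, t=t)
            val = osi(ser)
            assert np.all(val >= 0.0) and np.all(val <= 0.5)
            mean = np.abs(brute_force_cycle_mean(tau, t, 1.0))
            mean_abs = brute_force_cycle_mean(np.abs(tau), t, 1.0)
            expected = 0.5 * (1.0 - mean / mean_abs)
            assert np.max(np.abs(val - expected)) < 1e-12

    def test_sign_flip_invariance(self, rng):
        tau = rng.normal(size=(24, 5))
        a, b = make_series(tau), make_series(-tau)
        assert np.allclose(osi(a), osi(b), atol=1e-15)
        assert np.allclose(tawss(a), tawss(b), atol=1e-15)


class TestTawss:
    def test_steady_value(self):
        ser = make_series(np.full((16, 1), -3.0))
        assert tawss(ser)[0] == pytest.approx(3.0, abs=1e-14)

    def test_dominates_mean_shear(self, rng):
        tau = rng.normal(size=(32, 8))
        ser = make_series(tau)
        mean = np.abs(brute_force_cycle_mean(tau, ser.t, 1.0))
        assert np.all(tawss(ser) >= mean - 1e-14)


class TestWindowedOsi:
    def test_monotone_window_growth_for_oscillation(self):
        t = np.arange(64) / 64
        ser = make_series(np.sin(2 * np.pi * t).reshape(-1, 1), t=t)
        early = osi_windowed(ser, 0.3)[0]
        late = osi_windowed(ser, 0.999)[0]
        assert late > early
        assert late == pytest.approx(0.5, abs=2e-3)


class TestNeckVelocity:
    def test_uniform_field_recovers_magnitude(self, coarse_geometry):
        nx, ny = coarse_geometry.nx, coarse_geometry.ny
        V = 0.37
        state = FlowState(
            u=np.full((nx + 1, ny), V), v=np.zeros((nx, ny + 1)),
            p=np.zeros((nx, ny)), mu=np.zeros((nx, ny)), t=0.0,
        )
        val = neck_plane_average_velocity(state, coarse_geometry)
        assert val == pytest.approx(V, abs=1e-10)

    def test_quadrature_refinement(self, coarse_geometry):
        nx, ny = coarse_geometry.nx, coarse_geometry.ny
        x = coarse_geometry.x_centers[:, None]
        u = np.zeros((nx + 1, ny))
        u[:-1] = 0.1 + 20.0 * x  # smooth linear field
        u[-1] = u[-2]
        state = FlowState(u=u, v=np.zeros((nx, ny + 1)), p=np.zeros((nx, ny)),
                          mu=np.zeros((nx, ny)), t=0.0)
        v32 = neck_plane_average_velocity(state, coarse_geometry, n_samples=32)
        v64 = neck_plane_average_velocity(state, coarse_geometry, n_samples=64)
        assert abs(v64 - v32) / v64 < 0.005

    def test_rejects_few_samples(self, coarse_geometry):
        state = FlowState(
            u=np.zeros((coarse_geometry.nx + 1, coarse_geometry.ny)),
            v=np.zeros((coarse_geometry.nx, coarse_geometry.ny + 1)),
            p=np.zeros((coarse_geometry.nx, coarse_geometry.ny)),
            mu=np.zeros((coarse_geometry.nx, coarse_geometry.ny)), t=0.0,
        )
        with pytest.raises(ValueError):
            neck_plane_average_velocity(state, coarse_geometry, n_samples=8)


class TestWallProbe:
    def test_zero_field_gives_zero_stress(self, coarse_geometry, newtonian):
        probe = WallProbe(coarse_geometry, newtonian)
        nx, ny = coarse_geometry.nx, coarse_geometry.ny
        state = FlowState(u=np.zeros((nx + 1, ny)), v=np.zeros((nx, ny + 1)),
                          p=np.zeros((nx, ny)), mu=np.zeros((nx, ny)), t=0.0)
        tau, pw = probe.evaluate(state)
        assert np.all(tau == 0.0) and np.all(pw == 0.0)

    def test_orientation_flip_flips_sign(self, coarse_geometry, newtonian, rng):
        import dataclasses

        probe = WallProbe(coarse_geometry, newtonian)
        nx, ny = coarse_geometry.nx, coarse_geometry.ny
        state = FlowState(u=rng.normal(size=(nx + 1, ny)), v=rng.normal(size=(nx, ny + 1)),
                          p=np.zeros((nx, ny)), mu=np.zeros((nx, ny)), t=0.0)
        tau, _ = probe.evaluate(state)
        flipped = dataclasses.replace(
            coarse_geometry,
            wall_xy=coarse_geometry.wall_xy[::-1].copy(),
            wall_normals=coarse_geometry.wall_normals[::-1].copy(),
            wall_s=coarse_geometry.wall_s[::-1].copy(),
            wall_is_wall=coarse_geometry.wall_is_wall[::-1].copy(),
        )
        probe_f = WallProbe(flipped, newtonian)
        tau_f, _ = probe_f.evaluate(state)
        sel = probe.valid & probe_f.valid[::-1]
        assert np.allclose(tau_f[::-1][sel], -tau[sel], atol=1e-12)


class TestExportWallLoads:
    def _series(self, n_s=10, n_t=16):
        t = np.arange(n_t) / n_t
        tau = np.zeros((n_t, n_s))
        return make_series(tau, t=t), {n: 0.1 * (i + 1) for i, n in enumerate(PHASE_NAMES)}

    def test_zero_fields_full_shape(self):
        ser, phases = self._series()
        table = export_wall_loads(ser, phases)
        assert len(table) == 10 * 4
        assert (table["pressure_load"] == 0).all()

    def test_pressure_column_is_identity_export(self, rng):
        n_s, n_t = 7, 32
        t = np.arange(n_t) / n_t
        tau = rng.normal(size=(n_t, n_s))
        pw = rng.normal(size=(n_t, n_s))
        ser = WallSeries(s=np.arange(n_s) * 1e-3, t=t, tau_w=tau, p_w=pw, period=1.0)
        phases = {n: 0.2 * (i + 1) for i, n in enumerate(PHASE_NAMES)}
        table = export_wall_loads(ser, phases)
        k = int(np.argmin(np.abs(t - phases["peak_systole"])))
        block = table[table.phase == "peak_systole"]
        assert np.array_equal(block["pressure_load"].to_numpy(), pw[k])


def _report(label, H, phi, scale=1.0, ghash="abc"):
    vals = {n: scale * (i + 1.0) for i, n in enumerate(PHASE_NAMES)}
    return IndexReport(
        label=label, H=H, porosity=phi, geometry_hash=ghash,
        max_wss=dict(vals), wall_pressure_max=dict(vals),
        neck_avg_velocity=dict(vals), osi_windowed_max=dict(vals),
        max_osi=0.4 * scale, tawss_max=2.0 * scale, invalid_wall_fraction=0.0,
    )


class TestCompareConditions:
    def test_identical_reports_zero_reduction(self):
        reports = {"a": _report("a", 0.45, 0.89), "b": _report("b", 0.45, 0.79)}
        comp = compare_conditions(reports)
        assert all(r["pct_reduction"] == 0.0 for r in comp.rows)

    def test_halving_gives_fifty_percent(self):
        reports = {"a": _report("a", 0.45, 0.89), "b": _report("b", 0.45, 0.79, scale=0.5)}
        comp = compare_conditions(reports)
        assert all(r["pct_reduction"] == pytest.approx(50.0) for r in comp.rows)

    def test_antisymmetry_identity(self):
        # swapping reference and contrast maps r -> 100*(1 - 1/(1 - r/100))
        r_fwd = compare_conditions(
            {"a": _report("a", 0.45, 0.89), "b": _report("b", 0.45, 0.79, scale=0.5)}
        ).rows[0]["pct_reduction"]
        r_bwd = compare_conditions(
            {"a": _report("a", 0.45, 0.89, scale=0.5), "b": _report("b", 0.45, 0.79)}
        ).rows[0]["pct_reduction"]
        assert r_bwd == pytest.approx(100.0 * (1.0 - 1.0 / (1.0 - r_fwd / 100.0)))

    def test_default_six_conditions_enumerate_4_plus_2(self):
        reports = {}
        for h in (0.35, 0.45):
            for phi in (None, 0.89, 0.79):
                lbl = f"h{h}_p{phi}"
                reports[lbl] = _report(lbl, h, phi)
        comp = compare_conditions(reports)
        pairs = {(r["reference"], r["contrast"], r["kind"]) for r in comp.rows}
        kinds = [k for _, _, k in pairs]
        assert kinds.count("porosity") == 4
        assert kinds.count("hct") == 2

    def test_mismatched_geometry_rejected(self):
        reports = {"a": _report("a", 0.45, 0.89, ghash="x"),
                   "b": _report("b", 0.45, 0.79, ghash="y")}
        with pytest.raises(ValueError, match="geometr"):
            compare_conditions(reports)

    def test_roundtrip_dict(self):
        comp = compare_conditions(
            {"a": _report("a", 0.45, 0.89), "b": _report("b", 0.45, 0.79, scale=0.5)}
        )
        again = ComparisonReport.from_dict(comp.to_dict())
        assert again.rows == comp.rows
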