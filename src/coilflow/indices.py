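"""Hemodynamic wall indices: WSS, TAWSS, OSI, wall pressure, neck inflow.

Wall shear stress is extracted with a normal-probe scheme: at every wall
point the tangential velocity is sampled at 1.5*dx and 3*dx along the inward
normal by bilinear interpolation, and the wall-normal derivative is the
one-sided second-order difference anchored at the no-slip wall value.  In 2D
the WSS is a signed scalar along the wall tangent; OSI uses the signed value
while TAWSS and the per-phase maxima use the magnitude.

The oscillatory shear index follows the standard Ku definition,

    OSI = 0.5 * (1 - |<tau_w>| / <|tau_w|>),

with cycle averages <.> computed by periodic trapezoidal quadrature over the
final cycle; 0 marks unidirectional shear, 0.5 fully oscillatory shear.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import AneurysmGeometry
from .rheology import RheologyParams, casson_viscosity

__all__ = [
    "WallSeries",
    "WallProbe",
    "IndexReport",
    "ComparisonReport",
    "wall_shear_stress",
    "osi",
    "osi_windowed",
    "tawss",
    "neck_plane_average_velocity",
    "phase_metrics",
    "export_wall_loads",
    "compare_conditions",
]

SCHEMA_VERSION = 1
PHASE_NAMES = ("max_accel", "peak_systole", "max_decel", "early_diastole")


# ---------------------------------------------------------------------------
# wall series container


@dataclass
class WallSeries:
    """Signed wall shear stress and wall pressure along the wall chain over
    one cardiac cycle.

    ``t`` holds the sample instants within ``[0, period)`` (the periodic
    closure is implicit: the signal wraps); ``tau_w``/``p_w`` have shape
    ``(n_t, n_s)``.  ``valid`` marks wall points whose probes lie inside the
    lumen; ``fov`` marks the analysis field of view (sac wall plus parent
    wall within two channel widths of the neck).
    """

    s: np.ndarray
    t: np.ndarray
    tau_w: np.ndarray
    p_w: np.ndarray
    period: float
    valid: np.ndarray = None
    fov: np.ndarray = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.tau_w = np.atleast_2d(np.asarray(self.tau_w, dtype=float))
        self.p_w = np.atleast_2d(np.asarray(self.p_w, dtype=float))
        if self.valid is None:
            self.valid = np.ones(len(self.s), dtype=bool)
        if self.fov is None:
            self.fov = np.ones(len(self.s), dtype=bool)
        if not (np.isfinite(self.tau_w).all() and np.isfinite(self.p_w).all()):
            raise ValueError("wall series contains non-finite values")


def _cycle_weights(t: np.ndarray, period: float) -> np.ndarray:
    """Periodic trapezoidal weights for samples in [0, period) (wrap-around
    closure); reduces to uniform weights for uniform sampling."""
    t = np.asarray(t, dtype=float)
    tn = np.concatenate([t, [t[0] + period]])
    tp = np.concatenate([[t[-1] - period], t])
    return (tn[1:] - tp[:-1]) / 2.0


def _check_series(series: WallSeries, min_samples: int = 16) -> None:
    if series.tau_w.shape[0] < min_samples:
        raise ValueError(
            f"cycle quadrature needs at least {min_samples} samples, "
            f"got {series.tau_w.shape[0]}"
        )


def osi(series: WallSeries, min_samples: int = 16) -> np.ndarray:
    """Oscillatory shear index per wall point, in [0, 0.5].

    Points whose shear never changes sign score 0; a zero-mean oscillation
    scores 0.5; points with identically zero shear are assigned 0.
    ``min_samples`` guards the cycle quadrature (default 16); exact
    closed-form checks on shorter hand-built series may relax it.
    """
    _check_series(series, min_samples)
    w = _cycle_weights(series.t, series.period)[:, None]
    T = series.period
    mean = np.abs(np.sum(w * series.tau_w, axis=0)) / T
    mean_abs = np.sum(w * np.abs(series.tau_w), axis=0) / T
    out = np.zeros_like(mean)
    nz = mean_abs > 0
    out[nz] = 0.5 * (1.0 - mean[nz] / mean_abs[nz])
    return np.clip(out, 0.0, 0.5)


def osi_windowed(series: WallSeries, t_end: float) -> np.ndarray:
    """OSI accumulated over the partial cycle [t0, t_end].

    Mirrors per-instant OSI maps: the index is built from the shear history
    up to the given instant using ordinary (non-periodic) trapezoidal
    quadrature.  Early instants rest on few samples and are correspondingly
    coarse.
    """
    sel = series.t <= t_end + 1e-12
    if sel.sum() < 4:
        raise ValueError("windowed OSI needs at least 4 samples before t_end")
    t = series.t[sel]
    tau = series.tau_w[sel]
    mean = np.abs(np.trapezoid(tau, t, axis=0))
    mean_abs = np.trapezoid(np.abs(tau), t, axis=0)
    out = np.zeros_like(mean)
    nz = mean_abs > 0
    out[nz] = 0.5 * (1.0 - mean[nz] / mean_abs[nz])
    return np.clip(out, 0.0, 0.5)


def tawss(series: WallSeries, min_samples: int = 16) -> np.ndarray:
    """Time-averaged |tau_w| over the cycle, Pa (>= |time-mean tau_w|)."""
    _check_series(series, min_samples)
    w = _cycle_weights(series.t, series.period)[:, None]
    return np.sum(w * np.abs(series.tau_w), axis=0) / series.period


# ---------------------------------------------------------------------------
# wall probing


class _BilinearSampler:
    """Precomputed bilinear gather for cell-centered fields at fixed points."""

    def __init__(self, points: np.ndarray, dx: float, nx: int, ny: int):
        # cell-center c_i sits at (i + 0.5) dx
        fx = np.clip(points[:, 0] / dx - 0.5, 0.0, nx - 1.000001)
        fy = np.clip(points[:, 1] / dx - 0.5, 0.0, ny - 1.000001)
        i0 = np.floor(fx).astype(int)
        j0 = np.floor(fy).astype(int)
        tx = fx - i0
        ty = fy - j0
        self.idx = (i0, j0)
        self.w00 = (1 - tx) * (1 - ty)
        self.w10 = tx * (1 - ty)
        self.w01 = (1 - tx) * ty
        self.w11 = tx * ty

    def __call__(self, f: np.ndarray) -> np.ndarray:
        i0, j0 = self.idx
        return (
            self.w00 * f[i0, j0]
            + self.w10 * f[i0 + 1, j0]
            + self.w01 * f[i0, j0 + 1]
            + self.w11 * f[i0 + 1, j0 + 1]
        )


class WallProbe:
    """Normal-probe WSS and wall-pressure extractor bound to one geometry.

    Probe geometry, validity and the analysis field of view are precomputed
    once; evaluation per snapshot is a handful of vectorised gathers.
    """

    def __init__(self, geometry: AneurysmGeometry, rheology: RheologyParams):
        self.geo = geometry
        self.rheo = rheology
        dx = geometry.dx
        xy = geometry.wall_xy
        n_in = geometry.wall_normals
        p1 = xy + 1.5 * dx * n_in
        p2 = xy + 3.0 * dx * n_in

        # wall tangent follows the chain orientation
        fwd = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
        tl = np.linalg.norm(fwd, axis=1)
        tl[tl == 0] = 1.0
        self.tangent = fwd / tl[:, None]

        inside = lambda p: (
            (geometry.level(p[:, 0], p[:, 1]) < 0.0)
            & (p[:, 0] > 0) & (p[:, 0] < geometry.nx * dx)
            & (p[:, 1] > 0) & (p[:, 1] < geometry.ny * dx)
        )
        self.valid = geometry.wall_is_wall & inside(p1) & inside(p2)

        w = geometry.params.channel_width
        (xn1, yn1), (xn2, _) = geometry.neck_segment
        dxs = np.clip(xy[:, 0], min(xn1, xn2), max(xn1, xn2)) - xy[:, 0]
        dys = yn1 - xy[:, 1]
        dist_neck = np.hypot(dxs, dys)
        # sac wall strictly above the parent-wall line; the parent wall
        # enters the field of view only within two channel widths of the neck
        on_sac = xy[:, 1] > w + 0.5 * dx
        self.dist_neck = dist_neck
        self.fov = (on_sac | (dist_neck <= 2.0 * w)) & geometry.wall_is_wall

        nx, ny = geometry.nx, geometry.ny
        self._s1 = _BilinearSampler(p1, dx, nx, ny)
        self._s2 = _BilinearSampler(p2, dx, nx, ny)

    def evaluate(self, state) -> tuple[np.ndarray, np.ndarray]:
        """Signed tau_w (Pa) and wall pressure (Pa) along the chain.

        Invalid points (probes outside the lumen, or the open inlet/outlet
        ends of the chain) are returned as zero and must be excluded via
        ``self.valid``.
        """
        uc, vc = state.cell_velocity()
        ut1 = self._s1(uc) * self.tangent[:, 0] + self._s1(vc) * self.tangent[:, 1]
        ut2 = self._s2(uc) * self.tangent[:, 0] + self._s2(vc) * self.tangent[:, 1]
        dudn = (4.0 * ut1 - ut2) / (3.0 * self.geo.dx)
        mu_wall = casson_viscosity(np.abs(dudn), self.rheo)
        tau = mu_wall * dudn
        pw = self._s1(state.p)
        tau = np.where(self.valid, tau, 0.0)
        pw = np.where(self.valid, pw, 0.0)
        return tau, pw


def wall_shear_stress(state, geometry: AneurysmGeometry, rheology: RheologyParams):
    """One-shot signed WSS extraction (see :class:`WallProbe`).

    Returns ``(tau_w, valid)``; reuse a :class:`WallProbe` when evaluating
    many snapshots of the same geometry.
    """
    probe = WallProbe(geometry, rheology)
    tau, _ = probe.evaluate(state)
    return tau, probe.valid


def neck_plane_average_velocity(state, geometry: AneurysmGeometry, n_samples: int = 64) -> float:
    """Mean velocity magnitude over the neck plane, m/s.

    Samples ``n_samples`` points uniformly spaced strictly inside the neck
    segment (midpoint rule) with bilinear interpolation.
    """
    if n_samples < 32:
        raise ValueError("need at least 32 samples across the neck")
    (x1, y1), (x2, y2) = geometry.neck_segment
    frac = (np.arange(n_samples) + 0.5) / n_samples
    pts = np.column_stack([x1 + frac * (x2 - x1), y1 + frac * (y2 - y1)])
    if np.any(geometry.level(pts[:, 0], pts[:, 1]) > 0):
        raise ValueError("neck segment crosses solid material")
    sampler = _BilinearSampler(pts, geometry.dx, geometry.nx, geometry.ny)
    uc, vc = state.cell_velocity()
    return float(np.mean(np.hypot(sampler(uc), sampler(vc))))


# ---------------------------------------------------------------------------
# reports


@dataclass
class IndexReport:
    """Per-condition summary of the wall indices.

    Per-phase maxima are taken over valid wall points inside the field of
    view (sac wall + parent wall within two channel widths of the neck).
    ``osi_windowed_max`` accumulates shear history from cycle start to each
    phase instant; ``max_osi`` and ``tawss_max`` use the full final cycle.
    """

    label: str
    H: float
    porosity: float | None
    geometry_hash: str
    max_wss: dict
    wall_pressure_max: dict
    neck_avg_velocity: dict
    osi_windowed_max: dict
    max_osi: float
    tawss_max: float
    invalid_wall_fraction: float
    ke_sac_mean: float | None = None
    cycle_peak_wss: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IndexReport":
        return cls(**d)


def phase_metrics(
    series: WallSeries,
    snapshots: dict,
    phases: dict,
    geometry: AneurysmGeometry,
    rheology: RheologyParams,
    label: str = "",
    porosity: float | None = None,
    ke_sac_mean: float | None = None,
    cycle_peak_wss=None,
) -> IndexReport:
    """Assemble the per-phase index report from a wall series and the four
    phase snapshots."""
    missing = [n for n in PHASE_NAMES if n not in snapshots]
    if missing:
        raise ValueError(f"missing phase snapshots: {missing}")
    sel = series.valid & series.fov
    # invalid fraction over the analysis field of view (the open
    # inlet/outlet chain ends are not wall and are excluded by fov)
    invalid_fraction = 1.0 - (series.valid & series.fov).sum() / max(series.fov.sum(), 1)
    warnings = []
    if invalid_fraction > 0.10:
        warnings.append(
            f"{100 * invalid_fraction:.1f}% of wall points have probes outside the "
            "lumen (under-resolved wall); maxima exclude them"
        )

    max_wss, p_max, neck_v, osi_w = {}, {}, {}, {}
    for name in PHASE_NAMES:
        tp = phases[name]
        k = int(np.argmin(np.abs(series.t - tp)))
        max_wss[name] = float(np.max(np.abs(series.tau_w[k, sel])))
        p_max[name] = float(np.max(series.p_w[k, sel]))
        neck_v[name] = neck_plane_average_velocity(snapshots[name], geometry)
        try:
            ow = osi_windowed(series, tp)
            osi_w[name] = float(np.max(ow[sel]))
        except ValueError:
            osi_w[name] = float("nan")

    osi_full = osi(series)
    ta = tawss(series)
    return IndexReport(
        label=label,
        H=rheology.H,
        porosity=porosity,
        geometry_hash=geometry.params_hash(),
        max_wss=max_wss,
        wall_pressure_max=p_max,
        neck_avg_velocity=neck_v,
        osi_windowed_max=osi_w,
        max_osi=float(np.max(osi_full[sel])),
        tawss_max=float(np.max(ta[sel])),
        invalid_wall_fraction=float(invalid_fraction),
        ke_sac_mean=ke_sac_mean,
        cycle_peak_wss=[float(x) for x in cycle_peak_wss] if cycle_peak_wss is not None else [],
        warnings=warnings,
    )


def export_wall_loads(series: WallSeries, phases: dict):
    """Wall-load table for one-way coupling to a structural solver.

    One row per (wall point, phase): arc length, phase name, pressure load
    and shear traction at the phase instant.  Returns a pandas DataFrame
    (write with ``.to_csv``).
    """
    import pandas as pd

    rows = []
    for name in PHASE_NAMES:
        k = int(np.argmin(np.abs(series.t - phases[name])))
        rows.append(
            pd.DataFrame(
                {
                    "s": series.s,
                    "phase": name,
                    "pressure_load": series.p_w[k],
                    "shear_traction": series.tau_w[k],
                    "valid": series.valid,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# condition comparison


@dataclass
class ComparisonReport:
    """Pairwise percentage changes across study conditions.

    Each row compares metric values between a reference condition A and a
    contrast condition B as ``100*(A - B)/A`` (positive = reduction relative
    to the reference).  Reference order follows the study framing: higher
    porosity first (uncoiled -> 0.89 -> 0.79) and HCT 0.45 before 0.35.
    """

    rows: list
    schema_version: int = SCHEMA_VERSION

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_dict(self) -> dict:
        return {"rows": self.rows, "schema_version": self.schema_version}

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(rows=d["rows"], schema_version=d.get("schema_version", SCHEMA_VERSION))

    def select(self, kind=None, metric=None, phase=None):
        out = self.rows
        if kind is not None:
            out = [r for r in out if r["kind"] == kind]
        if metric is not None:
            out = [r for r in out if r["metric"] == metric]
        if phase is not None:
            out = [r for r in out if r["phase"] == phase]
        return out


_COMPARE_METRICS = ("max_wss", "osi_windowed_max", "wall_pressure_max", "neck_avg_velocity")


def _pct_reduction(a: float, b: float) -> float:
    return float("nan") if a == 0 else 100.0 * (a - b) / a


def _pairs(reports: dict):
    """Enumerate the study contrasts: the porosity chain per hematocrit and
    the HCT contrast at each coiled porosity."""
    by_cond = {(r.H, r.porosity): lbl for lbl, r in reports.items()}
    hcts = sorted({r.H for r in reports.values()}, reverse=True)
    poros = sorted({r.porosity for r in reports.values() if r.porosity is not None},
                   reverse=True)
    pairs = []
    for h in hcts:
        chain = [(h, None)] + [(h, p) for p in poros]
        chain = [c for c in chain if c in by_cond]
        for a, b in zip(chain[:-1], chain[1:]):
            pairs.append(("porosity", by_cond[a], by_cond[b]))
    if len(hcts) >= 2:
        h_hi, h_lo = hcts[0], hcts[1]
        for p in poros:
            if (h_hi, p) in by_cond and (h_lo, p) in by_cond:
                pairs.append(("hct", by_cond[(h_hi, p)], by_cond[(h_lo, p)]))
    return pairs


def compare_conditions(reports: dict) -> ComparisonReport:
    """Tabulate percentage reductions across HCT and porosity conditions.

    ``reports`` maps condition labels to :class:`IndexReport` objects on the
    same geometry (verified by hash).  Raises on mismatched geometries.
    """
    if len(reports) < 2:
        raise ValueError("need at least two condition reports to compare")
    hashes = {r.geometry_hash for r in reports.values()}
    if len(hashes) > 1:
        raise ValueError("reports computed on different geometries are not comparable")
    rows = []
    for kind, la, lb in _pairs(reports):
        ra, rb = reports[la], reports[lb]
        for metric in _COMPARE_METRICS:
            da, db = getattr(ra, metric), getattr(rb, metric)
            for phase in PHASE_NAMES:
                a, b = da[phase], db[phase]
                rows.append(
                    {
                        "kind": kind,
                        "reference": la,
                        "contrast": lb,
                        "metric": metric,
                        "phase": phase,
                        "a": a,
                        "b": b,
                        "pct_reduction": _pct_reduction(a, b),
                        "abs_diff": a - b,
                    }
                )
        rows.append(
            {
                "kind": kind,
                "reference": la,
                "contrast": lb,
                "metric": "max_osi",
                "phase": "cycle",
                "a": ra.max_osi,
                "b": rb.max_osi,
                "pct_reduction": _pct_reduction(ra.max_osi, rb.max_osi),
                "abs_diff": ra.max_osi - rb.max_osi,
            }
        )
    return ComparisonReport(rows=rows)
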