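"""Parametric bilobed-aneurysm geometry on a Cartesian grid.

The lumen is the union of a straight parent channel (a horizontal strip of
width ``channel_width``) and two overlapping circular domes that open into the
channel through a neck of width ``neck_width`` cut in the upper channel wall.
The geometry is represented by a Lipschitz level function (negative inside the
lumen), sampled on a uniform cell-centered grid, together with an ordered
wall-point chain extracted from the zero level set.  The coil occupying the
sac is a boolean cell mask filled from the dome tip toward the neck.

Everything here is deterministic and purely parametric: it stands in for a
patient-specific vessel while preserving the mechanisms the downstream
analysis probes (jet through the neck, twin recirculating domes, porous
damping of the sac).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "GeometryParams",
    "AneurysmGeometry",
    "build_geometry",
    "coil_mask",
]


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic double-dome aneurysm.

    Lengths are in metres.  The two domes are placed along a sac axis that
    starts at the neck midpoint on the upper channel wall and is tilted by
    ``sac_tilt`` radians from the vertical.  The proximal dome is positioned
    so that its circle intersects the upper wall exactly along the neck
    opening; the distal dome sits ``dome_offset`` further along the axis and
    must overlap the proximal dome so the sac is a single bilobed cavity.
    """

    channel_width: float = 4.0e-3
    channel_length: float = 26.0e-3
    neck_width: float = 3.0e-3
    dome1_radius: float = 3.0e-3
    dome2_radius: float = 2.4e-3
    dome_offset: float = 3.4e-3
    sac_tilt: float = 0.0
    grid_nx: int = 192
    grid_ny: int = 96
    dx: float = 26.0e-3 / 192

    def validate(self) -> None:
        if min(self.channel_width, self.channel_length, self.neck_width, self.dx) <= 0:
            raise ValueError("channel dimensions, neck width and dx must be positive")
        if self.dome1_radius < 0 or self.dome2_radius < 0:
            raise ValueError("dome radii must be non-negative")
        if self.neck_width >= self.channel_length:
            raise ValueError("neck_width must be smaller than channel_length")
        if self.grid_nx < 4 or self.grid_ny < 4:
            raise ValueError("grid must have at least 4 cells per direction")
        if self.dx * self.grid_nx < self.channel_length - 1e-12:
            raise ValueError("grid does not span the channel length (dx*grid_nx < channel_length)")
        if self.dome1_radius > 0 and self.dome2_radius > 0:
            if self.dome_offset >= self.dome1_radius + self.dome2_radius:
                raise ValueError(
                    "domes do not overlap (dome_offset >= r1 + r2): sac would be disconnected"
                )
        if self.dome1_radius > 0 and self.neck_width >= 2 * self.dome1_radius:
            raise ValueError("neck_width must be smaller than the proximal dome diameter")

    @property
    def domain_size(self) -> tuple[float, float]:
        return self.grid_nx * self.dx, self.grid_ny * self.dx

    @property
    def neck_center_x(self) -> float:
        return self.channel_length / 2.0

    def dome_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centres of the two domes (each ``None``-free 2-vector, metres)."""
        w = self.channel_width
        axis = np.array([np.sin(self.sac_tilt), np.cos(self.sac_tilt)])
        neck_mid = np.array([self.neck_center_x, w])
        if self.dome1_radius <= 0:
            return neck_mid, neck_mid
        # place dome 1 so that its circle meets the wall line y = w with a
        # chord of exactly neck_width (chord length depends only on the
        # perpendicular distance of the centre from the wall line)
        h1 = np.sqrt(max(self.dome1_radius**2 - (self.neck_width / 2) ** 2, 0.0))
        a1 = h1 / max(np.cos(self.sac_tilt), 1e-12)
        c1 = neck_mid + a1 * axis
        c2 = c1 + self.dome_offset * axis
        return c1, c2


def _strip_level(y: np.ndarray, width: float) -> np.ndarray:
    return np.maximum(y - width, -y)


def _disc_level(x: np.ndarray, y: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
    return np.hypot(x - center[0], y - center[1]) - r


@dataclass
class AneurysmGeometry:
    """Discretised lumen: level function, masks, wall chain and key segments.

    ``sdf`` is the level function at cell centres (negative inside the lumen);
    it is an exact signed distance for each primitive and a Lipschitz min over
    the union.  ``wall_xy``/``wall_normals``/``wall_s`` form a closed chain
    traversing the lumen boundary once, ordered by arc length,
    counter-clockwise.  ``wall_is_wall`` is False on the open inlet/outlet
    ends of the chain (no physical wall there).
    """

    params: GeometryParams
    dx: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    sdf: np.ndarray            # (nx, ny) cell centres
    sdf_node: np.ndarray       # (nx+1, ny+1) grid nodes
    lumen_mask: np.ndarray     # (nx, ny) bool
    coil_mask: np.ndarray      # (nx, ny) bool
    wall_xy: np.ndarray        # (n_wall, 2)
    wall_normals: np.ndarray   # (n_wall, 2) inward unit normals
    wall_s: np.ndarray         # (n_wall,) cumulative arc length
    wall_is_wall: np.ndarray   # (n_wall,) bool, False on inlet/outlet ends
    neck_segment: np.ndarray   # (2, 2) endpoints
    inlet_segment: np.ndarray  # (2, 2)
    outlet_segment: np.ndarray  # (2, 2)
    dome_centers: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    @property
    def nx(self) -> int:
        return self.sdf.shape[0]

    @property
    def ny(self) -> int:
        return self.sdf.shape[1]

    def level(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate the analytic level function at arbitrary points."""
        p = self.params
        phi = _strip_level(np.asarray(y, dtype=float), p.channel_width)
        if p.dome1_radius > 0:
            c1, c2 = self.dome_centers
            phi = np.minimum(phi, _disc_level(x, y, c1, p.dome1_radius))
            if p.dome2_radius > 0:
                phi = np.minimum(phi, _disc_level(x, y, c2, p.dome2_radius))
        return phi

    @property
    def sac_mask(self) -> np.ndarray:
        """Lumen cells on the sac side of the neck line (above the wall)."""
        yc = self.y_centers[None, :]
        return self.lumen_mask & (np.broadcast_to(yc, self.sdf.shape) > self.params.channel_width)

    def lumen_area(self) -> float:
        return float(self.lumen_mask.sum()) * self.dx**2

    def sac_area(self) -> float:
        return float(self.sac_mask.sum()) * self.dx**2

    def params_hash(self) -> str:
        key = repr(dataclasses.astuple(self.params)).encode()
        return hashlib.md5(key).hexdigest()[:12]


def _wall_chain(geo_level, params: GeometryParams, sdf_node: np.ndarray, dx: float):
    """Extract the closed lumen boundary chain from the node-sampled level set."""
    padded = np.pad(sdf_node, 1, mode="constant", constant_values=2.0 * dx)
    contours = measure.find_contours(padded, 0.0)
    if not contours:
        raise ValueError("no lumen boundary found (empty lumen?)")
    contour = max(contours, key=len)
    xy = (contour - 1.0) * dx  # node (i, j) sits at (i*dx, j*dx)
    # find_contours closes the loop by repeating the first point: drop it
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # enforce counter-clockwise orientation (positive shoelace area)
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    if area2 < 0:
        xy = xy[::-1]
    seg = np.linalg.norm(np.diff(xy, axis=0, append=xy[:1]), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg[:-1])))
    # inward normal from the analytic level-function gradient
    eps = 0.25 * dx
    gx = (geo_level(xy[:, 0] + eps, xy[:, 1]) - geo_level(xy[:, 0] - eps, xy[:, 1])) / (2 * eps)
    gy = (geo_level(xy[:, 0], xy[:, 1] + eps) - geo_level(xy[:, 0], xy[:, 1] - eps)) / (2 * eps)
    norm = np.hypot(gx, gy)
    lx = params.grid_nx * dx
    is_wall = (xy[:, 0] > 1.1 * dx) & (xy[:, 0] < lx - 1.1 * dx)
    # on the open inlet/outlet closure segments the level gradient is along
    # the wall; give them a streamwise inward normal instead
    degenerate = norm < 0.5
    norm[degenerate] = 1.0
    normals = -np.column_stack([gx, gy]) / norm[:, None]
    normals[degenerate] = np.where(
        xy[degenerate, 0:1] < lx / 2, [[1.0, 0.0]], [[-1.0, 0.0]]
    )
    return xy, normals, s, is_wall


def build_geometry(params: GeometryParams) -> AneurysmGeometry:
    """Build the discretised aneurysm geometry from its parameters.

    Raises
    ------
    ValueError
        If the parameters violate their invariants, the two domes do not
        overlap, or the grid is too coarse to resolve the neck (< 6 cells
        across ``neck_width``).
    """
    params.validate()
    if params.dome1_radius > 0 and params.neck_width / params.dx < 6:
        raise ValueError(
            f"grid too coarse: only {params.neck_width / params.dx:.1f} cells across the "
            "neck (need at least 6); refine dx"
        )
    nx, ny, dx = params.grid_nx, params.grid_ny, params.dx
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    xn = np.arange(nx + 1) * dx
    yn = np.arange(ny + 1) * dx

    centers = params.dome_centers()

    def level(x, y):
        phi = _strip_level(np.asarray(y, dtype=float), params.channel_width)
        if params.dome1_radius > 0:
            phi = np.minimum(phi, _disc_level(x, y, centers[0], params.dome1_radius))
            if params.dome2_radius > 0:
                phi = np.minimum(phi, _disc_level(x, y, centers[1], params.dome2_radius))
        return phi

    Xc, Yc = np.meshgrid(xc, yc, indexing="ij")
    Xn, Yn = np.meshgrid(xn, yn, indexing="ij")
    sdf = level(Xc, Yc)
    sdf_node = level(Xn, Yn)
    lumen = sdf < 0.0

    wall_xy, wall_n, wall_s, is_wall = _wall_chain(level, params, sdf_node, dx)

    w = params.channel_width
    xneck = params.neck_center_x
    neck = np.array([[xneck - params.neck_width / 2, w], [xneck + params.neck_width / 2, w]])
    lx = nx * dx
    inlet = np.array([[0.0, 0.0], [0.0, w]])
    outlet = np.array([[lx, 0.0], [lx, w]])

    return AneurysmGeometry(
        params=params,
        dx=dx,
        x_centers=xc,
        y_centers=yc,
        sdf=sdf,
        sdf_node=sdf_node,
        lumen_mask=lumen,
        coil_mask=np.zeros_like(lumen),
        wall_xy=wall_xy,
        wall_normals=wall_n,
        wall_s=wall_s,
        wall_is_wall=is_wall,
        neck_segment=neck,
        inlet_segment=inlet,
        outlet_segment=outlet,
        dome_centers=centers,
    )


def coil_mask(geometry: AneurysmGeometry, fill_fraction: float = 1.0) -> AneurysmGeometry:
    """Return a copy of ``geometry`` with the coil mask set.

    The coil occupies ``fill_fraction`` of the sac lumen area, filled from the
    distal dome tip toward the neck (cells sorted by distance from the neck
    segment, farthest first), emulating a coil mass packed into the dome.
    """
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    sac = geometry.sac_mask
    mask = np.zeros_like(sac)
    n_sac = int(sac.sum())
    k = int(round(fill_fraction * n_sac))
    if k > 0:
        ii, jj = np.nonzero(sac)
        x = geometry.x_centers[ii]
        y = geometry.y_centers[jj]
        (x1, y1), (x2, y2) = geometry.neck_segment
        # distance to the neck segment (a horizontal segment on the wall line)
        dxs = np.clip(x, min(x1, x2), max(x1, x2)) - x
        dys = y1 - y
        d = np.hypot(dxs, dys)
        order = np.argsort(-d, kind="stable")
        sel = order[:k]
        mask[ii[sel], jj[sel]] = True
    out = dataclasses.replace(geometry, coil_mask=mask)
    return out
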