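"""Bolus ellipsoid, antenna frames, and the surface interpolation grid.

All lengths are millimetres. The water-bolus surface is an axis-aligned
ellipsoid, optionally trimmed by a plane perpendicular to the cranial-caudal
(z) axis to leave a caudal opening. Points on the surface are addressed by
spherical coordinates (theta from +z, phi from +x, right-handed), with the
surface point

    P(theta, phi) = center + (a sin(t) cos(p), b sin(t) sin(p), c cos(t)).

Each antenna location carries a local orthonormal frame (U, V, W): W points
inward along the surface normal, U (the polarization axis) is tangent to the
surface in the plane spanned by the z axis and W, and V = W x U completes a
right-handed triple. The antenna origin O is retracted inward from the
surface just far enough that the rectangular back plate stays inside the
water; the phase center sits 14 mm further in along W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.spatial import ConvexHull

__all__ = [
    "Ellipsoid",
    "AntennaPose",
    "SurfaceGrid",
    "ANTENNA_EXTENT_MM",
    "ANTENNA_RADIUS_MM",
    "PHASE_CENTER_OFFSET_MM",
    "fit_bolus_ellipsoid",
    "antenna_frame",
    "spread_surface_grid",
    "size_search",
    "locate_patch",
    "clearance_constraints",
    "uniform_surface_sample",
]

# SGBT antenna footprint: extent along (U, V, W) and the radius of the
# smallest circle enclosing it on the UV plane (half the 87 mm U extent).
ANTENNA_EXTENT_MM = np.array([87.0, 62.0, 24.0])
ANTENNA_RADIUS_MM = 43.5
PHASE_CENTER_OFFSET_MM = 14.0

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid with an optional caudal trim plane.

    ``trim_offset`` is the distance (mm) of the cutting plane caudal to the
    center; the surface with z >= center_z - trim_offset is kept. ``None``
    disables trimming.
    """

    center: np.ndarray = (0.0, 0.0, 0.0)
    radii: np.ndarray = (125.0, 142.0, 144.0)
    trim_offset: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("ellipsoid radii must be positive")
        if self.trim_offset is not None and self.trim_offset >= self.radii[2]:
            raise ValueError("trim plane does not intersect the ellipsoid")

    @property
    def theta_max(self) -> float:
        """Largest polar angle on the kept (untrimmed) surface."""
        if self.trim_offset is None:
            return np.pi
        return float(np.arccos(-self.trim_offset / self.radii[2]))

    @property
    def trimmed_extent_z(self) -> float:
        """Cranial-caudal extent of the trimmed surface, mm."""
        off = self.trim_offset if self.trim_offset is not None else self.radii[2]
        return float(self.radii[2] + off)

    def surface_point(self, theta, phi):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        st = np.sin(theta)
        p = np.stack([self.radii[0] * st * np.cos(phi),
                      self.radii[1] * st * np.sin(phi),
                      self.radii[2] * np.cos(theta)], axis=-1)
        return self.center + p

    def surface_jacobian(self, theta, phi):
        """Tangent vectors d P/d theta and d P/d phi."""
        a, b, c = self.radii
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        dth = np.stack([a * ct * cp, b * ct * sp, -c * st * np.ones_like(cp)], axis=-1)
        dph = np.stack([-a * st * sp, b * st * cp, np.zeros_like(st * sp)], axis=-1)
        return dth, dph

    def level(self, points):
        """Quadric level function; negative inside, zero on the surface."""
        q = (np.asarray(points, dtype=float) - self.center) / self.radii
        return np.sum(q * q, axis=-1) - 1.0

    def outward_normal(self, points):
        g = 2.0 * (np.asarray(points, dtype=float) - self.center) / self.radii**2
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    def surface_coords(self, points):
        """Inverse parameterization: (theta, phi) of surface points."""
        q = (np.asarray(points, dtype=float) - self.center) / self.radii
        theta = np.arccos(np.clip(q[..., 2], -1.0, 1.0))
        phi = np.arctan2(q[..., 1], q[..., 0])
        return theta, phi

    def radial_projection(self, point):
        """Project a point radially (from the center) onto the surface."""
        d = np.asarray(point, dtype=float) - self.center
        k = 1.0 / np.sqrt(np.sum((d / self.radii) ** 2))
        return self.center + k * d, k


@dataclass
class AntennaPose:
    """Antenna placement: surface coordinates plus its local frame."""

    theta: float
    phi: float
    O: np.ndarray          # antenna origin after back-plate retraction, mm
    U: np.ndarray          # polarization axis (tangent, in the ZW plane)
    V: np.ndarray
    W: np.ndarray          # pointing axis, inward surface normal
    surface_point: np.ndarray = None
    retraction: float = 0.0
    phase_center_offset: float = PHASE_CENTER_OFFSET_MM

    @property
    def phase_center(self) -> np.ndarray:
        """O' = O + W * phase-center offset."""
        return self.O + self.phase_center_offset * self.W

    @property
    def frame(self) -> np.ndarray:
        """3x3 rotation with columns (U, V, W)."""
        return np.stack([self.U, self.V, self.W], axis=1)


def _frame_vectors(e: Ellipsoid, P: np.ndarray):
    W = -e.outward_normal(P)
    t = _Z - np.dot(_Z, W) * W
    nt = np.linalg.norm(t)
    if nt < 1e-9:
        # pole: the ZW plane is degenerate; fall back to the x axis
        t = np.array([1.0, 0.0, 0.0]) - W[0] * W
        nt = np.linalg.norm(t)
    U = t / nt
    V = np.cross(W, U)
    return U, V, W


def antenna_frame(e: Ellipsoid, theta: float, phi: float,
                  retract: bool = True,
                  extent: np.ndarray = ANTENNA_EXTENT_MM,
                  phase_center_offset: float = PHASE_CENTER_OFFSET_MM) -> AntennaPose:
    """Build the local antenna frame at surface coordinates (theta, phi).

    With ``retract=True`` the origin is pushed inward along W by the least
    distance that keeps the four corners of the back plate (extent[0] x
    extent[1] on the UV plane) inside the ellipsoid.
    """
    theta = float(theta)
    phi = float(phi)
    if e.trim_offset is not None and theta > e.theta_max + 1e-9:
        raise ValueError("pose lies on the trimmed (removed) part of the surface")
    P = e.surface_point(theta, phi)
    U, V, W = _frame_vectors(e, P)

    t_ret = 0.0
    if retract:
        hu, hv = extent[0] / 2.0, extent[1] / 2.0
        corners_uv = np.array([[hu, hv], [hu, -hv], [-hu, hv], [-hu, -hv]])

        def worst(t):
            pts = P + t * W + corners_uv[:, :1] * U + corners_uv[:, 1:] * V
            return float(np.max(e.level(pts)))

        if worst(0.0) > 0.0:
            t_hi = float(np.min(e.radii))  # generous bracket
            if worst(t_hi) > 0.0:
                raise ValueError("antenna back plate cannot be fit inside the bolus")
            t_ret = brentq(worst, 0.0, t_hi, xtol=1e-6)

    return AntennaPose(theta=theta, phi=phi, O=P + t_ret * W, U=U, V=V, W=W,
                       surface_point=P, retraction=t_ret,
                       phase_center_offset=phase_center_offset)


# ---------------------------------------------------------------------------
# ellipsoid fitting
# ---------------------------------------------------------------------------

def fit_bolus_ellipsoid(scalp_points, offset: float = 0.0,
                        trim_offset: float | None = None) -> tuple:
    """Least-squares axis-aligned ellipsoid through a point cloud.

    ``scalp_points`` (n, 3) are first pushed ``offset`` mm outward along the
    direction from their centroid (the bolus stand-off), then the quadric
    A x^2 + B y^2 + C z^2 + D x + E y + F z = 1 is fit by linear least
    squares. Returns ``(Ellipsoid, rms_residual)``.
    """
    pts = np.asarray(scalp_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 9:
        raise ValueError("need at least 9 three-dimensional points")
    if offset:
        centroid = pts.mean(axis=0)
        d = pts - centroid
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(nrm < 1e-9):
            raise ValueError("point coincides with the cloud centroid")
        pts = pts + offset * d / nrm

    M = np.column_stack([pts[:, 0] ** 2, pts[:, 1] ** 2, pts[:, 2] ** 2, pts])
    beta, *_ = np.linalg.lstsq(M, np.ones(len(pts)), rcond=None)
    quad, lin = beta[:3], beta[3:]
    if np.any(quad <= 0) or np.linalg.matrix_rank(M) < 6:
        raise ValueError("degenerate point cloud: ellipsoid fit failed")
    center = -lin / (2.0 * quad)
    g = 1.0 + np.sum(quad * center**2)
    if g <= 0:
        raise ValueError("degenerate point cloud: ellipsoid fit failed")
    radii = np.sqrt(g / quad)
    resid = float(np.sqrt(np.mean((M @ beta - 1.0) ** 2)))
    return Ellipsoid(center=center, radii=radii, trim_offset=trim_offset), resid


# ---------------------------------------------------------------------------
# repulsion spreading of the interpolation grid
# ---------------------------------------------------------------------------

def uniform_surface_sample(e: Ellipsoid, n: int, rng: np.random.Generator,
                           theta_max: float | None = None):
    """Area-uniform random surface coordinates by rejection sampling."""
    if theta_max is None:
        theta_max = e.theta_max
    if theta_max <= 0:
        raise ValueError("theta_max leaves no surface to sample")
    ths, phs = [], []
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        ct = rng.uniform(np.cos(theta_max), 1.0, m)
        th = np.arccos(ct)
        ph = rng.uniform(0.0, 2.0 * np.pi, m)
        dth, dph = e.surface_jacobian(th, ph)
        # surface element per d(cos theta) d(phi)
        w = np.linalg.norm(np.cross(dth, dph), axis=-1) / np.maximum(np.sin(th), 1e-12)
        keep = rng.uniform(0.0, w.max() * 1.05, m) < w
        ths.append(th[keep])
        phs.append(ph[keep])
        got += int(keep.sum())
    return np.concatenate(ths)[:n], np.concatenate(phs)[:n]


def _repulsion_energy_grad(x, e: Ellipsoid, n: int):
    th, ph = x[:n], x[n:]
    X = e.surface_point(th, ph)
    d = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(d2, np.inf)
    energy = 0.5 * float(np.sum(1.0 / d2))
    gX = np.einsum("ij,ijk->ik", -2.0 / d2**2, d)
    dth, dph = e.surface_jacobian(th, ph)
    return energy, np.concatenate([np.einsum("ik,ik->i", gX, dth),
                                   np.einsum("ik,ik->i", gX, dph)])


@dataclass
class SurfaceGrid:
    """Spread surface nodes with their triangulation and spacing statistics.

    ``triangles`` index into the node arrays and cover the untrimmed surface
    patchwise; hole-spanning hull facets across the caudal opening are
    dropped. ``max_edge``/``mean_edge`` are statistics over unique
    triangulation edges; ``max_nn``/``mean_nn`` over per-node nearest
    neighbors (chordal mm).
    """

    ellipsoid: Ellipsoid
    thetas: np.ndarray
    phis: np.ndarray
    triangles: np.ndarray
    max_edge: float
    mean_edge: float
    max_nn: float
    mean_nn: float
    energy: float
    seed: int = 0
    _pose_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_points(self) -> int:
        return len(self.thetas)

    @property
    def n_patches(self) -> int:
        return len(self.triangles)

    @property
    def points(self) -> np.ndarray:
        return self.ellipsoid.surface_point(self.thetas, self.phis)

    def pose(self, i: int, **kwargs) -> AntennaPose:
        key = (i, tuple(sorted(kwargs.items())))
        if key not in self._pose_cache:
            self._pose_cache[key] = antenna_frame(
                self.ellipsoid, self.thetas[i], self.phis[i], **kwargs)
        return self._pose_cache[key]

    @property
    def poses(self):
        return [self.pose(i) for i in range(self.n_points)]

    def edges(self) -> np.ndarray:
        pairs = set()
        for t in self.triangles:
            for i, j in ((0, 1), (1, 2), (0, 2)):
                pairs.add((min(t[i], t[j]), max(t[i], t[j])))
        return np.array(sorted(pairs), dtype=int)

    def to_dict(self) -> dict:
        return {
            "ellipsoid": {"center": self.ellipsoid.center.tolist(),
                          "radii": self.ellipsoid.radii.tolist(),
                          "trim_offset": self.ellipsoid.trim_offset},
            "thetas": self.thetas.tolist(),
            "phis": self.phis.tolist(),
            "triangles": self.triangles.tolist(),
            "max_edge": self.max_edge, "mean_edge": self.mean_edge,
            "max_nn": self.max_nn, "mean_nn": self.mean_nn,
            "energy": self.energy, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceGrid":
        ell = Ellipsoid(center=d["ellipsoid"]["center"],
                        radii=d["ellipsoid"]["radii"],
                        trim_offset=d["ellipsoid"]["trim_offset"])
        return cls(ellipsoid=ell, thetas=np.asarray(d["thetas"]),
                   phis=np.asarray(d["phis"]),
                   triangles=np.asarray(d["triangles"], dtype=int),
                   max_edge=d["max_edge"], mean_edge=d["mean_edge"],
                   max_nn=d["max_nn"], mean_nn=d["mean_nn"],
                   energy=d["energy"], seed=d.get("seed", 0))


def _triangulate_on_sphere(thetas, phis, theta_max):
    """Convex-hull (Delaunay) triangulation of nodes mapped to the unit
    sphere; facets spanning the caudal opening are discarded by their
    spherical centroid."""
    if len(thetas) < 4:
        return np.empty((0, 3), dtype=int)
    st = np.sin(thetas)
    Un = np.stack([st * np.cos(phis), st * np.sin(phis), np.cos(thetas)], axis=-1)
    tris = ConvexHull(Un).simplices
    if theta_max < np.pi - 1e-9:
        cen = Un[tris].mean(axis=1)
        cen /= np.linalg.norm(cen, axis=1, keepdims=True)
        keep = np.arccos(np.clip(cen[:, 2], -1.0, 1.0)) <= theta_max
        tris = tris[keep]
    return tris


def spread_surface_grid(e: Ellipsoid, n_points: int, seed: int = 0,
                        theta_max: float | None = None, n_starts: int = 8,
                        maxiter: int = 1500) -> SurfaceGrid:
    """Spread ``n_points`` nodes over the available surface by repulsion.

    The spread minimizes the sum of inverse squared (chordal) pairwise
    distances — the potential energy of like charges confined to the surface
    — from an area-uniform random start, subject to theta <= theta_max.
    ``n_starts`` independent starts are run and the lowest-energy result
    kept. Deterministic for fixed ``seed``.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if theta_max is None:
        theta_max = e.theta_max
    best = None
    for k in range(n_starts):
        rng = np.random.default_rng([seed, k])
        th0, ph0 = uniform_surface_sample(e, n_points, rng, theta_max)
        res = minimize(_repulsion_energy_grad, np.concatenate([th0, ph0]),
                       args=(e, n_points), jac=True, method="L-BFGS-B",
                       bounds=[(1e-6, theta_max)] * n_points + [(None, None)] * n_points,
                       options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    th, ph = best.x[:n_points], best.x[n_points:]
    ph = np.mod(ph, 2.0 * np.pi)
    tris = _triangulate_on_sphere(th, ph, theta_max)

    X = e.surface_point(th, ph)
    pairs = set()
    for t in tris:
        for i, j in ((0, 1), (1, 2), (0, 2)):
            pairs.add((min(t[i], t[j]), max(t[i], t[j])))
    if not pairs:  # too few points to triangulate: fall back to all pairs
        pairs = {(i, j) for i in range(n_points) for j in range(i + 1, n_points)}
    ed = np.array(sorted(pairs), dtype=int)
    L = np.linalg.norm(X[ed[:, 0]] - X[ed[:, 1]], axis=1)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)

    return SurfaceGrid(ellipsoid=e, thetas=th, phis=ph, triangles=tris,
                       max_edge=float(L.max()), mean_edge=float(L.mean()),
                       max_nn=float(nn.max()), mean_nn=float(nn.mean()),
                       energy=float(best.fun), seed=seed)


def size_search(e: Ellipsoid, target_distance_mm: float, n_start: int = 16,
                growth: float = 1.15, seed: int = 0, n_starts: int = 2,
                n_max: int = 2000) -> int:
    """Smallest grid size whose maximum nearest-neighbor distance falls
    below ``target_distance_mm`` (grid sizes grow geometrically)."""
    n = n_start
    while n <= n_max:
        g = spread_surface_grid(e, n, seed=seed, n_starts=n_starts)
        if g.max_nn < target_distance_mm:
            return n
        n = max(n + 1, int(round(n * growth)))
    raise RuntimeError("size_search did not reach the target distance")


# ---------------------------------------------------------------------------
# patch lookup (barycentric area weights, Eq. on area ratios)
# ---------------------------------------------------------------------------

def locate_patch(grid: SurfaceGrid, theta: float, phi: float):
    """Find the triangular patch containing (theta, phi) and its weights.

    The triangle is selected on the unit sphere (consistent with the grid's
    triangulation); the weights are the ratios of sub-triangle areas to the
    patch area, evaluated with the query projected onto the patch plane so
    they are exact barycentric coordinates (nonnegative, summing to 1).
    Queries outside the covered surface are clamped to theta_max and
    flagged. Returns ``(nodes, weights, clamped)``.
    """
    e = grid.ellipsoid
    clamped = False
    tmax = e.theta_max
    if theta > tmax:
        theta, clamped = tmax, True
    if theta < 0:
        theta, clamped = 0.0, True

    st = np.sin(grid.thetas)
    Un = np.stack([st * np.cos(grid.phis), st * np.sin(grid.phis),
                   np.cos(grid.thetas)], axis=-1)
    q = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                  np.cos(theta)])

    tris = grid.triangles
    A = Un[tris]  # (nt, 3, 3) vertex directions
    best_tri, best_score, best_bc = None, -np.inf, None
    # barycentric along the ray: q = l1*A1 + l2*A2 + l3*A3 (up to scale)
    for t_idx in range(len(tris)):
        M = A[t_idx].T
        try:
            lam = np.linalg.solve(M, q)
        except np.linalg.LinAlgError:
            continue
        s = lam.sum()
        if s <= 1e-12:
            # the ray exits through the opposite hemisphere of this facet
            continue
        lam = lam / s
        score = lam.min()
        if score > best_score:
            best_score, best_tri, best_bc = score, t_idx, lam
    if best_tri is None:
        raise RuntimeError("patch lookup failed: degenerate triangulation")
    if best_score < -1e-6:
        clamped = True  # outside grid coverage; nearest facet used

    nodes = tris[best_tri]
    P = grid.points[nodes]
    n_vec = np.cross(P[1] - P[0], P[2] - P[0])
    area2 = np.linalg.norm(n_vec)
    if area2 < 1e-12:
        raise ValueError("degenerate (zero-area) interpolation patch")
    n_hat = n_vec / area2
    Q = e.surface_point(theta, phi)
    Qp = Q - np.dot(Q - P[0], n_hat) * n_hat  # project onto the patch plane
    # signed sub-areas (ratios to the patch area)
    w = np.array([
        np.dot(np.cross(P[1] - Qp, P[2] - Qp), n_hat),
        np.dot(np.cross(P[2] - Qp, P[0] - Qp), n_hat),
        np.dot(np.cross(P[0] - Qp, P[1] - Qp), n_hat),
    ]) / area2
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    return nodes, w, clamped


# ---------------------------------------------------------------------------
# feasibility constraints
# ---------------------------------------------------------------------------

def _uv_footprint(pose_u, pose_v, L, r):
    """Projected half-extent of an antenna of enclosing radius r along L."""
    nL = np.linalg.norm(L)
    if nL < 1e-12:
        return r
    return r * np.sqrt(np.dot(pose_u, L / nL) ** 2 + np.dot(pose_v, L / nL) ** 2)


def clearance_constraints(poses, r: float = ANTENNA_RADIUS_MM,
                          eye_exclusions=None, ellipsoid: Ellipsoid = None):
    """Clearance values for an arrangement; positive values are feasible.

    Returns ``(pair_values, eye_values)``: ``pair_values[i, j] = |L| - l_i -
    l_j`` with ``L = O_i - O_j`` and ``l`` the antennas' UV-plane footprints
    projected on L (symmetric; diagonal is NaN). ``eye_values[i, k]`` is the
    distance on the bolus surface between antenna i and the projection of
    eye k minus the projected eye radius and the antenna radius.
    ``eye_exclusions`` is a list of ``(center_mm, radius_mm)``.
    """
    n = len(poses)
    pair = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            L = poses[i].O - poses[j].O
            li = _uv_footprint(poses[i].U, poses[i].V, L, r)
            lj = _uv_footprint(poses[j].U, poses[j].V, L, r)
            pair[i, j] = pair[j, i] = np.linalg.norm(L) - li - lj

    eye = None
    if eye_exclusions:
        if ellipsoid is None:
            raise ValueError("eye exclusions require the bolus ellipsoid")
        eye = np.zeros((n, len(eye_exclusions)))
        for k, (c_eye, r_eye) in enumerate(eye_exclusions):
            proj, _ = ellipsoid.radial_projection(np.asarray(c_eye, dtype=float))
            mag = (np.linalg.norm(proj - ellipsoid.center)
                   / max(np.linalg.norm(np.asarray(c_eye) - ellipsoid.center), 1e-9))
            r_proj = r_eye * mag
            for i in range(n):
                d = np.linalg.norm(poses[i].surface_point - proj)
                eye[i, k] = d - (r_proj + r)
    return pair, eye
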