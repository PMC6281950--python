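"""Forward models for the torso volume conductor.

The forward problem is the Laplace equation in the annular torso domain
between the epicardium and the external torso boundary,

    div(sigma_T grad u_T) = 0      in Omega_T,
    sigma_T grad u_T . n_T = 0     on Gamma_ext   (insulated torso),
    u_T = u_H                      on Gamma_H     (epicardial Dirichlet data),

with homogeneous isotropic conductivity (sigma_T = 1; it cancels for
Dirichlet-data transfer).  Discretization reduces it to a transfer system
A x = b.  Three builders live here:

* ``build_fem_transfer`` -- P1 tetrahedra on an internally extruded annulus
  mesh; unknowns x are the epicardial potentials themselves.
* ``build_mfs_transfer`` -- method of fundamental solutions; unknowns are a
  constant term plus weights of Laplace kernels 1/(4 pi r) anchored at
  fictitious sources outside the annulus, and b = [BSP; 0] stacks the
  measured potentials with the zero-flux constraint.
* ``build_dtn_operator`` -- the discrete Dirichlet-to-Neumann (Steklov-
  Poincare) map D taking epicardial potentials to outward normal
  derivatives, the operator penalized by L1 current-density regularization.

``analytic_annulus_forward`` provides the closed-form solution on concentric
spheres used as an independent oracle throughout the test-suite and by the
synthetic phantom generator (so inverse solvers are never tested against
data manufactured by the operator under test).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .geometry import SurfaceMesh, contains_mesh

__all__ = [
    "TransferSystem",
    "DtnOperator",
    "AnnulusHarmonic",
    "analytic_annulus_forward",
    "annulus_oracle_matrix",
    "real_spherical_harmonics",
    "build_fem_transfer",
    "build_dtn_operator",
    "build_mfs_transfer",
    "build_mfs_forward",
    "mfs_reconstruct_epicardial",
    "choose_mfs_sources",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TransferSystem:
    """Discrete forward map A x = b.

    ``m_total`` is the full row count of A (for MFS: Dirichlet + Neumann
    rows); trace-based selection criteria use it as their ``m``.
    """

    A: np.ndarray
    method: str  # "FEM" | "MFS"
    heart_vertices: np.ndarray  # coordinates the epicardial potentials live on
    n_dirichlet: int
    n_neumann: int = 0
    sources: np.ndarray | None = None  # MFS source points (ns, 3)
    electrodes: np.ndarray | None = None  # torso vertex indices of Dirichlet rows
    B: np.ndarray | None = None  # attached measurement frames (m x T)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if not np.all(np.isfinite(self.A)):
            raise ValueError("transfer matrix has non-finite entries")
        m, n = self.A.shape
        if m < n:
            raise ValueError(f"underdetermined transfer system: m={m} < n={n}")

    @property
    def m_total(self) -> int:
        return self.A.shape[0]

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[1]

    def stack_rhs(self, bsp: np.ndarray) -> np.ndarray:
        """Assemble b from body-surface potentials (appends the zero-flux
        block for MFS systems)."""
        bsp = np.atleast_2d(np.asarray(bsp, dtype=float))
        if bsp.shape[0] != self.n_dirichlet:
            bsp = bsp.T
        if bsp.shape[0] != self.n_dirichlet:
            raise ValueError("BSP frame length does not match Dirichlet row count")
        if self.n_neumann:
            zeros = np.zeros((self.n_neumann, bsp.shape[1]))
            out = np.vstack([bsp, zeros])
        else:
            out = bsp
        return out if out.shape[1] > 1 else out[:, 0]


@dataclasses.dataclass
class DtnOperator:
    """Discrete Dirichlet-to-Neumann map at the heart vertices.

    ``D @ x`` approximates the outward (heart-normal) derivative of the
    torso potential at each epicardial vertex, given epicardial potentials
    ``x``.  An insulated torso with constant Dirichlet data has a constant
    solution, so ``D @ 1 == 0`` up to discretization round-off.
    """

    D: np.ndarray
    points: np.ndarray  # heart vertex coordinates (n, 3)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape[0] != self.D.shape[1] or self.D.shape[0] != len(self.points):
            raise ValueError("D must be n x n with one row per heart vertex")


# ---------------------------------------------------------------------------
# analytic annulus oracle
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AnnulusHarmonic:
    """Closed-form Laplace solution on the spherical annulus a < r < b.

    For boundary data Y_lm on r=a and zero radial derivative on r=b the
    unique solution is  u = (A_l r^l + B_l r^-(l+1)) Y_lm  with

        B_l = A_l * l * b^(2l+1) / (l+1)   (l >= 1;  B_0 = 0),
        A_l a^l + B_l a^-(l+1) = 1.
    """

    l: int
    a: float
    b: float
    A_l: float
    B_l: float

    def radial(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.A_l * r**self.l + self.B_l * r ** -(self.l + 1)

    def radial_derivative(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.l * self.A_l * r ** (self.l - 1) - (self.l + 1) * self.B_l * r ** -(
            self.l + 2
        )


def analytic_annulus_forward(l: int, a: float, b_out: float) -> AnnulusHarmonic:
    """Radial attenuation profile of a degree-l harmonic across the annulus.

    The profile is independent of the order m; callers multiply by Y_lm.
    """
    if not (0 < a < b_out):
        raise ValueError("require 0 < a < b_out")
    if l < 0:
        raise ValueError("harmonic degree must be >= 0")
    if l == 0:
        return AnnulusHarmonic(0, a, b_out, 1.0, 0.0)
    # B = A * l b^(2l+1)/(l+1);  A a^l + B a^-(l+1) = 1
    ratio = l * b_out ** (2 * l + 1) / (l + 1)
    A_l = 1.0 / (a**l + ratio * a ** -(l + 1))
    return AnnulusHarmonic(l, a, b_out, A_l, A_l * ratio)


def real_spherical_harmonics(directions: np.ndarray, l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Real spherical harmonic basis evaluated at unit directions.

    Returns ``(Y, degrees)`` where Y is (n_points, (l_max+1)^2) and
    ``degrees[k]`` is the degree l of column k.  Columns are orthonormal on
    the continuous sphere.
    """
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols, degs = [], []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                col = y.real
            elif m > 0:
                col = np.sqrt(2.0) * (-1) ** m * y.real
            else:
                col = np.sqrt(2.0) * (-1) ** m * y.imag
            cols.append(col)
            degs.append(l)
    return np.column_stack(cols), np.array(degs)


def annulus_oracle_matrix(
    heart: SurfaceMesh, torso: SurfaceMesh, l_max: int = 10
) -> np.ndarray:
    """Analytic forward matrix for concentric-sphere phantoms.

    Expands the epicardial pattern in real spherical harmonics up to
    ``l_max`` (least squares on the heart vertices), attenuates each degree
    with the closed-form annulus profile and evaluates on the torso
    vertices.  Independent of the FEM/MFS operators under test.
    """
    c = heart.centroid()
    hv = heart.vertices - c
    tv = torso.vertices - c
    a = float(np.linalg.norm(hv, axis=1).mean())
    b = float(np.linalg.norm(tv, axis=1).mean())
    Yh, degs = real_spherical_harmonics(hv, l_max)
    Yt, _ = real_spherical_harmonics(tv, l_max)
    gains = np.array(
        [analytic_annulus_forward(l, a, b).radial(b) for l in range(l_max + 1)]
    )
    return (Yt * gains[degs]) @ np.linalg.pinv(Yh)


# ---------------------------------------------------------------------------
# FEM on the extruded annulus
# ---------------------------------------------------------------------------


def _match_radial(heart: SurfaceMesh, torso: SurfaceMesh, center: np.ndarray):
    """Map each heart-vertex direction to a torso vertex if the two surfaces
    are radially matched (same unit directions about ``center``); else None."""
    if torso.n_vertices != heart.n_vertices:
        return None
    hd = heart.vertices - center
    hd = hd / np.linalg.norm(hd, axis=1, keepdims=True)
    td = torso.vertices - center
    td = td / np.linalg.norm(td, axis=1, keepdims=True)
    tree = cKDTree(td)
    dist, idx = tree.query(hd)
    if dist.max() > 1e-8 or len(np.unique(idx)) != heart.n_vertices:
        return None
    return idx


def _outer_points(heart: SurfaceMesh, torso: SurfaceMesh, center: np.ndarray):
    """Outer extrusion targets: matched torso vertices, or ray intersections."""
    idx = _match_radial(heart, torso, center)
    if idx is not None:
        return torso.vertices[idx], idx
    from ._ray import ray_hits

    hd = heart.vertices - center
    hd = hd / np.linalg.norm(hd, axis=1, keepdims=True)
    outer = np.empty((heart.n_vertices, 3))
    for i, d in enumerate(hd):
        t = ray_hits(center, d, torso.vertices, torso.triangles)
        if len(t) == 0:
            raise RuntimeError("annulus extrusion failed: ray missed the torso surface")
        outer[i] = center + t.max() * d  # farthest hit = external boundary
    return outer, None


def _detect_sphere_radius(mesh: SurfaceMesh, center: np.ndarray) -> float | None:
    """Radius if all vertices are equidistant from ``center`` (rel. 1e-6)."""
    r = np.linalg.norm(mesh.vertices - center, axis=1)
    rm = float(r.mean())
    return rm if np.all(np.abs(r - rm) <= 1e-6 * rm) else None


def _refine_surface(
    vertices: np.ndarray,
    triangles: np.ndarray,
    center: np.ndarray,
    radius: float | None,
):
    """One 4:1 midpoint subdivision of a triangle surface.

    Original vertices keep their indices.  When ``radius`` is given (the
    surface is a sphere about ``center``), new midpoints are projected back
    onto the sphere, so refinement converges to the curved surface instead
    of the coarse polyhedron.  Returns (vertices, triangles, P) where P is
    the sparse piecewise-linear interpolation matrix from coarse to fine
    vertex values.
    """
    n0 = len(vertices)
    edge_mid: dict[tuple[int, int], int] = {}
    new_pts: list[np.ndarray] = []
    rows, cols, vals = list(range(n0)), list(range(n0)), [1.0] * n0

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in edge_mid:
            p = 0.5 * (vertices[i] + vertices[j])
            if radius is not None:
                d = p - center
                p = center + d * (radius / np.linalg.norm(d))
            edge_mid[key] = n0 + len(new_pts)
            new_pts.append(p)
            rows.extend([edge_mid[key]] * 2)
            cols.extend([i, j])
            vals.extend([0.5, 0.5])
        return edge_mid[key]

    tris = []
    for a, b, c in triangles:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        tris.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
    fine_v = np.vstack([vertices, np.array(new_pts)])
    P = csr_matrix((vals, (rows, cols)), shape=(len(fine_v), n0))
    return fine_v, np.array(tris, dtype=np.int64), P


def _radial_layers(n_layers: int) -> np.ndarray:
    """Normalized layer positions in [0, 1], geometrically graded toward the
    heart where harmonic solutions vary fastest."""
    q = 1.35
    steps = q ** np.arange(n_layers)
    return np.concatenate([[0.0], np.cumsum(steps) / steps.sum()])


def _extrude_annulus(inner_v: np.ndarray, outer_v: np.ndarray, surf_tris: np.ndarray, n_layers: int):
    """Tetrahedralize the annulus by radial extrusion of the inner surface.

    Returns (nodes, tets).  Node ``k*nH + i`` is inner vertex i pushed a
    fraction ``t_k`` of the way to its outer target; layer 0 is the inner
    (heart) surface, layer ``n_layers`` the outer (torso) surface.
    """
    nH = len(inner_v)
    t = _radial_layers(n_layers)
    nodes = np.concatenate([inner_v + tk * (outer_v - inner_v) for tk in t], axis=0)
    tris = np.sort(surf_tris, axis=1)  # sorted: conforming prism split
    i, j, k = tris[:, 0], tris[:, 1], tris[:, 2]
    tets = []
    for layer in range(n_layers):
        b0, t0 = layer * nH, (layer + 1) * nH
        bi, bj, bk = i + b0, j + b0, k + b0
        ti, tj, tk_ = i + t0, j + t0, k + t0
        # with i<j<k and diagonals from the lower-index bottom vertex, the
        # prism splits into three tets that conform across shared quads
        tets.append(np.stack([bi, bj, bk, tk_], axis=1))
        tets.append(np.stack([bi, bj, tj, tk_], axis=1))
        tets.append(np.stack([bi, ti, tj, tk_], axis=1))
    return nodes, np.concatenate(tets, axis=0)


def _p1_stiffness(nodes: np.ndarray, tets: np.ndarray) -> csr_matrix:
    """Linear tetrahedral stiffness matrix (unit conductivity), vectorized."""
    p = nodes[tets]  # (ne, 4, 3)
    e = p[:, 1:] - p[:, :1]  # edge matrix rows e1,e2,e3
    vol6 = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    if np.any(np.abs(vol6) < 1e-30):
        raise RuntimeError("degenerate tetrahedron in annulus mesh")
    inv = np.linalg.inv(e)  # (ne, 3, 3): columns are gradients of lam1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = inv.transpose(0, 2, 1)
    g[:, 0] = -g[:, 1:].sum(axis=1)
    ke = np.einsum("eid,ejd->eij", g, g) * (np.abs(vol6) / 6.0)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    n = len(nodes)
    return csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n))


def _lumped_surface_mass(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Diagonal (lumped) mass on a surface: one third of adjacent areas."""
    tri = vertices[triangles]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    m = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(m, triangles[:, k], areas / 3.0)
    return m


def _fem_solve_blocks(
    heart: SurfaceMesh, torso: SurfaceMesh, refinement: int, angular_refine: int = 1
):
    """Shared FEM machinery: extrusion, stiffness blocks, interior solve.

    The annulus is extruded from the heart surface, optionally subdivided
    ``angular_refine`` times in the angular direction (with projection back
    onto detected spherical surfaces, so refinement converges to the curved
    geometry rather than the coarse polyhedron).  The epicardial unknowns
    remain the coarse heart vertices; fine boundary values are their
    piecewise-linear interpolant through the matrix P.

    Returns (U_full, K, P, nH_fine, fine_heart_tris, fine_heart_v,
    torso_rows, torso_map) where U_full is (n_nodes, nH_coarse), mapping
    coarse epicardial data to every node value.
    """
    if refinement < 1:
        raise ValueError("refinement (number of radial layers) must be >= 1")
    heart.validate()
    torso.validate()
    if not contains_mesh(torso, heart):
        raise ValueError("heart surface must lie strictly inside the torso surface")
    c = heart.centroid()
    outer, torso_map = _outer_points(heart, torso, c)
    r_in = _detect_sphere_radius(heart, c)
    r_out = None
    if r_in is not None:
        ro = np.linalg.norm(outer - c, axis=1)
        rom = float(ro.mean())
        r_out = rom if np.all(np.abs(ro - rom) <= 1e-6 * rom) else None
    hv, ov, tris = heart.vertices, outer, heart.triangles
    P = csr_matrix(np.eye(heart.n_vertices))
    for _ in range(angular_refine):
        hv, tris_new, P1 = _refine_surface(hv, tris, c, r_in)
        ov, _, _ = _refine_surface(ov, tris, c, r_out)
        tris = tris_new
        P = P1 @ P
    nHf = len(hv)
    nodes, tets = _extrude_annulus(hv, ov, tris, refinement)
    K = _p1_stiffness(nodes, tets)
    interior = np.arange(nHf, len(nodes))
    K_II = K[interior][:, interior].tocsc()
    try:
        lu = splu(K_II)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular interior stiffness block: {exc}") from exc
    rhs = -(K[interior][:, :nHf] @ P).toarray()
    U_I = lu.solve(rhs)  # (n_interior, nH_coarse)
    U_full = np.vstack([P.toarray(), U_I])
    # the first nH_coarse vertices of the fine torso layer are the coarse
    # outer targets (midpoint subdivision keeps original vertex indices)
    torso_rows = refinement * nHf + np.arange(heart.n_vertices)
    return U_full, K, P, nHf, tris, hv, torso_rows, torso_map


def build_fem_transfer(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    refinement: int = 8,
    angular_refine: int = 1,
) -> TransferSystem:
    """FEM transfer matrix mapping epicardial potentials to torso potentials.

    ``refinement`` is the number of radial element layers of the internally
    extruded annulus mesh; ``angular_refine`` the number of internal 4:1
    angular subdivisions.  Columns are indexed by heart vertices; rows by
    torso-surface vertices (matched to the torso mesh ordering when the two
    surfaces are radially matched, as for concentric icospheres).  A
    constant epicardial potential propagates unchanged.
    """
    U_full, _, _, _, _, _, torso_rows, torso_map = _fem_solve_blocks(
        heart, torso, refinement, angular_refine
    )
    A = U_full[torso_rows]
    if torso_map is not None:
        # reorder rows into torso-mesh vertex order
        A_re = np.empty_like(A)
        A_re[torso_map] = A
        A = A_re
    return TransferSystem(
        A=A,
        method="FEM",
        heart_vertices=heart.vertices.copy(),
        n_dirichlet=A.shape[0],
        n_neumann=0,
    )


def fem_forward_apply(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    X: np.ndarray,
    refinement: int = 8,
    angular_refine: int = 1,
) -> np.ndarray:
    """Apply the FEM forward map to a few epicardial patterns without
    assembling the full transfer matrix.

    Solves the discrete Laplace problem once per column of ``X`` (heart
    vertices x patterns) and returns the torso-surface values; used for
    high-resolution validation where the full matrix would be wasteful.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != heart.n_vertices:
        X = X.T
    c = heart.centroid()
    outer, torso_map = _outer_points(heart, torso, c)
    r_in = _detect_sphere_radius(heart, c)
    r_out = None
    if r_in is not None:
        ro = np.linalg.norm(outer - c, axis=1)
        rom = float(ro.mean())
        r_out = rom if np.all(np.abs(ro - rom) <= 1e-6 * rom) else None
    hv, ov, tris = heart.vertices, outer, heart.triangles
    P = csr_matrix(np.eye(heart.n_vertices))
    for _ in range(angular_refine):
        hv, tris_new, P1 = _refine_surface(hv, tris, c, r_in)
        ov, _, _ = _refine_surface(ov, tris, c, r_out)
        tris = tris_new
        P = P1 @ P
    nHf = len(hv)
    nodes, tets = _extrude_annulus(hv, ov, tris, refinement)
    K = _p1_stiffness(nodes, tets)
    interior = np.arange(nHf, len(nodes))
    lu = splu(K[interior][:, interior].tocsc())
    U_I = lu.solve(-(K[interior][:, :nHf] @ (P @ X)))
    torso_rows = refinement * nHf + np.arange(heart.n_vertices) - nHf
    vals = U_I[torso_rows]
    if torso_map is not None:
        out = np.empty_like(vals)
        out[torso_map] = vals
        vals = out
    return vals


def build_dtn_operator(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    refinement: int = 8,
    angular_refine: int = 1,
) -> DtnOperator:
    """Discrete Dirichlet-to-Neumann operator at the heart vertices.

    Flux is recovered variationally: the weak residual of the discrete
    harmonic extension at heart-boundary nodes equals the boundary flux
    integral against each hat function; restriction to the coarse basis
    (P^T) and division by the coarse lumped boundary mass converts it to
    pointwise normal-derivative values at the heart vertices.  The sign
    convention is the heart-outward normal (current leaving the heart is
    positive).
    """
    U_full, K, P, nHf, ftris, fv, _, _ = _fem_solve_blocks(
        heart, torso, refinement, angular_refine
    )
    G = np.asarray(K[:nHf] @ U_full)  # weak residual, domain-outward flux
    mass_f = _lumped_surface_mass(fv, ftris)
    Gc = P.T @ G
    mass_c = P.T @ mass_f
    # domain-outward normal on Gamma_H is minus the heart-outward normal
    D = -Gc / mass_c[:, None]
    return DtnOperator(D=D, points=heart.vertices.copy())


# ---------------------------------------------------------------------------
# method of fundamental solutions
# ---------------------------------------------------------------------------


def _kernel(points: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Laplace fundamental solution f(r) = 1/(4 pi r), pairwise."""
    r = np.linalg.norm(points[:, None, :] - sources[None, :, :], axis=2)
    if np.any(r < 1e-12):
        raise ValueError("a source point coincides with an evaluation point")
    return 1.0 / (4.0 * np.pi * r)


def _kernel_normal_derivative(
    points: np.ndarray, normals: np.ndarray, sources: np.ndarray
) -> np.ndarray:
    diff = points[:, None, :] - sources[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-12):
        raise ValueError("a source point coincides with an evaluation point")
    return -np.einsum("ijk,ik->ij", diff, normals) / (4.0 * np.pi * r**3)


def _mfs_sources(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    inflation: float,
    deflation: float,
    heart_source_idx: np.ndarray | None = None,
) -> np.ndarray:
    if not inflation > 1:
        raise ValueError("inflation ratio must be > 1")
    if not 0 < deflation < 1:
        raise ValueError("deflation ratio must be in (0, 1)")
    c = heart.centroid()
    torso_src = c + inflation * (torso.vertices - c)
    hv = heart.vertices if heart_source_idx is None else heart.vertices[heart_source_idx]
    heart_src = c + deflation * (hv - c)
    return np.vstack([torso_src, heart_src])


def choose_mfs_sources(heart: SurfaceMesh, torso: SurfaceMesh, m_rows: int) -> np.ndarray | None:
    """Pick heart-source indices so the MFS system stays overdetermined.

    The default source layout (one source per inflated torso vertex plus one
    per deflated heart vertex, plus the constant term) can exceed the row
    count when the two meshes have similar cardinality.  Source placement is
    a free discretization choice in MFS, so we thin the heart cloud evenly
    in index just enough that ``m >= n``.  Returns None when no thinning is
    needed.
    """
    ns_max = m_rows - 1 - torso.n_vertices  # room left for heart sources
    if ns_max >= heart.n_vertices:
        return None
    if ns_max < 4:
        raise ValueError("too few rows for any sensible MFS source layout")
    return np.unique(np.linspace(0, heart.n_vertices - 1, ns_max).astype(int))


def build_mfs_transfer(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    electrodes: np.ndarray | None = None,
    inflation: float = 1.2,
    deflation: float = 0.8,
    heart_source_idx: np.ndarray | None = None,
) -> TransferSystem:
    """MFS transfer system with b = [BSP; 0].

    Rows: Dirichlet rows (kernel values at the electrode positions, first
    column 1 for the constant term) followed by Neumann rows (kernel normal
    derivatives at every torso vertex, first column 0).  Unknowns:
    x = [a0; a_1..a_ns], the constant term plus one weight per source.
    """
    if electrodes is None:
        electrodes = np.arange(torso.n_vertices)
    electrodes = np.asarray(electrodes, dtype=int)
    if electrodes.size == 0 or electrodes.min() < 0 or electrodes.max() >= torso.n_vertices:
        raise ValueError("invalid electrode indices")
    sources = _mfs_sources(heart, torso, inflation, deflation, heart_source_idx)
    epos = torso.vertices[electrodes]
    dirichlet = np.hstack([np.ones((len(epos), 1)), _kernel(epos, sources)])
    neumann = np.hstack(
        [
            np.zeros((torso.n_vertices, 1)),
            _kernel_normal_derivative(torso.vertices, torso.vertex_normals, sources),
        ]
    )
    A = np.vstack([dirichlet, neumann])
    return TransferSystem(
        A=A,
        method="MFS",
        heart_vertices=heart.vertices.copy(),
        n_dirichlet=len(electrodes),
        n_neumann=torso.n_vertices,
        sources=sources,
        electrodes=electrodes,
    )


def mfs_reconstruct_epicardial(system: TransferSystem, coefficients: np.ndarray) -> np.ndarray:
    """Evaluate the MFS expansion on the heart surface.

    u_H(p) = a0 + sum_j a_j / (4 pi ||p - y_j||) at each heart vertex.
    Accepts a single coefficient vector or a (ns+1, T) frame matrix.
    """
    if system.method != "MFS":
        raise ValueError("epicardial reconstruction requires an MFS system")
    coefficients = np.asarray(coefficients, dtype=float)
    ns = len(system.sources)
    if coefficients.shape[0] != ns + 1:
        raise ValueError(f"expected {ns + 1} coefficients, got {coefficients.shape[0]}")
    kern = _kernel(system.heart_vertices, system.sources)
    return coefficients[0] + kern @ coefficients[1:]


def build_mfs_forward(
    heart: SurfaceMesh,
    torso: SurfaceMesh,
    inflation: float = 1.2,
    deflation: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-posed MFS *forward* solve: epicardial pattern -> torso potentials.

    Constraints: Dirichlet at heart vertices (the given pattern) and zero
    flux at torso vertices.  Returns (A_forward, sources) with A_forward
    mapping epicardial vertex values to torso vertex potentials, used only
    to validate the forward map against the analytic annulus solution.
    """
    sources = _mfs_sources(heart, torso, inflation, deflation)
    rows_d = np.hstack([np.ones((heart.n_vertices, 1)), _kernel(heart.vertices, sources)])
    rows_n = np.hstack(
        [
            np.zeros((torso.n_vertices, 1)),
            _kernel_normal_derivative(torso.vertices, torso.vertex_normals, sources),
        ]
    )
    M = np.vstack([rows_d, rows_n])
    rhs = np.vstack([np.eye(heart.n_vertices), np.zeros((torso.n_vertices, heart.n_vertices))])
    coeff, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    eval_torso = np.hstack([np.ones((torso.n_vertices, 1)), _kernel(torso.vertices, sources)])
    return eval_torso @ coeff, sources
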