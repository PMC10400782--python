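"""Void surfaces, shape descriptors and branch detection.

A void (a connected set of probe spheres) is turned into a watertight
triangulated surface by alpha-shape reconstruction of points sampled on the
probe-sphere union boundary.  The surface doubles as a weighted graph whose
edges are mesh edges with Euclidean lengths, from which the descriptors are
computed:

``V``      enclosed volume (A^3), signed-tetrahedron sum over facets
``S``      surface area (A^2)
``L``      longest geodesic: the weighted diameter of the surface graph (A)
``nbr``    number of branches — surface protrusions reaching beyond a height
           threshold (default 5 A) from the solute vdW surface, found by
           density-peak clustering
``dmin/dmax/dave/dtotal``  statistics of the branch lengths (A)

plus the branch density ``nbr / n_heavy^(2/3)`` with ``n_heavy`` the number
of solute heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import Delaunay, cKDTree

from .extraction import ProbeGraph, Void
from .synthetic import minimum_image

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_FACTOR = 2.0  # alpha ball radius = factor * probe_radius
DEFAULT_BRANCH_THRESHOLD = 5.0  # Angstrom
DEFAULT_SAMPLE_AREA = 0.8  # one surface sample point per this many A^2


class DegenerateSurfaceError(ValueError):
    """Too few / degenerate probe centers to support a closed surface."""


class SurfaceConstructionError(RuntimeError):
    """Alpha-shape reconstruction failed to produce a watertight surface."""


@dataclass
class VoidSurface:
    """Watertight triangulated void boundary with its weighted graph."""

    vertices: np.ndarray  # (n, 3), Angstrom, unwrapped
    facets: np.ndarray  # (m, 3) int
    graph_edges: np.ndarray  # (e, 2) int, unique mesh edges
    graph_weights: np.ndarray  # (e,), Euclidean lengths
    mesh: trimesh.Trimesh = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @classmethod
    def from_mesh(cls, mesh: trimesh.Trimesh) -> "VoidSurface":
        """Wrap an existing triangulated mesh (e.g. a primitive) directly."""
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=float),
            facets=np.asarray(mesh.faces, dtype=int),
            graph_edges=np.asarray(mesh.edges_unique, dtype=int),
            graph_weights=np.asarray(mesh.edges_unique_length, dtype=float),
            mesh=mesh,
        )

    def adjacency(self):
        e, w = self.graph_edges, self.graph_weights
        n = self.n_vertices
        m = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
        return (m + m.T).tocsr()


@dataclass
class Branch:
    """One protrusion of the void surface."""

    member_ids: np.ndarray
    peak_id: int
    length: float  # Angstrom


@dataclass
class VoidDescriptors:
    """The eight shape variables plus branch density."""

    V: float
    S: float
    L: float
    nbr: int
    dmin: float
    dmax: float
    dave: float
    dtotal: float
    branch_density: float
    n_heavy: int

    def __post_init__(self):
        if self.V <= 0 or self.S <= 0:
            raise ValueError("V and S must be positive")
        if self.S**3 < 36 * np.pi * self.V**2 * (1 - 1e-9):
            raise ValueError("isoperimetric inequality violated: "
                             f"S^3={self.S**3:.3g} < 36 pi V^2")

    def as_dict(self) -> dict:
        return {
            "V": self.V, "S": self.S, "L": self.L, "nbr": self.nbr,
            "dmin": self.dmin, "dmax": self.dmax, "dave": self.dave,
            "dtotal": self.dtotal, "branch_density": self.branch_density,
            "n_heavy": self.n_heavy,
        }


DESCRIPTOR_COLUMNS = ["V", "S", "L", "nbr", "dmin", "dmax", "dave", "dtotal",
                      "branch_density"]


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------

def unwrap_void_centers(void: Void, graph: ProbeGraph) -> np.ndarray:
    """Minimum-image unwrap of a void's probe centers via BFS on its edges.

    Starting from the first member (kept at its wrapped position), every
    neighbour is placed at the minimum-image displacement from its BFS
    parent.  Raises if the unwrapped void spans the box (a percolating void
    has no consistent unwrapping).
    """
    ids = void.probe_ids
    centers = graph.centers[ids].copy()
    box = graph.box
    if box is None or len(ids) == 1:
        return centers
    local = {int(g): i for i, g in enumerate(ids)}
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(ids))}
    for a, b in graph.edges:
        ia, ib = local.get(int(a)), local.get(int(b))
        if ia is not None and ib is not None:
            nbrs[ia].append(ib)
            nbrs[ib].append(ia)
    out = np.full(len(ids), False)
    pos = centers.copy()
    order = [0]
    out[0] = True
    while order:
        i = order.pop()
        for j in nbrs[i]:
            if not out[j]:
                delta = minimum_image(centers[j] - pos[i], box)
                pos[j] = pos[i] + delta
                out[j] = True
                order.append(j)
    if not out.all():
        # fall back: place unreached probes at minimum image from centroid
        ref = pos[out].mean(axis=0)
        rest = ~out
        pos[rest] = ref + minimum_image(centers[rest] - ref, box)
    if np.any(pos.max(axis=0) - pos.min(axis=0) >= box):
        raise SurfaceConstructionError(
            "void percolates through the periodic box; no closed surface")
    return pos


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _tet_circumradius(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized)."""
    a = points[tets[:, 0]]
    b = points[tets[:, 1]] - a
    c = points[tets[:, 2]] - a
    d = points[tets[:, 3]] - a
    # circumcenter relative to a solves 2 M x = |row|^2
    M = np.stack([b, c, d], axis=1)
    rhs = 0.5 * np.stack([
        np.einsum("ij,ij->i", b, b),
        np.einsum("ij,ij->i", c, c),
        np.einsum("ij,ij->i", d, d),
    ], axis=1)
    det = np.linalg.det(M)
    ok = np.abs(det) > 1e-12
    x = np.full(M.shape[:1] + (3,), np.inf)
    if ok.any():
        x[ok] = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
    return np.where(ok, np.linalg.norm(x, axis=1), np.inf)


def sample_union_boundary(centers: np.ndarray, radii: np.ndarray,
                          sample_area: float = DEFAULT_SAMPLE_AREA
                          ) -> np.ndarray:
    """Points on the boundary of a union of spheres.

    Each sphere is covered with a Fibonacci lattice at roughly one point per
    ``sample_area`` A^2; points strictly inside another sphere are dropped.
    """
    pts = []
    for c, r in zip(centers, radii):
        n = max(int(np.ceil(4 * np.pi * r * r / sample_area)), 12)
        pts.append(c + r * _fibonacci_sphere(n))
    pts = np.vstack(pts)
    inside = np.zeros(len(pts), dtype=bool)

    # few large spheres: direct vectorized containment
    big_cut = 2.5
    big = np.flatnonzero(radii > big_cut)
    for j in big:
        d2 = ((pts - centers[j]) ** 2).sum(axis=1)
        inside |= d2 < (radii[j] - 1e-9) ** 2

    # many small spheres: bounded k-NN containment
    small = np.flatnonzero(radii <= big_cut)
    if len(small):
        tree = cKDTree(centers[small])
        kk = min(48, len(small))
        d, idx = tree.query(pts, k=kk, distance_upper_bound=big_cut)
        if kk == 1:
            d, idx = d[:, None], idx[:, None]
        hit = np.isfinite(d)
        r_near = np.zeros_like(d)
        r_near[hit] = radii[small][idx[hit]]
        inside |= np.any(hit & (d < r_near - 1e-9), axis=1)
    return pts[~inside]


def _interior_fill_points(centers: np.ndarray, radii: np.ndarray,
                          spacing: float, margin: float = 0.4) -> np.ndarray:
    """Lattice points strictly inside a union of spheres.

    The alpha complex of boundary samples alone is a thin crust with holes
    wherever the surface is locally flat (tetrahedron circumradii blow up);
    filling the interior makes the kept complex solid, so its boundary is a
    single closed surface.
    """
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    axes = [np.arange(l + spacing / 2, h, spacing) for l, h in zip(lo, hi)]
    if any(len(a) == 0 for a in axes):
        return np.empty((0, 3))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(centers)
    kk = min(16, len(centers))
    d, idx = tree.query(pts, k=kk)
    if kk == 1:
        d, idx = d[:, None], idx[:, None]
    depth = np.min(d - radii[idx], axis=1)  # negative inside the union
    return pts[depth < -margin]


def build_surface(
    void: Void,
    graph: ProbeGraph,
    alpha: float | None = None,
    sample_area: float = DEFAULT_SAMPLE_AREA,
    probe_radius: float = 1.2,
    alpha_factor: float = DEFAULT_ALPHA_FACTOR,
) -> VoidSurface:
    """Alpha-shape surface of a void's probe-sphere union.

    ``alpha`` is the alpha-ball radius: Delaunay tetrahedra with circumradius
    below it form the shape, whose boundary triangles are the surface.  It
    defaults to ``alpha_factor * probe_radius``.  The largest closed
    component is kept, oriented outward.
    """
    if alpha is None:
        alpha = alpha_factor * probe_radius
    centers = unwrap_void_centers(void, graph)
    radii = graph.empty_radii[void.probe_ids]
    if len(centers) < 1:
        raise DegenerateSurfaceError("empty void")

    pts = sample_union_boundary(centers, radii, sample_area)
    if len(pts) < 4:
        raise DegenerateSurfaceError(f"only {len(pts)} boundary points")
    spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-8:
        raise DegenerateSurfaceError("boundary points are coplanar/collinear")
    n_boundary = len(pts)
    fill = _interior_fill_points(centers, radii, spacing=alpha / 2.0)
    if len(fill):
        pts = np.vstack([pts, fill])

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # qhull degeneracy
        raise DegenerateSurfaceError(f"Delaunay failed: {exc}") from exc

    keep = _tet_circumradius(tri.points, tri.simplices) <= alpha
    tets = tri.simplices[keep]
    if len(tets) == 0:
        raise SurfaceConstructionError(
            f"no tetrahedron has circumradius <= alpha={alpha}; "
            "increase alpha")

    # boundary faces: triangles bounding exactly one kept tetrahedron
    faces = np.vstack([
        tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
        tets[:, [0, 2, 3]], tets[:, [1, 2, 3]],
    ])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    boundary = faces[counts[inv] == 1]
    if len(boundary) < 4:
        raise SurfaceConstructionError("alpha-shape boundary too small")

    mesh = trimesh.Trimesh(vertices=tri.points, faces=boundary, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) == 0:
        raise SurfaceConstructionError("no surface component")
    parts = sorted(parts, key=lambda m: len(m.faces), reverse=True)
    mesh = parts[0]
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
        trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise SurfaceConstructionError(
            f"surface not watertight after repair: {len(mesh.faces)} faces, "
            f"euler={mesh.euler_number}")
    if mesh.volume < 0:
        mesh.invert()

    edges = mesh.edges_unique
    weights = mesh.edges_unique_length
    return VoidSurface(
        vertices=np.asarray(mesh.vertices, dtype=float),
        facets=np.asarray(mesh.faces, dtype=int),
        graph_edges=np.asarray(edges, dtype=int),
        graph_weights=np.asarray(weights, dtype=float),
        mesh=mesh,
    )


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def compute_volume_area(surface: VoidSurface) -> tuple[float, float]:
    """Volume (signed-tetrahedron sum) and area of a watertight surface."""
    mesh = surface.mesh
    if not mesh.is_watertight:
        raise ValueError("surface is not watertight")
    v = float(mesh.volume)
    if v < 0:  # inward orientation slipped through: correct, don't fail
        v = -v
    return v, float(mesh.area)


def graph_diameter(n_vertices: int, edges: np.ndarray,
                   weights: np.ndarray) -> float:
    """Largest shortest-path distance between any two graph vertices."""
    e = np.asarray(edges, dtype=int).reshape(-1, 2)
    w = np.asarray(weights, dtype=float)
    m = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices))
    adj = (m + m.T).tocsr()
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(f"graph has {n_comp} components; diameter undefined")
    d = dijkstra(adj, directed=False)
    return float(d[np.isfinite(d)].max())


def longest_geodesic(surface: VoidSurface) -> float:
    """Weighted diameter of the surface graph (the length L, Angstrom)."""
    return graph_diameter(surface.n_vertices, surface.graph_edges,
                          surface.graph_weights)


def surface_heights(surface: VoidSurface, solute_pos: np.ndarray,
                    solute_radii: np.ndarray,
                    box: np.ndarray | None = None) -> np.ndarray:
    """Distance of each surface vertex to the nearest solute vdW surface."""
    solute_pos = np.asarray(solute_pos, float).reshape(-1, 3)
    solute_radii = np.asarray(solute_radii, float)
    if len(solute_pos) == 0:
        raise ValueError("no solute atoms")
    v = surface.vertices
    if box is not None:
        d = np.linalg.norm(
            minimum_image(v[:, None, :] - solute_pos[None, :, :], box), axis=2)
    else:
        d = np.linalg.norm(v[:, None, :] - solute_pos[None, :, :], axis=2)
    return np.min(d - solute_radii[None, :], axis=1)


def _density_peak_clusters(points: np.ndarray, dc: float) -> list[np.ndarray]:
    """Density-peak partition of a point cloud (Rodriguez-Laio).

    Local density is a Gaussian kernel at bandwidth ``dc`` (a continuous
    density avoids the tie plateaus an integer cutoff count produces on
    uniformly sampled surfaces); each point's separation is its distance to
    the nearest denser point.  Cluster centers are the points before the
    largest gap in the sorted log of the max-normalised density x separation
    product gamma; every other point joins the cluster of its nearest denser
    neighbour.
    """
    n = len(points)
    if n == 1:
        return [np.array([0])]
    D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1.0
    # deterministic strict ordering: density, then index
    rank = np.lexsort((np.arange(n), -rho))  # densest first
    delta = np.zeros(n)
    parent = np.full(n, -1)
    for pos in range(n):
        i = rank[pos]
        if pos == 0:
            delta[i] = D[i].max()
            parent[i] = i
            continue
        denser = rank[:pos]
        j = denser[np.argmin(D[i, denser])]
        delta[i] = D[i, j]
        parent[i] = j
    gamma = (rho / max(rho.max(), 1e-12)) * (delta / max(delta.max(), 1e-12))
    order = np.argsort(-gamma)
    g = np.log(np.maximum(gamma[order], 1e-9))
    # centers live at the top of the gamma sequence; searching the full tail
    # would find meaningless gaps between near-zero values, so the number of
    # clusters is capped at 25
    head = min(len(g) - 1, 25)
    gaps = g[:head] - g[1 : head + 1]
    n_centers = int(np.argmax(gaps)) + 1
    centers = order[:n_centers]

    labels = np.full(n, -1)
    for k, c in enumerate(centers):
        labels[c] = k
    for pos in range(n):
        i = rank[pos]
        if labels[i] < 0:
            labels[i] = labels[parent[i]]
    return [np.flatnonzero(labels == k) for k in range(n_centers)]


def detect_branches(
    surface: VoidSurface,
    solute_pos: np.ndarray,
    solute_radii: np.ndarray,
    threshold: float = DEFAULT_BRANCH_THRESHOLD,
    dc: float | None = None,
    box: np.ndarray | None = None,
) -> list[Branch]:
    """Branches: clusters of surface vertices beyond ``threshold`` from the
    solute surface, partitioned by density-peak clustering.

    ``dc`` (density cutoff) defaults to half the threshold.  Each branch's
    length is the largest vertex height in its cluster.
    """
    if dc is None:
        dc = threshold / 2.0
    h = surface_heights(surface, solute_pos, solute_radii, box)
    cand = np.flatnonzero(h > threshold)
    if len(cand) == 0:
        return []
    clusters = _density_peak_clusters(surface.vertices[cand], dc)
    branches = []
    for members in clusters:
        ids = cand[members]
        peak = ids[np.argmax(h[ids])]
        branches.append(Branch(member_ids=ids, peak_id=int(peak),
                               length=float(h[ids].max())))
    branches.sort(key=lambda b: -b.length)
    return branches


def summarize_descriptors(surface: VoidSurface, branches: list[Branch],
                          n_heavy: int) -> VoidDescriptors:
    """Assemble the descriptor vector for one frame."""
    if n_heavy <= 0:
        raise ValueError("n_heavy must be positive")
    V, S = compute_volume_area(surface)
    L = longest_geodesic(surface)
    nbr = len(branches)
    if nbr:
        lengths = np.array([b.length for b in branches])
        dmin, dmax = float(lengths.min()), float(lengths.max())
        dave, dtotal = float(lengths.mean()), float(lengths.sum())
    else:
        dmin = dmax = dave = dtotal = 0.0
    return VoidDescriptors(
        V=V, S=S, L=L, nbr=nbr, dmin=dmin, dmax=dmax, dave=dave,
        dtotal=dtotal, branch_density=nbr / n_heavy ** (2.0 / 3.0),
        n_heavy=n_heavy,
    )


def count_facets_near_group(
    surface: VoidSurface,
    solute_pos: np.ndarray,
    solute_radii: np.ndarray,
    solute_groups: list[str],
    group: str,
    box: np.ndarray | None = None,
) -> int:
    """Number of facets whose centroid's nearest solute atom is in ``group``.

    Nearness is measured to the atom vdW surface; ties go to the lowest atom
    index.
    """
    groups = list(solute_groups)
    if group not in groups:
        raise ValueError(f"unknown group {group!r}; have {sorted(set(groups))}")
    solute_pos = np.asarray(solute_pos, float).reshape(-1, 3)
    solute_radii = np.asarray(solute_radii, float)
    centroids = surface.vertices[surface.facets].mean(axis=1)
    if box is not None:
        d = np.linalg.norm(
            minimum_image(centroids[:, None, :] - solute_pos[None, :, :], box),
            axis=2)
    else:
        d = np.linalg.norm(centroids[:, None, :] - solute_pos[None, :, :],
                           axis=2)
    nearest = np.argmin(d - solute_radii[None, :], axis=1)  # argmin: lowest index wins ties
    in_group = np.array([groups[a] == group for a in nearest])
    return int(in_group.sum())


def aggregate_frames(per_frame: list[VoidDescriptors]):
    """Mean and standard error of each descriptor across frames."""
    import pandas as pd

    if not per_frame:
        raise ValueError("no frames to aggregate")
    df = pd.DataFrame([d.as_dict() for d in per_frame])
    mean = df.mean(axis=0)
    n = len(df)
    se = df.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else df.iloc[0] * 0.0
    out = pd.DataFrame({"mean": mean, "se": se})
    out.index.name = "descriptor"
    return out
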