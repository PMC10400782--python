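"""Void extraction from solvent sphere packings.

The solute is removed from a snapshot and the space left behind is meshed by
a Voronoi tessellation of the solvent atom centers (O and H treated as
spheres of vdW radius 1.52 and 1.2 A).  Each Voronoi vertex carries a maximal
empty sphere; vertices whose empty radius reaches the probe radius (1.2 A)
become probe spheres, and probes joined by Voronoi edges whose narrowest
empty radius stays above the bottleneck radius (1.1 A) are merged into voids.
The void hosting the solute is the one whose probe-sphere union overlaps the
solute's vdW volume most.

The tessellation is an ordinary Voronoi diagram of atom centers; atom radii
enter when the empty radius is measured (distance to the nearest atom
*surface*).  Periodic boundaries are handled by replicating atoms within a
shell of each face and keeping only vertices wrapped into the primary cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, cKDTree

from .synthetic import SolvatedConfiguration, minimum_image

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.2  # Angstrom
DEFAULT_BOTTLENECK_RADIUS = 1.1  # Angstrom
DEFAULT_PBC_SHELL = 6.0  # Angstrom image-replication margin
_JITTER = 1e-6  # deterministic degeneracy-breaking jitter, Angstrom


@dataclass(frozen=True)
class ExtractionParameters:
    """Probe / bottleneck radii controlling void construction (Angstrom)."""

    probe_radius: float = DEFAULT_PROBE_RADIUS
    bottleneck_radius: float = DEFAULT_BOTTLENECK_RADIUS
    pbc_shell: float = DEFAULT_PBC_SHELL

    def __post_init__(self):
        if self.probe_radius <= 0 or self.bottleneck_radius <= 0:
            raise ValueError("radii must be positive")
        if self.bottleneck_radius > self.probe_radius:
            raise ValueError(
                f"bottleneck_radius {self.bottleneck_radius} must not exceed "
                f"probe_radius {self.probe_radius}"
            )


@dataclass
class ProbeGraph:
    """Probe spheres at Voronoi vertices plus bottleneck-weighted edges."""

    centers: np.ndarray  # (n, 3) wrapped into the primary cell
    empty_radii: np.ndarray  # (n,)
    edges: np.ndarray  # (m, 2) int vertex ids
    bottlenecks: np.ndarray  # (m,)
    box: np.ndarray | None  # None for open boundaries

    @property
    def n_probes(self) -> int:
        return len(self.empty_radii)

    def adjacency(self, min_bottleneck: float | None = None):
        """Sparse symmetric adjacency, optionally gated by bottleneck."""
        if self.n_probes == 0:
            return coo_matrix((0, 0))
        if min_bottleneck is None or len(self.edges) == 0:
            e = self.edges
        else:
            e = self.edges[self.bottlenecks >= min_bottleneck]
        if len(e) == 0:
            return coo_matrix((self.n_probes, self.n_probes))
        data = np.ones(len(e))
        m = coo_matrix(
            (data, (e[:, 0], e[:, 1])), shape=(self.n_probes, self.n_probes)
        )
        return m + m.T


@dataclass
class Void:
    """A connected set of probe spheres forming one cavity."""

    probe_ids: np.ndarray
    component_id: int
    host_flag: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _replicate_for_pbc(points: np.ndarray, radii: np.ndarray, box: np.ndarray,
                       shell: float):
    """Copy atoms within ``shell`` of each face across the boundary.

    Returns replicated positions/radii and, for each replica, the index of
    its source atom in the primary cell.
    """
    shifts = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shifts.append((sx, sy, sz))
    all_pos = [points]
    all_rad = [radii]
    all_src = [np.arange(len(points))]
    lo, hi = -shell, box + shell
    for s in shifts:
        if s == (0, 0, 0):
            continue
        shifted = points + np.asarray(s) * box
        inside = np.all((shifted > lo) & (shifted < hi), axis=1)
        if np.any(inside):
            all_pos.append(shifted[inside])
            all_rad.append(radii[inside])
            all_src.append(np.flatnonzero(inside))
    return np.vstack(all_pos), np.concatenate(all_rad), np.concatenate(all_src)


def _empty_radius(points: np.ndarray, tree: cKDTree, radii: np.ndarray,
                  k: int = 16) -> np.ndarray:
    """min over atoms of (center distance - atom radius) at each point.

    Atom radii here span only 0.32 A (O vs H), so the true nearest surface is
    always among the k nearest centers for modest k.
    """
    kk = min(k, tree.n)
    d, idx = tree.query(points, k=kk)
    if kk == 1:
        d = d[:, None]
        idx = idx[:, None]
    return np.min(d - radii[idx], axis=1)


def compute_probe_spheres(
    config: SolvatedConfiguration,
    params: ExtractionParameters | None = None,
    periodic: bool = True,
) -> ProbeGraph:
    """Voronoi-vertex probe spheres of the solvent packing.

    The configuration must already have the solute removed (any solute atoms
    present are ignored with a warning).  Vertices with empty radius below
    ``params.probe_radius`` are dropped; edges carry the minimum empty radius
    sampled at the two endpoint vertices and the edge midpoint.
    """
    if params is None:
        params = ExtractionParameters()
    if config.n_solute:
        warnings.warn("solute atoms present; they are ignored — remove the "
                      "solute before probe construction", stacklevel=2)
    pos = np.asarray(config.solvent_pos, dtype=float)
    radii = np.asarray(config.solvent_radii, dtype=float)
    if len(pos) < 4:
        raise ValueError(f"need at least 4 solvent atoms, got {len(pos)}")

    box = np.asarray(config.box, dtype=float) if periodic else None
    if periodic:
        pos = np.mod(pos, box)
        work_pos, work_rad, _ = _replicate_for_pbc(pos, radii, box,
                                                   params.pbc_shell)
    else:
        work_pos, work_rad = pos, radii

    # deterministic jitter keyed to atom index breaks co-spherical degeneracy
    # in the tessellation only; empty radii are measured on the raw atoms
    n_work = len(work_pos)
    jitter = _JITTER * (np.arange(n_work * 3, dtype=float) % 7 - 3).reshape(
        n_work, 3)

    vor = Voronoi(work_pos + jitter)
    verts = vor.vertices
    tree = cKDTree(work_pos)
    v_empty = _empty_radius(verts, tree, work_rad)

    ok = v_empty >= params.probe_radius
    if periodic:
        # keep vertices lying in the primary cell; their periodic images in
        # the replication shell are recovered by wrapping when edges resolve
        in_cell = np.all((verts >= 0) & (verts < box), axis=1)
        ok &= in_cell
    else:
        # open boundary: drop the unbounded exterior vertices outside the
        # convex hull of the atom cloud
        from scipy.spatial import Delaunay as _Delaunay

        try:
            hull = _Delaunay(work_pos)
            ok &= hull.find_simplex(verts) >= 0
        except Exception:
            pass  # degenerate cloud (e.g. 4 atoms): nothing to filter

    keep_idx = np.flatnonzero(ok)
    if len(keep_idx) == 0:
        return ProbeGraph(np.empty((0, 3)), np.empty(0),
                          np.empty((0, 2), dtype=int), np.empty(0), box)

    centers = verts[keep_idx]
    radii_kept = v_empty[keep_idx]
    id_map = {int(v): i for i, v in enumerate(keep_idx)}
    kept_tree = cKDTree(np.mod(centers, box) if periodic else centers)

    def resolve(v: int) -> int:
        """Map a raw Voronoi vertex to a kept primary-cell probe id."""
        if v in id_map:
            return id_map[v]
        if not periodic:
            return -1
        w = np.mod(verts[v], box)
        d, i = kept_tree.query(w)
        return int(i) if d < 1e-4 else -1

    # Voronoi edges: consecutive vertex pairs along each ridge polygon
    pair_set = set()
    for ridge in vor.ridge_vertices:
        if -1 in ridge:
            continue
        m = len(ridge)
        for a in range(m):
            i, j = ridge[a], ridge[(a + 1) % m]
            if v_empty[i] < params.probe_radius or v_empty[j] < params.probe_radius:
                continue
            pi, pj = resolve(i), resolve(j)
            if pi < 0 or pj < 0 or pi == pj:
                continue
            key = (min(pi, pj), max(pi, pj), min(i, j), max(i, j))
            pair_set.add(key)

    pairs = sorted(pair_set)
    seen: dict[tuple[int, int], float] = {}
    if pairs:
        ii = np.array([p[2] for p in pairs])
        jj = np.array([p[3] for p in pairs])
        mids = 0.5 * (verts[ii] + verts[jj])
        mid_empty = _empty_radius(mids, tree, work_rad)
        bns = np.minimum(np.minimum(v_empty[ii], v_empty[jj]), mid_empty)
        for (pi, pj, _i, _j), bn in zip(pairs, bns):
            key = (pi, pj)
            # a periodic edge may be seen through several images: keep the
            # widest, clamped by the kept probes' own empty radii (images
            # differ at jitter level)
            bn = min(float(bn), float(radii_kept[pi]), float(radii_kept[pj]))
            if key not in seen or bn > seen[key]:
                seen[key] = bn
    edge_rows = []
    bn_rows = []
    for (pi, pj), bn in sorted(seen.items()):
        edge_rows.append((pi, pj))
        bn_rows.append(bn)

    edges = np.asarray(edge_rows, dtype=int).reshape(-1, 2)
    bottlenecks = np.asarray(bn_rows, dtype=float)
    if periodic:
        centers = np.mod(centers, box)
    return ProbeGraph(centers, radii_kept, edges, bottlenecks, box)


def merge_probes(graph: ProbeGraph,
                 params: ExtractionParameters | None = None) -> list[Void]:
    """Split probes into voids: components under bottleneck-gated edges."""
    if params is None:
        params = ExtractionParameters()
    if graph.n_probes == 0:
        return []
    adj = graph.adjacency(min_bottleneck=params.bottleneck_radius)
    n_comp, labels = connected_components(adj, directed=False)
    voids = []
    for c in range(n_comp):
        voids.append(Void(probe_ids=np.flatnonzero(labels == c),
                          component_id=c))
    # deterministic ordering: largest first, ties by smallest member id
    voids.sort(key=lambda v: (-v.n_probes, int(v.probe_ids[0])))
    for new_id, v in enumerate(voids):
        v.component_id = new_id
    return voids


def select_host_void(
    voids: list[Void],
    solute_pos: np.ndarray,
    solute_radii: np.ndarray,
    graph: ProbeGraph,
    n_samples: int = 20_000,
    seed: int = 1_234_567,
) -> Void | None:
    """Pick the void overlapping the solute vdW union most (Monte-Carlo).

    Sample points uniformly in the bounding box of the solute spheres, keep
    those inside the vdW union, and count how many fall inside each void's
    probe-sphere union.  Ties within counting resolution go to the smaller
    component id (logged).  Returns None when no void overlaps the solute.
    """
    if not voids:
        return None
    solute_pos = np.asarray(solute_pos, dtype=float).reshape(-1, 3)
    solute_radii = np.asarray(solute_radii, dtype=float)
    if len(solute_pos) == 0:
        return None
    rng = np.random.default_rng(seed)
    lo = (solute_pos - solute_radii[:, None]).min(axis=0)
    hi = (solute_pos + solute_radii[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    d2 = ((pts[:, None, :] - solute_pos[None, :, :]) ** 2).sum(axis=2)
    inside_solute = np.any(d2 <= solute_radii[None, :] ** 2, axis=1)
    pts = pts[inside_solute]
    if len(pts) == 0:
        return None

    box = graph.box
    counts = []
    for v in voids:
        c = graph.centers[v.probe_ids]
        r = graph.empty_radii[v.probe_ids]
        if box is not None:
            dd = minimum_image(pts[:, None, :] - c[None, :, :], box)
        else:
            dd = pts[:, None, :] - c[None, :, :]
        in_probe = (dd**2).sum(axis=2) <= r[None, :] ** 2
        counts.append(int(np.any(in_probe, axis=1).sum()))

    counts = np.asarray(counts)
    if counts.max() == 0:
        return None
    best = int(np.argmax(counts))
    tied = np.flatnonzero(counts == counts[best])
    if len(tied) > 1:
        best = int(min(tied, key=lambda i: voids[i].component_id))
        logger.info("host-void tie between components %s; picked %d",
                    [voids[i].component_id for i in tied],
                    voids[best].component_id)
    host = voids[best]
    host.host_flag = True
    return host


def void_probe_union_volume(void: Void, graph: ProbeGraph,
                            n_samples: int = 50_000, seed: int = 7) -> float:
    """Monte-Carlo volume of a void's probe-sphere union (cubic Angstrom)."""
    c = graph.centers[void.probe_ids]
    r = graph.empty_radii[void.probe_ids]
    box = graph.box
    rng = np.random.default_rng(seed)
    lo = (c - r[:, None]).min(axis=0)
    hi = (c + r[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    if box is not None:
        dd = minimum_image(pts[:, None, :] - c[None, :, :], box)
    else:
        dd = pts[:, None, :] - c[None, :, :]
    inside = np.any((dd**2).sum(axis=2) <= r[None, :] ** 2, axis=1)
    return float(inside.mean() * np.prod(hi - lo))


def grid_cavity_oracle(
    config: SolvatedConfiguration,
    params: ExtractionParameters | None = None,
    cell: float = 0.4,
    return_labels: bool = False,
):
    """Brute-force cavity volume on a periodic grid (test oracle).

    Marks grid cells reachable by an empty probe-radius ball: the atom-free
    space is eroded to the probe-center region (clearance >= probe_radius)
    and re-dilated by the probe radius, i.e. a morphological opening, which
    equals the union of all empty probe spheres.  Components are counted on
    the eroded (probe-center) set with 26-connectivity and periodic wrap.

    Returns ``(volume_A3, n_components)``, or with ``return_labels`` also the
    opened occupancy grid and the per-cell component labels.
    """
    if params is None:
        params = ExtractionParameters()
    if cell <= 0:
        raise ValueError("cell must be positive")
    box = np.asarray(config.box, dtype=float)
    shape = np.maximum(np.round(box / cell).astype(int), 1)
    spacing = box / shape

    axes = [
        (np.arange(s) + 0.5) * sp for s, sp in zip(shape, spacing)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    pos = np.asarray(config.solvent_pos, dtype=float)
    radii = np.asarray(config.solvent_radii, dtype=float)
    if config.n_solute:
        pos = np.vstack([pos, config.solute_pos]) if len(pos) else config.solute_pos
        radii = np.concatenate([radii, config.solute_radii])

    if len(pos) == 0:
        clearance = np.full(len(pts), np.inf)
    else:
        rep_pos, rep_rad, _ = _replicate_for_pbc(
            np.mod(pos, box), radii, box, shell=max(radii) + params.probe_radius + 2 * cell
        )
        tree = cKDTree(rep_pos)
        clearance = _empty_radius(pts, tree, rep_rad)

    core = (clearance >= params.probe_radius).reshape(shape)

    # dilate by a probe-radius ball with periodic wrap
    rad_cells = np.ceil(params.probe_radius / spacing).astype(int)
    ball = _ball_structure(rad_cells, spacing, params.probe_radius)
    padded = np.pad(core, [(r, r) for r in rad_cells], mode="wrap")
    opened = ndimage.binary_dilation(padded, structure=ball)
    sl = tuple(slice(r, r + s) for r, s in zip(rad_cells, shape))
    opened = opened[sl]

    volume = float(opened.sum() * np.prod(spacing))

    labels, n_comp = _periodic_label(core)
    if return_labels:
        return volume, n_comp, opened, labels, spacing
    return volume, n_comp


def grid_component_volume(
    config: SolvatedConfiguration,
    point: np.ndarray,
    params: ExtractionParameters | None = None,
    cell: float = 0.4,
) -> float:
    """Opened-cavity volume of the single component containing ``point``.

    Same construction as :func:`grid_cavity_oracle`, but the probe-center
    set is restricted to the 26-connected component around ``point`` before
    re-dilation, giving the brute-force volume of one cavity (e.g. the one
    hosting the solute).
    """
    if params is None:
        params = ExtractionParameters()
    box = np.asarray(config.box, dtype=float)
    _, _, _, labels, spacing = grid_cavity_oracle(
        config, params, cell, return_labels=True)
    idx = tuple(np.minimum((np.mod(np.asarray(point, float), box) / spacing
                            ).astype(int), np.array(labels.shape) - 1))
    lab = labels[idx]
    if lab == 0:
        # point sits between grid samples of the cavity; take nearest label
        occ = np.argwhere(labels > 0)
        if len(occ) == 0:
            return 0.0
        centers = (occ + 0.5) * spacing
        d = minimum_image(centers - np.mod(np.asarray(point, float), box), box)
        lab = labels[tuple(occ[np.argmin((d**2).sum(axis=1))])]
    comp = labels == lab
    rad_cells = np.ceil(params.probe_radius / spacing).astype(int)
    ball = _ball_structure(rad_cells, spacing, params.probe_radius)
    padded = np.pad(comp, [(r, r) for r in rad_cells], mode="wrap")
    opened = ndimage.binary_dilation(padded, structure=ball)
    sl = tuple(slice(r, r + s) for r, s in zip(rad_cells, comp.shape))
    return float(opened[sl].sum() * np.prod(spacing))


def _ball_structure(rad_cells: np.ndarray, spacing: np.ndarray,
                    radius: float) -> np.ndarray:
    ax = [np.arange(-r, r + 1) * sp for r, sp in zip(rad_cells, spacing)]
    bx, by, bz = np.meshgrid(*ax, indexing="ij")
    return bx**2 + by**2 + bz**2 <= radius**2 + 1e-12


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected labelling with periodic wrap via face-merging union-find."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # merge labels adjacent across each periodic face (incl. diagonal shifts)
    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        for sa in (-1, 0, 1):
            for sb in (-1, 0, 1):
                hh = np.roll(hi, (sa, sb), axis=(0, 1))
                both = (lo > 0) & (hh > 0)
                for a, b in set(zip(lo[both].ravel(), hh[both].ravel())):
                    union(int(a), int(b))

    remap = np.zeros(n + 1, dtype=int)
    roots = sorted({find(i) for i in range(1, n + 1)})
    for new, r in enumerate(roots, start=1):
        for i in range(1, n + 1):
            if find(i) == r:
                remap[i] = new
    return remap[labels], len(roots)


def voids_to_dict(voids: list[Void], graph: ProbeGraph) -> dict:
    """JSON-serializable voids: probe centers, radii and gated adjacency."""
    return {
        "box": None if graph.box is None else graph.box.tolist(),
        "voids": [
            {
                "component_id": int(v.component_id),
                "host": bool(v.host_flag),
                "centers": graph.centers[v.probe_ids].tolist(),
                "radii": graph.empty_radii[v.probe_ids].tolist(),
            }
            for v in voids
        ],
        "edges": graph.edges.tolist(),
        "bottlenecks": graph.bottlenecks.tolist(),
    }
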