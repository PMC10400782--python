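"""Synthetic solvated configurations and regression fixtures.

Real inputs to the cavity pipeline are MD snapshots of a solute in explicit
water.  This module produces geometric stand-ins with known ground truth so
every downstream stage (Voronoi probe extraction, alpha-shape surfacing,
branch detection, regression) can be validated without running dynamics:

* a water-like bath of rigid 3-site molecules packed at ambient density in an
  orthorhombic periodic box,
* phantom cavities (sphere, or star with tendrils) carved out of the bath,
  with analytic volume/area and a known branch count,
* feature tables drawn from a known linear model ``y = sum_j w_j X_j + noise``.

All randomness is local: each operation builds its own ``numpy.random
.Generator`` from the seed it is given and touches no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

# default van der Waals radii, Angstrom
VDW_RADIUS_O = 1.52
VDW_RADIUS_H = 1.2

# rigid 3-site water geometry
OH_BOND = 0.9572  # Angstrom
HOH_ANGLE_DEG = 104.52

# first-peak O-O exclusion distance used by the hard-core insertion
OO_HARD_CORE = 2.6  # Angstrom


class DensityInfeasibleError(RuntimeError):
    """Random sequential insertion could not reach the requested density."""


class GeometryError(ValueError):
    """A carved region or solute does not fit the periodic box."""


@dataclass
class SolvatedConfiguration:
    """A solute plus solvent snapshot in an orthorhombic periodic box.

    Positions are in Angstrom and wrapped into ``[0, box)``.  Solvent atoms
    are the O/H spheres of the water stand-in; solute atoms carry a group
    label (e.g. ``"N-term"``, ``"C-term"``, ``"side"``) used for facet
    counting.
    """

    box: np.ndarray  # (3,) Angstrom
    solute_pos: np.ndarray  # (n_solute, 3)
    solute_elements: list[str]
    solute_radii: np.ndarray  # (n_solute,)
    solute_groups: list[str]
    solvent_pos: np.ndarray  # (n_solvent, 3)
    solvent_elements: list[str]
    solvent_radii: np.ndarray  # (n_solvent,)
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.solute_pos = np.asarray(self.solute_pos, dtype=float).reshape(-1, 3)
        self.solvent_pos = np.asarray(self.solvent_pos, dtype=float).reshape(-1, 3)
        self.solute_radii = np.asarray(self.solute_radii, dtype=float).reshape(-1)
        self.solvent_radii = np.asarray(self.solvent_radii, dtype=float).reshape(-1)

    @property
    def n_solute(self) -> int:
        return len(self.solute_radii)

    @property
    def n_solvent(self) -> int:
        return len(self.solvent_radii)

    @property
    def n_waters(self) -> int:
        return sum(1 for e in self.solvent_elements if e == "O")

    def n_heavy(self) -> int:
        """Number of solute heavy (non-hydrogen) atoms."""
        return sum(1 for e in self.solute_elements if e.upper() != "H")

    def without_solute(self) -> "SolvatedConfiguration":
        return replace(
            self,
            solute_pos=np.empty((0, 3)),
            solute_elements=[],
            solute_radii=np.empty(0),
            solute_groups=[],
        )

    def wrapped(self) -> "SolvatedConfiguration":
        return replace(
            self,
            solute_pos=np.mod(self.solute_pos, self.box),
            solvent_pos=np.mod(self.solvent_pos, self.box),
        )

    def to_dict(self) -> dict:
        return {
            "box": self.box.tolist(),
            "frame_id": self.frame_id,
            "solute": {
                "positions": self.solute_pos.tolist(),
                "elements": list(self.solute_elements),
                "radii": self.solute_radii.tolist(),
                "groups": list(self.solute_groups),
            },
            "solvent": {
                "positions": self.solvent_pos.tolist(),
                "elements": list(self.solvent_elements),
                "radii": self.solvent_radii.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolvatedConfiguration":
        return cls(
            box=np.array(d["box"], dtype=float),
            solute_pos=np.array(d["solute"]["positions"], dtype=float).reshape(-1, 3),
            solute_elements=list(d["solute"]["elements"]),
            solute_radii=np.array(d["solute"]["radii"], dtype=float),
            solute_groups=list(d["solute"]["groups"]),
            solvent_pos=np.array(d["solvent"]["positions"], dtype=float).reshape(-1, 3),
            solvent_elements=list(d["solvent"]["elements"]),
            solvent_radii=np.array(d["solvent"]["radii"], dtype=float),
            frame_id=int(d.get("frame_id", 0)),
        )


@dataclass
class PhantomTruth:
    """Analytic ground truth for a carved phantom cavity."""

    cavity_kind: str  # "sphere" | "star"
    analytic_volume: float  # cubic Angstrom
    analytic_area: float  # square Angstrom
    true_branch_count: int
    tendril_length: float  # Angstrom
    volume_se: float = 0.0  # Monte-Carlo standard error on the volume
    tendril_axes: np.ndarray | None = None  # (k, 3) unit directions

    def to_dict(self) -> dict:
        return {
            "cavity_kind": self.cavity_kind,
            "analytic_volume": self.analytic_volume,
            "analytic_area": self.analytic_area,
            "true_branch_count": self.true_branch_count,
            "tendril_length": self.tendril_length,
            "volume_se": self.volume_se,
        }


@dataclass
class RegressionFixture:
    """Features and targets drawn from a known linear model."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,)
    true_weights: np.ndarray  # (p,), standardized scale
    noise_sd: float
    seed: int
    feature_names: list[str] = field(default_factory=list)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return delta - box * np.round(delta / box)


def _water_sites(rng: np.random.Generator) -> np.ndarray:
    """O at origin plus two H at the rigid bond length/angle, random orientation."""
    half = np.deg2rad(HOH_ANGLE_DEG) / 2.0
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [OH_BOND * np.sin(half), 0.0, OH_BOND * np.cos(half)],
            [-OH_BOND * np.sin(half), 0.0, OH_BOND * np.cos(half)],
        ]
    )
    # uniform random rotation via QR of a Gaussian matrix
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return local @ q.T


def generate_water_bath(
    box_side: float,
    number_density: float = 33.4,
    seed: int = 0,
    hard_core: float = OO_HARD_CORE,
    max_attempts_per_molecule: int = 2000,
) -> SolvatedConfiguration:
    """Pack rigid 3-site waters into a cubic periodic box.

    Parameters
    ----------
    box_side : float
        Cube edge, Angstrom (> 10).
    number_density : float
        Target molecular density in molecules/nm^3 (ambient water is ~33.4).
    seed : int
        Seed for the local random generator; identical seeds give identical
        configurations.
    hard_core : float
        Minimum-image O-O exclusion distance, Angstrom.

    Returns
    -------
    SolvatedConfiguration with no solute and ``round(density * volume)``
    waters, or raises :class:`DensityInfeasibleError` if random sequential
    insertion cannot reach within 5% of that count.
    """
    if box_side <= 10:
        raise ValueError(f"box_side must exceed 10 A, got {box_side}")
    if not (10 < number_density < 40):
        raise ValueError(
            f"number_density must lie in (10, 40) /nm^3, got {number_density}"
        )
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_side))
    volume_nm3 = (box_side / 10.0) ** 3
    target = int(round(number_density * volume_nm3))

    o_pos: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_molecule * target
    while len(o_pos) < target and attempts < budget:
        attempts += 1
        trial = rng.uniform(0.0, box_side, size=3)
        if o_pos:
            d = minimum_image(np.asarray(o_pos) - trial, box)
            if np.min(np.einsum("ij,ij->i", d, d)) < hard_core**2:
                continue
        o_pos.append(trial)

    achieved = len(o_pos)
    if achieved < 0.95 * target:
        raise DensityInfeasibleError(
            f"placed {achieved}/{target} waters after {attempts} attempts; "
            f"density {number_density}/nm^3 infeasible at hard core {hard_core} A"
        )

    positions = []
    elements = []
    radii = []
    for o in o_pos:
        sites = _water_sites(rng) + o
        positions.extend(sites)
        elements.extend(["O", "H", "H"])
        radii.extend([VDW_RADIUS_O, VDW_RADIUS_H, VDW_RADIUS_H])

    return SolvatedConfiguration(
        box=box,
        solute_pos=np.empty((0, 3)),
        solute_elements=[],
        solute_radii=np.empty(0),
        solute_groups=[],
        solvent_pos=np.mod(np.asarray(positions), box),
        solvent_elements=elements,
        solvent_radii=np.asarray(radii),
    )


def _star_axes(n_tendrils: int, rng: np.random.Generator, min_angle_deg: float = 60.0):
    """Unit tendril directions with pairwise angular separation above a floor."""
    if n_tendrils <= 6:
        # well-separated canonical directions, lightly rotated for generality
        canon = np.array(
            [
                [1, 0, 0],
                [-1, 0, 0],
                [0, 1, 0],
                [0, -1, 0],
                [0, 0, 1],
                [0, 0, -1],
            ],
            dtype=float,
        )[:n_tendrils]
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        return canon @ q.T
    # rejection sampling for larger counts
    cos_floor = np.cos(np.deg2rad(min_angle_deg))
    axes: list[np.ndarray] = []
    for _ in range(100000):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.dot(v, a) < cos_floor for a in axes):
            axes.append(v)
            if len(axes) == n_tendrils:
                return np.asarray(axes)
    raise GeometryError(f"cannot place {n_tendrils} tendrils above {min_angle_deg} deg")


def _region_distance(
    points: np.ndarray,
    center: np.ndarray,
    core_radius: float,
    axes: np.ndarray | None,
    tendril_length: float,
    tendril_radius: float,
    box: np.ndarray,
) -> np.ndarray:
    """Signed distance from points to the carved region (negative inside).

    The region is a core sphere plus, for stars, capsules along each axis:
    a segment from the center to ``center + axis*(core_radius +
    tendril_length - tendril_radius)`` swept by ``tendril_radius``, so each
    tendril tip reaches ``core_radius + tendril_length`` from the center.
    """
    d = minimum_image(points - center, box)
    dist = np.linalg.norm(d, axis=1) - core_radius
    if axes is not None:
        seg_len = max(core_radius + tendril_length - tendril_radius, 0.0)
        for ax in axes:
            t = np.clip(d @ ax, 0.0, seg_len)
            closest = t[:, None] * ax[None, :]
            cap_dist = np.linalg.norm(d - closest, axis=1) - tendril_radius
            dist = np.minimum(dist, cap_dist)
    return dist


def carve_phantom_cavity(
    config: SolvatedConfiguration,
    kind: str,
    center: np.ndarray,
    core_radius: float,
    n_tendrils: int = 0,
    tendril_length: float = 8.0,
    tendril_radius: float = 2.0,
    seed: int = 0,
    mc_samples: int = 1_000_000,
) -> tuple[SolvatedConfiguration, PhantomTruth]:
    """Remove every water whose any atom sphere intersects a carved region.

    ``kind`` is ``"sphere"`` or ``"star"``.  The sphere volume/area are
    analytic; the star union volume is estimated by Monte-Carlo with
    ``mc_samples`` points and its standard error recorded.
    A ``core_radius`` of 0 carves nothing and returns the configuration
    unchanged.
    """
    if kind not in ("sphere", "star"):
        raise ValueError(f"kind must be 'sphere' or 'star', got {kind!r}")
    center = np.asarray(center, dtype=float)
    box = config.box
    rng = np.random.default_rng(seed)

    if core_radius < 0:
        raise ValueError("core_radius must be >= 0")
    if core_radius == 0:
        truth = PhantomTruth(kind, 0.0, 0.0, 0, 0.0)
        return config, truth

    reach = core_radius if kind == "sphere" else core_radius + tendril_length
    if 2 * reach >= np.min(box):
        raise GeometryError(
            f"carved region of reach {reach} A does not fit box {box}"
        )

    axes = None
    if kind == "star":
        if n_tendrils < 1:
            raise ValueError("star cavity needs n_tendrils >= 1")
        axes = _star_axes(n_tendrils, rng)

    # a water is removed if any of its 3 atom spheres touches the region
    dist = _region_distance(
        config.solvent_pos, center, core_radius, axes, tendril_length,
        tendril_radius, box,
    )
    atom_hits = dist < config.solvent_radii
    mol_hits = atom_hits.reshape(-1, 3).any(axis=1)
    keep = np.repeat(~mol_hits, 3)

    carved = replace(
        config,
        solvent_pos=config.solvent_pos[keep],
        solvent_elements=[e for e, k in zip(config.solvent_elements, keep) if k],
        solvent_radii=config.solvent_radii[keep],
    )

    if kind == "sphere":
        vol = 4.0 / 3.0 * np.pi * core_radius**3
        area = 4.0 * np.pi * core_radius**2
        truth = PhantomTruth("sphere", vol, area, 0, 0.0)
    else:
        # Monte-Carlo union volume over the bounding cube of the region
        half = reach
        samples = rng.uniform(-half, half, size=(mc_samples, 3)) + center
        inside = _region_distance(
            samples, center, core_radius, axes, tendril_length, tendril_radius, box
        ) < 0.0
        frac = inside.mean()
        bbox_vol = (2 * half) ** 3
        vol = frac * bbox_vol
        se = bbox_vol * np.sqrt(frac * (1 - frac) / mc_samples)
        area = 4.0 * np.pi * core_radius**2  # core only; tendril area not analytic
        truth = PhantomTruth("star", vol, area, n_tendrils, tendril_length, se,
                             tendril_axes=axes)

    return carved, truth


def line_cavity_wall(
    config: SolvatedConfiguration,
    truth: PhantomTruth,
    center: np.ndarray,
    core_radius: float,
    tendril_length: float = 8.0,
    tendril_radius: float = 2.0,
    seed: int = 0,
    wall_spacing: float = 1.25,
) -> SolvatedConfiguration:
    """Tile the carved-region wall with tangent, outward-oriented waters.

    Wall oxygens are placed on the region's offset surface (one O radius
    outside it) so their vdW spheres touch the carved surface exactly; the
    two hydrogens point away from the region.  This emulates the tight first
    hydration shell of real water, which a random-insertion bath lacks: it
    pins the void boundary to the carved geometry and seals it off from bulk
    interstitial voids.  Wall spacing is far below the bath O-O hard core on
    purpose — the wall is a geometric boundary, not an equilibrium packing.
    """
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    box = config.box
    axes = truth.tendril_axes
    offset = VDW_RADIUS_O

    def region_dist(points):
        return _region_distance(points, center, core_radius, axes,
                                tendril_length, tendril_radius, box)

    # dense candidate points on the offset surfaces of each primitive
    cands = []
    n_sphere = max(int(8 * 4 * np.pi * (core_radius + offset) ** 2), 200)
    v = rng.normal(size=(n_sphere, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cands.append(center + (core_radius + offset) * v)
    if axes is not None:
        seg_len = max(core_radius + tendril_length - tendril_radius, 0.0)
        r_off = tendril_radius + offset
        for ax in axes:
            # orthonormal frame for the capsule axis
            u = np.array([1.0, 0.0, 0.0])
            if abs(ax[0]) > 0.9:
                u = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(ax, u)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(ax, e1)
            n_lat = max(int(8 * 2 * np.pi * r_off * seg_len), 100)
            t = rng.uniform(0.0, seg_len, size=n_lat)
            phi = rng.uniform(0.0, 2 * np.pi, size=n_lat)
            lat = (center + t[:, None] * ax
                   + r_off * (np.cos(phi)[:, None] * e1
                              + np.sin(phi)[:, None] * e2))
            cands.append(lat)
            n_cap = max(int(8 * 2 * np.pi * r_off**2), 50)
            w = rng.normal(size=(n_cap, 3))
            w /= np.linalg.norm(w, axis=1, keepdims=True)
            w = np.where((w @ ax)[:, None] < 0, -w, w)  # outward hemisphere
            cands.append(center + seg_len * ax + r_off * w)
    cands = np.vstack(cands)

    # keep only points on the union's offset surface (not inside another
    # primitive's offset), then thin to the wall spacing greedily
    d = region_dist(cands)
    cands = cands[d >= offset - 1e-6]
    order = rng.permutation(len(cands))
    accepted: list[np.ndarray] = []
    acc = np.empty((0, 3))
    for i in order:
        p = cands[i]
        if len(accepted):
            dd = minimum_image(acc - p, box)
            if np.min(np.einsum("ij,ij->i", dd, dd)) < wall_spacing**2:
                continue
        accepted.append(p)
        acc = np.asarray(accepted)

    # outward normal = gradient of the region distance field
    eps = 1e-4
    grads = np.empty_like(acc)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = eps
        grads[:, k] = (region_dist(acc + dp) - region_dist(acc - dp)) / (2 * eps)
    grads /= np.linalg.norm(grads, axis=1, keepdims=True)

    half = np.deg2rad(HOH_ANGLE_DEG) / 2.0
    positions = []
    elements = []
    radii = []
    for o, n_out in zip(acc, grads):
        u = np.array([1.0, 0.0, 0.0])
        if abs(n_out[0]) > 0.9:
            u = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n_out, u)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n_out, e1)
        phi = rng.uniform(0.0, 2 * np.pi)
        t_dir = np.cos(phi) * e1 + np.sin(phi) * e2
        # H-O-H bisector along the outward normal
        h1 = o + OH_BOND * (np.cos(half) * n_out + np.sin(half) * t_dir)
        h2 = o + OH_BOND * (np.cos(half) * n_out - np.sin(half) * t_dir)
        positions.extend([o, h1, h2])
        elements.extend(["O", "H", "H"])
        radii.extend([VDW_RADIUS_O, VDW_RADIUS_H, VDW_RADIUS_H])

    all_pos = np.vstack([config.solvent_pos, np.mod(np.asarray(positions), box)])
    return replace(
        config,
        solvent_pos=all_pos,
        solvent_elements=list(config.solvent_elements) + elements,
        solvent_radii=np.concatenate([config.solvent_radii, np.asarray(radii)]),
    )


def make_phantom_frame(
    kind: str,
    core_radius: float,
    n_tendrils: int = 0,
    tendril_length: float = 8.0,
    tendril_radius: float = 2.0,
    solute_radius: float | None = None,
    box_side: float = 30.0,
    number_density: float = 33.4,
    seed: int = 0,
    frame_id: int = 0,
) -> tuple[SolvatedConfiguration, PhantomTruth]:
    """Bath + carve + wall lining + centered spherical solute, in one call.

    The standard phantom fixture: a water bath with a cavity of known
    geometry whose wall is lined (see :func:`line_cavity_wall`) and a single
    spherical solute atom at the center providing the reference surface for
    branch heights.  ``solute_radius`` defaults to one O radius short of
    ``core_radius`` for spheres and ``core_radius - 0.5`` for stars (clear of
    the wall waters while keeping tendril heights close to their length).
    """
    bath = generate_water_bath(box_side, number_density, seed=seed)
    center = bath.box / 2.0
    carved, truth = carve_phantom_cavity(
        bath, kind, center, core_radius, n_tendrils=n_tendrils,
        tendril_length=tendril_length, tendril_radius=tendril_radius,
        seed=seed + 1,
    )
    lined = line_cavity_wall(
        carved, truth, center, core_radius, tendril_length=tendril_length,
        tendril_radius=tendril_radius, seed=seed + 2,
    )
    if solute_radius is None:
        solute_radius = core_radius - 1.0 if kind == "sphere" else core_radius - 0.5
    framed = place_model_solute(
        lined, [((0.0, 0.0, 0.0), "C", float(solute_radius), "core")]
    )
    framed.frame_id = frame_id
    return framed, truth


def place_model_solute(
    config: SolvatedConfiguration,
    solute_spec: list[tuple],
) -> SolvatedConfiguration:
    """Insert solute atoms (offsets relative to the box center) into a bath.

    Each spec entry is ``(offset_xyz, element, vdw_radius, group_label)``.
    Waters whose any atom sphere overlaps any solute vdW sphere are removed;
    surviving solvent atoms are untouched.
    """
    if not solute_spec:
        raise ValueError("solute_spec is empty")
    box = config.box
    center = box / 2.0
    offsets = np.asarray([s[0] for s in solute_spec], dtype=float).reshape(-1, 3)
    if np.any(np.ptp(offsets, axis=0) >= box):
        raise GeometryError("solute does not fit in the box")
    pos = np.mod(offsets + center, box)
    elements = [s[1] for s in solute_spec]
    radii = np.asarray([s[2] for s in solute_spec], dtype=float)
    groups = [s[3] for s in solute_spec]

    mol_hit = np.zeros(config.n_waters, dtype=bool)
    for p, r in zip(pos, radii):
        d = minimum_image(config.solvent_pos - p, box)
        overlap = np.linalg.norm(d, axis=1) < (r + config.solvent_radii)
        mol_hit |= overlap.reshape(-1, 3).any(axis=1)
    keep = np.repeat(~mol_hit, 3)

    return replace(
        config,
        solute_pos=pos,
        solute_elements=elements,
        solute_radii=radii,
        solute_groups=groups,
        solvent_pos=config.solvent_pos[keep],
        solvent_elements=[e for e, k in zip(config.solvent_elements, keep) if k],
        solvent_radii=config.solvent_radii[keep],
    )


def generate_regression_fixture(
    n: int,
    true_weights,
    noise_sd: float,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> RegressionFixture:
    """Draw an n x p feature table with ``y = X @ w + N(0, noise_sd)``.

    Columns of X are independent standard normals, so the generating weights
    are already on the standardized scale up to sampling noise.
    """
    w = np.asarray(true_weights, dtype=float)
    p = len(w)
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 = {p + 2}, got n = {n}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ w + rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else X @ w
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    return RegressionFixture(X=X, y=y, true_weights=w, noise_sd=float(noise_sd),
                             seed=int(seed), feature_names=list(feature_names))


def save_fixture_csv(fix: RegressionFixture, path) -> None:
    import pandas as pd

    df = pd.DataFrame(fix.X, columns=fix.feature_names)
    df["y"] = fix.y
    df.to_csv(path, index=False)


def save_truth_json(truth: PhantomTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
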