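"""Grid-based negative-image cavity detection at interfaces.

A cavity is modelled as the set of unoccupied, partially buried lattice
points near the region where the binding partner (protein chain or
ligand) sits. The lattice is seeded on the partner-side atoms of the
interaction patch, points clashing with the host protein are removed,
the remainder is scored for buriedness by ray casting against the host,
thresholded, clustered by 26-connectivity, and each surviving probe is
assigned a pharmacophore type complementary to its nearest typed host
atom.

The grid is axis-aligned, so probe placement is translation-equivariant
but not rotation-equivariant; shape descriptors computed downstream are
rotation-invariant functions of the probe cloud.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._atom_types import COMPLEMENT, atom_functional_class
from .model import Atom, coords_array


class ProbeType(enum.Enum):
    HYDROPHOBIC = "HYDROPHOBIC"
    AROMATIC = "AROMATIC"
    HB_ACCEPTOR = "HB_ACCEPTOR"
    HB_DONOR = "HB_DONOR"
    ACCEPTOR_NEG = "ACCEPTOR_NEG"
    DONOR_POS = "DONOR_POS"
    DUMMY = "DUMMY"


TYPED_PROBE_TYPES = [t for t in ProbeType if t is not ProbeType.DUMMY]


@dataclass
class CavityParams:
    """Lattice and scoring parameters for cavity detection.

    spacing/margin/clash_distance/ray_length in Angstrom; buriedness is a
    blocked-ray count out of ``n_rays``. ``min_buriedness`` = 55 of 120
    rays corresponds to roughly 46% occlusion.
    """

    spacing: float = 1.5
    margin: float = 4.0
    clash_distance: float = 2.5
    n_rays: int = 120
    ray_length: float = 8.0
    min_buriedness: int = 55
    min_probes: int = 10
    probe_range: float = 4.0   # nearest-atom search range for probe typing
    atom_radius: float = 1.7   # blocking-sphere radius for ray casting


@dataclass
class Probe:
    coords: np.ndarray
    probe_type: ProbeType
    buriedness: int
    grid_index: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


class PocketSource(enum.Enum):
    HD_ORTHOSTERIC = "HD_ORTHOSTERIC"
    PL = "PL"


@dataclass
class Pocket:
    pocket_id: str
    probes: list[Probe]
    source: PocketSource = PocketSource.HD_ORTHOSTERIC
    structure_id: str = ""
    facing: str = ""

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probe_coords(self) -> np.ndarray:
        if not self.probes:
            return np.empty((0, 3))
        return np.vstack([p.coords for p in self.probes])


@dataclass
class Grid:
    origin: np.ndarray       # (3,) A
    spacing: float
    dims: tuple[int, int, int]
    occupied: Optional[np.ndarray] = None  # bool, shape dims

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    def points(self) -> np.ndarray:
        """All lattice points as an (N, 3) array in C index order."""
        nx, ny, nz = self.dims
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return self.origin + self.spacing * idx

    def point(self, i: int, j: int, k: int) -> np.ndarray:
        return self.origin + self.spacing * np.array([i, j, k], dtype=float)


def build_grid(seed_atoms: Sequence[Atom], spacing: float = 1.5,
               margin: float = 4.0) -> Grid:
    """Axis-aligned lattice covering the seed-region bounding box + margin.

    The origin is snapped down to a multiple of ``spacing`` so that
    identical inputs always produce the identical lattice.
    """
    if not seed_atoms:
        raise ValueError("empty seed region")
    xyz = coords_array(list(seed_atoms))
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = tuple(int(np.floor((hi[i] - origin[i]) / spacing)) + 1
                 for i in range(3))
    return Grid(origin=origin, spacing=spacing, dims=dims)


def occupancy(grid: Grid, atoms: Sequence[Atom],
              clash_distance: float = 2.5) -> np.ndarray:
    """Boolean mask: lattice point within ``clash_distance`` of a heavy atom."""
    heavy = [a for a in atoms if a.is_heavy]
    mask = np.zeros(grid.dims, dtype=bool)
    if heavy:
        tree = cKDTree(coords_array(heavy))
        pts = grid.points()
        hits = tree.query_ball_point(pts, r=clash_distance,
                                     return_length=True)
        mask = (hits > 0).reshape(grid.dims)
    grid.occupied = mask
    return mask


def ray_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = 2.0 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _buriedness_batch(points: np.ndarray, atom_xyz: np.ndarray,
                      dirs: np.ndarray, ray_length: float,
                      atom_radius: float) -> np.ndarray:
    """Blocked-ray counts for many points against one atom set."""
    counts = np.zeros(len(points), dtype=int)
    if len(atom_xyz) == 0:
        return counts
    tree = cKDTree(atom_xyz)
    reach = ray_length + atom_radius
    nbrs = tree.query_ball_point(points, r=reach)
    r2 = atom_radius * atom_radius
    for idx, (pt, nbr) in enumerate(zip(points, nbrs)):
        if not nbr:
            continue
        rel = atom_xyz[nbr] - pt                      # (m, 3)
        d2 = np.einsum("ij,ij->i", rel, rel)          # (m,)
        if np.any(d2 <= r2):        # point inside a blocking sphere
            counts[idx] = len(dirs)
            continue
        t = rel @ dirs.T                              # (m, B)
        perp2 = d2[:, None] - t * t
        disc = r2 - perp2
        hit = disc >= 0.0
        # first intersection along the ray must lie within ray_length
        entry = np.where(hit, t - np.sqrt(np.where(hit, disc, 0.0)), np.inf)
        blocked = hit & (t > 0.0) & (entry <= ray_length)
        counts[idx] = int(np.count_nonzero(blocked.any(axis=0)))
    return counts


def buriedness(point: np.ndarray, protein_atoms: Sequence[Atom],
               n_rays: int = 120, ray_length: float = 8.0,
               atom_radius: float = 1.7) -> int:
    """Count of rays (0..n_rays) blocked by host heavy atoms."""
    heavy = coords_array([a for a in protein_atoms if a.is_heavy])
    dirs = ray_directions(n_rays)
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    return int(_buriedness_batch(pt, heavy, dirs, ray_length, atom_radius)[0])


def _typed_atoms(atoms: Sequence[Atom]):
    """Coordinates, functional class and serial of every typed heavy atom."""
    coords, classes, serials = [], [], []
    for a in atoms:
        cls = atom_functional_class(a.res_name, a.name, a.element)
        if cls is None:
            continue
        coords.append(a.coords)
        classes.append(cls)
        serials.append(a.serial)
    xyz = np.vstack(coords) if coords else np.empty((0, 3))
    return xyz, classes, np.asarray(serials)


def assign_probe_type(point: np.ndarray, protein_atoms: Sequence[Atom],
                      probe_range: float = 4.0) -> ProbeType:
    """Complementary probe type from the nearest typed host atom.

    Ties are broken by smaller distance, then smaller atom serial; a point
    with no typed atom within ``probe_range`` is a DUMMY probe.
    """
    xyz, classes, serials = _typed_atoms(protein_atoms)
    if len(xyz) == 0:
        return ProbeType.DUMMY
    pt = np.asarray(point, dtype=float)
    d = np.linalg.norm(xyz - pt, axis=1)
    in_range = np.nonzero(d <= probe_range)[0]
    if in_range.size == 0:
        return ProbeType.DUMMY
    order = sorted(in_range, key=lambda i: (d[i], serials[i]))
    return ProbeType[COMPLEMENT[classes[order[0]]]]


def detect_pockets(host_atoms: Sequence[Atom], seed_atoms: Sequence[Atom],
                   params: CavityParams | None = None,
                   structure_id: str = "",
                   source: PocketSource = PocketSource.HD_ORTHOSTERIC,
                   facing: str = "") -> list[Pocket]:
    """Full negative-image pipeline on one host/seed pair.

    host_atoms: the chain that owns the pocket (its atoms occlude and
    type the probes). seed_atoms: the partner-side patch atoms (protein
    partner for heterodimers, ligand for protein-ligand complexes) that
    define where to look. Returns pockets ordered by descending probe
    count; an input with no surviving cluster returns an empty list.
    """
    if params is None:
        params = CavityParams()
    if not seed_atoms:
        raise ValueError("empty seed region")
    host_atoms = list(host_atoms)
    grid = build_grid(seed_atoms, spacing=params.spacing, margin=params.margin)
    occ = occupancy(grid, host_atoms, clash_distance=params.clash_distance)

    pts = grid.points()
    free_flat = ~occ.reshape(-1)
    free_idx = np.nonzero(free_flat)[0]
    if free_idx.size == 0:
        return []
    heavy_xyz = coords_array([a for a in host_atoms if a.is_heavy])
    dirs = ray_directions(params.n_rays)
    bur = _buriedness_batch(pts[free_idx], heavy_xyz, dirs,
                            params.ray_length, params.atom_radius)
    keep = bur >= params.min_buriedness

    mask = np.zeros(grid.dims, dtype=bool)
    flat_mask = mask.reshape(-1)
    flat_mask[free_idx[keep]] = True
    bur_grid = np.zeros(grid.dims, dtype=int).reshape(-1)
    bur_grid[free_idx] = bur
    bur_grid = bur_grid.reshape(grid.dims)

    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n_lab == 0:
        return []

    xyz_typed, classes, serials = _typed_atoms(host_atoms)
    typed_tree = cKDTree(xyz_typed) if len(xyz_typed) else None

    clusters = []
    for lab in range(1, n_lab + 1):
        ijk = np.argwhere(labels == lab)
        if len(ijk) < params.min_probes:
            continue
        clusters.append(ijk)
    # descending size; ties by smallest first lattice index (row-major)
    clusters.sort(key=lambda ijk: (-len(ijk), tuple(ijk[0])))

    pockets: list[Pocket] = []
    for rank, ijk in enumerate(clusters):
        probes = []
        for (i, j, k) in ijk:
            pt = grid.point(i, j, k)
            ptype = ProbeType.DUMMY
            if typed_tree is not None:
                cand = typed_tree.query_ball_point(pt, r=params.probe_range)
                if cand:
                    dists = np.linalg.norm(xyz_typed[cand] - pt, axis=1)
                    best = min(range(len(cand)),
                               key=lambda q: (dists[q], serials[cand[q]]))
                    ptype = ProbeType[COMPLEMENT[classes[cand[best]]]]
            probes.append(Probe(coords=pt, probe_type=ptype,
                                buriedness=int(bur_grid[i, j, k]),
                                grid_index=(int(i), int(j), int(k))))
        pid = f"{structure_id}:{facing}:{rank}" if structure_id else str(rank)
        pockets.append(Pocket(pocket_id=pid, probes=probes, source=source,
                              structure_id=structure_id, facing=facing))
    return pockets
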