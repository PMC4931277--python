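"""Membrane-bound particle agents constrained to the cell boundary.

Two independent particle layers live on the boundary of the in-silico
cell: blue particles are cortical force generators (they set the division
axis through the cell vector) and yellow particles are Delta molecules
(their partition between the daughters initializes the fate ODE).

Initialization encodes the cell shape: a random boundary site at distance
``d1`` from the centre of mass is accepted when ``d1`` exceeds the
distance ``d2`` of a second site drawn uniformly from the whole lattice,
which makes the per-site generation probability roughly proportional to
``d1^3`` — boundary sites far from the centre (the spiky end) are loaded
most heavily.  During mitotic rounding every accepted copy attempt can
strand a particle off the boundary; it is repaired onto one of the nearest
boundary sites.  Once per mcs each particle takes a random-walk step to a
uniformly chosen boundary site in the open Euclidean annulus
``(s - L/2, s + L/2)`` around its position (``s`` = step size, ``L`` =
lattice length).  Particle counts are conserved from initialization to
division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpm import NEIGH6, Lattice

__all__ = [
    "BLUE",
    "YELLOW",
    "ParticleSet",
    "boundary_sites",
    "boundary_mask",
    "init_particles_shape_weighted",
    "init_particles_uniform",
    "reattach_after_copy",
    "diffuse_particles",
    "cell_vector",
    "partition_particles",
]

BLUE = 0      # cortical force generators
YELLOW = 1    # Delta molecules


@dataclass
class ParticleSet:
    """Site-valued particles of one color bound to one cell's boundary."""

    positions: np.ndarray          # (n, 3) int site coordinates
    color: int = YELLOW
    cell: int = 1
    step: float = 2.0              # lattice lengths per mcs
    stuck_events: int = 0          # diffusion steps with an empty annulus
    flags: list = field(default_factory=list)

    def __post_init__(self):
        # own copy: positions are mutated in place by the walk/reattachment
        self.positions = np.array(self.positions, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.positions)


def boundary_mask(lattice: Lattice, cell: int) -> np.ndarray:
    """Boolean grid of the cell's boundary sites (6-face adjacency).

    A boundary site belongs to the cell and touches at least one 6-neighbor
    with a different identifier (the lattice exterior counts as medium).
    """
    ids = lattice.cell_ids
    mine = ids == cell
    padded = np.pad(ids, 1, constant_values=0)
    other = np.zeros_like(mine)
    for dx, dy, dz in NEIGH6:
        shifted = padded[
            1 + dx : padded.shape[0] - 1 + dx,
            1 + dy : padded.shape[1] - 1 + dy,
            1 + dz : padded.shape[2] - 1 + dz,
        ]
        other |= shifted != cell
    return mine & other


def boundary_sites(lattice: Lattice, cell: int) -> np.ndarray:
    """(m, 3) sorted site coordinates of the cell boundary."""
    if lattice.volumes.get(cell, 0) == 0:
        raise ValueError(f"cell {cell} is empty")
    return np.argwhere(boundary_mask(lattice, cell))


def _center_of_mass(lattice: Lattice, cell: int) -> np.ndarray:
    return lattice.centroid(cell)


def init_particles_shape_weighted(
    lattice: Lattice,
    cell: int,
    n_particles: int,
    rng: np.random.Generator,
    color: int = YELLOW,
    step: float = 2.0,
) -> ParticleSet:
    """Distance-cubed-weighted initialization on the cell boundary.

    Repeats until ``n_particles`` are generated: draw a random boundary
    site (distance ``d1`` from the centre of mass), draw a random site from
    the whole lattice (distance ``d2`` from the same centre), and generate
    a particle at the boundary site iff ``d1 > d2``.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    bsites = boundary_sites(lattice, cell)
    if len(bsites) == 0:
        raise ValueError("cell has no boundary sites")
    if n_particles == 0:
        return ParticleSet(np.empty((0, 3)), color=color, cell=cell, step=step)
    com = _center_of_mass(lattice, cell)
    centers = bsites + 0.5
    d1 = np.linalg.norm(centers - com, axis=1)
    shape = np.asarray(lattice.cell_ids.shape)
    # the whole-lattice draw always spans the boundary distances (the
    # farthest lattice corner bounds every interior distance), but the
    # d^3 proportionality flattens for boundary sites farther than the
    # inscribed lattice radius; size the medium margin accordingly
    placed = np.empty((n_particles, 3), dtype=np.int64)
    count = 0
    while count < n_particles:
        # vectorized batch of paired draws
        batch = max(64, 2 * (n_particles - count))
        i = rng.integers(0, len(bsites), size=batch)
        probe = rng.integers(0, shape, size=(batch, 3)) + 0.5
        d2 = np.linalg.norm(probe - com, axis=1)
        ok = np.flatnonzero(d1[i] > d2)[: n_particles - count]
        placed[count : count + len(ok)] = bsites[i[ok]]
        count += len(ok)
    return ParticleSet(placed, color=color, cell=cell, step=step)


def init_particles_uniform(
    lattice: Lattice,
    cell: int,
    n_particles: int,
    rng: np.random.Generator,
    color: int = YELLOW,
    step: float = 2.0,
) -> ParticleSet:
    """Uniform placement over boundary sites (the no-shape-memory control)."""
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    bsites = boundary_sites(lattice, cell)
    if len(bsites) == 0:
        raise ValueError("cell has no boundary sites")
    i = rng.integers(0, len(bsites), size=n_particles)
    return ParticleSet(bsites[i], color=color, cell=cell, step=step)


def _nearest_boundary_sites(bmask: np.ndarray, site: np.ndarray) -> np.ndarray:
    """All boundary sites at minimal Euclidean distance from ``site``.

    Searches cubes of growing Chebyshev radius; since Euclidean distance is
    at least the Chebyshev distance, a minimum found within radius R is
    global once ``min_d <= R``.
    """
    shape = bmask.shape
    max_r = max(shape)
    best: list = []
    best_d2 = np.inf
    for radius in range(1, max_r + 1):
        lo = np.maximum(site - radius, 0)
        hi = np.minimum(site + radius + 1, shape)
        sub = bmask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        cand = np.argwhere(sub) + lo
        if len(cand):
            d2 = np.sum((cand - site) ** 2, axis=1)
            m = d2.min()
            if m < best_d2:
                best_d2 = m
                best = cand[d2 == m]
            if best_d2 <= radius * radius:
                return np.asarray(best)
    if len(best):
        return np.asarray(best)
    raise RuntimeError("cell has no boundary sites (annihilated)")


def reattach_after_copy(
    pset: ParticleSet,
    lattice: Lattice,
    changed_site,
    rng: np.random.Generator,
) -> ParticleSet:
    """Repair particle attachment after an accepted copy at ``changed_site``.

    Only the changed site and its 6-neighbors can switch boundary status.
    A particle no longer on a boundary site of its cell steps to one of the
    nearest boundary sites, chosen uniformly.  Counts are conserved.
    """
    changed = np.asarray(changed_site, dtype=np.int64)
    affected = np.vstack([changed[None, :], changed + NEIGH6])
    pos = pset.positions
    if len(pos) == 0:
        return pset
    hit = np.flatnonzero((pos[:, None, :] == affected[None, :, :]).all(-1).any(1))
    if len(hit) == 0:
        return pset
    bmask = boundary_mask(lattice, pset.cell)
    if not bmask.any():
        raise RuntimeError("cell annihilated: no boundary to reattach to")
    for k in hit:
        p = pos[k]
        if not bmask[p[0], p[1], p[2]]:
            cand = _nearest_boundary_sites(bmask, p)
            pos[k] = cand[int(rng.integers(0, len(cand)))]
    return pset


def diffuse_particles(
    pset: ParticleSet,
    lattice: Lattice,
    rng: np.random.Generator,
) -> ParticleSet:
    """One random-walk step per particle on the cell boundary.

    Each particle moves to a uniformly chosen boundary site whose Euclidean
    distance lies in the open annulus ``(s - L/2, s + L/2)`` in lattice
    units.  ``s = 0`` means no movement; an empty annulus leaves the
    particle in place (counted in ``stuck_events``).
    """
    s = float(pset.step)
    if s <= 0 or len(pset) == 0:
        return pset
    bmask = boundary_mask(lattice, pset.cell)
    lo2 = (s - 0.5) ** 2
    hi2 = (s + 0.5) ** 2
    radius = int(np.ceil(s + 0.5))
    shape = np.asarray(bmask.shape)
    for k in range(len(pset)):
        p = pset.positions[k]
        a = np.maximum(p - radius, 0)
        b = np.minimum(p + radius + 1, shape)
        sub = bmask[a[0]:b[0], a[1]:b[1], a[2]:b[2]]
        cand = np.argwhere(sub) + a
        d2 = np.sum((cand - p) ** 2, axis=1)
        sel = cand[(d2 > lo2) & (d2 < hi2)]
        if len(sel) == 0:
            pset.stuck_events += 1
            continue
        pset.positions[k] = sel[int(rng.integers(0, len(sel)))]
    return pset


def cell_vector(
    positions_blue: np.ndarray,
    c_mass: np.ndarray,
) -> np.ndarray:
    """Sum of unit vectors from the centre of mass to the blue particles.

    The division plane is perpendicular to this vector.  A particle sitting
    exactly at the centre of mass has no direction and is excluded.
    """
    pos = np.asarray(positions_blue, dtype=float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("need at least one blue particle")
    vec = pos + 0.5 - np.asarray(c_mass, dtype=float)
    norms = np.linalg.norm(vec, axis=1)
    keep = norms > 0
    if not keep.all():
        vec = vec[keep]
        norms = norms[keep]
    if len(vec) == 0:
        return np.zeros(3)
    return (vec / norms[:, None]).sum(axis=0)


def partition_particles(
    pset: ParticleSet,
    lattice: Lattice,
    plus_id: int = 2,
    minus_id: int = 1,
) -> tuple[int, int]:
    """Count particles owned by each daughter after division.

    Every particle site must belong to one of the daughters; the counts sum
    to the total exactly.
    """
    pos = pset.positions
    owners = lattice.cell_ids[pos[:, 0], pos[:, 1], pos[:, 2]]
    n_plus = int(np.count_nonzero(owners == plus_id))
    n_minus = int(np.count_nonzero(owners == minus_id))
    if n_plus + n_minus != len(pos):
        raise AssertionError("particle on a site owned by neither daughter")
    return n_plus, n_minus
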