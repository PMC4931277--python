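"""3D cellular Potts model of a single cell in medium.

A lattice of cubic sites (side 0.5 um by default) carries integer cell
identifiers (0 = medium).  The energy of a configuration is

    H = sum_faces J(id, id')              (interfacial, 6-connected faces)
      + sum_cells lambda_v (v - V)^2      (volume elasticity)
      + sum_cells lambda_s (s - S)^2      (cortical tension)

with ``v`` the site count of a cell and ``s`` its surface area.  Metropolis
dynamics attempt, per Monte Carlo step (mcs), as many site-copy moves as
there are lattice sites: a random target site takes the identifier of a
random 26-neighbor, accepted outright when the energy change is negative
and with Boltzmann probability exp(-dH/T) otherwise (dH = 0 is accepted,
exp(0) = 1).

Surface area enters twice and is measured two ways.  Boundary sites and
the interfacial term use plain 6-connected face adjacency (a face costs J).
The cortical-tension term and the division trigger use the local
marching-cubes estimator of :mod:`shapemem._mcsurface`: face counting
measures axis projections, which is minimized by cubes rather than spheres
and is nearly blind to elongation, so it cannot express "the cell has not
rounded yet"; the window estimator tracks true area, makes the sphere the
minimizer, and keeps energy differences local.

Mitotic rounding is driven by setting the target surface to that of the
volume-equivalent sphere (scaled by the measured digitized-ball bias of
the estimator, ~1.09).  When the cell surface first drops to the division
trigger ``S_division`` the cell divides along the plane perpendicular to
the cell vector.

This module is the readable reference implementation used by the tests;
the ensemble driver runs a numerically identical fused kernel
(:mod:`shapemem._engine`) for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._mcsurface import AREA_TABLE, MC_SPHERE_CORRECTION, mc_surface_area

__all__ = [
    "CPMParams",
    "Lattice",
    "DIGITAL_SURFACE_CORRECTION",
    "hamiltonian",
    "delta_h",
    "metropolis_attempt",
    "run_mcs",
    "set_rounding_targets",
    "check_division_trigger",
    "divide_cell",
]

#: measured digitized-ball bias of the marching-cubes area estimator
DIGITAL_SURFACE_CORRECTION = MC_SPHERE_CORRECTION

#: 26-neighborhood offsets used for copy attempts
NEIGH26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)

#: 6-neighborhood (faces) used for surface/boundary definitions
NEIGH6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


@dataclass
class CPMParams:
    """Energy and schedule parameters of the Potts model.

    Defaults are the calibrated baseline: division of the fixture shapes
    occurs near 215 mcs (the model's match to the ~21 min mitotic-rounding
    phase of a real cell, ~6 s per mcs).
    """

    j_cell_medium: float = 3.0
    j_cell_cell: float = 1.5
    lambda_v: float = 1.0
    lambda_s: float = 0.025
    temperature: float = 3.0
    target_volume: dict = field(default_factory=dict)    # cell id -> sites
    target_surface: dict = field(default_factory=dict)   # cell id -> area units
    s_division: float = 0.0                              # area units; 0 = never
    s_division_factor: float = 1.10
    surface_correction: float = DIGITAL_SURFACE_CORRECTION
    total_mcs: int = 500
    side_length_um: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lambda_v < 0 or self.lambda_s < 0:
            raise ValueError("elasticities must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def coupling(self, a: int, b: int) -> float:
        """Interfacial energy per unit face between identifiers a and b."""
        if a == b:
            return 0.0
        if a == 0 or b == 0:
            return self.j_cell_medium
        return self.j_cell_cell


class Lattice:
    """3D grid of cell identifiers with cached per-cell volume/surface.

    The outermost layer of sites is a frozen medium frame; copy attempts
    never modify it, so every cell stays strictly inside the grid.
    """

    def __init__(self, cell_ids: np.ndarray, side_length_um: float = 0.5):
        ids = np.asarray(cell_ids)
        if ids.ndim != 3:
            raise ValueError("lattice must be 3D")
        if ids.min() < 0:
            raise ValueError("cell ids must be nonnegative")
        self.cell_ids = ids.astype(np.int32)
        self.side_length_um = float(side_length_um)
        self._rebuild_caches()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_mask(cls, mask: np.ndarray, margin: int = 6,
                  side_length_um: float = 0.5, cell_id: int = 1) -> "Lattice":
        """Embed a binary mask as one cell, tightly cropped plus a margin."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        idx = np.argwhere(mask)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        core = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        shape = tuple(s + 2 * margin for s in core.shape)
        ids = np.zeros(shape, dtype=np.int32)
        sl = tuple(slice(margin, margin + s) for s in core.shape)
        ids[sl] = np.where(core, cell_id, 0)
        return cls(ids, side_length_um)

    # -- caches ------------------------------------------------------------

    def _rebuild_caches(self):
        ids = self.cell_ids
        labels = np.unique(ids)
        self.volumes = {
            int(c): int(np.count_nonzero(ids == c)) for c in labels if c != 0
        }
        self.surfaces = {int(c): 0 for c in self.volumes}
        padded = np.pad(ids, 1, constant_values=0)
        for ax in range(3):
            a = padded
            sl_lo = [slice(1, -1)] * 3
            sl_hi = [slice(1, -1)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            left = a[tuple(sl_lo)]
            right = a[tuple(sl_hi)]
            diff = left != right
            for c in self.volumes:
                self.surfaces[c] += int(
                    np.count_nonzero(diff & ((left == c) | (right == c)))
                )
        # marching-cubes surface areas (cortical tension / division trigger)
        self.areas = {
            c: mc_surface_area(ids == c) for c in self.volumes
        }

    def centroid(self, cell: int) -> np.ndarray:
        """Centre of mass of a cell in site coordinates (voxel centers)."""
        idx = np.argwhere(self.cell_ids == cell)
        if idx.size == 0:
            raise ValueError(f"cell {cell} not present")
        return idx.mean(axis=0) + 0.5

    def neighbors6(self, site):
        x, y, z = site
        shape = self.cell_ids.shape
        for dx, dy, dz in NEIGH6:
            u = (x + dx, y + dy, z + dz)
            if 0 <= u[0] < shape[0] and 0 <= u[1] < shape[1] and 0 <= u[2] < shape[2]:
                yield u

    def id_at(self, site) -> int:
        """Identifier at a site; out-of-bounds reads as medium."""
        x, y, z = site
        s = self.cell_ids.shape
        if 0 <= x < s[0] and 0 <= y < s[1] and 0 <= z < s[2]:
            return int(self.cell_ids[x, y, z])
        return 0

    def is_interior_site(self, site) -> bool:
        """True when the site is off the frozen medium frame."""
        s = self.cell_ids.shape
        return all(1 <= site[i] <= s[i] - 2 for i in range(3))


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def hamiltonian(lattice: Lattice, params: CPMParams) -> float:
    """Global energy: interfacial term plus volume/surface penalties."""
    ids = lattice.cell_ids
    padded = np.pad(ids, 1, constant_values=0)
    h = 0.0
    for ax in range(3):
        sl_lo = [slice(1, -1)] * 3
        sl_hi = [slice(1, -1)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        left = padded[tuple(sl_lo)]
        right = padded[tuple(sl_hi)]
        both_cell = (left > 0) & (right > 0) & (left != right)
        one_cell = (left != right) & ~both_cell
        h += params.j_cell_cell * np.count_nonzero(both_cell)
        h += params.j_cell_medium * np.count_nonzero(one_cell)
    # interior faces are shared by two sites but the padded sweep counts each
    # ordered pair once per axis, i.e. every face exactly once -- except the
    # outer frame faces which only exist once anyway.
    for c, v in lattice.volumes.items():
        tv = params.target_volume.get(c)
        if tv is not None:
            h += params.lambda_v * (v - tv) ** 2
        ts = params.target_surface.get(c)
        if ts is not None:
            h += params.lambda_s * (lattice.areas[c] - ts) ** 2
    return float(h)


def _local_area_delta(lattice: Lattice, site, cell: int, old: int, new: int) -> float:
    """Marching-cubes area change of one cell if the site flipped old -> new.

    Only the 8 windows containing the site change; each is repacked from
    the current identifiers (out-of-bounds reads as medium).
    """
    if (old == cell) == (new == cell):
        return 0.0
    x, y, z = site
    delta = 0.0
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                ox, oy, oz = x - 1 + i, y - 1 + j, z - 1 + k
                cfg = 0
                for b in range(8):
                    u = (ox + (b >> 2 & 1), oy + (b >> 1 & 1), oz + (b & 1))
                    if lattice.id_at(u) == cell:
                        cfg |= 1 << b
                bit = (1 - i) << 2 | (1 - j) << 1 | (1 - k)
                delta += AREA_TABLE[cfg ^ (1 << bit)] - AREA_TABLE[cfg]
    return float(delta)


def delta_h(lattice: Lattice, source_site, target_site, params: CPMParams) -> float:
    """Energy change if the source identifier were copied onto the target.

    Computed from local bookkeeping only; equals the difference of global
    Hamiltonians exactly.
    """
    old = lattice.id_at(target_site)
    new = lattice.id_at(source_site)
    if old == new:
        raise ValueError("source and target share an identifier (no-op attempt)")
    dh = 0.0
    # interfacial: only faces incident to the target change
    for u in lattice.neighbors6(target_site):
        other = lattice.id_at(u)
        dh += params.coupling(new, other) - params.coupling(old, other)
    # faces against the lattice exterior (target on the frame never happens
    # in dynamics, but delta_h stays correct if asked)
    n_outside = 6 - len(list(lattice.neighbors6(target_site)))
    if n_outside:
        dh += (params.coupling(new, 0) - params.coupling(old, 0)) * n_outside
    for c, dv in ((old, -1), (new, +1)):
        if c == 0:
            continue
        v = lattice.volumes.get(c, 0)
        tv = params.target_volume.get(c)
        if tv is not None:
            dh += params.lambda_v * ((v + dv - tv) ** 2 - (v - tv) ** 2)
        ts = params.target_surface.get(c)
        if ts is not None:
            s = lattice.areas.get(c, 0.0)
            da = _local_area_delta(lattice, target_site, c, old, new)
            dh += params.lambda_s * ((s + da - ts) ** 2 - (s - ts) ** 2)
    return float(dh)


def _apply_copy(lattice: Lattice, source_site, target_site):
    """Commit an accepted copy and update the volume/surface caches."""
    old = lattice.id_at(target_site)
    new = lattice.id_at(source_site)
    for c, dv in ((old, -1), (new, +1)):
        if c != 0:
            lattice.volumes[c] = lattice.volumes.get(c, 0) + dv
    for c in (old, new):
        if c == 0:
            continue
        ds = 0
        for u in lattice.neighbors6(target_site):
            other = lattice.id_at(u)
            ds += int((new == c) != (other == c)) - int((old == c) != (other == c))
        n_outside = 6 - len(list(lattice.neighbors6(target_site)))
        ds += (int(new == c) - int(old == c)) * n_outside
        lattice.surfaces[c] = lattice.surfaces.get(c, 0) + ds
        lattice.areas[c] = lattice.areas.get(c, 0.0) + _local_area_delta(
            lattice, target_site, c, old, new
        )
    lattice.cell_ids[tuple(target_site)] = new


def metropolis_attempt(
    lattice: Lattice,
    params: CPMParams,
    rng: np.random.Generator,
    particle_set=None,
) -> bool:
    """One copy attempt: random target site, random 26-neighbor source.

    Accepts with probability 1 when dH < 0 and exp(-dH/T) otherwise.  When a
    particle set is supplied its boundary attachment is repaired after an
    accepted copy.
    """
    shape = lattice.cell_ids.shape
    target = tuple(int(rng.integers(0, s)) for s in shape)
    if not lattice.is_interior_site(target):
        return False
    off = NEIGH26[int(rng.integers(0, len(NEIGH26)))]
    source = tuple(int(t + o) for t, o in zip(target, off))
    if lattice.id_at(source) == lattice.id_at(target):
        return False
    dh = delta_h(lattice, source, target, params)
    if dh >= 0 and rng.random() >= math.exp(-dh / params.temperature):
        return False
    _apply_copy(lattice, source, target)
    if particle_set is not None:
        from .particles import reattach_after_copy

        reattach_after_copy(particle_set, lattice, changed_site=target, rng=rng)
    return True


def run_mcs(
    lattice: Lattice,
    params: CPMParams,
    rng: np.random.Generator,
    particle_set=None,
) -> int:
    """One Monte Carlo step: as many copy attempts as lattice sites.

    Particles (if any) are reattached after every accepted copy and diffuse
    once at the end of the step.  Returns the number of accepted copies.
    """
    n_sites = int(np.prod(lattice.cell_ids.shape))
    accepted = 0
    for _ in range(n_sites):
        if metropolis_attempt(lattice, params, rng, particle_set):
            accepted += 1
    if particle_set is not None:
        from .particles import diffuse_particles

        diffuse_particles(particle_set, lattice, rng)
    return accepted


# ---------------------------------------------------------------------------
# Rounding and division
# ---------------------------------------------------------------------------

def sphere_target_surface(volume_sites: float, correction: float
                          = DIGITAL_SURFACE_CORRECTION) -> float:
    """Surface-area target of the volume-equivalent sphere (area units)."""
    r = (3.0 * volume_sites / (4.0 * math.pi)) ** (1.0 / 3.0)
    return correction * 4.0 * math.pi * r * r


def set_rounding_targets(lattice: Lattice, cell: int, params: CPMParams) -> CPMParams:
    """Fix the rounding targets: V = current volume, S = sphere surface.

    The division trigger ``S_division`` is set slightly above the sphere
    target (``s_division_factor``) so the cell divides as rounding
    completes.  Returns an updated copy of the parameters.
    """
    if cell not in lattice.volumes:
        raise ValueError(f"cell {cell} not present")
    v = lattice.volumes[cell]
    s_target = sphere_target_surface(v, params.surface_correction)
    return replace(
        params,
        target_volume={**params.target_volume, cell: float(v)},
        target_surface={**params.target_surface, cell: s_target},
        s_division=params.s_division_factor * s_target,
    )


def check_division_trigger(lattice: Lattice, cell: int, s_division: float) -> bool:
    """True when the cell surface has come down to the trigger value.

    Surface decreases during rounding, so "reaches" is the first downward
    crossing; a trigger of 0 never fires.
    """
    if s_division <= 0:
        return False
    return lattice.areas.get(cell, 0.0) <= s_division


def divide_cell(
    lattice: Lattice,
    cell: int,
    cell_vector: np.ndarray,
    plus_id: int = 2,
) -> tuple[int, int]:
    """Split a cell along the plane through its centroid perpendicular to CV.

    Sites on the positive side of the cell vector receive ``plus_id``; sites
    exactly on the plane are assigned alternately to balance the daughter
    volumes.  Daughter target volumes are set to their actual post-split
    volumes by the caller (see :func:`set_post_division_targets`).  Returns
    ``(plus_id, minus_id)``.
    """
    cv = np.asarray(cell_vector, dtype=float)
    norm = np.linalg.norm(cv)
    if norm == 0:
        raise ValueError("zero cell vector: degenerate division")
    cv = cv / norm
    idx = np.argwhere(lattice.cell_ids == cell)
    if idx.size == 0:
        raise ValueError(f"cell {cell} not present")
    centroid = idx.mean(axis=0)
    side = (idx + 0.5 - (centroid + 0.5)) @ cv
    plus = side > 1e-12
    minus = side < -1e-12
    on_plane = ~plus & ~minus
    # alternate plane sites (in lexicographic order) to balance volumes
    n_plus = int(plus.sum())
    n_minus = int(minus.sum())
    flip = np.zeros(on_plane.sum(), dtype=bool)
    for k in range(len(flip)):
        if n_plus <= n_minus:
            flip[k] = True
            n_plus += 1
        else:
            n_minus += 1
    plane_idx = idx[on_plane]
    lattice.cell_ids[tuple(idx[plus].T)] = plus_id
    if len(plane_idx):
        lattice.cell_ids[tuple(plane_idx[flip].T)] = plus_id
        lattice.cell_ids[tuple(plane_idx[~flip].T)] = cell
    lattice._rebuild_caches()
    return plus_id, cell


def set_post_division_targets(lattice: Lattice, params: CPMParams,
                              daughters: tuple[int, int]) -> CPMParams:
    """Daughters keep their shapes: targets equal actual post-split values."""
    tv = dict(params.target_volume)
    ts = dict(params.target_surface)
    for d in daughters:
        tv[d] = float(lattice.volumes[d])
        ts[d] = float(lattice.areas[d])
    return replace(params, target_volume=tv, target_surface=ts, s_division=0.0)
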