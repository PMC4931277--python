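"""Local digital surface-area estimator (marching-cubes window weights).

Plain exposed-face counting measures the sum of a shape's axis projections,
which is almost blind to elongation (a 2:1 prolate body counts only ~5%
more faces than the equal-volume ball) and is minimized by cubes rather
than spheres.  The cortical-tension term and the division trigger of the
Potts model therefore use a marching-cubes estimate instead: the binary
mask is scanned with overlapping 2x2x2 windows (one isosurface cell each)
and every window contributes the triangle area of its local configuration.
The per-configuration areas below are frozen geometric constants of the
standard (Lewiner) triangulation at iso-level 0.5, in units of the squared
lattice side.  The estimator is strictly local: flipping one voxel only
changes the 8 windows containing it, so energy differences stay O(1).

On digitized balls the estimator reads high by a known, slowly varying
factor (~1.06-1.10 for radii 6-12); the sphere surface target is scaled by
the configurable ``MC_SPHERE_CORRECTION`` so that a rounded cell actually
sits at its target.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AREA_TABLE", "MC_SPHERE_CORRECTION", "mc_surface_area", "window_configs"]

#: measured area ratio (estimator / 4 pi r^2) of digitized balls at the
#: cell radii used here; folded into the sphere surface target
MC_SPHERE_CORRECTION = 1.09

#: isosurface area of each 2x2x2 voxel configuration (bit b set <=> voxel
#: (b>>2 & 1, b>>1 & 1, b & 1) is foreground), lattice-side^2 units
AREA_TABLE = np.array([
    0.000000000000000, 0.216506347060204, 0.216506347060204, 0.707106769084930,
    0.216506347060204, 0.707106769084930, 1.299038052558899, 1.149518966674805,
    0.216506347060204, 1.299038052558899, 0.707106769084930, 1.149518966674805,
    0.707106769084930, 1.149518966674805, 1.149518966674805, 1.000000000000000,
    0.216506347060204, 0.707106769084930, 1.299038052558899, 1.149518966674805,
    1.299038052558899, 1.149518966674805, 2.149518966674805, 1.299038052558899,
    0.433012694120407, 1.950841069221497, 1.950841069221497, 1.573132157325745,
    1.950841069221497, 1.573132157325745, 1.366025447845459, 1.149518966674805,
    0.216506347060204, 1.299038052558899, 0.707106769084930, 1.149518966674805,
    0.433012694120407, 1.950841069221497, 1.950841069221497, 1.573132157325745,
    1.299038052558899, 2.149518966674805, 1.149518966674805, 1.299038052558899,
    1.950841069221497, 1.366025447845459, 1.573132157325745, 1.149518966674805,
    0.707106769084930, 1.149518966674805, 1.149518966674805, 1.000000000000000,
    1.950841069221497, 1.573132157325745, 1.366025447845459, 1.149518966674805,
    1.950841069221497, 1.366025447845459, 1.573132157325745, 1.149518966674805,
    1.414213538169861, 2.609759569168091, 2.609759569168091, 0.707106769084930,
    0.216506347060204, 1.299038052558899, 0.433012694120407, 1.950841069221497,
    0.707106769084930, 1.149518966674805, 1.950841069221497, 1.573132157325745,
    1.299038052558899, 2.149518966674805, 1.950841069221497, 1.366025447845459,
    1.149518966674805, 1.299038052558899, 1.573132157325745, 1.149518966674805,
    0.707106769084930, 1.149518966674805, 1.950841069221497, 1.573132157325745,
    1.149518966674805, 1.000000000000000, 1.366025447845459, 1.149518966674805,
    1.950841069221497, 1.366025447845459, 1.414213538169861, 2.609759569168091,
    1.573132157325745, 1.149518966674805, 2.609759569168091, 0.707106769084930,
    1.299038052558899, 2.149518966674805, 1.950841069221497, 1.366025447845459,
    1.950841069221497, 1.366025447845459, 1.414213538169861, 2.609759569168091,
    2.149518966674805, 0.866025388240814, 1.366025447845459, 0.649519026279449,
    1.366025447845459, 0.649519026279449, 2.609759569168091, 0.433012694120407,
    1.149518966674805, 1.299038052558899, 1.573132157325745, 1.149518966674805,
    1.573132157325745, 1.149518966674805, 2.609759569168091, 0.707106769084930,
    1.366025447845459, 0.649519026279449, 2.609759569168091, 0.433012694120407,
    2.609759569168091, 0.433012694120407, 0.433012694120407, 0.216506347060204,
    0.216506347060204, 0.433012694120407, 1.299038052558899, 1.950841069221497,
    1.299038052558899, 1.950841069221497, 2.149518966674805, 1.366025447845459,
    0.707106769084930, 1.950841069221497, 1.149518966674805, 1.573132157325745,
    1.149518966674805, 1.573132157325745, 1.299038052558899, 1.149518966674805,
    1.299038052558899, 1.950841069221497, 2.149518966674805, 1.366025447845459,
    2.149518966674805, 1.366025447845459, 0.866025388240814, 0.649519026279449,
    1.950841069221497, 1.414213538169861, 1.366025447845459, 2.609759569168091,
    1.366025447845459, 2.609759569168091, 0.649519026279449, 0.433012694120407,
    0.707106769084930, 1.950841069221497, 1.149518966674805, 1.573132157325745,
    1.950841069221497, 1.414213538169861, 1.366025447845459, 2.609759569168091,
    1.149518966674805, 1.366025447845459, 1.000000000000000, 1.149518966674805,
    1.573132157325745, 2.609759569168091, 1.149518966674805, 0.707106769084930,
    1.149518966674805, 1.573132157325745, 1.299038052558899, 1.149518966674805,
    1.366025447845459, 2.609759569168091, 0.649519026279449, 0.433012694120407,
    1.573132157325745, 2.609759569168091, 1.149518966674805, 0.707106769084930,
    2.609759569168091, 0.433012694120407, 0.433012694120407, 0.216506347060204,
    0.707106769084930, 1.950841069221497, 1.950841069221497, 1.414213538169861,
    1.149518966674805, 1.573132157325745, 1.366025447845459, 2.609759569168091,
    1.149518966674805, 1.366025447845459, 1.573132157325745, 2.609759569168091,
    1.000000000000000, 1.149518966674805, 1.149518966674805, 0.707106769084930,
    1.149518966674805, 1.573132157325745, 1.366025447845459, 2.609759569168091,
    1.299038052558899, 1.149518966674805, 0.649519026279449, 0.433012694120407,
    1.573132157325745, 2.609759569168091, 2.609759569168091, 0.433012694120407,
    1.149518966674805, 0.707106769084930, 0.433012694120407, 0.216506347060204,
    1.149518966674805, 1.366025447845459, 1.573132157325745, 2.609759569168091,
    1.573132157325745, 2.609759569168091, 2.609759569168091, 0.433012694120407,
    1.299038052558899, 0.649519026279449, 1.149518966674805, 0.433012694120407,
    1.149518966674805, 0.433012694120407, 0.707106769084930, 0.216506347060204,
    1.000000000000000, 1.149518966674805, 1.149518966674805, 0.707106769084930,
    1.149518966674805, 0.707106769084930, 0.433012694120407, 0.216506347060204,
    1.149518966674805, 0.433012694120407, 0.707106769084930, 0.216506347060204,
    0.707106769084930, 0.216506347060204, 0.216506347060204, 0.000000000000000,
])


def window_configs(mask: np.ndarray) -> np.ndarray:
    """Pack every (padded) 2x2x2 window of a binary mask into a uint8 code."""
    m = np.pad(np.asarray(mask, dtype=bool), 1).astype(np.uint8)
    shape = tuple(s - 1 for s in m.shape)
    cfg = np.zeros(shape, dtype=np.uint8)
    for b in range(8):
        i, j, k = b >> 2 & 1, b >> 1 & 1, b & 1
        cfg |= m[i : i + shape[0], j : j + shape[1], k : k + shape[2]] << b
    return cfg


def mc_surface_area(mask: np.ndarray) -> float:
    """Marching-cubes surface area of a binary mask, lattice-side^2 units."""
    return float(AREA_TABLE[window_configs(mask)].sum())
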