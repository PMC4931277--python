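"""Quantification of 3D cellular eccentricity and protein localization.

The central quantity is the dimensionless eccentricity index ``A_long``.
For a segmented cell the moment-of-inertia tensor about the centre of mass
``C_mass`` yields principal axes; the long axis carries the *smallest*
eigenvalue.  Projecting every foreground voxel onto the principal axes gives
an axis-aligned minimum bounding box whose centre is ``C_median``.  The
asymmetry vector ``D_asym = C_median - C_mass`` defines the (+) side of the
cell (its spiky end); the axes are sign-flipped so each has a nonnegative
dot product with ``D_asym``.  Then

    D_long = D_asym . a_long          (um)
    A_long = D_long / r,   r = (3V / 4 pi)^(1/3)

so ``A_long`` is invariant under rigid motion and uniform scaling.  A
perfectly centrosymmetric cell has ``A_long = 0``.

Also provided: the fate-axis angle ``theta_fate`` between the oriented long
axis and the division/fate axis, intensity-centroid localization indices
(the normalized displacement ``d`` of a fluorescence signal from the cell
centre), surface-area-to-volume ratios, and a ROC threshold scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import BinaryVolume, IntensityVolume

__all__ = [
    "ShapeDescriptor",
    "FateGeometry",
    "LocalizationDescriptor",
    "inertia_tensor",
    "principal_axes",
    "asymmetry_vector",
    "orient_axes",
    "describe_shape",
    "theta_fate",
    "axis_change_angle",
    "localization_descriptor",
    "surface_area",
    "sav_ratio",
    "roc_threshold",
]

#: relative eigenvalue gap below which the principal axes are flagged degenerate
EIGENVALUE_GAP_TOL = 1e-3


@dataclass
class ShapeDescriptor:
    """Full set of shape indices for one segmented cell (units: um)."""

    c_mass: np.ndarray
    inertia: np.ndarray
    eigenvalues: np.ndarray        # (lambda_long, lambda_mid, lambda_short), ascending
    e_long: np.ndarray
    e_mid: np.ndarray
    e_short: np.ndarray
    a_long: np.ndarray
    a_middle: np.ndarray
    a_short: np.ndarray
    c_median: np.ndarray
    d_asym: np.ndarray
    d_long: float
    a_long_index: float
    volume: float
    surface_area: float
    sav: float
    equiv_radius: float
    degenerate: bool = False


@dataclass
class FateGeometry:
    """Orientation of the daughter-cell fates relative to the long axis."""

    a_cd: np.ndarray
    theta_fate: float              # degrees in [0, 180]
    plus_side_fate: str            # "V2a" | "V2b"
    tie: bool = False              # cos(theta) exactly 0


@dataclass
class LocalizationDescriptor:
    """Intensity-centroid localization of a fluorescent signal in one cell."""

    b_sum: float
    c_signal: np.ndarray
    d_signal: np.ndarray
    plus_side: bool
    d_norm: float


def _voxel_centers(mask: BinaryVolume) -> np.ndarray:
    """(n, 3) physical coordinates (um) of foreground voxel centers."""
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return (idx + 0.5) * np.asarray(mask.spacing)


def inertia_tensor(mask: BinaryVolume) -> tuple[np.ndarray, np.ndarray]:
    """Moment-of-inertia tensor about the centre of mass, unit voxel mass.

    Returns ``(I, c_mass)`` where ``I`` is the symmetric 3x3 tensor in
    um^2 * voxel and ``c_mass`` the unweighted centroid of foreground voxel
    centers in um.
    """
    pts = _voxel_centers(mask)
    c_mass = pts.mean(axis=0)
    d = pts - c_mass
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    tensor = np.array(
        [
            [np.sum(y * y + z * z), -np.sum(x * y), -np.sum(x * z)],
            [-np.sum(x * y), np.sum(x * x + z * z), -np.sum(y * z)],
            [-np.sum(x * z), -np.sum(y * z), np.sum(x * x + y * y)],
        ]
    )
    return tensor, c_mass


def principal_axes(tensor: np.ndarray, gap_tol: float = EIGENVALUE_GAP_TOL):
    """Eigen-decompose an inertia tensor into principal axes.

    The long axis is the eigenvector with the *smallest* eigenvalue (mass
    spread far along an axis contributes little moment about it) and the
    short axis the one with the largest.  Returns
    ``(e_long, e_mid, e_short, lambdas_ascending, degenerate)`` where
    ``degenerate`` flags a relative eigenvalue gap below ``gap_tol``.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-9):
        raise ValueError("inertia tensor must be symmetric 3x3")
    vals, vecs = np.linalg.eigh(tensor)  # ascending
    scale = max(abs(vals[-1]), 1.0)
    degenerate = bool(
        (vals[1] - vals[0]) < gap_tol * scale or (vals[2] - vals[1]) < gap_tol * scale
    )
    e_long, e_mid, e_short = vecs[:, 0], vecs[:, 1], vecs[:, 2]
    return e_long, e_mid, e_short, vals, degenerate


def asymmetry_vector(
    mask: BinaryVolume,
    c_mass: np.ndarray,
    axes: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Centre of the principal-axis-aligned bounding box and D_asym.

    Every foreground voxel centre is projected onto the three principal
    axes; the box centre is the midpoint of the min/max interval on each
    axis, mapped back to world coordinates.  ``d_asym = c_median - c_mass``.
    """
    pts = _voxel_centers(mask) - c_mass
    axes = np.column_stack(axes)          # 3x3, columns are axes
    proj = pts @ axes
    mid = (proj.min(axis=0) + proj.max(axis=0)) / 2.0
    c_median = c_mass + axes @ mid
    return c_median, c_median - c_mass


def orient_axes(e_long, e_mid, e_short, d_asym):
    """Flip raw eigenvector signs so each axis points toward D_asym.

    An axis with an exactly zero dot product keeps its raw sign (the choice
    does not affect any derived scalar).
    """
    out = []
    for e in (e_long, e_mid, e_short):
        dot = float(np.dot(d_asym, e))
        out.append(-e if dot < 0 else e)
    return tuple(out)


def surface_area(mask: BinaryVolume) -> float:
    """Exposed-face surface area in um^2 (6-connected face counting)."""
    m = mask.mask
    sp = mask.spacing
    face_area = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    total = 0.0
    for ax in range(3):
        pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        total += np.count_nonzero(np.diff(pad, axis=ax)) * face_area[ax]
    return float(total)


def describe_shape(mask: BinaryVolume) -> ShapeDescriptor:
    """Compute the full shape descriptor (D_asym, D_long, A_long, SAV, ...)."""
    if not mask.mask.any():
        raise ValueError("empty mask")
    tensor, c_mass = inertia_tensor(mask)
    e_long, e_mid, e_short, vals, degenerate = principal_axes(tensor)
    c_median, d_asym = asymmetry_vector(mask, c_mass, (e_long, e_mid, e_short))
    if np.allclose(d_asym, 0.0):
        degenerate = True
        a_long, a_middle, a_short = e_long, e_mid, e_short
    else:
        a_long, a_middle, a_short = orient_axes(e_long, e_mid, e_short, d_asym)
    d_long = float(np.dot(d_asym, a_long))
    volume = float(np.count_nonzero(mask.mask)) * mask.voxel_volume
    r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    area = surface_area(mask)
    return ShapeDescriptor(
        c_mass=c_mass,
        inertia=tensor,
        eigenvalues=vals,
        e_long=e_long,
        e_mid=e_mid,
        e_short=e_short,
        a_long=a_long,
        a_middle=a_middle,
        a_short=a_short,
        c_median=c_median,
        d_asym=d_asym,
        d_long=d_long,
        a_long_index=d_long / r,
        volume=volume,
        surface_area=area,
        sav=area / volume,
        equiv_radius=r,
        degenerate=degenerate,
    )


def theta_fate(a_long: np.ndarray, a_cd: np.ndarray) -> FateGeometry:
    """Angle between the oriented long axis and the fate/division axis.

    ``a_cd`` points from the V2b daughter toward the V2a daughter.  When
    ``cos(theta) > 0`` the daughter on the (+) side of the long axis is the
    V2a; when negative it is the V2b; an exactly orthogonal pair is flagged
    as a tie (and reported as V2a by convention).
    """
    a_long = np.asarray(a_long, dtype=float)
    a_cd = np.asarray(a_cd, dtype=float)
    nl, nc = np.linalg.norm(a_long), np.linalg.norm(a_cd)
    if nl == 0 or nc == 0:
        raise ValueError("zero-length axis vector")
    cos = float(np.clip(np.dot(a_long / nl, a_cd / nc), -1.0, 1.0))
    theta = math.degrees(math.acos(cos))
    return FateGeometry(
        a_cd=a_cd / nc,
        theta_fate=theta,
        plus_side_fate="V2a" if cos > 0 else ("V2b" if cos < 0 else "V2a"),
        tie=(cos == 0.0),
    )


def axis_change_angle(a_before, a_after, cut_deg: float = 45.0):
    """Line angle (degrees, [0, 90]) between two long axes and the 45-deg call.

    Axes are compared as undirected lines, so the angle is folded into
    [0, 90].  Returns ``(angle, changed)`` with ``changed`` true above the
    cut.
    """
    a = np.asarray(a_before, dtype=float)
    b = np.asarray(a_after, dtype=float)
    cos = abs(float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))
    angle = math.degrees(math.acos(min(cos, 1.0)))
    return angle, angle > cut_deg


def localization_descriptor(
    intensity: IntensityVolume,
    mask: BinaryVolume,
    shape: ShapeDescriptor,
) -> LocalizationDescriptor:
    """Intensity-weighted centroid of a signal and its normalized offset.

    ``c_signal`` is the brightness-weighted centroid over foreground voxels,
    ``d_signal = c_signal - c_mass``, and ``d = |d_signal| / r`` with ``r``
    the equivalent-sphere radius of the cell.  The signal sits on the (+)
    side when ``a_long . d_signal > 0``.
    """
    if intensity.data.shape != mask.mask.shape:
        raise ValueError("intensity and mask shapes differ")
    idx = np.argwhere(mask.mask)
    weights = intensity.data[mask.mask].astype(float)
    b_sum = float(weights.sum())
    if b_sum <= 0:
        raise ValueError("zero total intensity inside mask")
    pts = (idx + 0.5) * np.asarray(mask.spacing)
    c_signal = (pts * weights[:, None]).sum(axis=0) / b_sum
    d_signal = c_signal - shape.c_mass
    return LocalizationDescriptor(
        b_sum=b_sum,
        c_signal=c_signal,
        d_signal=d_signal,
        plus_side=bool(np.dot(shape.a_long, d_signal) > 0),
        d_norm=float(np.linalg.norm(d_signal)) / shape.equiv_radius,
    )


def sav_ratio(mask: BinaryVolume) -> float:
    """Surface-area-to-volume ratio in um^-1 (exposed faces / voxel volume)."""
    if not mask.mask.any():
        raise ValueError("empty mask")
    volume = float(np.count_nonzero(mask.mask)) * mask.voxel_volume
    return surface_area(mask) / volume


def roc_threshold(samples: Sequence[tuple[float, bool]]) -> float:
    """Threshold on A_long maximizing Youden's J for the shape-fate relation.

    ``samples`` are ``(A_long, plus_side_is_V2a)`` pairs.  Candidate
    thresholds are the observed A_long values ("predict V2a-biased when
    A_long >= threshold"); ties in J are broken toward the smaller
    threshold.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    values = np.array([s[0] for s in samples], dtype=float)
    labels = np.array([bool(s[1]) for s in samples])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcomes must be present")
    best_j, best_thr = -np.inf, None
    for thr in np.unique(values):
        pred = values >= thr
        sens = np.count_nonzero(pred & labels) / n_pos
        spec = np.count_nonzero(~pred & ~labels) / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_thr = j, float(thr)
    return best_thr
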