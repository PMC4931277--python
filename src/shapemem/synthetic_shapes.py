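"""Synthetic voxelized cell shapes of controlled eccentricity.

Real segmented cells are replaced by a parametric family built from
three features of pre-mitotic progenitors: overall elongation (a prolate
base; it sets how far the cell is from round and therefore how long
mitotic rounding takes), asymmetric elongation (the (+) half of the
spheroid has a longer semi-axis, an egg silhouette; this is what the
eccentricity index ``A_long`` measures), and a spiky (+) end (a small
cluster of oblique protrusions at the (+) pole, as in the protrusive end
of a real cell).  A single asymmetry parameter drives the egg asymmetry
and the protrusion length together, so a symmetric cell is smooth and an
eccentric cell is spiky — the covariation the distance-cubed Delta
loading feeds on.  Off-axis protrusions carry far-from-centre boundary
area without extending the bounding box, so the family reaches realistic
(+)-side Delta enrichment at small ``A_long``.  The family is tuned by
bisection until the measured ``A_long`` matches a requested target.  A sub-voxel placement offset of the
analytic surface relative to the voxel grid provides the fine control that
discrete voxelization alone cannot: as the offset slides, the bounding-box
extremes stay put while the centre of mass moves continuously, sweeping
``A_long`` through a quasi-continuous range.

Also generates confocal-like intensity stacks with a linear intensity
gradient (polarized staining) plus optional Poisson noise, for end-to-end
tests of the I/O and localization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .shape_metrics import ShapeDescriptor, describe_shape
from .volume_io import BinaryVolume, IntensityVolume

__all__ = [
    "ShapeFixture",
    "PAPER_ALONG_TARGETS",
    "make_sphere",
    "make_teardrop",
    "tune_to_target",
    "make_synthetic_stack",
]

#: the six in-silico eccentricities used in the division ensembles
PAPER_ALONG_TARGETS = (0.002, 0.024, 0.031, 0.052, 0.063, 0.092)

#: default cell scale: a 10-um-equivalent-diameter progenitor at the
#: 0.5-um lattice pitch
DEFAULT_RADIUS_UM = 5.0
DEFAULT_SPACING_UM = 0.5

#: default long/short aspect ratio of the prolate base
DEFAULT_ASPECT = 2.5


@dataclass
class ShapeFixture:
    """A voxelized cell of known, measured eccentricity."""

    mask: BinaryVolume
    family: str
    params: dict
    a_long: float
    descriptor: ShapeDescriptor = field(repr=False)

    @property
    def equiv_radius(self) -> float:
        return self.descriptor.equiv_radius


def _is_26_connected(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return n == 1


def _teardrop_mask(
    radius_um: float,
    taper: float,
    spacing: float,
    offset_vox: float,
    aspect: float = 1.0,
    spike_scale: float = 60.0,
    margin_vox: int = 4,
) -> np.ndarray:
    """Voxelize the eccentric-cell family, (+) end along +axis0.

    Three features compose the shape.  (1) An asymmetric prolate spheroid:
    semi-axes ``(a_plus, b, b)`` for the +axis0 half and ``(a_minus, b,
    b)`` for the other, ``a_plus = mu (1 + taper)``, ``a_minus = mu (1 -
    taper)``, ``mu = aspect * b``, ``b`` fixed by the volume of the ball
    of ``radius_um``.  (2) A spiky (+) end: five thin protrusions (radius
    1.5 voxels) of length ``spike_scale * taper`` leaving the (+) pole
    region at 30 degrees off the long axis.  (3) Area ballast on the (-)
    pole: six shorter, wider bumps whose lateral area and mass lever roughly balance the
    protrusions', so that uniform-by-area particle placement stays
    unpolarized while the distance-cubed placement is enriched on the (+)
    side (the protrusion tips reach far from the centre of mass).
    ``taper = 0`` reduces to the bare spheroid; ``offset_vox`` shifts the
    analytic centre along axis 0 by a fraction of a voxel.
    """
    if taper < 0:
        raise ValueError("taper must be >= 0")
    if aspect < 1:
        raise ValueError("aspect must be >= 1")
    r_vox = radius_um / spacing
    b_ax = r_vox / aspect ** (1.0 / 3.0)
    mu = aspect * b_ax
    a_p = mu * (1.0 + taper)
    a_m = mu * (1.0 - taper)
    len_plus = spike_scale * taper
    # ballast length tracks the taper so that uniform-by-area placement
    # stays unpolarized across the whole family (larger tapers need
    # relatively less minus-side area: the egg itself supplies some)
    len_minus = max(0.30, 0.73 - 1.07 * taper) * len_plus
    n_plus, r_plus, th_plus = 5, 1.5, np.radians(30.0)
    n_minus, r_minus, th_minus = 6, 2.6, np.radians(135.0)

    ext = b_ax + max(len_plus * np.sin(th_plus), len_minus * np.sin(th_minus))
    n_lo = int(np.ceil(a_m + len_minus)) + margin_vox
    n_hi = int(np.ceil(max(a_p, 0.7 * a_p + len_plus * np.cos(th_plus)))) + margin_vox
    n_perp = 2 * (int(np.ceil(ext)) + margin_vox) + 1
    cx = n_lo + 0.5 + offset_vox        # analytic centre, voxel units
    cperp = n_perp / 2.0
    nx = n_lo + n_hi + 1

    x = np.arange(nx) + 0.5 - cx
    y = np.arange(n_perp) + 0.5 - cperp
    z = np.arange(n_perp) + 0.5 - cperp
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    rho2 = Y * Y + Z * Z
    ax = np.where(X >= 0, a_p, a_m)
    mask = (X / ax) ** 2 + rho2 / (b_ax * b_ax) <= 1.0
    pts = np.stack([X, Y, Z], axis=-1)

    def add_protrusions(count, length, radius, theta, phase):
        nonlocal mask
        if length < 1.0:
            return
        for k in range(count):
            phi = 2.0 * np.pi * k / count + phase
            u = np.array(
                [
                    np.cos(theta),
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                ]
            )
            a_here = a_p if u[0] >= 0 else a_m
            reach = 1.0 / np.sqrt(
                (u[0] / a_here) ** 2 + (u[1] / b_ax) ** 2 + (u[2] / b_ax) ** 2
            )
            p0 = u * reach * 0.9        # anchored just inside the surface
            d = pts - p0
            proj = d @ u
            perp2 = np.sum(d * d, axis=-1) - proj ** 2
            mask |= (
                (proj >= 0)
                & (proj <= length + 0.1 * reach)
                & (perp2 <= radius ** 2)
            )

    # protrusions and their ballast appear only as a balanced pair: a
    # sub-voxel member of either set would leave the boundary area and the
    # distance-cubed load unbalanced
    if len_plus >= 1.0 and len_minus >= 1.0:
        add_protrusions(n_plus, len_plus, r_plus, th_plus, np.pi / 4.0)
        add_protrusions(n_minus, len_minus, r_minus, th_minus, 0.0)
    return mask


def make_sphere(
    radius_um: float = DEFAULT_RADIUS_UM,
    spacing: float = DEFAULT_SPACING_UM,
) -> ShapeFixture:
    """Digitized ball: the symmetric control (A_long ~ 0)."""
    if radius_um / spacing < 3:
        raise ValueError("radius must span at least 3 voxels for stable metrics")
    m = _teardrop_mask(radius_um, 0.0, spacing, 0.0)
    mask = BinaryVolume(m, (spacing,) * 3)
    desc = describe_shape(mask)
    return ShapeFixture(
        mask=mask,
        family="sphere",
        params={"radius_um": radius_um, "spacing": spacing},
        a_long=desc.a_long_index,
        descriptor=desc,
    )


def make_teardrop(
    radius_um: float = DEFAULT_RADIUS_UM,
    taper: float = 0.1,
    spacing: float = DEFAULT_SPACING_UM,
    offset_vox: float = 0.0,
    aspect: float = DEFAULT_ASPECT,
) -> ShapeFixture:
    """Eccentric cell: egg-shaped prolate body with a spiky (+) end.

    ``taper`` drives the egg asymmetry and the (+)-pole protrusion length
    together; ``A_long`` grows with it over the working range (taper in
    [0, 0.25] covers A_long 0 to ~0.13 at default scale).  ``taper = 0``
    is the smooth symmetric prolate control.
    """
    if radius_um / spacing < 3:
        raise ValueError("radius must span at least 3 voxels")
    m = _teardrop_mask(radius_um, taper, spacing, offset_vox, aspect)
    if not _is_26_connected(m):
        raise ValueError(f"taper {taper} produced a disconnected mask")
    mask = BinaryVolume(m, (spacing,) * 3)
    desc = describe_shape(mask)
    return ShapeFixture(
        mask=mask,
        family="teardrop",
        params={
            "radius_um": radius_um,
            "taper": taper,
            "spacing": spacing,
            "offset_vox": offset_vox,
            "aspect": aspect,
        },
        a_long=desc.a_long_index,
        descriptor=desc,
    )


def tune_to_target(
    target_a_long: float,
    family: str = "teardrop",
    tol: float = 0.002,
    radius_um: float = DEFAULT_RADIUS_UM,
    spacing: float = DEFAULT_SPACING_UM,
    aspect: float = DEFAULT_ASPECT,
) -> ShapeFixture:
    """Tune the asymmetry parameter until the measured A_long hits a target.

    Voxelization makes the raw A_long(taper) curve noisy (single-voxel
    bounding-box jumps of ~0.01), so the taper is set by inverting an
    isotonic (monotone least-squares) fit of a coarse scan — the fixture's
    *physical* asymmetry then scales with the requested target — and the
    sub-voxel placement offset provides the fine control down to ``tol``.
    Deterministic for fixed spacing.
    """
    if family not in ("teardrop", "sphere"):
        raise ValueError(f"unknown family {family!r}")
    if family == "sphere":
        fx = make_sphere(radius_um, spacing)
        if abs(fx.a_long - target_a_long) > tol:
            raise ValueError(
                f"sphere family cannot reach A_long={target_a_long}"
            )
        return fx

    def measure(taper: float, offset: float) -> ShapeFixture:
        return make_teardrop(radius_um, taper, spacing, offset, aspect)

    # the exactly symmetric member has A_long = 0 by mirror symmetry; it is
    # the correct stand-in for a symmetric cell whenever the target allows,
    # since voxelization asymmetry of a nominally symmetric shape would be
    # amplified by the fate switch into a spurious bias
    if abs(target_a_long) <= tol:
        return measure(0.0, 0.0)

    t_grid = np.linspace(0.0, 0.32, 9)
    a_raw = np.array([measure(float(t), 0.0).a_long for t in t_grid])
    a_fit = _isotonic(a_raw)
    if target_a_long > a_fit[-1] + 0.02 or target_a_long < -tol:
        raise ValueError(
            f"target A_long={target_a_long} unreachable for family "
            f"{family!r} (range ~[0, {a_fit[-1]:.3f}])"
        )
    t0 = float(np.interp(target_a_long, a_fit, t_grid))
    best = None
    for dt in (0.0, 0.01, -0.01, 0.02, -0.02, 0.03):
        taper = max(0.0, t0 + dt)
        for offset in np.linspace(0.0, 0.95, 20):
            fx = measure(taper, float(offset))
            err = abs(fx.a_long - target_a_long)
            if best is None or err < abs(best.a_long - target_a_long):
                best = fx
            if err <= tol:
                return fx
    raise ValueError(
        f"could not reach A_long={target_a_long} within {tol} "
        f"(best {best.a_long:.4f})"
    )


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: monotone nondecreasing least-squares fit."""
    y = np.asarray(y, dtype=float)
    levels = [[v, 1] for v in y]
    merged = []
    for lv in levels:
        merged.append(lv)
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            b = merged.pop()
            a = merged.pop()
            merged.append(
                [(a[0] * a[1] + b[0] * b[1]) / (a[1] + b[1]), a[1] + b[1]]
            )
    out = []
    for value, count in merged:
        out.extend([value] * count)
    return np.array(out)


def make_synthetic_stack(
    fixture: ShapeFixture,
    polarization_axis=None,
    gradient_strength: float = 0.0,
    noise_model: str | None = None,
    rng: np.random.Generator | None = None,
    base_intensity: float = 100.0,
    blur_sigma: float = 0.0,
    background: float = 0.0,
) -> IntensityVolume:
    """Confocal-like stack with a linear intensity gradient inside the mask.

    Intensity is ``base * (1 + g * t)`` inside the cell, where ``t`` is the
    coordinate along ``polarization_axis`` (default: the measured oriented
    long axis) normalized to [-1/2, 1/2] over the cell's extent.  Optional
    Poisson shot noise and Gaussian blur emulate imaging; with both off the
    weighted centroid is exactly computable from the profile.
    """
    if gradient_strength < 0:
        raise ValueError("gradient_strength must be >= 0")
    desc = fixture.descriptor
    axis = desc.a_long if polarization_axis is None else np.asarray(
        polarization_axis, dtype=float
    )
    axis = axis / np.linalg.norm(axis)
    mask = fixture.mask.mask
    sp = np.asarray(fixture.mask.spacing)
    idx = np.argwhere(mask)
    pts = (idx + 0.5) * sp
    t = (pts - desc.c_mass) @ axis
    extent = t.max() - t.min()
    t_norm = (t - (t.max() + t.min()) / 2.0) / extent if extent > 0 else t * 0.0
    vals = base_intensity * (1.0 + gradient_strength * t_norm)
    vals = np.clip(vals, 0.0, None)
    data = np.full(mask.shape, float(background))
    data[tuple(idx.T)] = vals
    if noise_model == "poisson":
        if rng is None:
            rng = np.random.default_rng()
        data = rng.poisson(data).astype(float)
    elif noise_model not in (None, "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma)
    return IntensityVolume(data, fixture.mask.spacing)
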