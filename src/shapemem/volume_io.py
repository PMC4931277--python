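"""Reading, writing and preprocessing of 3D voxel volumes.

Volumes are plain 3D arrays with a physical voxel spacing per axis (in
micrometres).  Axis order is array order: axis 0 is the slowest axis (TIFF
pages / confocal z), axes 1 and 2 are the in-plane rows and columns.  The
preprocessing chain mirrors a standard single-cell confocal pipeline:
3D median filter, discriminant-analysis (Otsu) binarization, and largest
connected-component extraction.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "IntensityVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "median_filter_3d",
    "binarize_discriminant",
    "largest_component",
    "resample_isotropic",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    return spacing


@dataclass
class IntensityVolume:
    """A 3D scalar field (e.g. fluorescence brightness) with voxel spacing in um."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("volume contains negative values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryVolume:
    """A 3D boolean mask (segmented cell object) with voxel spacing in um."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF and NRRD
# ---------------------------------------------------------------------------

_NRRD_DTYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "uint16": np.uint16,
    "unsigned short": np.uint16,
    "int16": np.int16,
    "short": np.int16,
    "int32": np.int32,
    "int": np.int32,
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
}
_NRRD_TYPE_NAMES = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int16): "int16",
    np.dtype(np.int32): "int32",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def _read_nrrd(path: str) -> tuple[np.ndarray, tuple | None]:
    """Minimal NRRD reader: 3D, raw/gzip encoding, little-endian.

    ``sizes`` in an NRRD header are listed fastest-axis first; we store arrays
    C-ordered with axis 0 slowest, so the header order is reversed on read.
    """
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path} is not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()

    if int(header.get("dimension", "0")) != 3:
        raise ValueError("only 3D NRRD volumes are supported")
    dtype = _NRRD_DTYPES.get(header.get("type", ""))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {header.get('type')!r}")
    sizes = [int(v) for v in header["sizes"].split()]
    encoding = header.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        payload = zlib.decompress(payload, wbits=zlib.MAX_WBITS | 32)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    data = data[: int(np.prod(sizes))].reshape(sizes[::-1])

    spacing = None
    if "space directions" in header:
        vecs = []
        for token in header["space directions"].replace(") (", ")|(").split("|"):
            token = token.strip().strip("()")
            if token.lower() == "none":
                continue
            vecs.append([float(v) for v in token.replace(",", " ").split()])
        if len(vecs) == 3:
            spacing = tuple(float(np.linalg.norm(v)) for v in reversed(vecs))
    elif "spacings" in header:
        vals = [float(v) for v in header["spacings"].split()]
        if len(vals) == 3:
            spacing = tuple(reversed(vals))
    return np.array(data), spacing


def _write_nrrd(path: str, data: np.ndarray, spacing: tuple) -> None:
    dtype = np.dtype(data.dtype)
    if dtype not in _NRRD_TYPE_NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {dtype}")
    dirs = " ".join(
        "(%.17g,0,0) (0,%.17g,0) (0,0,%.17g)".split()[i] % s
        for i, s in enumerate(reversed(spacing))
    )
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_TYPE_NAMES[dtype]}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data.astype(dtype.newbyteorder("<"))).tobytes())


def read_volume(path: str, spacing_override=None) -> IntensityVolume:
    """Read a multi-page TIFF or NRRD volume.

    Spacing is taken from file metadata when present; ``spacing_override``
    (three values, um, in array-axis order) replaces or supplies it.  Missing
    spacing with no override is an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    spacing = None
    if ext == ".nrrd":
        data, spacing = _read_nrrd(path)
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
            try:
                meta = json.loads(desc)
                spacing = tuple(float(s) for s in meta["spacing"])
            except (json.JSONDecodeError, KeyError, TypeError):
                spacing = None
            if spacing is None and tif.imagej_metadata:
                z = tif.imagej_metadata.get("spacing")
                res = tif.pages[0].resolution
                if z is not None and res and res[0] and res[1]:
                    spacing = (float(z), 1.0 / float(res[1]), 1.0 / float(res[0]))
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
    if spacing_override is not None:
        spacing = tuple(spacing_override)
    if spacing is None:
        raise ValueError(f"{path} carries no voxel spacing; pass spacing_override")
    return IntensityVolume(data, spacing)


def write_volume(path: str, vol: IntensityVolume) -> None:
    """Write a volume as multi-page TIFF or NRRD (by file extension).

    For TIFF the spacing is stored losslessly as JSON in the image
    description, so ``read_volume(write_volume(v))`` is value-identical.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".nrrd":
        _write_nrrd(path, vol.data, vol.spacing)
    else:
        desc = json.dumps({"spacing": list(vol.spacing), "unit": "um"})
        tifffile.imwrite(
            path, vol.data, description=desc, photometric="minisblack"
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def median_filter_3d(vol: IntensityVolume, radius: int = 1) -> IntensityVolume:
    """3D median filter over a cubic (2r+1)^3 neighborhood.

    Edges are handled by nearest-border replication, which keeps the filter
    idempotent on piecewise-constant volumes.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    size = 2 * int(radius) + 1
    out = ndimage.median_filter(vol.data, size=size, mode="nearest")
    return IntensityVolume(out, vol.spacing)


def binarize_discriminant(
    vol: IntensityVolume,
    threshold: float | str = "otsu",
    foreground: str = "bright",
) -> BinaryVolume:
    """Threshold a volume by discriminant analysis (Otsu) or a manual value.

    The discriminant threshold maximizes the between-class variance of the
    two classes it separates.  ``foreground`` selects which side of the
    threshold is the object: ``"bright"`` (values above threshold, default),
    ``"dark"`` (values at or below), or ``"minority"`` (the smaller class —
    convenient for single-cell stacks where the cell occupies a minority of
    voxels regardless of staining polarity).
    """
    data = vol.data
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if np.all(data == data.flat[0]):
            raise ValueError("constant volume: no discriminant threshold exists")
        level = float(threshold_otsu(data))
    else:
        level = float(threshold)
    bright = data > level
    if foreground == "bright":
        mask = bright
    elif foreground == "dark":
        mask = ~bright
    elif foreground == "minority":
        mask = bright if bright.sum() <= bright.size - bright.sum() else ~bright
    else:
        raise ValueError(f"unknown foreground mode {foreground!r}")
    return BinaryVolume(mask, vol.spacing)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BinaryVolume, connectivity: int = 26) -> BinaryVolume:
    """Keep only the largest connected foreground component.

    Ties are broken toward the component containing the lexicographically
    smallest voxel index.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    if not mask.mask.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask.mask, structure=_STRUCTS[connectivity])
    if n == 1:
        return BinaryVolume(mask.mask.copy(), mask.spacing)
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # lexicographic tie-break: first flat index in C order is the
        # smallest (z, y, x) tuple
        first_idx = {
            lab: np.argmax(labels.ravel() == lab) for lab in candidates
        }
        keep = min(candidates, key=lambda lab: first_idx[lab])
    return BinaryVolume(labels == keep, mask.spacing)


def resample_isotropic(mask: BinaryVolume, target_um: float = 0.5) -> BinaryVolume:
    """Resample a mask from anisotropic voxels to an isotropic grid.

    Confocal stacks are anisotropic (e.g. 0.42 x 0.42 x 0.89 um); the
    Potts lattice uses cubic 0.5-um sites, so segmented cells are
    resampled (order-1 interpolation of the indicator, threshold 0.5)
    before simulation.  Shape metrics do NOT need this: they operate in
    physical coordinates directly.
    """
    if target_um <= 0:
        raise ValueError("target spacing must be positive")
    zoom = [s / target_um for s in mask.spacing]
    out = ndimage.zoom(mask.mask.astype(np.float32), zoom, order=1) >= 0.5
    return BinaryVolume(out, (target_um,) * 3)
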