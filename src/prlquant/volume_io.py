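"""I/O for OCT volumes, layer masks, score maps and en-face products.

Volumes are stored as multi-page TIFF or as a directory of equally-sized
PNG/TIFF B-scans (filename-sorted).  Axis convention is ``(bscan b, depth
row z, ascan column x)`` with row 0 at the top of the B-scan (vitreous
side).  En-face grids are ``(n_bscans x n_ascans)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import tifffile
import imageio.v3 as iio


# Spectralis-like acquisition defaults: 49 B-scans of 496x512 px over ~6x6 mm.
DEFAULT_N_BSCANS = 49
DEFAULT_N_DEPTH = 496
DEFAULT_N_ASCANS = 512
DEFAULT_DX_MM = 6.0 / DEFAULT_N_ASCANS
DEFAULT_DY_MM = 6.0 / DEFAULT_N_BSCANS


@dataclass(frozen=True)
class Geometry:
    """Physical spacing of a volume. ``dz_um`` defaults to 1 so axial
    distances are reported in pixels unless a calibration is supplied."""

    dx_mm: float = DEFAULT_DX_MM
    dy_mm: float = DEFAULT_DY_MM
    dz_um: float = 1.0

    def __post_init__(self) -> None:
        if self.dx_mm <= 0 or self.dy_mm <= 0 or self.dz_um <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class OCTVolume:
    """Ordered stack of grayscale B-scans with intensities in [0, 1]."""

    voxels: np.ndarray  # (n_bscans, n_depth, n_ascans) float
    dx_mm: float = DEFAULT_DX_MM
    dy_mm: float = DEFAULT_DY_MM
    dz_um: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("voxels must lie in [0, 1]")
        if self.dx_mm <= 0 or self.dy_mm <= 0 or self.dz_um <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_bscans(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_depth(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.voxels.shape[2]

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.dx_mm, self.dy_mm, self.dz_um)


@dataclass
class LayerMask:
    """Binary photoreceptor mask congruent with an :class:`OCTVolume`."""

    mask: np.ndarray  # (n_bscans, n_depth, n_ascans) uint8 in {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {m.shape}")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.mask = m.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


_SUPPORTED_DTYPES = {
    np.dtype(np.uint8): 255.0,
    np.dtype(np.uint16): 65535.0,
}

_RASTER_EXTS = (".png", ".tif", ".tiff")


def _normalize_page(page: np.ndarray, source: str) -> np.ndarray:
    """Rescale an integer/float raster page to [0,1] by its dtype max."""
    page = np.asarray(page)
    if page.ndim == 3 and page.shape[-1] in (3, 4):  # collapse RGB(A)
        page = page[..., 0]
    if page.ndim != 2:
        raise ValueError(f"page {source!r} is not a 2-D grayscale image")
    if page.dtype in _SUPPORTED_DTYPES:
        return page.astype(np.float64) / _SUPPORTED_DTYPES[page.dtype]
    if np.issubdtype(page.dtype, np.floating):
        out = page.astype(np.float64)
        if not np.all(np.isfinite(out)) or out.min() < 0 or out.max() > 1:
            raise ValueError(f"float page {source!r} must already lie in [0, 1]")
        return out
    raise ValueError(f"unsupported bit depth {page.dtype} in page {source!r}")


def load_volume(path: str | os.PathLike, geometry: Geometry | None = None) -> OCTVolume:
    """Load an OCT volume from a multi-page TIFF or a directory of B-scans.

    Pages (or filename-sorted files) become B-scan indices 0..n-1.
    Intensities are rescaled to [0,1] by the container dtype maximum.
    """
    geometry = geometry or Geometry()
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")

    pages: list[np.ndarray] = []
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path) if f.lower().endswith(_RASTER_EXTS)
        )
        if not names:
            raise ValueError(f"directory {path} contains no PNG/TIFF B-scans")
        for name in names:
            img = iio.imread(os.path.join(path, name))
            pages.append(_normalize_page(img, name))
    else:
        with tifffile.TiffFile(path) as tf:
            for i, page in enumerate(tf.pages):
                pages.append(_normalize_page(page.asarray(), f"{path}#page{i}"))

    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape0:
            raise ValueError(
                f"inconsistent page sizes: page {i} is {p.shape}, expected {shape0}"
            )
    voxels = np.stack(pages, axis=0)
    return OCTVolume(voxels, geometry.dx_mm, geometry.dy_mm, geometry.dz_um)


def save_volume(volume: OCTVolume | np.ndarray, path: str | os.PathLike,
                dtype: str = "uint16") -> None:
    """Write a volume (values in [0,1]) as a multi-page TIFF."""
    voxels = volume.voxels if isinstance(volume, OCTVolume) else np.asarray(volume)
    if dtype == "uint8":
        data = np.round(np.clip(voxels, 0, 1) * 255).astype(np.uint8)
    elif dtype == "uint16":
        data = np.round(np.clip(voxels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    # force grayscale pages: a 3-page stack must not be mistaken for RGB planes
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


def save_mask(mask: LayerMask | np.ndarray, path: str | os.PathLike) -> None:
    m = mask.mask if isinstance(mask, LayerMask) else np.asarray(mask)
    tifffile.imwrite(os.fspath(path), (m > 0).astype(np.uint8) * 255,
                     photometric="minisblack")


def load_mask(path: str | os.PathLike) -> LayerMask:
    vol = load_volume(path)
    return LayerMask((vol.voxels >= 0.5).astype(np.uint8))


def save_enface_csv(grid: np.ndarray, path: str | os.PathLike) -> None:
    """Write an en-face grid as CSV: one row per B-scan, one column per A-scan."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("refusing to write an empty en-face map")
    if grid.ndim != 2:
        raise ValueError(f"en-face map must be 2-D, got shape {grid.shape}")
    if not np.all(np.isfinite(grid)):
        raise ValueError("en-face map contains non-finite values")
    np.savetxt(os.fspath(path), grid, delimiter=",", fmt="%.6f")


def load_enface_csv(path: str | os.PathLike) -> np.ndarray:
    arr = np.loadtxt(os.fspath(path), delimiter=",", ndmin=2)
    return arr


def save_enface_png(grid01: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] en-face grid as a 16-bit grayscale PNG preview."""
    g = np.asarray(grid01, dtype=np.float64)
    if g.min() < 0 or g.max() > 1:
        raise ValueError("grid must be normalized to [0,1] first")
    iio.imwrite(os.fspath(path), np.round(g * 65535).astype(np.uint16))


def save_json(obj, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
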