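"""Synthetic OCT phantom generator with exact photoreceptor ground truth.

Generates Spectralis-like volumes containing a thin bright band with smooth
thickness variation, focal disruptions (thickness -> 0), columnar shadow
artefacts, hyporeflective cyst blobs and multiplicative speckle noise.  The
ground-truth mask and analytic thickness map are produced alongside, so the
full segmentation/quantification pipeline can be trained and validated
without clinical data.

Geometry and noise never interact with the mask: disruptions carve the mask
(and the band), while shadows and speckle only perturb intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from prlquant.volume_io import (
    DEFAULT_DX_MM,
    DEFAULT_DY_MM,
    DEFAULT_N_ASCANS,
    DEFAULT_N_BSCANS,
    DEFAULT_N_DEPTH,
    LayerMask,
    OCTVolume,
)


@dataclass(frozen=True)
class Ellipse:
    """En-face ellipse (indices): used for disruption footprints."""

    center_b: float
    center_x: float
    radius_b: float
    radius_x: float

    def contains(self, bb: np.ndarray, xx: np.ndarray) -> np.ndarray:
        return (
            ((bb - self.center_b) / max(self.radius_b, 1e-9)) ** 2
            + ((xx - self.center_x) / max(self.radius_x, 1e-9)) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Shadow:
    """Columnar intensity attenuation on A-scans [x_start, x_stop) of the
    given B-scans (all B-scans when bscan_range is None)."""

    x_start: int
    x_stop: int
    factor: float = 0.35
    bscan_range: tuple[int, int] | None = None


@dataclass(frozen=True)
class Cyst:
    """Dark ellipsoid blob placed above the layer (hyporeflective fluid)."""

    center_b: float
    center_z: float
    center_x: float
    radius_b: float
    radius_z: float
    radius_x: float
    intensity: float = 0.02


@dataclass
class PhantomSpec:
    """Full description of a synthetic volume.

    The default geometry matches the emulated acquisition protocol
    (49 B-scans x 496 depth x 512 A-scans over ~6x6 mm) and the default
    band thickness of 10 px yields a foreground fraction of ~2% of B-scan
    pixels (10/496).
    """

    n_bscans: int = DEFAULT_N_BSCANS
    n_depth: int = DEFAULT_N_DEPTH
    n_ascans: int = DEFAULT_N_ASCANS
    dx_mm: float = DEFAULT_DX_MM
    dy_mm: float = DEFAULT_DY_MM
    dz_um: float = 1.0
    band_center_row: float = 0.55  # fraction of depth if <=1, else pixels
    band_thickness_px: float = 10.0
    thickness_amplitude: float = 2.0
    thickness_corr_length: float = 0.35  # relative wavelength of modulation
    center_amplitude: float = 8.0
    disruptions: list[Ellipse] = field(default_factory=list)
    shadows: list[Shadow] = field(default_factory=list)
    cysts: list[Cyst] = field(default_factory=list)
    speckle_sigma: float = 0.15
    background: float = 0.08
    band_intensity: float = 0.85
    seed: int = 0

    def center_row_px(self) -> float:
        c = self.band_center_row
        return c * self.n_depth if c <= 1.0 else c


def default_spec(seed: int = 0, pathology: bool = True) -> PhantomSpec:
    """Default phantom with mild, seeded pathology (disruptions, shadows,
    cysts) on top of the smooth band."""
    spec = PhantomSpec(seed=seed)
    if pathology:
        rng = np.random.default_rng(seed + 7919)
        nb, nx = spec.n_bscans, spec.n_ascans
        spec.disruptions = [
            Ellipse(
                center_b=float(rng.uniform(0.2 * nb, 0.8 * nb)),
                center_x=float(rng.uniform(0.2 * nx, 0.8 * nx)),
                radius_b=float(rng.uniform(1.5, 4.0)),
                radius_x=float(rng.uniform(10, 35)),
            )
            for _ in range(2)
        ]
        starts = rng.integers(0, nx - 30, size=2)
        widths = rng.integers(8, 25, size=2)
        factors = rng.uniform(0.3, 0.6, size=2)
        spec.shadows = [
            Shadow(int(s), int(s + w), float(f))
            for s, w, f in zip(starts, widths, factors)
        ]
        spec.cysts = [
            Cyst(
                center_b=float(rng.uniform(0.2 * nb, 0.8 * nb)),
                center_z=float(rng.uniform(0.25, 0.4) * spec.n_depth),
                center_x=float(rng.uniform(0.2 * nx, 0.8 * nx)),
                radius_b=float(rng.uniform(2, 5)),
                radius_z=float(rng.uniform(10, 30)),
                radius_x=float(rng.uniform(20, 50)),
            )
            for _ in range(2)
        ]
    return spec


@dataclass
class PhantomTruth:
    """Exact ground truth for a generated phantom volume."""

    mask: LayerMask
    thickness_true: np.ndarray  # (n_bscans, n_ascans) px; 0 where disrupted
    upper_true: np.ndarray  # (n_bscans, n_ascans) top foreground row (NaN if none)
    lower_true: np.ndarray  # bottom foreground row (NaN if none)
    disrupted: np.ndarray  # boolean en-face grid


def _smooth_field(rng: np.random.Generator, nb: int, nx: int,
                  amplitude: float, corr_length: float, n_terms: int = 4) -> np.ndarray:
    """Low-frequency cosine mixture over the en-face grid, bounded by
    +-amplitude. Cheap, smooth, analytically bounded."""
    bb = np.linspace(0, 1, nb)[:, None]
    xx = np.linspace(0, 1, nx)[None, :]
    out = np.zeros((nb, nx))
    weights = rng.uniform(0.3, 1.0, size=n_terms)
    weights /= weights.sum()
    for w in weights:
        fb = rng.uniform(0.3, 1.0) / corr_length
        fx = rng.uniform(0.3, 1.0) / corr_length
        pb = rng.uniform(0, 2 * math.pi)
        px = rng.uniform(0, 2 * math.pi)
        out += w * np.cos(2 * math.pi * fb * bb + pb) * np.cos(2 * math.pi * fx * xx + px)
    return amplitude * out


def generate_volume(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Render a phantom volume and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises ``ValueError`` naming
    the offending (b, x) if the band would escape the depth range.
    """
    rng = np.random.default_rng(spec.seed)
    nb, nz, nx = spec.n_bscans, spec.n_depth, spec.n_ascans

    center = spec.center_row_px() + _smooth_field(
        rng, nb, nx, spec.center_amplitude, spec.thickness_corr_length
    )
    t_cont = spec.band_thickness_px + _smooth_field(
        rng, nb, nx, spec.thickness_amplitude, spec.thickness_corr_length
    )
    t_int = np.maximum(np.round(t_cont), 0).astype(np.int64)

    z_top = np.round(center - 0.5 * (t_int - 1)).astype(np.int64)
    z_bot = z_top + t_int - 1

    bad = (t_int > 0) & ((z_top < 0) | (z_bot > nz - 1))
    if np.any(bad):
        b, x = np.argwhere(bad)[0]
        raise ValueError(
            f"band escapes depth range at (b={b}, x={x}): "
            f"rows [{z_top[b, x]}, {z_bot[b, x]}] outside [0, {nz - 1}]"
        )

    # Disruption carving: thickness -> 0 inside each en-face ellipse.
    bb, xx = np.meshgrid(np.arange(nb), np.arange(nx), indexing="ij")
    disrupted = np.zeros((nb, nx), dtype=bool)
    for ell in spec.disruptions:
        disrupted |= ell.contains(bb, xx)
    t_int = np.where(disrupted, 0, t_int)

    zz = np.arange(nz)[None, :, None]
    band = (zz >= z_top[:, None, :]) & (zz <= z_bot[:, None, :]) & (t_int[:, None, :] > 0)
    mask = band.astype(np.uint8)

    thickness_true = t_int.astype(np.float64)
    upper_true = np.where(t_int > 0, z_top, np.nan).astype(np.float64)
    lower_true = np.where(t_int > 0, z_bot, np.nan).astype(np.float64)

    # --- image rendering (never touches the mask) ---
    depth_gradient = 0.5 + 0.5 * np.linspace(0, 1, nz)  # slightly brighter below
    img = spec.background * depth_gradient[None, :, None] * np.ones((nb, nz, nx))

    # neighbouring layers: a dim band above (inner retina) and a bright thin
    # band below (RPE-like), following the same geometry even at disruptions
    center_i = np.round(center).astype(np.int64)
    above = (zz >= np.clip(center_i - 18, 0, nz - 1)[:, None, :]) & (
        zz <= np.clip(center_i - 14, 0, nz - 1)[:, None, :]
    )
    below = (zz >= np.clip(center_i + 10, 0, nz - 1)[:, None, :]) & (
        zz <= np.clip(center_i + 13, 0, nz - 1)[:, None, :]
    )
    img = np.where(above, 0.35, img)
    img = np.where(below, 0.55, img)
    img = np.where(band, spec.band_intensity, img)

    for cyst in spec.cysts:
        blob = (
            ((np.arange(nb)[:, None, None] - cyst.center_b) / max(cyst.radius_b, 1e-9)) ** 2
            + ((np.arange(nz)[None, :, None] - cyst.center_z) / max(cyst.radius_z, 1e-9)) ** 2
            + ((np.arange(nx)[None, None, :] - cyst.center_x) / max(cyst.radius_x, 1e-9)) ** 2
        ) <= 1.0
        img = np.where(blob, cyst.intensity, img)

    for sh in spec.shadows:
        x0, x1 = max(sh.x_start, 0), min(sh.x_stop, nx)
        if x1 <= x0:
            continue
        b0, b1 = (0, nb) if sh.bscan_range is None else sh.bscan_range
        img[b0:b1, :, x0:x1] *= sh.factor

    if spec.speckle_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=spec.speckle_sigma, size=img.shape)
        img = img * noise
    img = np.clip(img, 0.0, 1.0)

    volume = OCTVolume(img, spec.dx_mm, spec.dy_mm, spec.dz_um)
    truth = PhantomTruth(LayerMask(mask), thickness_true, upper_true, lower_true, disrupted)
    return volume, truth


def split_dataset(items: list, fractions: tuple[float, float, float], seed: int,
                  labels: list | None = None) -> tuple[list, list, list]:
    """Stratified random train/val/test split.

    ``fractions`` must sum to 1 (within rounding).  When ``labels`` is given,
    each stratum contributes proportionally to every split (largest-remainder
    apportionment), mirroring a disease-balanced division.
    """
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if labels is None:
        labels = [0] * n
    if len(labels) != n:
        raise ValueError("labels must match items length")

    rng = np.random.default_rng(seed)
    splits: tuple[list, list, list] = ([], [], [])
    for stratum in sorted(set(labels), key=str):
        idx = [i for i, lab in enumerate(labels) if lab == stratum]
        rng.shuffle(idx)
        counts = _apportion(len(idx), fractions)
        start = 0
        for part, c in zip(splits, counts):
            part.extend(items[i] for i in idx[start:start + c])
            start += c
    return splits


def _apportion(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items into len(fractions) bins."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for _ in range(n - sum(counts)):
        j = max(range(len(fractions)), key=lambda k: (remainders[k], -k))
        counts[j] += 1
        remainders[j] = -1.0
    return counts
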