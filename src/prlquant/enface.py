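"""En-face thickness and disagreement map reconstruction.

Per B-scan, smoothing B-splines are fit to the upper and lower interfaces of
the binary segmentation, bridging disruptions and holes; thickness per
A-scan is the inclusive distance between the fitted edges, forced to 0 on
columns with no raw foreground.  The disagreement (std) map is sampled
along the medial axis between the two fitted interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from prlquant.ensemble import EnsembleResult


@dataclass
class InterfaceSet:
    """Sub-pixel layer interfaces for one B-scan."""

    upper: np.ndarray  # raw topmost foreground row per column (NaN if empty)
    lower: np.ndarray  # raw bottommost foreground row per column (NaN if empty)
    upper_fit: np.ndarray  # spline evaluation over all columns (NaN if no fit)
    lower_fit: np.ndarray
    medial: np.ndarray  # (upper_fit + lower_fit) / 2
    disrupted: np.ndarray  # boolean: raw column has zero foreground
    empty: bool = False  # whole mask empty; no fits available


@dataclass
class EnFaceMap:
    """(n_bscans x n_ascans) grid of thickness or disagreement values."""

    grid: np.ndarray
    kind: str  # "thickness" | "std"
    units: str  # "px" | "um" | "score-std"
    dx_mm: float
    dy_mm: float


def _fit_spline(x: np.ndarray, y: np.ndarray, n_columns: int,
                smoothing_per_point: float) -> np.ndarray:
    """Cubic smoothing spline through (x, y), evaluated on all columns.

    Falls back to lower order (or a constant) when support is scarce."""
    k = min(3, len(x) - 1)
    grid = np.arange(n_columns, dtype=np.float64)
    if k < 1:
        return np.full(n_columns, float(y[0]))
    s = smoothing_per_point * len(x)
    spl = UnivariateSpline(x, y, k=k, s=s)
    return spl(grid)


def extract_interfaces(binary: np.ndarray, smoothing_per_point: float = 0.05
                       ) -> InterfaceSet:
    """Locate the layer's upper/lower interfaces in one B-scan mask.

    Upper/lower are the topmost/bottommost foreground rows per column
    (columns with multiple blobs span all of them).  Cubic smoothing splines
    interpolate across disruptions; disruption flags come from the raw mask,
    never from the splines.
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {binary.shape}")
    fg = binary > 0
    n_rows, n_cols = fg.shape
    any_fg = fg.any(axis=0)
    disrupted = ~any_fg

    upper = np.full(n_cols, np.nan)
    lower = np.full(n_cols, np.nan)
    rows = np.arange(n_rows)
    first = np.where(any_fg, fg.argmax(axis=0), -1)
    last = np.where(any_fg, n_rows - 1 - fg[::-1].argmax(axis=0), -1)
    upper[any_fg] = first[any_fg]
    lower[any_fg] = last[any_fg]

    if not any_fg.any():
        nanrow = np.full(n_cols, np.nan)
        return InterfaceSet(upper, lower, nanrow.copy(), nanrow.copy(),
                            nanrow.copy(), disrupted, empty=True)

    support = np.flatnonzero(any_fg).astype(np.float64)
    upper_fit = _fit_spline(support, upper[any_fg], n_cols, smoothing_per_point)
    lower_fit = _fit_spline(support, lower[any_fg], n_cols, smoothing_per_point)
    # fitted edges may cross on wild extrapolation; enforce ordering
    upper_fit, lower_fit = np.minimum(upper_fit, lower_fit), np.maximum(upper_fit, lower_fit)
    medial = 0.5 * (upper_fit + lower_fit)
    return InterfaceSet(upper, lower, upper_fit, lower_fit, medial, disrupted)


def thickness_profile(ifs: InterfaceSet) -> np.ndarray:
    """Per-A-scan thickness in pixels: inclusive extent of the fitted edges
    (lower - upper + 1), exactly 0 on disrupted columns."""
    n = len(ifs.disrupted)
    if ifs.empty:
        return np.zeros(n)
    thickness = ifs.lower_fit - ifs.upper_fit + 1.0
    thickness = np.clip(thickness, 0.0, None)
    thickness[ifs.disrupted] = 0.0
    return thickness


def enface_thickness(results: list[EnsembleResult] | list[np.ndarray],
                     dx_mm: float, dy_mm: float, dz_um: float = 1.0,
                     smoothing_per_point: float = 0.05) -> EnFaceMap:
    """Stack per-B-scan thickness profiles into an en-face map.

    Row b derives solely from B-scan b.  ``dz_um`` scales pixel thickness
    to microns (default 1 -> values stay in pixels).
    """
    rows = []
    for res in results:
        binary = res.binary if isinstance(res, EnsembleResult) else res
        ifs = extract_interfaces(binary, smoothing_per_point)
        rows.append(thickness_profile(ifs) * dz_um)
    units = "px" if dz_um == 1.0 else "um"
    return EnFaceMap(np.vstack(rows), "thickness", units, dx_mm, dy_mm)


def enface_std(results: list[EnsembleResult], dx_mm: float, dy_mm: float,
               smoothing_per_point: float = 0.05) -> tuple[EnFaceMap, np.ndarray]:
    """Sample each B-scan's std map along the medial axis of its layer.

    Returns the map and a boolean coverage grid (False where the B-scan had
    no foreground at all and the value was substituted with 0).
    """
    rows = []
    coverage = []
    for res in results:
        ifs = extract_interfaces(res.binary, smoothing_per_point)
        n_rows = res.std_map.shape[0]
        if ifs.empty:
            rows.append(np.zeros(res.std_map.shape[1]))
            coverage.append(np.zeros(res.std_map.shape[1], dtype=bool))
            continue
        rr = np.clip(np.round(ifs.medial).astype(int), 0, n_rows - 1)
        cols = np.arange(res.std_map.shape[1])
        rows.append(res.std_map[rr, cols])
        coverage.append(np.ones(res.std_map.shape[1], dtype=bool))
    return (EnFaceMap(np.vstack(rows), "std", "score-std", dx_mm, dy_mm),
            np.vstack(coverage))


def normalize_for_display(grid: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize to [0,1]; constant input -> zeros with a flag."""
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(grid)):
        raise ValueError("map contains non-finite values")
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        return np.zeros_like(grid), True
    return (grid - lo) / (hi - lo), False
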