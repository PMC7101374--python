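"""Pixel-level evaluation, ETDRS-grid regions and B-scan sampling.

Region membership is decided in the en-face plane (physical distances via
dx/dy spacings) and applied to whole A-scan columns when counting pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ETDRSRegions:
    """Boolean en-face membership grids for the standard macular areas."""

    fovea_center: tuple[float, float]  # (b, x) index coordinates
    csf: np.ndarray  # central subfield: disk of 1 mm diameter
    cmm3: np.ndarray  # 3 central mm: disk of 3 mm diameter
    ring31: np.ndarray  # annulus cmm3 \ csf
    full: np.ndarray

    def by_name(self, name: str) -> np.ndarray:
        try:
            return {"csf": self.csf, "cmm3": self.cmm3,
                    "ring31": self.ring31, "full": self.full}[name]
        except KeyError:
            raise ValueError(f"unknown region {name!r}") from None


@dataclass
class SegmentationScores:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    dice: float
    region: str = "full"
    degenerate: bool = False  # empty truth and empty prediction


def etdrs_regions(n_bscans: int, n_ascans: int, dx_mm: float, dy_mm: float,
                  fovea_center: tuple[float, float] | None = None) -> ETDRSRegions:
    """Build CSF (<= 0.5 mm), 3-CMM (<= 1.5 mm) and 3-1 ring membership by
    Euclidean distance of cell centers from the fovea.

    The fovea defaults to the volume's geometric center (scans are
    fovea-centred)."""
    if dx_mm <= 0 or dy_mm <= 0:
        raise ValueError("spacings must be positive")
    if fovea_center is None:
        fovea_center = ((n_bscans - 1) / 2.0, (n_ascans - 1) / 2.0)
    fb, fx = fovea_center
    bb = (np.arange(n_bscans)[:, None] - fb) * dy_mm
    xx = (np.arange(n_ascans)[None, :] - fx) * dx_mm
    dist = np.sqrt(bb ** 2 + xx ** 2)
    csf = dist <= 0.5
    cmm3 = dist <= 1.5
    return ETDRSRegions(fovea_center, csf, cmm3, cmm3 & ~csf,
                        np.ones((n_bscans, n_ascans), dtype=bool))


def _region_to_voxels(region: np.ndarray, shape: tuple) -> np.ndarray:
    """Broadcast an en-face (b,x) membership grid to full (b,z,x) columns."""
    if region.shape != (shape[0], shape[2]):
        raise ValueError(
            f"region grid {region.shape} incompatible with volume {shape}"
        )
    return np.broadcast_to(region[:, None, :], shape)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     region: np.ndarray | None = None) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over region-selected pixels.

    ``pred``/``truth`` are congruent binary grids; 2-D (one B-scan, region
    selects columns) or 3-D (volume, en-face region selects whole A-scan
    columns)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if region is None:
        sel = np.ones(pred.shape, dtype=bool)
    elif pred.ndim == 3:
        sel = _region_to_voxels(np.asarray(region).astype(bool), pred.shape)
    else:
        region = np.asarray(region).astype(bool)
        if region.ndim == 1:  # column selector on a single B-scan
            sel = np.broadcast_to(region[None, :], pred.shape)
        else:
            sel = region
    p = pred[sel]
    t = truth[sel]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return tp, fp, fn, tn


def scores_from_counts(tp: int, fp: int, fn: int, tn: int,
                       region: str = "full") -> SegmentationScores:
    """Precision, recall and Dice (= 2PR/(P+R) = 2TP/(2TP+FP+FN)).

    All three are NaN (flagged degenerate) when truth and prediction are
    both empty, so healthy empty regions don't inflate averages."""
    if tp + fp + fn == 0:
        return SegmentationScores(tp, fp, fn, tn, float("nan"), float("nan"),
                                  float("nan"), region, degenerate=True)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    dice = 2.0 * tp / (2 * tp + fp + fn)
    return SegmentationScores(tp, fp, fn, tn, precision, recall, dice, region)


def evaluate_masks(pred: np.ndarray, truth: np.ndarray,
                   region: np.ndarray | None = None,
                   region_name: str = "full") -> SegmentationScores:
    return scores_from_counts(*confusion_counts(pred, truth, region), region_name)


def pr_curve(scores: np.ndarray, truth: np.ndarray,
             region: np.ndarray | None = None,
             n_thresholds: int = 101) -> tuple[list[tuple[float, float]], float]:
    """Precision/recall pairs over a descending threshold grid plus the
    trapezoidal area under the curve (integrated over recall).

    The curve is anchored at recall 0 with the precision of the highest
    threshold yielding >= 1 prediction (1.0 if none does)."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores/truth shape mismatch")
    if region is not None:
        if scores.ndim == 3:
            sel = _region_to_voxels(np.asarray(region).astype(bool), scores.shape)
        else:
            sel = np.asarray(region).astype(bool)
        scores = scores[sel]
        truth = truth[sel]
    scores = scores.ravel()
    truth = truth.ravel()
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("no positive pixels in region; PR curve undefined")

    thresholds = np.linspace(0.0, 1.0, n_thresholds)[::-1]
    points: list[tuple[float, float]] = []
    anchor_precision = 1.0
    have_anchor = False
    for t in thresholds:
        pred = scores >= t
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue
        tp = int(np.count_nonzero(pred & truth))
        precision = tp / n_pred
        if not have_anchor:
            anchor_precision = precision
            have_anchor = True
        points.append((tp / n_pos, precision))

    recalls = np.array([0.0] + [r for r, _ in points])
    precisions = np.array([anchor_precision] + [p for _, p in points])
    order = np.argsort(recalls, kind="stable")
    auc = float(np.trapezoid(precisions[order], recalls[order]))
    return points, auc


def region_mean_thickness(grid: np.ndarray, regions: ETDRSRegions,
                          names: tuple[str, ...] = ("csf", "cmm3", "ring31", "full")
                          ) -> dict[str, float]:
    """Arithmetic mean of an en-face thickness grid over each region
    (disruption zeros included)."""
    grid = np.asarray(grid, dtype=np.float64)
    out = {}
    for name in names:
        member = regions.by_name(name)
        if member.shape != grid.shape:
            raise ValueError("region grid incongruent with map")
        # a region can be empty on small/truncated en-face grids
        out[name] = float(grid[member].mean()) if member.any() else float("nan")
    return out


# Distance bands (min_mm, max_mm) used for the inter-observer B-scan sampling.
SAMPLING_BANDS = ((0.0, 1.0), (1.0, 3.0), (3.0, 6.0))


def sample_bscans(n_bscans: int, dy_mm: float, fovea_b: float | None = None,
                  seed: int = 0, n_per_band: int = 2) -> list[list[int]]:
    """Draw ``n_per_band`` distinct B-scans per distance band (0-1, 1-3 and
    3-6 mm from the fovea along the slow axis), without replacement.

    Reproducible under ``seed``; raises if a band has too few eligible scans.
    """
    if fovea_b is None:
        fovea_b = (n_bscans - 1) / 2.0
    rng = np.random.default_rng(seed)
    dist = np.abs(np.arange(n_bscans) - fovea_b) * dy_mm
    samples: list[list[int]] = []
    for lo, hi in SAMPLING_BANDS:
        eligible = np.flatnonzero((dist >= lo) & (dist <= hi) if lo == 0.0
                                  else (dist > lo) & (dist <= hi))
        if len(eligible) < n_per_band:
            raise ValueError(
                f"band {lo}-{hi} mm has only {len(eligible)} eligible B-scans, "
                f"need {n_per_band}"
            )
        pick = rng.choice(eligible, size=n_per_band, replace=False)
        samples.append(sorted(int(i) for i in pick))
    return samples
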