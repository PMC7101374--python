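"""Score-map fusion and Otsu binarization for the model ensemble.

Per B-scan: the members' score maps are averaged pixel-wise into a mean
score map, their population standard deviation forms a disagreement map,
and the mean map is binarized with a 256-bin Otsu threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prlquant.volume_io import OCTVolume

OTSU_BINS = 256


@dataclass
class EnsembleResult:
    """Fused outputs for a single B-scan."""

    mean_score: np.ndarray  # (n_depth, n_ascans) in [0,1]
    std_map: np.ndarray  # population std per pixel, in [0, 0.5]
    binary: np.ndarray  # uint8 mask, == (mean_score >= threshold)
    threshold: float
    degenerate: bool = False  # constant mean map; no valid Otsu split


def fuse_scores(score_maps: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise mean and population standard deviation of >= 2 score maps."""
    if len(score_maps) < 2:
        raise ValueError(f"need >= 2 score maps, got {len(score_maps)}")
    arrs = [np.asarray(m, dtype=np.float64) for m in score_maps]
    shape0 = arrs[0].shape
    for i, a in enumerate(arrs):
        if a.shape != shape0:
            raise ValueError(f"score map {i} has shape {a.shape}, expected {shape0}")
        if a.min() < 0 or a.max() > 1:
            raise ValueError(f"score map {i} has values outside [0, 1]")
    stack = np.stack(arrs)
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)  # population (ddof=0): bounded by 0.5 on [0,1]
    return mean, std


def otsu_binarize(mean_score: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Threshold a [0,1] score map by maximizing between-class variance over
    a 256-bin histogram; ties broken toward the lowest threshold.

    Returns ``(binary, threshold, degenerate)``.  A constant map is flagged
    degenerate: threshold = the constant, mask all-zero.
    """
    scores = np.asarray(mean_score, dtype=np.float64)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    if scores.max() == scores.min():
        return np.zeros(scores.shape, dtype=np.uint8), float(scores.flat[0]), True

    counts, edges = np.histogram(scores, bins=OTSU_BINS, range=(0.0, 1.0))
    total = counts.sum()
    p = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])

    # Candidate thresholds: lower edge of each bin k (classes split as
    # bins < k vs bins >= k).  Vectorized cumulative form of the
    # between-class variance sigma_b^2(k) = w0*w1*(mu0-mu1)^2.
    w0 = np.cumsum(p)[:-1]  # weight of class {bins 0..k-1}, k = 1..255
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    mu_total = float((p * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, cum_mu / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - cum_mu) / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sigma_b)) + 1  # argmax takes first (lowest) maximizer
    threshold = float(edges[k])
    binary = (scores >= threshold).astype(np.uint8)
    return binary, threshold, False


def fuse_bscan(score_maps: list[np.ndarray]) -> EnsembleResult:
    """Fuse one B-scan's member score maps and binarize the mean."""
    mean, std = fuse_scores(score_maps)
    binary, threshold, degenerate = otsu_binarize(mean)
    return EnsembleResult(mean, std, binary, threshold, degenerate)


def segment_volume(models: list, volume: OCTVolume,
                   predict_fn=None) -> list[EnsembleResult]:
    """Run every member model on every B-scan and fuse the outputs.

    ``models`` are :class:`~prlquant.networks.TrainedModel` instances (or
    anything accepted by ``predict_fn(model, bscan)``).
    """
    if predict_fn is None:
        from prlquant.networks import predict_bscan as predict_fn  # lazy import
    if len(models) < 2:
        raise ValueError("ensemble needs >= 2 models")
    results = []
    for b in range(volume.n_bscans):
        bscan = volume.voxels[b]
        maps = [predict_fn(m, bscan) for m in models]
        results.append(fuse_bscan(maps))
    return results
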