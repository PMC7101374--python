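"""End-to-end orchestration: phantom -> train -> predict -> quantify -> evaluate.

A single global seed is expanded into per-stage seeds by a fixed derivation
(CRC32 of "stage:seed") so stages can be re-run independently and a rerun of
the same config reproduces all deterministic outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from prlquant import phantom as ph
from prlquant import metrics as mx
from prlquant import stats as st
from prlquant.ensemble import segment_volume
from prlquant.enface import enface_thickness, enface_std
from prlquant.networks import ModelConfig, build_model, train_model, save_checkpoint
from prlquant.volume_io import save_enface_csv, save_json

log = logging.getLogger("prlquant")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed from the global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    n_volumes: int = 8
    fractions: tuple[float, float, float] = (0.625, 0.125, 0.25)
    # toy phantom geometry keeps CPU training fast; scale up via config
    n_bscans: int = 4
    n_depth: int = 64
    n_ascans: int = 64
    band_thickness_px: float = 8.0
    speckle_sigma: float = 0.10
    archs: tuple[str, ...] = ("unet", "all_dropout", "bru_net", "u2net")
    depth: int = 3
    base_channels: int = 8
    max_epochs: int = 25
    patience: int = 8
    learning_rate: float = 2e-3
    dropout_rate: float = 0.1
    dz_um: float = 1.0
    smoothing_per_point: float = 0.05
    seed: int = 0
    out_dir: str = "runs/default"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.fractions = tuple(cfg.fractions)
        cfg.archs = tuple(cfg.archs)
        return cfg


def _toy_spec(cfg: RunConfig, seed: int, with_disruption: bool) -> ph.PhantomSpec:
    nz = cfg.n_depth
    spec = ph.PhantomSpec(
        n_bscans=cfg.n_bscans, n_depth=nz, n_ascans=cfg.n_ascans,
        band_center_row=0.55, band_thickness_px=cfg.band_thickness_px,
        thickness_amplitude=1.5, center_amplitude=max(2.0, nz * 0.03),
        speckle_sigma=cfg.speckle_sigma, seed=seed,
    )
    if with_disruption:
        rng = np.random.default_rng(seed + 13)
        spec.disruptions = [ph.Ellipse(
            center_b=float(rng.uniform(0, cfg.n_bscans)),
            center_x=float(rng.uniform(0.2, 0.8) * cfg.n_ascans),
            radius_b=1.5, radius_x=float(rng.uniform(3, 8)),
        )]
    return spec


def make_dataset(cfg: RunConfig) -> tuple[list, list]:
    """Generate phantom volumes; every other volume carries a disruption
    (the stratification label for splitting)."""
    seed0 = derive_seed(cfg.seed, "phantom")
    volumes = []
    labels = []
    for i in range(cfg.n_volumes):
        with_disruption = i % 2 == 1
        spec = _toy_spec(cfg, seed0 + i, with_disruption)
        volumes.append(ph.generate_volume(spec))
        labels.append(int(with_disruption))
    return volumes, labels


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write a JSON manifest to ``cfg.out_dir``.

    Any stage failure aborts with the stage name; a partial manifest is
    persisted for debugging."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg_dict = asdict(cfg)
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    stage = "init"
    try:
        stage = "phantom"
        t0 = time.time()
        volumes, labels = make_dataset(cfg)
        train_set, val_set, test_set = ph.split_dataset(
            list(range(cfg.n_volumes)), cfg.fractions,
            derive_seed(cfg.seed, "split"), labels=labels,
        )
        if not train_set:
            raise ValueError("empty training split")
        manifest["stages"]["phantom"] = {
            "n_volumes": cfg.n_volumes, "split": {
                "train": train_set, "val": val_set, "test": test_set},
            "seconds": round(time.time() - t0, 2),
        }
        log.info("phantom stage done: %d volumes", cfg.n_volumes)

        def pairs(indices):
            out = []
            for i in indices:
                vol, truth = volumes[i]
                for b in range(vol.n_bscans):
                    out.append((vol.voxels[b], truth.mask.mask[b]))
            return out

        stage = "train"
        t0 = time.time()
        trained = []
        histories = {}
        for k, arch in enumerate(cfg.archs):
            mcfg = ModelConfig(
                arch_name=arch, depth=cfg.depth, base_channels=cfg.base_channels,
                dropout_rate=cfg.dropout_rate, learning_rate=cfg.learning_rate,
                max_epochs=cfg.max_epochs, patience=cfg.patience,
                seed=derive_seed(cfg.seed, f"train:{arch}:{k}"),
            )
            model = build_model(mcfg)
            tm = train_model(model, pairs(train_set), pairs(val_set), mcfg)
            trained.append(tm)
            histories[arch] = tm.history
            save_checkpoint(tm, os.path.join(cfg.out_dir, f"model_{arch}.npz"))
            log.info("trained %s: best val dice %.3f", arch,
                     max(h["val_dice"] for h in tm.history))
        manifest["stages"]["train"] = {
            "histories": histories, "seconds": round(time.time() - t0, 2)}

        stage = "predict"
        t0 = time.time()
        test_results = {}
        for i in test_set:
            vol, truth = volumes[i]
            test_results[i] = segment_volume(trained, vol)
        manifest["stages"]["predict"] = {"seconds": round(time.time() - t0, 2)}

        stage = "quantify"
        t0 = time.time()
        thickness_maps = {}
        for i, results in test_results.items():
            vol, truth = volumes[i]
            tmap = enface_thickness(results, vol.dx_mm, vol.dy_mm, cfg.dz_um,
                                    cfg.smoothing_per_point)
            smap, _ = enface_std(results, vol.dx_mm, vol.dy_mm,
                                 cfg.smoothing_per_point)
            thickness_maps[i] = tmap
            save_enface_csv(tmap.grid, os.path.join(cfg.out_dir, f"thickness_{i}.csv"))
            save_enface_csv(smap.grid, os.path.join(cfg.out_dir, f"std_{i}.csv"))
        manifest["stages"]["quantify"] = {"seconds": round(time.time() - t0, 2)}

        stage = "evaluate"
        t0 = time.time()
        per_volume = {}
        dices = []
        est_means, true_means = [], []
        for i, results in test_results.items():
            vol, truth = volumes[i]
            pred = np.stack([r.binary for r in results])
            scores = mx.evaluate_masks(pred, truth.mask.mask)
            regions = mx.etdrs_regions(vol.n_bscans, vol.n_ascans,
                                       vol.dx_mm, vol.dy_mm)
            mean_est = mx.region_mean_thickness(thickness_maps[i].grid, regions)
            mean_true = mx.region_mean_thickness(truth.thickness_true * cfg.dz_um,
                                                 regions)
            per_volume[i] = {
                "dice": scores.dice, "precision": scores.precision,
                "recall": scores.recall, "mean_thickness_est": mean_est,
                "mean_thickness_true": mean_true,
            }
            dices.append(scores.dice)
            est_means.append(mean_est["full"])
            true_means.append(mean_true["full"])
        summary = {"per_volume": per_volume,
                   "test_dice_mean": float(np.mean(dices))}
        if len(est_means) >= 3:
            comp = st.thickness_bias_test(est_means, true_means)
            summary["thickness_bias"] = {
                "test_used": comp.test_used, "p_value": comp.p_value,
                "reject": comp.reject,
            }
        manifest["stages"]["evaluate"] = {
            "summary": summary, "seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        save_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    save_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
    return manifest
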