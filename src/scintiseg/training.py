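"""Alternating adversarial optimization.

Each step first updates the critic (minimizing 1 minus the signature
distance, i.e. maximizing its ability to separate predicted from true
image-mask products, with the generator outputs detached), then updates
the generator (minimizing alpha * segmentation loss + beta * adversarial
distance). Both networks use Adam at the same learning rate. With
``use_gan`` off the critic is skipped entirely and the generator trains on
the segmentation loss alone.

``fit`` repeats the whole procedure ``n_runs`` times with seeds
``seed + run_index``, checkpoints each run, logs per-epoch losses to CSV,
and reports test-split metrics as per-run values plus mean +/- std.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import nn
from .data_io import DatasetManifest, read_mask, read_scintigram
from .discriminator import Critic, CriticConfig, build_critic
from .errors import ConfigurationError, TrainingError
from .generator import (Generator, GeneratorConfig, build_generator,
                        normalize_image, predict_mask, save_checkpoint)
from .objectives import (LossWeights, MetricsReport, adv_loss_G, disc_loss,
                         evaluate, seg_loss, summarize_runs, write_report)

__all__ = ["TrainConfig", "StepLosses", "train_step", "fit", "load_split_arrays"]


class StepLosses(NamedTuple):
    """Scalar losses from one alternating update.

    ``gen`` is the full generator objective (alpha * seg + beta * adv),
    ``disc`` the critic loss (0 when adversarial training is off), and
    ``seg`` the segmentation component alone — logged separately so that
    adversarial and non-adversarial runs can be compared on the same
    quantity.
    """
    gen: float
    disc: float
    seg: float


@dataclass
class TrainConfig:
    lr: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 32
    epochs: int = 600
    seed: int = 42
    n_runs: int = 5
    d_steps_per_g_step: int = 1
    device: str = "cpu"
    threshold: float = 0.5
    # ablation switches
    use_gan: bool = True
    use_pyramid: bool = True
    use_deep_supervision: bool = True
    use_msfe: bool = True
    use_cdc: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.batch_size < 1 or self.epochs < 1 or self.n_runs < 1:
            raise ConfigurationError("batch_size, epochs and n_runs must be >= 1")


def apply_ablations(gen_cfg: GeneratorConfig, cfg: TrainConfig) -> GeneratorConfig:
    """Project the training ablation switches onto a generator config."""
    enc = list(gen_cfg.encoder_block_types)
    if not cfg.use_cdc and enc[0] == "cdc":
        enc[0] = "plain"
    if not cfg.use_msfe:
        enc = [enc[0]] + ["plain"] * (len(enc) - 1)
    return dataclasses.replace(
        gen_cfg,
        encoder_block_types=tuple(enc),
        use_pyramid=gen_cfg.use_pyramid and cfg.use_pyramid,
        use_deep_supervision=gen_cfg.use_deep_supervision and cfg.use_deep_supervision)


def train_step(batch: tuple[np.ndarray, np.ndarray], generator: Generator,
               critic: Critic | None, w: LossWeights, cfg: TrainConfig,
               opt_g: nn.Adam, opt_d: nn.Adam | None,
               batch_index: int = 0) -> StepLosses:
    """One alternating update: critic first (on detached generator outputs),
    then the generator."""
    images, gts = batch
    img_t = nn.Tensor(images)
    gt_t = nn.Tensor(gts)

    generator.train(True)
    outputs = generator(img_t)

    d_val = 0.0
    g_seg = nn.mul(seg_loss(outputs, gt_t, w), np.float32(w.alpha))
    seg_val = g_seg.item() / w.alpha if w.alpha else 0.0
    if cfg.use_gan and critic is not None and w.beta > 0:
        critic.train(True)
        for _ in range(cfg.d_steps_per_g_step):
            d_loss = disc_loss(outputs, gt_t, img_t, critic)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
        d_val = d_loss.item()
        g_adv = adv_loss_G(outputs, gt_t, img_t, critic)
        g_loss = nn.add(g_seg, nn.mul(g_adv, np.float32(w.beta)))
    else:
        # beta-term dropped entirely when adversarial training is off
        g_loss = g_seg

    opt_g.zero_grad()
    g_loss.backward()
    opt_g.step()
    g_val = g_loss.item()

    if not (np.isfinite(g_val) and np.isfinite(d_val)):
        raise TrainingError(f"non-finite loss at batch {batch_index}: "
                            f"gen={g_val}, disc={d_val}")
    return StepLosses(g_val, d_val, seg_val)


def load_split_arrays(manifest: DatasetManifest, split: str,
                      normalization: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a split into (images, masks) arrays shaped (N, 1, H, W)."""
    records = manifest.subset(split)
    if records.empty:
        raise ConfigurationError(f"manifest has no records in split {split!r}")
    images, masks = [], []
    for _, row in records.iterrows():
        img = read_scintigram(row["image_path"])
        msk = read_mask(row["mask_path"], pair=img)
        images.append(normalize_image(img.pixels, normalization))
        masks.append(msk.pixels.astype(np.float32))
    return (np.stack(images)[:, None], np.stack(masks)[:, None])


def _train_one_run(run_seed: int, train_x, train_y, gen_cfg, critic_cfg, w, cfg):
    gen = build_generator(dataclasses.replace(gen_cfg, seed=run_seed))
    critic = None
    opt_d = None
    if cfg.use_gan:
        critic = build_critic(dataclasses.replace(critic_cfg, seed=run_seed + 1))
        opt_d = nn.Adam(critic.parameters(), lr=cfg.lr)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr)

    n = train_x.shape[0]
    trace = []  # (epoch, mean gen loss, mean disc loss, mean seg loss)
    for epoch in range(cfg.epochs):
        order = np.random.default_rng((run_seed, epoch)).permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses.append(train_step(
                (train_x[idx], train_y[idx]), gen, critic, w, cfg,
                opt_g, opt_d, batch_index=start // cfg.batch_size))
        arr = np.asarray(losses, dtype=np.float64).mean(axis=0)
        trace.append((epoch, float(arr[0]), float(arr[1]), float(arr[2])))
    return gen, critic, trace


def fit(manifest: DatasetManifest, gen_cfg: GeneratorConfig,
        critic_cfg: CriticConfig, w: LossWeights, cfg: TrainConfig,
        out_dir: str | Path) -> dict:
    """Train ``cfg.n_runs`` seeded runs and evaluate each on the test split.

    Writes per-run checkpoints, a loss CSV, a JSON metrics report and a
    resolved-config snapshot into ``out_dir``; returns the same artifacts
    in memory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_cfg = apply_ablations(gen_cfg, cfg)

    train_x, train_y = load_split_arrays(manifest, "train",
                                         gen_cfg.input_normalization)
    test_records = manifest.subset("test")
    if test_records.empty:
        raise ConfigurationError("manifest has no test split")

    reports: list[MetricsReport] = []
    traces = []
    for run in range(cfg.n_runs):
        run_seed = cfg.seed + run
        gen, critic, trace = _train_one_run(
            run_seed, train_x, train_y, gen_cfg, critic_cfg, w, cfg)
        traces.append(trace)

        preds, gts = [], []
        for _, row in test_records.iterrows():
            img = read_scintigram(row["image_path"])
            gts.append(read_mask(row["mask_path"], pair=img))
            preds.append(predict_mask(gen, img, cfg.threshold))
        reports.append(evaluate(preds, gts))
        save_checkpoint(out_dir / f"generator_run{run}.npz", gen)

        with open(out_dir / f"loss_run{run}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "gen_loss", "disc_loss", "seg_loss"])
            writer.writerows(trace)

    summary = summarize_runs(reports)
    write_report(out_dir / "metrics.json", summary)
    resolved = {
        "train": dataclasses.asdict(cfg),
        "generator": dataclasses.asdict(gen_cfg),
        "critic": dataclasses.asdict(critic_cfg),
        "loss": dataclasses.asdict(w),
    }
    (out_dir / "config.json").write_text(json.dumps(resolved, indent=2))
    return {"reports": reports, "summary": summary, "traces": traces,
            "out_dir": out_dir}
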