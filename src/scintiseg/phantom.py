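"""Synthetic bone-scintigram phantoms.

Real planar bone scans are Poisson-noisy count images in which the spine is
a bright vertical band, metastatic lesions are compact high-uptake ellipses
spanning a wide range of sizes (sometimes clustered), and benign hot spots
(arthritis, fractures, tracer pooling) mimic the lesion intensity range.
The phantom reproduces exactly that statistical structure: a rate map
(uniform background + spine band + lesion ellipses + non-lesion confounder
blobs) and an independent Poisson draw per pixel. The mask marks the union
of the lesion ellipse supports and nothing else — confounders are
deliberately left outside the mask so that a segmenter cannot succeed on
intensity alone.

Each synthetic patient yields an anterior and a posterior view: the
posterior rate map is the horizontal mirror of the anterior with
independently redrawn noise, emulating the two acquisitions of a real exam.
Everything is reproducible: views of patient ``i`` are generated from
``seed + i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (MANIFEST_COLUMNS, DatasetManifest, LesionMask,
                      Scintigram, write_mask, write_scintigram)
from .errors import ConfigurationError, GenerationError

__all__ = ["PhantomConfig", "Ellipse", "PhantomFields",
           "generate_phantom_fields", "generate_phantom_pair", "generate_dataset"]

_MAX_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in (row, column) pixel coordinates."""
    cy: float
    cx: float
    ry: float
    rx: float

    def support(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (((yy - self.cy) / self.ry) ** 2
                + ((xx - self.cx) / self.rx) ** 2) <= 1.0


@dataclass
class PhantomConfig:
    """Generation parameters; rates are Poisson means in counts per pixel."""

    image_size: int = 64
    n_patients: int = 16
    lesions_per_image: tuple[int, int] = (1, 3)
    small_radius_px: tuple[float, float] = (1.5, 3.0)
    large_radius_px: tuple[float, float] = (4.0, 8.0)
    small_lesion_prob: float = 0.5
    background_rate: float = 20.0
    spine_rate: float = 60.0
    lesion_rate: float = 120.0
    confounder_rate: float = 120.0
    n_confounders: tuple[int, int] = (0, 2)
    cluster_prob: float = 0.2
    seed: int = 42

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if not (self.lesion_rate > self.spine_rate > self.background_rate > 0):
            raise ConfigurationError(
                "rates must satisfy lesion_rate > spine_rate > background_rate > 0")
        for name in ("small_radius_px", "large_radius_px"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"invalid radius range {name}={lo, hi}")
        if not 0.0 <= self.small_lesion_prob <= 1.0:
            raise ConfigurationError("small_lesion_prob must be in [0,1]")
        if not 0.0 <= self.cluster_prob <= 1.0:
            raise ConfigurationError("cluster_prob must be in [0,1]")

    @property
    def cluster_diameter(self) -> float:
        """Max center-to-center spread of a lesion cluster, in pixels."""
        return 2.0 * self.large_radius_px[1]


@dataclass
class PhantomFields:
    """Noise-free generation record for one anterior view."""
    rate_map: np.ndarray
    lesions: list[Ellipse] = field(default_factory=list)
    confounders: list[Ellipse] = field(default_factory=list)
    clustered: bool = False


def _sample_radii(cfg: PhantomConfig, rng: np.random.Generator) -> tuple[float, float]:
    lo, hi = (cfg.small_radius_px if rng.random() < cfg.small_lesion_prob
              else cfg.large_radius_px)
    a = rng.uniform(lo, hi)
    b = a * rng.uniform(0.5, 1.0)  # eccentricity: minor/major in [0.5, 1]
    return (a, b) if rng.random() < 0.5 else (b, a)


def _place_center(cfg: PhantomConfig, rng: np.random.Generator,
                  ry: float, rx: float,
                  cluster_center: tuple[float, float] | None) -> tuple[float, float]:
    n = cfg.image_size
    ylo, yhi = ry, n - 1 - ry
    xlo, xhi = rx, n - 1 - rx
    if ylo > yhi or xlo > xhi:
        raise GenerationError(
            f"lesion radii ({ry:.1f},{rx:.1f}) do not fit in a {n}x{n} frame")
    for _ in range(_MAX_PLACEMENT_RETRIES):
        if cluster_center is None:
            cy = rng.uniform(ylo, yhi)
            cx = rng.uniform(xlo, xhi)
            return cy, cx
        sigma = cfg.cluster_diameter / 4.0
        cy = cluster_center[0] + rng.normal(0.0, sigma)
        cx = cluster_center[1] + rng.normal(0.0, sigma)
        dist = math.hypot(cy - cluster_center[0], cx - cluster_center[1])
        if dist <= cfg.cluster_diameter / 2.0 and ylo <= cy <= yhi and xlo <= cx <= xhi:
            return cy, cx
    raise GenerationError("could not place a lesion after bounded retries")


def generate_phantom_fields(cfg: PhantomConfig, patient_index: int) -> PhantomFields:
    """Build the anterior rate map and the logged lesion/confounder geometry."""
    rng = np.random.default_rng(cfg.seed + patient_index)
    n = cfg.image_size
    rate = np.full((n, n), cfg.background_rate, dtype=np.float64)

    # spine: bright vertical band through the image center
    band = max(2, n // 8)
    c0 = n // 2 - band // 2
    rate[:, c0:c0 + band] += cfg.spine_rate

    n_lesions = int(rng.integers(cfg.lesions_per_image[0],
                                 cfg.lesions_per_image[1] + 1))
    clustered = n_lesions >= 2 and rng.random() < cfg.cluster_prob
    cluster_center = None
    if clustered:
        margin = cfg.large_radius_px[1]
        cluster_center = (rng.uniform(margin, n - 1 - margin),
                          rng.uniform(margin, n - 1 - margin))

    lesions: list[Ellipse] = []
    lesion_mask = np.zeros((n, n), dtype=bool)
    for _ in range(n_lesions):
        ry, rx = _sample_radii(cfg, rng)
        cy, cx = _place_center(cfg, rng, ry, rx, cluster_center)
        e = Ellipse(cy, cx, ry, rx)
        lesions.append(e)
        lesion_mask |= e.support((n, n))
    rate[lesion_mask] += cfg.lesion_rate

    # Benign confounders share the lesion intensity range but sit at
    # characteristic peripheral sites (shoulder joints, injection sites,
    # tracer pooling near the frame edge) — the positional cue a segmenter
    # must learn, since intensity alone cannot separate them from lesions.
    n_conf = int(rng.integers(cfg.n_confounders[0], cfg.n_confounders[1] + 1))
    confounders: list[Ellipse] = []
    conf_mask = np.zeros((n, n), dtype=bool)
    for _ in range(n_conf):
        for _ in range(_MAX_PLACEMENT_RETRIES):
            ry, rx = _sample_radii(cfg, rng)
            try:
                cy, cx = _place_center(cfg, rng, ry, rx, None)
            except GenerationError:
                break
            border_dist = min(cy, cx, n - 1 - cy, n - 1 - cx)
            if border_dist > max(ry, rx) + 2.0:  # not peripheral: resample
                continue
            e = Ellipse(cy, cx, ry, rx)
            sup = e.support((n, n))
            if not (sup & lesion_mask).any():  # confounders stay outside the mask
                confounders.append(e)
                conf_mask |= sup
                break
    rate[conf_mask & ~lesion_mask] += cfg.confounder_rate

    return PhantomFields(rate, lesions, confounders, clustered)


def generate_phantom_pair(
    cfg: PhantomConfig, patient_index: int
) -> tuple[Scintigram, Scintigram, LesionMask, LesionMask]:
    """Anterior/posterior scintigrams plus masks for one synthetic patient.

    The posterior view mirrors the anterior rate map left-right and draws
    fresh Poisson noise. Deterministic given (cfg.seed, patient_index).
    """
    fields = generate_phantom_fields(cfg, patient_index)
    # a second, offset stream for the noise keeps geometry and noise draws
    # independent of each other while staying reproducible
    noise_rng = np.random.default_rng((cfg.seed + patient_index, 1))
    mask_ant = _lesion_union(fields, cfg.image_size)
    ant = _draw(noise_rng, fields.rate_map)
    post = _draw(noise_rng, fields.rate_map[:, ::-1])
    return (ant, post, LesionMask(mask_ant.astype(np.uint8)),
            LesionMask(mask_ant[:, ::-1].astype(np.uint8)))


def _lesion_union(fields: PhantomFields, n: int) -> np.ndarray:
    out = np.zeros((n, n), dtype=bool)
    for e in fields.lesions:
        out |= e.support((n, n))
    return out


def _draw(rng: np.random.Generator, rate: np.ndarray) -> Scintigram:
    counts = rng.poisson(rate)
    return Scintigram(np.clip(counts, 0, np.iinfo(np.uint16).max).astype(np.uint16))


def generate_dataset(cfg: PhantomConfig, out_dir: str | Path) -> DatasetManifest:
    """Write 2 * n_patients image/mask pairs plus a CSV manifest.

    Every synthetic patient contributes exactly one anterior and one
    posterior record (a real cohort may screen out some views; the phantom
    always emits both).
    """
    out_dir = Path(out_dir)
    images = out_dir / "images"
    masks = out_dir / "masks"
    images.mkdir(parents=True, exist_ok=True)
    masks.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i:04d}"
        ant, post, m_ant, m_post = generate_phantom_pair(cfg, i)
        for view, img, msk in (("anterior", ant, m_ant), ("posterior", post, m_post)):
            tag = "ant" if view == "anterior" else "post"
            img_path = images / f"{pid}_{tag}.tif"
            msk_path = masks / f"{pid}_{tag}_mask.png"
            write_scintigram(img_path, img)
            write_mask(msk_path, msk)
            rows.append((pid, view, str(img_path), str(msk_path), "unassigned"))
    manifest = DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
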