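"""Synthetic dual-channel fluorescence image generators with ground truth.

Two schemes emulate the classes of images used to validate colocalization
methods:

* **Pixel objects** — 160x160 images carrying single-pixel objects at a
  chosen area density per channel (5-30%), integer intensities uniform in
  [30, 155].  A chosen fraction of the green objects is deliberately
  colocalized: those pixels share position *and* intensity across channels.
  Uniform integer noise in [10, 30] is added to every pixel of both
  channels, so images must be background-subtracted (level 30) before
  analysis to restore an exact-zero background.

* **Circle objects** — 256x256 images of digital disks of exactly 220
  pixels, per-object integer intensities uniform in [40, 160].  Twenty disks
  are placed at common positions in both channels (deliberate
  colocalization) and 15 further disks per channel at independent positions;
  incidental disk overlap adds to the colocalized area, bringing the
  expected colocalized fraction to about 7% of the image.  Gaussian noise
  (mean 10, sd 15) is added to each whole image and negatives clipped to 0.

Ground truth is captured before noise: for pixel objects it is the set of
deliberately colocalized pixels (coincidental placements of independent
objects are excluded); for circle objects it is every pixel non-zero in both
pre-noise channels (deliberate plus incidental overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .algorithm import AlgorithmConfig, evaluate_detection, run_colocalization
from .coefficients import ImagePair, UndefinedCoefficientError, pearson_r
from .costes import costes_thresholds
from .kinetics import subtract_background

__all__ = [
    "SimConfigA",
    "SimConfigB",
    "SimulationTruth",
    "simulate_pixel_objects",
    "simulate_circle_objects",
    "disk_offsets",
    "benchmark_grid",
]


@dataclass(frozen=True)
class SimConfigA:
    """Pixel-sized-object scheme (160x160, densities 5-30%)."""

    image_side: int = 160
    intensity_range: tuple[int, int] = (30, 155)
    density_green: float = 0.10
    density_red: float = 0.10
    coloc_fraction: float = 0.5
    noise_range: tuple[int, int] = (10, 30)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("density_green", "density_red"):
            d = getattr(self, name)
            if not 0.0 < d < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {d}")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimConfigB:
    """Circle-object scheme (256x256, 220-pixel disks)."""

    image_side: int = 256
    object_area: int = 220
    intensity_range: tuple[int, int] = (40, 160)
    n_coloc_objects: int = 20
    n_extra_per_channel: int = 15
    noise_mean: float = 10.0
    noise_sd: float = 15.0
    shared_intensity: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.object_area < 1:
            raise ValueError("object_area must be >= 1")
        if self.n_coloc_objects < 0 or self.n_extra_per_channel < 0:
            raise ValueError("object counts must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth accompanying a synthetic pair.

    ``truth_mask`` marks the colocalized pixels as defined pre-noise;
    per-channel object locations and intensities, and the pre-noise images,
    are retained for diagnostics.
    """

    truth_mask: np.ndarray
    green_objects: np.ndarray  # (n, 2) pixel coordinates or disk centers
    red_objects: np.ndarray
    green_intensities: np.ndarray
    red_intensities: np.ndarray
    prenoise_s1: np.ndarray = field(repr=False)
    prenoise_s2: np.ndarray = field(repr=False)
    config: object = None


def simulate_pixel_objects(
    config: SimConfigA = SimConfigA(),
) -> tuple[ImagePair, SimulationTruth]:
    """Generate a pixel-object pair and its deliberate-colocalization truth.

    Deliberately colocalized pixels carry bitwise-identical pre-noise
    intensities in both channels; independent green and red objects that
    happen to land on the same pixel are *not* part of the truth mask.
    """
    rng = np.random.default_rng(config.rng_seed)
    side = config.image_side
    n_pixels = side * side
    lo, hi = config.intensity_range
    nlo, nhi = config.noise_range

    n_green = round(config.density_green * n_pixels)
    n_red = round(config.density_red * n_pixels)
    n_coloc = round(config.coloc_fraction * n_green)
    if n_green > n_pixels or n_red > n_pixels:
        raise ValueError("requested density exceeds the image area")
    if n_coloc > n_red:
        raise ValueError(
            "colocalized green objects exceed the red channel's object count"
        )

    green_pos = rng.choice(n_pixels, size=n_green, replace=False)
    coloc_pos = rng.choice(green_pos, size=n_coloc, replace=False)
    non_coloc_candidates = np.setdiff1d(np.arange(n_pixels), coloc_pos)
    red_extra = rng.choice(
        non_coloc_candidates, size=n_red - n_coloc, replace=False
    )
    red_pos = np.concatenate([coloc_pos, red_extra])

    s1 = np.zeros(n_pixels)
    s2 = np.zeros(n_pixels)
    green_int = rng.integers(lo, hi + 1, size=n_green)
    s1[green_pos] = green_int
    # colocalized pixels copy the green intensity; independent red objects
    # draw their own
    red_int = np.empty(n_red)
    red_int[:n_coloc] = s1[coloc_pos]
    red_int[n_coloc:] = rng.integers(lo, hi + 1, size=n_red - n_coloc)
    s2[red_pos] = red_int

    truth = np.zeros(n_pixels, dtype=bool)
    truth[coloc_pos] = True

    prenoise_s1 = s1.reshape(side, side).copy()
    prenoise_s2 = s2.reshape(side, side).copy()
    s1 += rng.integers(nlo, nhi + 1, size=n_pixels)
    s2 += rng.integers(nlo, nhi + 1, size=n_pixels)

    pair = ImagePair(s1.reshape(side, side), s2.reshape(side, side))
    truth_rec = SimulationTruth(
        truth_mask=truth.reshape(side, side),
        green_objects=np.column_stack(np.unravel_index(green_pos, (side, side))),
        red_objects=np.column_stack(np.unravel_index(red_pos, (side, side))),
        green_intensities=green_int.astype(float),
        red_intensities=red_int.astype(float),
        prenoise_s1=prenoise_s1,
        prenoise_s2=prenoise_s2,
        config=config,
    )
    return pair, truth_rec


def disk_offsets(area: int) -> np.ndarray:
    """Offsets of a digital disk of exactly ``area`` pixels around (0, 0).

    Candidate pixels are ranked by distance from the center; ties at the
    boundary radius are broken deterministically (by row, then column), so
    the disk shape is fixed for a given area.
    """
    if area < 1:
        raise ValueError("area must be >= 1")
    r = int(np.ceil(np.sqrt(area / np.pi))) + 2
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy**2 + dx**2
    order = np.lexsort((dx.ravel(), dy.ravel(), d2.ravel()))
    sel = order[:area]
    return np.column_stack([dy.ravel()[sel], dx.ravel()[sel]])


def _paint_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    intensities: np.ndarray,
    offsets: np.ndarray,
) -> np.ndarray:
    """Render disks on a zero canvas; overlaps take the maximum intensity."""
    img = np.zeros(shape)
    for (cy, cx), val in zip(centers, intensities):
        ys = cy + offsets[:, 0]
        xs = cx + offsets[:, 1]
        np.maximum.at(img, (ys, xs), val)
    return img


def simulate_circle_objects(
    config: SimConfigB = SimConfigB(),
) -> tuple[ImagePair, SimulationTruth]:
    """Generate a circle-object pair with deliberate + incidental truth.

    Disk centers are drawn uniformly within margins that keep the whole disk
    inside the frame.  Colocalized disks share a position in both channels;
    their intensities are drawn independently per channel unless
    ``shared_intensity`` is set.
    """
    rng = np.random.default_rng(config.rng_seed)
    side = config.image_side
    offsets = disk_offsets(config.object_area)
    margin_lo = int(-offsets.min())
    margin_hi = int(offsets.max())
    lo_c, hi_c = margin_lo, side - margin_hi  # valid center range [lo_c, hi_c)
    if hi_c <= lo_c:
        raise ValueError(
            f"image side {side} too small for {config.object_area}-pixel disks"
        )
    lo, hi = config.intensity_range

    def draw_centers(n: int) -> np.ndarray:
        return rng.integers(lo_c, hi_c, size=(n, 2))

    coloc_centers = draw_centers(config.n_coloc_objects)
    extra_green = draw_centers(config.n_extra_per_channel)
    extra_red = draw_centers(config.n_extra_per_channel)

    def draw_int(n: int) -> np.ndarray:
        return rng.integers(lo, hi + 1, size=n).astype(float)

    coloc_int_green = draw_int(config.n_coloc_objects)
    coloc_int_red = (
        coloc_int_green if config.shared_intensity
        else draw_int(config.n_coloc_objects)
    )
    green_centers = np.vstack([coloc_centers, extra_green])
    red_centers = np.vstack([coloc_centers, extra_red])
    green_int = np.concatenate(
        [coloc_int_green, draw_int(config.n_extra_per_channel)]
    )
    red_int = np.concatenate(
        [coloc_int_red, draw_int(config.n_extra_per_channel)]
    )

    shape = (side, side)
    pre1 = _paint_disks(shape, green_centers, green_int, offsets)
    pre2 = _paint_disks(shape, red_centers, red_int, offsets)
    truth = (pre1 > 0) & (pre2 > 0)

    s1 = np.clip(pre1 + rng.normal(config.noise_mean, config.noise_sd, shape), 0, None)
    s2 = np.clip(pre2 + rng.normal(config.noise_mean, config.noise_sd, shape), 0, None)

    pair = ImagePair(s1, s2)
    truth_rec = SimulationTruth(
        truth_mask=truth,
        green_objects=green_centers,
        red_objects=red_centers,
        green_intensities=green_int,
        red_intensities=red_int,
        prenoise_s1=pre1,
        prenoise_s2=pre2,
        config=config,
    )
    return pair, truth_rec


def benchmark_grid(
    densities: Sequence[float],
    coloc_fractions: Sequence[float],
    replicates: int = 5,
    rng_seed: int = 0,
    algorithm_config: AlgorithmConfig = AlgorithmConfig(),
    image_side: int = 160,
) -> pd.DataFrame:
    """Benchmark the classification algorithm and the Costes baseline.

    For every (density, colocalization fraction, replicate) cell a
    pixel-object pair is generated with equal green and red densities,
    background-subtracted at the noise ceiling, and analysed with both
    methods against the ground truth.  Fractions in the returned table are
    percentages of image area; ``overall_r_x100`` is the whole-image Pearson
    coefficient scaled by 100 for plotting alongside them.
    """
    seed_seq = np.random.SeedSequence(rng_seed)
    rows = []
    for density in densities:
        for cf in coloc_fractions:
            for rep in range(replicates):
                child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                sim_cfg = SimConfigA(
                    image_side=image_side,
                    density_green=density,
                    density_red=density,
                    coloc_fraction=cf,
                    rng_seed=child_seed,
                )
                noisy_pair, truth = simulate_pixel_objects(sim_cfg)
                bg = sim_cfg.noise_range[1]
                pair = ImagePair(
                    subtract_background(noisy_pair.s1, bg),
                    subtract_background(noisy_pair.s2, bg),
                )
                try:
                    overall_r = pearson_r(pair)
                except UndefinedCoefficientError:
                    overall_r = float("nan")

                result = run_colocalization(pair, algorithm_config)
                main = evaluate_detection(result.coloc_mask, truth.truth_mask)

                costes = costes_thresholds(pair)
                if costes.failed:
                    costes_metrics = None
                else:
                    costes_metrics = evaluate_detection(
                        costes.coloc_mask, truth.truth_mask
                    )
                rows.append(
                    {
                        "density": density,
                        "coloc_fraction": cf,
                        "replicate": rep,
                        "seed": child_seed,
                        "true_pct": 100 * main.true_fraction,
                        "detected_pct": 100 * main.detected_fraction,
                        "precision": main.precision,
                        "recall": main.recall,
                        "jaccard": main.jaccard,
                        "selected_round": result.selected_round,
                        "n_rounds": len(result.rounds),
                        "overall_r": overall_r,
                        "overall_r_x100": 100 * overall_r,
                        "costes_failed": costes.failed,
                        "costes_detected_pct": (
                            float("nan") if costes_metrics is None
                            else 100 * costes_metrics.detected_fraction
                        ),
                        "costes_precision": (
                            float("nan") if costes_metrics is None
                            else costes_metrics.precision
                        ),
                        "costes_recall": (
                            float("nan") if costes_metrics is None
                            else costes_metrics.recall
                        ),
                    }
                )
    return pd.DataFrame(rows)
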