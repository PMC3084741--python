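"""File I/O and the run orchestration behind the command line.

Masks are written as 8-bit TIFF (0/255), coefficient maps as 32-bit float
TIFF, tabular output as headered CSV, and run summaries as JSON carrying the
full configuration and seed so every run is reproducible from its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .algorithm import AlgorithmConfig, ColocResult, run_colocalization
from .coefficients import (
    ImagePair,
    UndefinedCoefficientError,
    contribution_maps,
    manders_overlap,
    overlap_k,
    pearson_r,
)
from .costes import costes_thresholds
from .kinetics import subtract_background
from .significance import ScrambleConfig, significance_test

__all__ = ["RunConfig", "read_image", "read_image_pair", "write_mask",
           "write_map", "run_coloc"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one colocalization run."""

    channel1: str
    channel2: str
    background1: float = 0.0
    background2: float = 0.0
    method: str = "main"  # "main" | "costes"
    algorithm: AlgorithmConfig = AlgorithmConfig()
    scramble: ScrambleConfig | None = None
    outdir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("main", "costes"):
            raise ValueError("method must be 'main' or 'costes'")


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel image as float64, preserving integer values."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, "
                         f"got shape {arr.shape}")
    return arr.astype(np.float64)


def read_image_pair(
    path1: str | Path,
    path2: str | Path,
    background_levels: tuple[float, float] = (0.0, 0.0),
) -> ImagePair:
    """Load two registered single-channel images into an ImagePair.

    Both images are converted to float, background-subtracted by the given
    per-channel levels and clipped at zero on load.
    """
    s1 = read_image(path1)
    s2 = read_image(path2)
    if s1.shape != s2.shape:
        raise ValueError(
            f"image shapes differ: {path1} is {s1.shape}, "
            f"{path2} is {s2.shape}"
        )
    return ImagePair(
        subtract_background(s1, background_levels[0]),
        subtract_background(s2, background_levels[1]),
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit TIFF with values 0/255."""
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_map(path: str | Path, values: np.ndarray) -> None:
    """Write a coefficient map as a 32-bit float single-channel TIFF."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _rounds_frame(result: ColocResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "round": [rec.round_index for rec in result.rounds],
            "n_newly_coloc": [int(rec.newly_coloc.sum()) for rec in result.rounds],
            "n_newly_anticoloc": [
                int(rec.newly_anticoloc.sum()) for rec in result.rounds
            ],
            "n_cumulative_coloc": [
                int(rec.cumulative_coloc.sum()) for rec in result.rounds
            ],
            "R_in_coloc_mask": [rec.R_in_coloc_mask for rec in result.rounds],
            "background_fraction": [
                rec.background_fraction_this_round for rec in result.rounds
            ],
        }
    )


def run_coloc(config: RunConfig) -> dict:
    """Execute a full colocalization run and write all artifacts.

    Writes into ``config.outdir``: the colocalization mask
    (``coloc_mask.tif``), the r/R/m1/m2 contribution maps, a JSON summary
    with global and in-mask coefficients, the per-round CSV (main method),
    and the significance verdict when a scramble configuration is present.
    Returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = read_image_pair(
        config.channel1, config.channel2,
        (config.background1, config.background2),
    )

    summary: dict = {"config": _config_dict(config), "method": config.method}
    try:
        summary["global"] = {
            "r": pearson_r(pair),
            "R": manders_overlap(pair),
        }
        k1, k2 = overlap_k(pair)
        summary["global"]["k1"] = k1
        summary["global"]["k2"] = k2
    except UndefinedCoefficientError as exc:
        summary["global"] = {"error": str(exc)}

    mask = None
    if config.method == "main":
        result = run_colocalization(pair, config.algorithm)
        mask = result.coloc_mask
        summary["coloc"] = {
            "no_colocalization": result.no_colocalization,
            "selected_round": result.selected_round,
            "n_rounds": len(result.rounds),
            "stop_reason": result.stop_reason,
            "r": result.r,
            "R": result.R,
            "m1": result.m1,
            "m2": result.m2,
            "mask_pixels": int(mask.sum()),
        }
        _rounds_frame(result).to_csv(outdir / "rounds.csv", index=False)
        write_mask(outdir / "anticoloc_mask.tif", result.anticoloc_mask)
    else:
        costes = costes_thresholds(pair)
        summary["coloc"] = {
            "failed": costes.failed,
            "reason": costes.reason,
            "t1": costes.t1,
            "t2": costes.t2,
            "slope": costes.slope,
            "intercept": costes.intercept,
        }
        if not costes.failed:
            mask = costes.coloc_mask
            summary["coloc"]["mask_pixels"] = int(mask.sum())

    if mask is not None:
        write_mask(outdir / "coloc_mask.tif", mask)
        try:
            maps = contribution_maps(pair, coloc_mask=mask)
            write_map(outdir / "r_map.tif", maps.r_map)
            write_map(outdir / "R_map.tif", maps.R_map)
            write_map(outdir / "m1_map.tif", maps.m1_map)
            write_map(outdir / "m2_map.tif", maps.m2_map)
        except UndefinedCoefficientError as exc:
            summary["maps_error"] = str(exc)

    if config.scramble is not None:
        sig = significance_test(pair, config.scramble)
        summary["significance"] = {
            "statistic": sig.statistic,
            "observed": sig.observed,
            "scrambled_mean": sig.sample_mean,
            "scrambled_sd": sig.sample_sd,
            "P": sig.P,
            "significant": sig.significant,
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary
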