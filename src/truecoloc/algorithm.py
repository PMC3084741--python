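"""Iterative r-by-R pixel classification for automatic true colocalization.

The method classifies pixels round by round from a *mixed map*: the per-pixel
product of the Pearson-r contribution and the Manders-overlap contribution,
both computed over the population of still-unclassified pixels.  Pixels whose
mixed value reaches 80% of the round's maximum are marked colocalizing;
pixels at or below 80% of a negative minimum are marked anti-colocalizing.
Background pixels (zero intensity in either channel) have a mixed value of
exactly zero, so they are swept in only when the positive signal is
exhausted; the first round in which more than 1% of the newly classified
pixels are background terminates the run and is rolled back.

A final mask is then selected among the per-round cumulative colocalizing
masks: the overlap coefficient R restricted to each mask is plotted against
the round index (minimum subtracted), and the round at which the cumulative
area under that curve reaches 86% of its total is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coefficients import (
    ImagePair,
    UndefinedCoefficientError,
    manders_m,
    manders_overlap,
    overlap_contribution_map,
    pearson_r,
    r_contribution_map,
)

__all__ = [
    "AlgorithmConfig",
    "RoundRecord",
    "ColocResult",
    "DetectionMetrics",
    "NoSignalError",
    "mixed_map",
    "classify_round",
    "run_classification",
    "select_mask",
    "run_colocalization",
    "evaluate_detection",
]


class NoSignalError(ValueError):
    """One or both channels carry no signal at all."""


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the classification.

    threshold_fraction
        Fraction of the mixed map's extremum a pixel must reach to be
        classified in a round (default 0.8).
    area_fraction
        Fraction of the area under the (R - Rmin) vs round curve at which the
        final mask is selected (default 0.86).
    background_fraction_limit
        A round classifying more than this fraction of background pixels
        (zero intensity in either channel) stops the run (default 0.01).
    max_rounds
        Safety bound on the number of rounds; the stop rules terminate far
        earlier on any realistic image.
    """

    threshold_fraction: float = 0.8
    area_fraction: float = 0.86
    background_fraction_limit: float = 0.01
    max_rounds: int = 10_000

    def __post_init__(self) -> None:
        for name in ("threshold_fraction", "area_fraction",
                     "background_fraction_limit"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class RoundRecord:
    """State after one classification round (cumulative masks are copies)."""

    round_index: int
    newly_coloc: np.ndarray
    newly_anticoloc: np.ndarray
    cumulative_coloc: np.ndarray
    cumulative_anticoloc: np.ndarray
    remaining: np.ndarray
    R_in_coloc_mask: float  # NaN while the cumulative mask is empty
    background_fraction_this_round: float


@dataclass(frozen=True)
class ColocResult:
    """Outcome of a full classification run plus mask selection."""

    rounds: tuple[RoundRecord, ...]
    selected_round: int  # 0 when no colocalization was detected
    coloc_mask: np.ndarray
    anticoloc_mask: np.ndarray
    r: float
    R: float
    m1: float
    m2: float
    area_rounds: np.ndarray
    area_curve: np.ndarray  # R - Rmin per round in area_rounds
    area_cumulative_fraction: np.ndarray
    no_colocalization: bool
    stop_reason: str = field(default="", compare=False)


def _background(pair: ImagePair) -> np.ndarray:
    return (pair.s1 == 0) | (pair.s2 == 0)


def mixed_map(pair: ImagePair, remaining: np.ndarray) -> np.ndarray:
    """Product of the r and R contribution maps over the remaining pixels.

    Means and denominators are recomputed over the remaining population, so
    the map reflects the statistics of the pixels still in play.  Pixels
    outside ``remaining`` carry 0 and must be ignored by callers.

    Raises
    ------
    UndefinedCoefficientError
        If the remaining population is degenerate (fewer than two pixels,
        a constant channel, or an all-zero channel) — the caller treats this
        as a termination condition.
    """
    r_map = r_contribution_map(pair, remaining)
    R_map = overlap_contribution_map(pair, remaining)
    return r_map * R_map


def classify_round(
    pair: ImagePair,
    remaining: np.ndarray,
    config: AlgorithmConfig = AlgorithmConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Classify one round of pixels from the current mixed map.

    Returns ``(newly_coloc, newly_anticoloc, new_remaining,
    background_fraction)``.  Thresholds are inclusive so the extremal pixel
    is always classified and the remaining set strictly shrinks whenever any
    candidate exists.  When the maximum mixed value is exactly 0 the
    colocalizing threshold is 0 and every zero-mixed pixel — in particular
    all background pixels — is swept in, which is what ultimately triggers
    the background stop rule; a strictly negative maximum yields no
    colocalizing candidates.
    """
    remaining = np.asarray(remaining, dtype=bool)
    if not remaining.any():
        raise ValueError("remaining population is empty")
    mm = mixed_map(pair, remaining)
    vals = mm[remaining]
    vmax = vals.max()
    vmin = vals.min()

    newly_coloc = np.zeros(pair.shape, dtype=bool)
    if vmax >= 0.0:
        newly_coloc = remaining & (mm >= config.threshold_fraction * vmax)
        if vmax == 0.0:
            # threshold is 0; restrict to the exactly-zero pixels so that a
            # negative-valued pixel is never marked colocalizing
            newly_coloc = remaining & (mm == 0.0)
    newly_anticoloc = np.zeros(pair.shape, dtype=bool)
    if vmin < 0.0:
        newly_anticoloc = remaining & (mm <= config.threshold_fraction * vmin)
        newly_anticoloc &= ~newly_coloc

    new_remaining = remaining & ~newly_coloc & ~newly_anticoloc
    classified = newly_coloc | newly_anticoloc
    n_classified = int(classified.sum())
    if n_classified == 0:
        background_fraction = 0.0
    else:
        background_fraction = float(
            (classified & _background(pair)).sum() / n_classified
        )
    return newly_coloc, newly_anticoloc, new_remaining, background_fraction


def run_classification(
    pair: ImagePair,
    config: AlgorithmConfig = AlgorithmConfig(),
) -> tuple[list[RoundRecord], str]:
    """Iterate classification rounds until a stop rule fires.

    Returns the accepted rounds and a stop reason.  The round that violates
    the background limit is rolled back (not appended), so an image whose
    very first round is background-dominated yields an empty round list —
    the "no colocalization detected" case.

    Stop reasons: ``background_limit``, ``no_candidates``,
    ``degenerate_population``, ``exhausted``, ``max_rounds``.
    """
    if float(pair.s1.sum()) == 0.0 or float(pair.s2.sum()) == 0.0:
        raise NoSignalError("one or both channels are identically zero")

    rounds: list[RoundRecord] = []
    remaining = np.ones(pair.shape, dtype=bool)
    cum_coloc = np.zeros(pair.shape, dtype=bool)
    cum_anti = np.zeros(pair.shape, dtype=bool)

    for k in range(1, config.max_rounds + 1):
        if not remaining.any():
            return rounds, "exhausted"
        try:
            newly_c, newly_a, remaining_next, bg_frac = classify_round(
                pair, remaining, config
            )
        except UndefinedCoefficientError:
            return rounds, "degenerate_population"
        if not (newly_c.any() or newly_a.any()):
            return rounds, "no_candidates"
        if bg_frac > config.background_fraction_limit:
            # contaminated round: roll back its classifications
            return rounds, "background_limit"

        cum_coloc = cum_coloc | newly_c
        cum_anti = cum_anti | newly_a
        try:
            R_mask = (
                manders_overlap(pair, cum_coloc) if cum_coloc.any()
                else float("nan")
            )
        except UndefinedCoefficientError:
            R_mask = float("nan")
        rounds.append(
            RoundRecord(
                round_index=k,
                newly_coloc=newly_c,
                newly_anticoloc=newly_a,
                cumulative_coloc=cum_coloc.copy(),
                cumulative_anticoloc=cum_anti.copy(),
                remaining=remaining_next.copy(),
                R_in_coloc_mask=R_mask,
                background_fraction_this_round=bg_frac,
            )
        )
        remaining = remaining_next
    return rounds, "max_rounds"


def select_mask(
    rounds: list[RoundRecord],
    pair: ImagePair,
    config: AlgorithmConfig = AlgorithmConfig(),
    stop_reason: str = "",
) -> ColocResult:
    """Pick the final colocalizing mask by the area-under-the-R-curve rule.

    The curve y_k = R_k - min(R) over rounds with a defined in-mask R is
    integrated by the trapezoidal rule on the round axis; the selected round
    is the first at which the cumulative area reaches
    ``config.area_fraction`` of the total.  A flat curve (zero total area)
    selects the first round with a defined R.
    """
    defined = [rec for rec in rounds if np.isfinite(rec.R_in_coloc_mask)]
    shape = pair.shape
    if not defined:
        empty = np.zeros(shape, dtype=bool)
        anti = rounds[-1].cumulative_anticoloc if rounds else empty
        return ColocResult(
            rounds=tuple(rounds),
            selected_round=0,
            coloc_mask=empty,
            anticoloc_mask=anti,
            r=float("nan"),
            R=float("nan"),
            m1=0.0,
            m2=0.0,
            area_rounds=np.array([], dtype=int),
            area_curve=np.array([]),
            area_cumulative_fraction=np.array([]),
            no_colocalization=True,
            stop_reason=stop_reason,
        )

    x = np.array([rec.round_index for rec in defined], dtype=float)
    R_vals = np.array([rec.R_in_coloc_mask for rec in defined])
    y = R_vals - R_vals.min()
    if len(y) == 1:
        cum = np.array([0.0])
        total = 0.0
    else:
        seg = 0.5 * (y[1:] + y[:-1]) * np.diff(x)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = float(cum[-1])
    if total == 0.0:
        sel_idx = 0
        cum_frac = np.zeros_like(cum)
    else:
        cum_frac = cum / total
        sel_idx = int(np.argmax(cum_frac >= config.area_fraction))
    selected = defined[sel_idx]

    coloc = selected.cumulative_coloc
    try:
        r_sel = pearson_r(pair, coloc)
    except UndefinedCoefficientError:
        r_sel = float("nan")
    R_sel = float(selected.R_in_coloc_mask)
    m1, m2 = manders_m(pair, coloc)
    return ColocResult(
        rounds=tuple(rounds),
        selected_round=selected.round_index,
        coloc_mask=coloc,
        anticoloc_mask=selected.cumulative_anticoloc,
        r=r_sel,
        R=R_sel,
        m1=m1,
        m2=m2,
        area_rounds=x.astype(int),
        area_curve=y,
        area_cumulative_fraction=cum_frac,
        no_colocalization=False,
        stop_reason=stop_reason,
    )


def run_colocalization(
    pair: ImagePair,
    config: AlgorithmConfig = AlgorithmConfig(),
) -> ColocResult:
    """Full pipeline: iterate rounds, then select the final mask."""
    rounds, stop_reason = run_classification(pair, config)
    return select_mask(rounds, pair, config, stop_reason=stop_reason)


@dataclass(frozen=True)
class DetectionMetrics:
    """Set-overlap metrics of a predicted mask against a ground-truth mask.

    Conventions for empty masks: an empty prediction has precision 1 (no
    false positives); an empty truth has recall 1 (nothing missed); Jaccard
    of two empty masks is 1.
    """

    precision: float
    recall: float
    jaccard: float
    detected_fraction: float
    true_fraction: float


def evaluate_detection(
    predicted: np.ndarray, truth: np.ndarray
) -> DetectionMetrics:
    """Compare a predicted colocalization mask with the ground truth."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: {predicted.shape} vs {truth.shape}"
        )
    inter = float((predicted & truth).sum())
    union = float((predicted | truth).sum())
    n_pred = float(predicted.sum())
    n_true = float(truth.sum())
    precision = inter / n_pred if n_pred else 1.0
    recall = inter / n_true if n_true else 1.0
    jaccard = inter / union if union else 1.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        jaccard=jaccard,
        detected_fraction=float(predicted.mean()),
        true_fraction=float(truth.mean()),
    )
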