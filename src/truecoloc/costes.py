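"""Costes automatic-threshold colocalization, the comparison baseline.

The method fits the 2D scattergram of channel-2 vs channel-1 intensities by
orthogonal (total least squares) regression, S2 ~ a*S1 + b, then walks a
channel-1 threshold T1 down from the maximum intensity with T2 = a*T1 + b,
computing Pearson's r over the below-threshold population (S1 < T1 or
S2 < T2) at each step.  The walk stops at the first threshold pair for which
that r is no longer positive; pixels at or above both thresholds form the
colocalization mask.  The method presupposes a positive overall correlation
and reports failure otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import ImagePair, UndefinedCoefficientError, pearson_r

__all__ = ["CostesResult", "costes_thresholds", "costes_compare"]


@dataclass(frozen=True)
class CostesResult:
    slope: float
    intercept: float
    t1: float
    t2: float
    coloc_mask: np.ndarray | None
    failed: bool
    reason: str = ""
    converged: bool = True  # False when no threshold made the below-r <= 0


def _orthogonal_fit(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line through the scattergram (slope, intercept)."""
    x = s1.ravel()
    y = s2.ravel()
    mx, my = x.mean(), y.mean()
    cov = np.cov(np.vstack([x - mx, y - my]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]  # principal direction
    if v[0] == 0.0:
        raise UndefinedCoefficientError("vertical scattergram; slope undefined")
    slope = float(v[1] / v[0])
    return slope, float(my - slope * mx)


def _r_below(pair: ImagePair, below: np.ndarray) -> float | None:
    """Pearson's r over the below-threshold pixels, None while undefined."""
    try:
        return pearson_r(pair, below)
    except UndefinedCoefficientError:
        return None


def costes_thresholds(pair: ImagePair) -> CostesResult:
    """Run the automatic threshold search.

    The walk steps through the sorted distinct channel-1 intensities in
    descending order (scale-free; no 8-bit assumption).  Steps where the
    below-threshold r is still undefined (too few pixels, constant channel)
    are passed over.  If no threshold drives the below-threshold r to <= 0
    the walk ends with ``converged=False`` at the lowest threshold whose
    below-population r was defined — for a clean image that is the boundary
    between signal and background — and the mask covers every pixel at or
    above those thresholds.
    """
    try:
        overall_r = pearson_r(pair)
    except UndefinedCoefficientError as exc:
        return CostesResult(
            slope=float("nan"), intercept=float("nan"),
            t1=float("nan"), t2=float("nan"), coloc_mask=None,
            failed=True, reason=f"overall correlation undefined: {exc}",
        )
    if overall_r <= 0.0:
        return CostesResult(
            slope=float("nan"), intercept=float("nan"),
            t1=float("nan"), t2=float("nan"), coloc_mask=None,
            failed=True, reason="negative overall correlation",
        )
    slope, intercept = _orthogonal_fit(pair.s1, pair.s2)

    candidates = np.unique(pair.s1)[::-1]  # descending distinct intensities
    t1 = float(candidates[-1])
    t2 = slope * t1 + intercept
    converged = False
    for cand in candidates:
        cand_t2 = slope * cand + intercept
        below = (pair.s1 < cand) | (pair.s2 < cand_t2)
        r_b = _r_below(pair, below)
        if r_b is None:
            # below-population degenerate (too few pixels / constant
            # channel, e.g. pure background under identical images):
            # keep the last well-defined thresholds
            continue
        t1, t2 = float(cand), float(cand_t2)
        if r_b <= 0.0:
            converged = True
            break
    mask = (pair.s1 >= t1) & (pair.s2 >= t2)
    return CostesResult(
        slope=slope, intercept=intercept, t1=t1, t2=t2,
        coloc_mask=mask, failed=False, converged=converged,
    )


def costes_compare(pair: ImagePair, truth) -> dict:
    """Benchmark row: Costes mask vs ground truth (see ``benchmark_grid``).

    A failed run yields a flagged row with NaN metrics rather than an
    exception, so grid sweeps can proceed.
    """
    from .algorithm import evaluate_detection  # local import avoids a cycle

    result = costes_thresholds(pair)
    if result.failed:
        return {
            "costes_failed": True,
            "costes_reason": result.reason,
            "costes_detected_pct": float("nan"),
            "costes_precision": float("nan"),
            "costes_recall": float("nan"),
            "costes_jaccard": float("nan"),
        }
    metrics = evaluate_detection(result.coloc_mask, truth.truth_mask)
    return {
        "costes_failed": False,
        "costes_reason": "",
        "costes_detected_pct": 100 * metrics.detected_fraction,
        "costes_precision": metrics.precision,
        "costes_recall": metrics.recall,
        "costes_jaccard": metrics.jaccard,
    }
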