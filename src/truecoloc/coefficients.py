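"""Global colocalization coefficients and their per-pixel contribution maps.

The coefficients quantify the spatial coincidence of signal in a pair of
registered single-channel fluorescence images (channel 1, "green", intensities
``S1``; channel 2, "red", intensities ``S2``):

* Pearson's correlation coefficient ``r`` — mean-centred, variance-normalised
  covariance of the two channels, in [-1, 1].
* Manders overlap coefficient ``R`` — non-centred normalised inner product,
  in [0, 1]; insensitive to intensity scaling and positive-valued per pixel.
* ``m1`` / ``m2`` — fraction of each channel's total intensity residing in a
  set of colocalized pixels.
* ``k1`` / ``k2`` — asymmetric overlap coefficients with ``k1 * k2 == R**2``.

Every coefficient decomposes into per-pixel contributions: the pixel's term
in the numerator divided by the whole denominator of the coefficient.  The
contribution maps therefore sum exactly to the coefficient, which is what the
downstream classification algorithm exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImagePair",
    "ContributionMapSet",
    "UndefinedCoefficientError",
    "pearson_r",
    "manders_overlap",
    "manders_m",
    "overlap_k",
    "contribution_maps",
]


class UndefinedCoefficientError(ValueError):
    """A coefficient is mathematically undefined for the given pixels.

    Raised instead of silently returning NaN so that callers (in particular
    the iterative classification algorithm) can distinguish degenerate input
    from genuine zero colocalization.
    """


@dataclass(frozen=True)
class ImagePair:
    """Two registered nonnegative intensity grids of identical shape.

    Intensities are held as ``float64`` regardless of the source bit depth;
    integer image data is converted losslessly.  Channel 1 is conventionally
    the "green" channel and channel 2 the "red" channel.
    """

    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1, dtype=np.float64)
        s2 = np.asarray(self.s2, dtype=np.float64)
        if s1.shape != s2.shape:
            raise ValueError(
                f"channel shapes differ: {s1.shape} vs {s2.shape}"
            )
        if s1.ndim != 2:
            raise ValueError(f"expected 2D images, got {s1.ndim}D")
        for name, arr in (("s1", s1), ("s2", s2)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite intensities")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s2", s2)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s1.shape


@dataclass(frozen=True)
class ContributionMapSet:
    """Per-pixel contributions to r, R and (optionally) m1/m2.

    Each map has the shape of the source images and sums to its coefficient.
    ``r_map`` is signed; ``R_map`` is nonnegative everywhere; the m maps are
    zero outside the colocalization mask and are ``None`` when no mask was
    supplied.
    """

    r_map: np.ndarray
    R_map: np.ndarray
    m1_map: np.ndarray | None = None
    m2_map: np.ndarray | None = None
    coloc_mask: np.ndarray | None = field(default=None, repr=False)


def _region_mask(pair: ImagePair, region: np.ndarray | None) -> np.ndarray:
    if region is None:
        return np.ones(pair.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != pair.shape:
        raise ValueError(
            f"region shape {region.shape} does not match images {pair.shape}"
        )
    return region


def pearson_r(pair: ImagePair, region: np.ndarray | None = None) -> float:
    """Pearson's correlation coefficient over ``region`` (whole image if None).

    Means and denominators are taken over the region pixels only, so a
    region-restricted r is a genuine correlation within that population.

    Raises
    ------
    UndefinedCoefficientError
        If the region has fewer than two pixels or either channel is constant
        within it.
    """
    mask = _region_mask(pair, region)
    x = pair.s1[mask]
    y = pair.s2[mask]
    if x.size < 2:
        raise UndefinedCoefficientError(
            f"correlation needs >= 2 pixels, region has {x.size}"
        )
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.sum(dx * dx) * np.sum(dy * dy))
    if denom == 0.0:
        raise UndefinedCoefficientError(
            "zero variance in at least one channel within the region"
        )
    return float(np.sum(dx * dy) / denom)


def manders_overlap(pair: ImagePair, region: np.ndarray | None = None) -> float:
    """Manders overlap coefficient R over ``region`` (whole image if None).

    R = sum(S1*S2) / sqrt(sum(S1^2) * sum(S2^2)), all sums over the region.

    Raises
    ------
    UndefinedCoefficientError
        If either channel is identically zero within the region.
    """
    mask = _region_mask(pair, region)
    x = pair.s1[mask]
    y = pair.s2[mask]
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0.0:
        raise UndefinedCoefficientError(
            "all-zero channel within the region; overlap undefined"
        )
    return float(np.sum(x * y) / denom)


def manders_m(pair: ImagePair, coloc_mask: np.ndarray) -> tuple[float, float]:
    """Manders colocalization fractions (m1, m2) for a colocalization mask.

    m1 is the fraction of channel 1's total intensity that lies inside the
    mask; m2 analogously for channel 2.  Totals are over the whole image.
    """
    mask = _region_mask(pair, coloc_mask)
    tot1 = float(pair.s1.sum())
    tot2 = float(pair.s2.sum())
    if tot1 == 0.0 or tot2 == 0.0:
        raise UndefinedCoefficientError(
            "all-zero channel; colocalization fraction undefined"
        )
    m1 = float(pair.s1[mask].sum()) / tot1
    m2 = float(pair.s2[mask].sum()) / tot2
    return m1, m2


def overlap_k(
    pair: ImagePair, region: np.ndarray | None = None
) -> tuple[float, float]:
    """Asymmetric overlap coefficients (k1, k2); k1*k2 equals R**2.

    k1 = sum(S1*S2) / sum(S1^2), k2 = sum(S1*S2) / sum(S2^2).
    """
    mask = _region_mask(pair, region)
    x = pair.s1[mask]
    y = pair.s2[mask]
    ssq1 = float(np.sum(x * x))
    ssq2 = float(np.sum(y * y))
    if ssq1 == 0.0 or ssq2 == 0.0:
        raise UndefinedCoefficientError(
            "all-zero channel within the region; k coefficients undefined"
        )
    cross = float(np.sum(x * y))
    return cross / ssq1, cross / ssq2


def r_contribution_map(
    pair: ImagePair, region: np.ndarray | None = None
) -> np.ndarray:
    """Signed per-pixel contributions to Pearson's r within ``region``.

    Pixel i carries (S1_i - S1_mean)(S2_i - S2_mean) / denom where the means
    and denominator are those of r over the region; pixels outside the region
    carry 0.  The map sums to ``pearson_r(pair, region)``.
    """
    mask = _region_mask(pair, region)
    x = pair.s1[mask]
    y = pair.s2[mask]
    if x.size < 2:
        raise UndefinedCoefficientError(
            f"correlation needs >= 2 pixels, region has {x.size}"
        )
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.sum(dx * dx) * np.sum(dy * dy))
    if denom == 0.0:
        raise UndefinedCoefficientError(
            "zero variance in at least one channel within the region"
        )
    out = np.zeros(pair.shape, dtype=np.float64)
    out[mask] = dx * dy / denom
    return out


def overlap_contribution_map(
    pair: ImagePair, region: np.ndarray | None = None
) -> np.ndarray:
    """Nonnegative per-pixel contributions to the Manders overlap R.

    Pixel i carries S1_i * S2_i / denom with the denominator of R over the
    region; zero-intensity pixels contribute exactly 0.  Sums to
    ``manders_overlap(pair, region)``.
    """
    mask = _region_mask(pair, region)
    x = pair.s1[mask]
    y = pair.s2[mask]
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0.0:
        raise UndefinedCoefficientError(
            "all-zero channel within the region; overlap undefined"
        )
    out = np.zeros(pair.shape, dtype=np.float64)
    out[mask] = x * y / denom
    return out


def contribution_maps(
    pair: ImagePair,
    coloc_mask: np.ndarray | None = None,
    region: np.ndarray | None = None,
) -> ContributionMapSet:
    """Build the full set of coefficient contribution maps.

    The r and R maps are computed over ``region`` (whole image by default).
    The m1/m2 maps require a colocalization mask: inside the mask each pixel
    carries its intensity divided by the channel's whole-image total, so the
    map sums to m1 (resp. m2); outside the mask the maps are zero.
    """
    r_map = r_contribution_map(pair, region)
    R_map = overlap_contribution_map(pair, region)
    m1_map = m2_map = None
    if coloc_mask is not None:
        cmask = _region_mask(pair, coloc_mask)
        tot1 = float(pair.s1.sum())
        tot2 = float(pair.s2.sum())
        if tot1 == 0.0 or tot2 == 0.0:
            raise UndefinedCoefficientError(
                "all-zero channel; colocalization fraction undefined"
            )
        m1_map = np.where(cmask, pair.s1 / tot1, 0.0)
        m2_map = np.where(cmask, pair.s2 / tot2, 0.0)
    return ContributionMapSet(
        r_map=r_map,
        R_map=R_map,
        m1_map=m1_map,
        m2_map=m2_map,
        coloc_mask=None if coloc_mask is None else np.asarray(coloc_mask, bool),
    )
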