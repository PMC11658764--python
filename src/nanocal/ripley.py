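"""Envelope-normalized Ripley's K for nanocluster point patterns.

For a pattern of N points, the statistic is the mean number of neighbours
within radius r,

    K(r) = (1/N) * sum_i sum_{j != i} 1[dist(i, j) <= r],

with Euclidean distance, ordered pairs (each unordered pair counts twice)
and an inclusive radius boundary.  No analytic edge correction is applied:
instead a Monte-Carlo envelope is built by drawing the same number of
random locations uniformly from the cell support, and K is affinely
rescaled so the envelope maximum maps to +1 and the minimum to -1.
Normalized values above 1 indicate aggregation, below -1 dispersion, and
anything in [-1, 1] is indistinguishable from complete spatial randomness.

An aggregation index summarizes many patterns: for each pattern with at
least ``min_points`` points, count the radii whose normalized value
exceeds 1, then average the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from nanocal.core_io import BinaryMask

__all__ = [
    "PointPattern",
    "RipleyCurve",
    "AggregationResult",
    "ripley_k",
    "mc_envelope",
    "normalize_k",
    "classify",
    "aggregation_index",
]


@dataclass(frozen=True)
class PointPattern:
    """Point locations (um) on a binary support mask (the cell surface)."""

    points: np.ndarray  # (n, 2) array of (x, y) in um
    support: BinaryMask

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RipleyCurve:
    """K(r) with its Monte-Carlo envelope and normalized values."""

    radii_um: np.ndarray
    k: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    normalized: np.ndarray
    n_points: int


@dataclass(frozen=True)
class AggregationResult:
    """Aggregation index over a set of (cell, timepoint) Ripley curves."""

    counts: tuple[int, ...]  # per included curve: #radii with normalized > 1
    index: float  # mean of counts; nan if nothing included
    n_curves_included: int
    n_curves_excluded: int


def _check_radii(radii_um) -> np.ndarray:
    r = np.asarray(radii_um, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("radii must be a non-empty 1-D sequence")
    if r[0] <= 0 or np.any(np.diff(r) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    return r


def ripley_k(
    pattern: PointPattern | np.ndarray,
    radii_um,
    classical: bool = False,
    support_area_um2: float | None = None,
) -> np.ndarray:
    """K(r) = (1/N) * number of ordered pairs within distance r.

    Patterns with fewer than two points have an empty pair sum, so K is
    identically zero.

    The default normalization by the point count N is what the envelope
    rescaling expects.  ``classical=True`` instead scales the ordered-pair
    count by |support| / N^2 (the textbook estimator, without edge
    correction) for comparison with other tools; it requires the support
    area, taken from the pattern's mask unless given explicitly.
    """
    radii = _check_radii(radii_um)
    is_pattern = isinstance(pattern, PointPattern)
    points = pattern.points if is_pattern else np.asarray(
        pattern, dtype=float
    ).reshape(-1, 2)
    n = len(points)
    if n < 2:
        return np.zeros_like(radii)
    d = pdist(points)  # unordered pair distances
    # ordered pairs: each unordered pair contributes twice
    counts = 2 * np.searchsorted(np.sort(d), radii, side="right")
    if classical:
        if support_area_um2 is None:
            if not is_pattern:
                raise ValueError(
                    "classical K needs support_area_um2 or a PointPattern"
                )
            support_area_um2 = pattern.support.area_um2
        return counts * support_area_um2 / n**2
    return counts / n


def mc_envelope(
    support: BinaryMask,
    n_points: int,
    radii_um,
    n_sims: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise min/max K(r) envelope from random locations on the support.

    Each of the ``n_sims`` simulations draws exactly ``n_points`` locations
    uniformly from the support's pixel centers (the same grid observed
    centroids are quantized to) and computes K(r).
    """
    radii = _check_radii(radii_um)
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rr, cc = np.nonzero(support.pixels)
    if rr.size == 0:
        raise ValueError("support mask is empty")
    centers = np.column_stack([cc, rr]).astype(float) * support.pixel_size_um
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, radii.size))
    for s in range(n_sims):
        idx = rng.integers(0, len(centers), size=n_points)
        sims[s] = ripley_k(centers[idx], radii)
    return sims.max(axis=0), sims.min(axis=0)


def normalize_k(
    k: np.ndarray, upper: np.ndarray, lower: np.ndarray
) -> np.ndarray:
    """Affine rescale so the envelope maps to [-1, +1] at every radius.

    normalized = 2 * (K - lower) / (upper - lower) - 1.  A degenerate
    radius (upper == lower) maps to 0 when K equals the common value and
    to a flagged sentinel of +/-(1 + eps) otherwise.
    """
    k = np.asarray(k, dtype=float)
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if not (k.shape == upper.shape == lower.shape):
        raise ValueError("k, upper and lower must have identical shapes")
    if np.any(upper < lower):
        raise ValueError("upper envelope must be >= lower envelope")
    span = upper - lower
    out = np.empty_like(k)
    ok = span > 0
    out[ok] = 2 * (k[ok] - lower[ok]) / span[ok] - 1
    degen = ~ok
    if np.any(degen):
        eps = np.finfo(float).eps
        same = degen & np.isclose(k, upper)
        out[same] = 0.0
        above = degen & (k > upper) & ~same
        below = degen & (k < lower) & ~same
        out[above] = 1 + eps
        out[below] = -(1 + eps)
        if np.any(above | below):
            warnings.warn(
                "degenerate envelope radius with K outside the common value; "
                "normalized value clamped to +/-(1+eps)",
                stacklevel=2,
            )
    return out


def classify(normalized: np.ndarray) -> list[str]:
    """Per-radius label: > 1 aggregated, < -1 dispersed, else random.

    The boundary values +/-1 belong to the random band.
    """
    normalized = np.asarray(normalized, dtype=float)
    labels = np.where(
        normalized > 1, "aggregated", np.where(normalized < -1, "dispersed", "random")
    )
    return labels.tolist()


def ripley_curve(
    pattern: PointPattern,
    radii_um,
    n_sims: int = 100,
    seed: int = 0,
) -> RipleyCurve:
    """Convenience: K, envelope and normalized values for one pattern."""
    radii = _check_radii(radii_um)
    k = ripley_k(pattern, radii)
    upper, lower = mc_envelope(pattern.support, max(len(pattern), 2), radii,
                               n_sims=n_sims, seed=seed)
    return RipleyCurve(
        radii_um=radii,
        k=k,
        upper=upper,
        lower=lower,
        normalized=normalize_k(k, upper, lower),
        n_points=len(pattern),
    )


def aggregation_index(
    curves: list[RipleyCurve], min_points: int = 10
) -> AggregationResult:
    """Count supra-envelope radii per curve and average into one index.

    Curves from patterns with fewer than ``min_points`` points are
    excluded.  With nothing left, the index is missing (nan) with a
    warning, never silently zero.
    """
    included = [c for c in curves if c.n_points >= min_points]
    excluded = len(curves) - len(included)
    counts = tuple(int(np.sum(np.asarray(c.normalized) > 1)) for c in included)
    if not included:
        warnings.warn(
            f"all {len(curves)} curves excluded by the {min_points}-point rule",
            stacklevel=2,
        )
        index = float("nan")
    else:
        index = float(np.mean(counts))
    return AggregationResult(
        counts=counts,
        index=index,
        n_curves_included=len(included),
        n_curves_excluded=excluded,
    )
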