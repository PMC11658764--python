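"""Ground-truthed synthetic microscopy data.

Generates single-cell, multi-channel time-lapse frames and 1-D calcium
traces with known ground truth, emulating confocal movies of crawling
neutrophils: 512x512 px frames at 0.284 um/px, ~10 um cells containing
punctate integrin nanoclusters, calcium enrichment colocalized with the
clusters, and transient cell-wide calcium flickers.  Every stochastic call
takes an explicit seed; identical seeds give bit-identical output.

The point patterns come in three regimes:

``csr``
    complete spatial randomness — uniform independent placement on the
    cell mask (the null model of the Ripley analysis);
``clustered``
    a Thomas-type parent/offspring process: parents uniform on the mask,
    offspring displaced by an isotropic Gaussian (sd ``offspring_sd_um``);
``dispersed``
    sequential inhibition with a hard minimum inter-point distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from nanocal.core_io import BinaryMask, IntensityTrace
from nanocal.ripley import PointPattern

__all__ = [
    "FlickerEvent",
    "GroundTruth",
    "ClusterProcessParams",
    "make_cell_mask",
    "sample_point_pattern",
    "render_cluster_channel",
    "render_calcium_channel",
    "generate_trace",
]

REGIMES = ("csr", "clustered", "dispersed")


@dataclass(frozen=True)
class FlickerEvent:
    """One injected calcium transient on a cell trace."""

    onset_s: float
    amplitude: float
    half_width_s: float  # full width at half maximum of the pulse


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a synthetic data set."""

    cluster_centroids_um: np.ndarray | None = None  # (n, 2) x,y
    regime: str | None = None
    ca_enrichment: float | None = None
    flickers: tuple[FlickerEvent, ...] = ()
    rng_seed: int | None = None
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterProcessParams:
    """Parameters of the synthetic nanocluster point process."""

    regime: str = "csr"
    expected_total_points: float = 40.0
    parent_intensity: float = 0.05  # parents per um^2 of cell area (clustered)
    offspring_sd_um: float = 0.3
    min_distance_um: float = 1.0  # inhibition radius (dispersed)
    hard_core_um: float = 0.0  # object-level minimum separation (0 = off)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}; got {self.regime!r}")
        if self.expected_total_points < 0:
            raise ValueError("expected_total_points must be >= 0")
        if self.regime == "clustered" and self.offspring_sd_um <= 0:
            raise ValueError("offspring_sd_um must be > 0 for the clustered regime")
        if self.regime == "dispersed" and self.min_distance_um <= 0:
            raise ValueError("min_distance_um must be > 0 for the dispersed regime")


def make_cell_mask(
    shape_px: tuple[int, int],
    cell_radius_um: float,
    pixel_size_um: float,
    irregularity: float = 0.0,
    seed: int = 0,
) -> BinaryMask:
    """Rasterize a single connected, hole-free cell-shaped region.

    ``irregularity`` = 0 gives a disk; larger values modulate the radius
    with a smooth random Fourier perturbation (amoeboid outline), up to
    roughly +/- ``irregularity`` relative radius change.
    """
    rows, cols = shape_px
    radius_px = cell_radius_um / pixel_size_um
    if not 0 <= irregularity <= 1:
        raise ValueError("irregularity must be in [0, 1]")
    # the perturbed outline can reach (1 + irregularity) * r
    if radius_px * (1 + irregularity) >= min(rows, cols) / 2:
        raise ValueError(
            f"cell of radius {cell_radius_um} um does not fit a "
            f"{rows}x{cols} frame at {pixel_size_um} um/px"
        )
    center = (rows / 2, cols / 2)
    if irregularity == 0:
        rr, cc = draw.disk(center, radius_px, shape=(rows, cols))
        px = np.zeros((rows, cols), dtype=bool)
        px[rr, cc] = True
        return BinaryMask(px, pixel_size_um)

    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    # low-order Fourier modes keep the outline smooth and star-convex
    modulation = np.zeros_like(theta)
    for k in range(2, 6):
        modulation += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(
            k * theta
        )
    modulation *= irregularity / max(1e-12, np.abs(modulation).max())
    r = radius_px * (1 + modulation)
    rr, cc = draw.polygon(
        center[0] + r * np.sin(theta), center[1] + r * np.cos(theta), shape=(rows, cols)
    )
    px = np.zeros((rows, cols), dtype=bool)
    px[rr, cc] = True
    px = ndimage.binary_fill_holes(px)
    # star-convex polygons are connected by construction; keep largest CC
    # defensively in case of rasterization slivers
    labels, n = ndimage.label(px)
    if n > 1:
        sizes = ndimage.sum_labels(px, labels, index=np.arange(1, n + 1))
        px = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(px, pixel_size_um)


def _mask_pixel_centers_um(mask: BinaryMask) -> np.ndarray:
    """(n, 2) array of (x, y) physical coordinates of mask pixel centers."""
    rr, cc = np.nonzero(mask.pixels)
    return np.column_stack([cc, rr]).astype(float) * mask.pixel_size_um


def _points_to_pixels(points_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    return np.rint(points_um / pixel_size_um).astype(int)


def _inside(points_um: np.ndarray, mask: BinaryMask) -> np.ndarray:
    ij = _points_to_pixels(points_um, mask.pixel_size_um)
    cols, rows = ij[:, 0], ij[:, 1]
    ok = (
        (rows >= 0)
        & (rows < mask.pixels.shape[0])
        & (cols >= 0)
        & (cols < mask.pixels.shape[1])
    )
    ok[ok] &= mask.pixels[rows[ok], cols[ok]]
    return ok


def sample_point_pattern(
    mask: BinaryMask, params: ClusterProcessParams
) -> PointPattern:
    """Sample nanocluster locations on a cell mask under the given regime.

    The realized point count is Poisson with mean ``expected_total_points``
    in the CSR and clustered regimes.  Points live on mask pixel centers,
    matching how observed centroids are quantized by the pixel grid.
    """
    if mask.n_pixels == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(params.rng_seed)
    candidates = _mask_pixel_centers_um(mask)
    n = int(rng.poisson(params.expected_total_points))
    if n == 0:
        return PointPattern(np.empty((0, 2)), mask)

    if params.regime == "csr":
        points = candidates[rng.integers(0, len(candidates), size=n)]
    elif params.regime == "clustered":
        area = mask.area_um2
        n_parents = max(1, int(np.round(params.parent_intensity * area)))
        parents = candidates[rng.integers(0, len(candidates), size=n_parents)]
        assignment = rng.integers(0, n_parents, size=n)
        points = np.empty((n, 2))
        for i in range(n):
            # resample the Gaussian displacement until the offspring lands
            # on the mask; bounded retries, then fall back to the parent
            p = parents[assignment[i]]
            for _ in range(100):
                cand = p + rng.normal(0, params.offspring_sd_um, size=2)
                if _inside(cand[None, :], mask)[0]:
                    points[i] = cand
                    break
            else:
                points[i] = p
        points = _snap_to_grid(points, mask)
    else:  # dispersed: simple sequential inhibition
        accepted: list[np.ndarray] = []
        attempts = 0
        max_attempts = 200 * n
        while len(accepted) < n and attempts < max_attempts:
            attempts += 1
            cand = candidates[rng.integers(0, len(candidates))]
            if all(
                np.hypot(*(cand - a)) >= params.min_distance_um for a in accepted
            ):
                accepted.append(cand)
        if len(accepted) < n:
            raise RuntimeError(
                f"inhibition radius {params.min_distance_um} um infeasible for "
                f"{n} points on a {mask.area_um2:.1f} um^2 mask"
            )
        points = np.array(accepted)
    if params.hard_core_um > 0 and len(points) > 1:
        points = _hard_core_thin(points, params.hard_core_um)
    return PointPattern(points, mask)


def _hard_core_thin(points: np.ndarray, hard_core_um: float) -> np.ndarray:
    """Greedy Matern-I-style thinning: drop points within the hard core of
    an already accepted point.

    Models nanoclusters as physical objects: two generated locations closer
    than one object diameter would segment as a single cluster anyway, so
    the generator never emits them.  Thinning reduces the realized count
    below the Poisson mean; callers that need exact count calibration keep
    ``hard_core_um`` at 0.
    """
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.hypot(*(p - q)) >= hard_core_um for q in kept):
            kept.append(p)
    return np.array(kept)


def _snap_to_grid(points_um: np.ndarray, mask: BinaryMask) -> np.ndarray:
    ij = _points_to_pixels(points_um, mask.pixel_size_um)
    return ij.astype(float) * mask.pixel_size_um


def _render_spots(
    shape: tuple[int, int],
    points_um: np.ndarray,
    sigma_um: float,
    amplitude: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Sum of isotropic Gaussian spots evaluated at pixel centers."""
    img = np.zeros(shape, dtype=float)
    sigma_px = sigma_um / pixel_size_um
    half = max(1, int(np.ceil(4 * sigma_px)))
    for x_um, y_um in points_um:
        c = x_um / pixel_size_um
        r = y_um / pixel_size_um
        r0, r1 = int(np.floor(r - half)), int(np.ceil(r + half)) + 1
        c0, c1 = int(np.floor(c - half)), int(np.ceil(c + half)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px**2)
        )
    return img


def render_cluster_channel(
    mask: BinaryMask,
    pattern: PointPattern,
    spot_sigma_um: float = 0.25,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Render the nanocluster (integrin) channel for one frame.

    Each point becomes an isotropic Gaussian spot of peak ``amplitude``
    over a constant ``background``, plus additive Gaussian noise clipped
    at zero.
    """
    if amplitude <= noise_sd:
        raise ValueError("amplitude must exceed noise_sd")
    frame = np.full(mask.pixels.shape, background, dtype=float)
    if len(pattern) > 0:
        frame += _render_spots(
            mask.pixels.shape, pattern.points, spot_sigma_um, amplitude,
            mask.pixel_size_um,
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame += rng.normal(0, noise_sd, size=frame.shape)
    return np.clip(frame, 0, None)


def spot_footprint(
    mask: BinaryMask, pattern: PointPattern, radius_um: float
) -> np.ndarray:
    """Boolean footprint: mask pixels within ``radius_um`` of any point."""
    foot = np.zeros(mask.pixels.shape, dtype=bool)
    for x_um, y_um in pattern.points:
        rr, cc = draw.disk(
            (y_um / mask.pixel_size_um, x_um / mask.pixel_size_um),
            max(radius_um / mask.pixel_size_um, 1.0),
            shape=mask.pixels.shape,
        )
        foot[rr, cc] = True
    return foot & mask.pixels


def _pulse(t: np.ndarray, onset_s: float, amplitude: float, half_width_s: float
           ) -> np.ndarray:
    """Gaussian-in-time bump whose FWHM equals ``half_width_s``.

    The pulse peaks one FWHM after onset so that its rise is effectively
    complete within the trace when the onset is in range.
    """
    sigma = half_width_s / (2 * np.sqrt(2 * np.log(2)))
    peak_t = onset_s + half_width_s
    return amplitude * np.exp(-((t - peak_t) ** 2) / (2 * sigma**2))


def render_calcium_channel(
    mask: BinaryMask,
    pattern: PointPattern,
    enrichment: float = 2.0,
    flickers: tuple[FlickerEvent, ...] = (),
    frame_times_s: np.ndarray | None = None,
    baseline: float = 50.0,
    spot_radius_um: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render the cytosolic calcium channel over time.

    Inside the cell the baseline is flat; pixels within ``spot_radius_um``
    of a nanocluster are scaled by ``enrichment`` (>= 1); each flicker adds
    a cell-wide Gaussian-in-time transient.  Returns the (T, Y, X) frames
    and the ground truth that produced them.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if frame_times_s is None:
        frame_times_s = np.array([0.0])
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    base = np.where(mask.pixels, baseline, 0.0)
    foot = spot_footprint(mask, pattern, spot_radius_um)
    base = np.where(foot, base * enrichment, base)
    pulses = np.zeros_like(frame_times_s)
    for ev in flickers:
        pulses += _pulse(frame_times_s, ev.onset_s, ev.amplitude, ev.half_width_s)
    frames = base[None, :, :] + np.where(mask.pixels, 1.0, 0.0)[None] * pulses[
        :, None, None
    ]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0, noise_sd, size=frames.shape)
    frames = np.clip(frames, 0, None)
    truth = GroundTruth(
        cluster_centroids_um=pattern.points.copy(),
        ca_enrichment=enrichment,
        flickers=tuple(flickers),
        rng_seed=seed,
        params={
            "baseline": baseline,
            "spot_radius_um": spot_radius_um,
            "noise_sd": noise_sd,
        },
    )
    return frames, truth


def generate_trace(
    duration_s: float,
    dt_s: float,
    baseline: float = 100.0,
    noise_sd: float = 1.0,
    events: tuple[FlickerEvent, ...] = (),
    seed: int = 0,
    cell_id: str = "cell0",
) -> tuple[IntensityTrace, GroundTruth]:
    """Generate a per-cell calcium trace with injected transients.

    The trace is ``baseline + sum of pulses + N(0, noise_sd)`` sampled on a
    regular grid ``0, dt, 2dt, ...`` covering ``duration_s``.  Pulse shape
    is a Gaussian bump whose full width at half maximum is the event's
    ``half_width_s``.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    t = np.arange(0, duration_s, dt_s)
    for ev in events:
        if not 0 <= ev.onset_s < duration_s:
            raise ValueError(f"event onset {ev.onset_s} outside [0, {duration_s})")
    values = np.full_like(t, float(baseline))
    for ev in events:
        values += _pulse(t, ev.onset_s, ev.amplitude, ev.half_width_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0, noise_sd, size=t.shape)
    trace = IntensityTrace(times_s=t, values=values, cell_id=cell_id)
    truth = GroundTruth(
        flickers=tuple(events),
        rng_seed=seed,
        params={"baseline": baseline, "noise_sd": noise_sd, "dt_s": dt_s},
    )
    return trace, truth
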