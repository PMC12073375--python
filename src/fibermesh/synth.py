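"""Synthetic SEM-like fiber-mesh micrographs with exact ground truth.

Electrospun meshes imaged by SEM look like a 2-D projection of long,
roughly cylindrical fibers lying on top of each other: bright fibers on a
dark background, diameters positively skewed (a lognormal fits well), and
sub-micron voids between them.  This module renders such images from known
fiber geometry so that every downstream estimator (binarization, skeleton
length, distance-transform diameters, pore statistics, surface area) can be
validated against analytic truth.

A fiber is a polyline centerline stroked with a constant width: a pixel
belongs to the fiber iff its center lies within ``diameter/2`` (in pixels)
of the centerline.  Ground-truth length is the polyline arc length, and the
analytic lateral surface of the cylinder is ``pi * d * L`` per fiber.
Overlap between fibers is allowed by default (the mask is the union, while
ground-truth totals count every fiber fully — the projection convention);
``allow_overlap=False`` switches to rejection-sampled disjoint placement,
which is what quantitative estimator validation needs, since crossings bias
mask-based measurements.

Noise is additive Gaussian on [0, 1] intensities and is applied only after
all masks are frozen, so the truth is exact by construction.  Equal
``(spec, seed)`` reproduces bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ComputationError, ValidationError

__all__ = [
    "DiameterLaw",
    "ScaleBar",
    "MeshSpec",
    "FiberRecord",
    "MeshGroundTruth",
    "sample_diameters",
    "generate_mesh",
    "render_fibers",
    "save_image",
    "save_ground_truth",
]

_MAX_PLACEMENT_ATTEMPTS = 2000


@dataclass(frozen=True)
class DiameterLaw:
    """Distribution of fiber diameters, in microns.

    ``lognormal`` is parameterized by its median (the lognormal median is
    ``exp(mu)``) and the log-space sigma, so the mean is
    ``median * exp(sigma_log**2 / 2)``.  ``constant`` ignores ``sigma_log``.
    """

    kind: str = "lognormal"
    median_um: float = 0.48
    sigma_log: float = 0.586


@dataclass(frozen=True)
class ScaleBar:
    """Optional scale bar drawn in a reserved bottom margin.

    The margin is kept clear of fibers so the bar cannot pollute
    morphometry; the bar region is recorded in the ground truth so callers
    can crop it away before analysis.
    """

    length_um: float = 10.0
    thickness_px: int = 6
    margin_px: int = 40


@dataclass(frozen=True)
class MeshSpec:
    """Full description of one synthetic micrograph.

    Defaults emulate the study conditions of the electrospun bacterial
    cellulose meshes this package targets: 0.05 um/px, lognormal diameters
    with median 0.48 um and sigma_log 0.586 (mean ~0.57 um), bright fibers
    (0.8) on a dark background (0.2) with noise SD 0.05.
    """

    image_width_px: int = 1024
    image_height_px: int = 1024
    um_per_px: float = 0.05
    n_fibers: int = 60
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    curvature: float = 0.0
    fg_intensity: float = 0.8
    bg_intensity: float = 0.2
    noise_sd: float = 0.05
    # chord: endpoints on the image border (long through-going fibers,
    # overlap expected).  segment: finite strokes placed fully inside the
    # frame, the only geometry for which disjoint placement is feasible.
    placement: str = "chord"
    diameter_sampling: str = "iid"  # iid | stratified (variance-reduced)
    fiber_length_px: tuple[float, float] | None = None
    allow_overlap: bool = True
    min_separation_px: int = 2
    scale_bar: ScaleBar | None = None
    seed: int = 0


@dataclass
class FiberRecord:
    """Ground truth for a single fiber."""

    polyline: np.ndarray  # (k, 2) float array of (row, col) pixel coords
    diameter_um: float
    length_um: float


@dataclass
class MeshGroundTruth:
    """Exact truth frozen before noise is applied.

    ``fiber_mask`` and ``void_mask`` partition the image exactly.  Totals
    use the projection convention: each fiber contributes its full polyline
    length and full cylinder surface ``pi * d * L`` regardless of overlap.
    """

    fibers: list[FiberRecord]
    fiber_mask: np.ndarray
    void_mask: np.ndarray
    label_image: np.ndarray
    total_centerline_length_um: float
    analytic_surface_area_um2: float
    fiber_area_fraction: float
    um_per_px: float
    scale_bar_bbox: tuple[int, int, int, int] | None
    seed: int


def validate_spec(spec: MeshSpec) -> None:
    """Raise :class:`ValidationError` naming the first offending field."""
    if spec.image_width_px <= 0:
        raise ValidationError("image_width_px must be positive")
    if spec.image_height_px <= 0:
        raise ValidationError("image_height_px must be positive")
    if not (spec.um_per_px > 0 and math.isfinite(spec.um_per_px)):
        raise ValidationError("um_per_px must be positive and finite")
    if spec.n_fibers < 0:
        raise ValidationError("n_fibers must be non-negative")
    law = spec.diameter_law
    if law.kind not in ("constant", "lognormal"):
        raise ValidationError(f"diameter_law.kind: unsupported kind {law.kind!r}")
    if law.median_um <= 0:
        raise ValidationError("diameter_law.median_um must be positive")
    if law.sigma_log < 0:
        raise ValidationError("diameter_law.sigma_log must be non-negative")
    if spec.n_fibers > 0 and law.median_um / spec.um_per_px < 2:
        raise ValidationError(
            "diameter_law.median_um: median diameter must span >= 2 pixels "
            "for skeletons to be well defined"
        )
    if spec.curvature < 0:
        raise ValidationError("curvature must be non-negative")
    if not (0.0 <= spec.bg_intensity < spec.fg_intensity <= 1.0):
        raise ValidationError(
            "fg_intensity/bg_intensity must satisfy 0 <= bg < fg <= 1"
        )
    if spec.noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if spec.placement not in ("chord", "segment"):
        raise ValidationError(f"placement: unsupported mode {spec.placement!r}")
    if spec.diameter_sampling not in ("iid", "stratified"):
        raise ValidationError(
            f"diameter_sampling: unsupported method {spec.diameter_sampling!r}"
        )
    if spec.fiber_length_px is not None:
        lo, hi = spec.fiber_length_px
        if not (0 < lo <= hi):
            raise ValidationError("fiber_length_px must be an increasing positive pair")
    if spec.scale_bar is not None and spec.scale_bar.length_um <= 0:
        raise ValidationError("scale_bar.length_um must be positive")


def sample_diameters(
    law: DiameterLaw, n: int, seed: int, method: str = "iid"
) -> np.ndarray:
    """Draw ``n`` fiber diameters (um) from a diameter law.

    For the lognormal law the sample median converges to ``median_um`` and
    the sample mean to ``median_um * exp(sigma_log**2 / 2)``.

    ``method='stratified'`` draws one point uniformly from each of n equal
    probability strata (then shuffles).  Marginals are unchanged and the
    sample mean stays unbiased, but its Monte Carlo variance collapses —
    the right design when validating an estimator against population
    parameters, where finite-sample noise would otherwise dominate.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_diameters(law, n, rng, method)


def _sample_diameters(
    law: DiameterLaw, n: int, rng: np.random.Generator, method: str = "iid"
) -> np.ndarray:
    if method not in ("iid", "stratified"):
        raise ValidationError(f"unsupported diameter sampling method {method!r}")
    if law.kind == "constant":
        return np.full(n, float(law.median_um))
    if law.kind == "lognormal":
        if method == "stratified":
            from scipy.special import ndtri

            p = (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
            z = rng.permutation(ndtri(p))
        else:
            z = rng.normal(0.0, 1.0, size=n)
        return law.median_um * np.exp(law.sigma_log * z)
    raise ValidationError(f"diameter_law.kind: unsupported kind {law.kind!r}")


# ---------------------------------------------------------------------------
# rasterization


def _polyline_length_px(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def _stroke_mask(
    shape: tuple[int, int], poly: np.ndarray, radius_px: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a constant-width stroke along a polyline.

    Returns a boolean crop covering the stroke plus its (row, col) offset in
    the full image.  A pixel is set iff the distance from its center to the
    polyline is <= radius_px (capsule union over segments).
    """
    H, W = shape
    pad = radius_px + 1.5
    r0 = max(int(np.floor(poly[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(poly[:, 0].max() + pad)) + 1, H)
    c0 = max(int(np.floor(poly[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(poly[:, 1].max() + pad)) + 1, W)
    crop = np.zeros((max(r1 - r0, 0), max(c1 - c0, 0)), dtype=bool)
    if crop.size == 0:
        return crop, (r0, c0)
    for a, b in zip(poly[:-1], poly[1:]):
        sr0 = max(int(np.floor(min(a[0], b[0]) - pad)), r0)
        sr1 = min(int(np.ceil(max(a[0], b[0]) + pad)) + 1, r1)
        sc0 = max(int(np.floor(min(a[1], b[1]) - pad)), c0)
        sc1 = min(int(np.ceil(max(a[1], b[1]) + pad)) + 1, c1)
        if sr1 <= sr0 or sc1 <= sc0:
            continue
        yy, xx = np.meshgrid(
            np.arange(sr0, sr1, dtype=float),
            np.arange(sc0, sc1, dtype=float),
            indexing="ij",
        )
        v = b - a
        vv = float(v @ v)
        if vv == 0.0:
            d2 = (yy - a[0]) ** 2 + (xx - a[1]) ** 2
        else:
            t = np.clip(((yy - a[0]) * v[0] + (xx - a[1]) * v[1]) / vv, 0.0, 1.0)
            d2 = (yy - (a[0] + t * v[0])) ** 2 + (xx - (a[1] + t * v[1])) ** 2
        crop[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] |= d2 <= radius_px**2
    return crop, (r0, c0)


def _bend(poly: np.ndarray, curvature: float, rng: np.random.Generator) -> np.ndarray:
    """Replace a straight chord by a sampled quadratic Bezier.

    ``curvature`` is the maximum perpendicular mid-offset as a fraction of
    the chord length; 0 keeps the straight chord.
    """
    if curvature <= 0:
        return poly
    a, b = poly[0], poly[-1]
    chord = b - a
    length = np.linalg.norm(chord)
    if length == 0:
        return poly
    perp = np.array([-chord[1], chord[0]]) / length
    offset = curvature * length * rng.uniform(-1.0, 1.0)
    ctrl = (a + b) / 2.0 + perp * offset
    t = np.linspace(0.0, 1.0, max(16, int(length / 4)))[:, None]
    return (1 - t) ** 2 * a + 2 * t * (1 - t) * ctrl + t**2 * b


def _perimeter_point(t: float, H: float, W: float) -> np.ndarray:
    """Map arclength parameter t in [0, perimeter) to a border point."""
    if t < W:
        return np.array([0.0, t])
    t -= W
    if t < H:
        return np.array([t, W])
    t -= H
    if t < W:
        return np.array([H, W - t])
    return np.array([H - t + W, 0.0])


def _sample_polyline(
    spec: MeshSpec, rng: np.random.Generator, radius_px: float, height_eff: int
) -> np.ndarray:
    H, W = float(height_eff - 1), float(spec.image_width_px - 1)
    if spec.placement == "chord":
        perim = 2 * (H + W)
        for _ in range(100):
            p0 = _perimeter_point(rng.uniform(0, perim), H, W)
            p1 = _perimeter_point(rng.uniform(0, perim), H, W)
            if np.linalg.norm(p1 - p0) >= 0.3 * min(H, W):
                break
        poly = np.stack([p0, p1])
    else:  # segment
        if spec.fiber_length_px is not None:
            length = rng.uniform(*spec.fiber_length_px)
        else:
            m = min(H, W)
            length = rng.uniform(0.2 * m, 0.4 * m)
        g = radius_px + 2.0
        for _ in range(200):
            p0 = np.array(
                [rng.uniform(g, H - g), rng.uniform(g, W - g)]
            )
            theta = rng.uniform(0.0, np.pi)
            p1 = p0 + length * np.array([np.sin(theta), np.cos(theta)])
            if g <= p1[0] <= H - g and g <= p1[1] <= W - g:
                break
        else:
            raise ComputationError(
                "segment placement failed: fiber_length_px too large for the image"
            )
        poly = np.stack([p0, p1])
    return _bend(poly, spec.curvature, rng)


def render_fibers(
    polylines: list[np.ndarray],
    diameters_um: np.ndarray,
    *,
    image_width_px: int,
    image_height_px: int,
    um_per_px: float,
    fg_intensity: float = 0.8,
    bg_intensity: float = 0.2,
    noise_sd: float = 0.0,
    scale_bar: ScaleBar | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, MeshGroundTruth]:
    """Render explicit fiber geometry into an image plus exact ground truth.

    This is the deterministic back half of :func:`generate_mesh`; it is
    public so tests and callers can place fibers analytically (e.g. a single
    horizontal fiber of known diameter).
    """
    shape = (image_height_px, image_width_px)
    fiber_mask = np.zeros(shape, dtype=bool)
    label = np.zeros(shape, dtype=np.uint16)
    fibers: list[FiberRecord] = []
    for i, (poly, d_um) in enumerate(zip(polylines, diameters_um)):
        poly = np.asarray(poly, dtype=float)
        r_px = max(d_um / um_per_px / 2.0, 0.71)
        crop, (r0, c0) = _stroke_mask(shape, poly, r_px)
        sl = (slice(r0, r0 + crop.shape[0]), slice(c0, c0 + crop.shape[1]))
        fiber_mask[sl] |= crop
        label[sl][crop] = i + 1
        fibers.append(
            FiberRecord(poly, float(d_um), _polyline_length_px(poly) * um_per_px)
        )

    bar_bbox = None
    image = np.full(shape, float(bg_intensity))
    image[fiber_mask] = float(fg_intensity)
    if scale_bar is not None:
        bar_px = int(round(scale_bar.length_um / um_per_px))
        t = scale_bar.thickness_px
        rb = image_height_px - scale_bar.margin_px // 2 - t // 2
        cb = image_width_px - bar_px - 20
        if rb < 0 or cb < 0:
            raise ValidationError("scale_bar does not fit in the image margin")
        bar_bbox = (rb, rb + t, cb, cb + bar_px)
        image[rb : rb + t, cb : cb + bar_px] = float(fg_intensity)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + rng.normal(0.0, noise_sd, shape), 0.0, 1.0)

    total_len = sum(f.length_um for f in fibers)
    truth = MeshGroundTruth(
        fibers=fibers,
        fiber_mask=fiber_mask,
        void_mask=~fiber_mask,
        label_image=label,
        total_centerline_length_um=total_len,
        analytic_surface_area_um2=sum(
            math.pi * f.diameter_um * f.length_um for f in fibers
        ),
        fiber_area_fraction=float(fiber_mask.mean()),
        um_per_px=um_per_px,
        scale_bar_bbox=bar_bbox,
        seed=seed,
    )
    return image, truth


def generate_mesh(spec: MeshSpec) -> tuple[np.ndarray, MeshGroundTruth]:
    """Generate a synthetic micrograph and its exact ground truth.

    Masks and totals are frozen before noise is applied.  With
    ``allow_overlap=False`` fibers are placed by rejection so that their
    strokes stay at least ``min_separation_px`` apart; placement raises
    :class:`ComputationError` if the requested coverage is infeasible.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    height_eff = spec.image_height_px - (
        spec.scale_bar.margin_px if spec.scale_bar is not None else 0
    )
    if height_eff < 8:
        raise ValidationError("scale_bar.margin_px leaves no room for fibers")

    diams = _sample_diameters(
        spec.diameter_law, max(spec.n_fibers, 1), rng, spec.diameter_sampling
    )
    diams = diams[: spec.n_fibers]
    if not spec.allow_overlap:
        # thickest first: the standard packing order, markedly improves the
        # feasible coverage of disjoint placement
        diams = np.sort(diams)[::-1]
    occupied = np.zeros(shape, dtype=bool)
    polylines: list[np.ndarray] = []
    for i in range(spec.n_fibers):
        r_px = max(diams[i] / spec.um_per_px / 2.0, 0.71)
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            poly = _sample_polyline(spec, rng, r_px, height_eff)
            if spec.allow_overlap:
                break
            guard, (r0, c0) = _stroke_mask(
                shape, poly, r_px + spec.min_separation_px
            )
            sl = (slice(r0, r0 + guard.shape[0]), slice(c0, c0 + guard.shape[1]))
            if not (guard & occupied[sl]).any():
                core, (r0, c0) = _stroke_mask(shape, poly, r_px)
                sl = (slice(r0, r0 + core.shape[0]), slice(c0, c0 + core.shape[1]))
                occupied[sl] |= core
                break
        else:
            raise ComputationError(
                f"could not place fiber {i} without overlap after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; lower n_fibers or coverage"
            )
        polylines.append(poly)

    # Noise seed is drawn from the same stream so (spec, seed) fixes
    # everything downstream.
    noise_seed = int(rng.integers(0, 2**31 - 1))
    image, truth = render_fibers(
        polylines,
        diams,
        image_width_px=spec.image_width_px,
        image_height_px=spec.image_height_px,
        um_per_px=spec.um_per_px,
        fg_intensity=spec.fg_intensity,
        bg_intensity=spec.bg_intensity,
        noise_sd=spec.noise_sd,
        scale_bar=spec.scale_bar,
        seed=noise_seed,
    )
    truth.seed = spec.seed
    return image, truth


# ---------------------------------------------------------------------------
# persistence


def save_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0,1] float image as 8- or 16-bit grayscale TIFF/PNG."""
    from . import io as fio

    fio.save_image(image, path, bit_depth=bit_depth)


def save_ground_truth(truth: MeshGroundTruth, json_path, label_tiff_path=None) -> None:
    """Persist ground truth as JSON (+ optional 16-bit label TIFF)."""
    payload = {
        "um_per_px": truth.um_per_px,
        "seed": truth.seed,
        "total_centerline_length_um": truth.total_centerline_length_um,
        "analytic_surface_area_um2": truth.analytic_surface_area_um2,
        "fiber_area_fraction": truth.fiber_area_fraction,
        "scale_bar_bbox": truth.scale_bar_bbox,
        "fibers": [
            {
                "polyline_px": f.polyline.tolist(),
                "diameter_um": f.diameter_um,
                "length_um": f.length_um,
            }
            for f in truth.fibers
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
    if label_tiff_path is not None:
        tifffile.imwrite(label_tiff_path, truth.label_image)
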