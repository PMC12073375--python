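"""Binarization and skeletonization of fiber micrographs.

The measurement chain is: threshold the image into a fiber mask (fibers
bright on a dark background), clean small noise objects, thin the mask to a
1-pixel-wide centerline skeleton, prune short spur branches left by
thinning, and convert the skeleton to a physical total centerline length.

Length metric: adjacent skeleton pixels are connected under 8-neighbour
adjacency and each edge is counted once, weighted 1 px for axial steps and
sqrt(2) px for diagonal steps.  A plain ``pixel_count`` metric (every
skeleton pixel counts 1 px) is offered as a documented compatibility
option, since some image-analysis workflows report lengths that way.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters, morphology

from .errors import ComputationError, ValidationError
from .io import Calibration

__all__ = [
    "FiberMask",
    "FiberSkeleton",
    "binarize",
    "clean_mask",
    "skeletonize_mask",
    "total_length",
    "export_skeleton_json",
    "export_skeleton_overlay",
]

_SQRT2 = math.sqrt(2.0)
_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FiberMask:
    """Binary fiber mask plus the provenance of how it was produced."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class FiberSkeleton:
    """1-pixel-wide centerline skeleton of a fiber mask.

    ``endpoints`` (degree 1) and ``junctions`` (degree >= 3) are under
    8-neighbour adjacency.  ``border_flagged`` marks skeleton pixels
    adjacent to the image border, whose local measurements are unreliable;
    morphometry excludes them from diameter statistics.
    """

    pixels: np.ndarray
    endpoints: np.ndarray
    junctions: np.ndarray
    border_flagged: np.ndarray
    total_length_px: float
    prune_px: int = 0


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> FiberMask:
    """Threshold a [0,1] image into a fiber mask (intensity >= threshold).

    Otsu is the default; a fixed threshold is available for exact
    reproducibility.  A constant image has no foreground/background
    separation and raises :class:`ComputationError` under Otsu.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValidationError("image intensities must lie in [0, 1]")
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ComputationError("no foreground/background separation")
        thr = float(filters.threshold_otsu(image))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValidationError("fixed_threshold is required with method='fixed'")
        thr = float(fixed_threshold)
    else:
        raise ValidationError(f"unsupported binarization method {method!r}")
    return FiberMask(
        mask=image >= thr,
        provenance={"method": method, "threshold": thr},
    )


def clean_mask(
    mask: FiberMask | np.ndarray, min_object_px: int = 0, closing_radius_px: int = 0
) -> FiberMask:
    """Remove small foreground specks and close small gaps.

    Idempotent: re-applying with the same parameters is a no-op, and
    (0, 0) is the identity.
    """
    if min_object_px < 0 or closing_radius_px < 0:
        raise ValidationError("cleanup parameters must be non-negative")
    m, prov = _as_mask(mask)
    out = m.copy()
    if min_object_px > 0:
        # components strictly smaller than min_object_px are dropped
        out = morphology.remove_small_objects(out, max_size=min_object_px - 1)
    if closing_radius_px > 0:
        out = morphology.closing(out, morphology.disk(closing_radius_px))
        if min_object_px > 0:  # closing can merge but never shrink objects
            out = morphology.remove_small_objects(out, max_size=min_object_px - 1)
    prov = dict(prov)
    prov.update(
        {"min_object_px": int(min_object_px), "closing_radius_px": int(closing_radius_px)}
    )
    return FiberMask(mask=out, provenance=prov)


def _as_mask(mask) -> tuple[np.ndarray, dict]:
    if isinstance(mask, FiberMask):
        return mask.mask.astype(bool), mask.provenance
    return np.asarray(mask, dtype=bool), {}


def _degree(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbours of each skeleton pixel."""
    k = np.ones((3, 3), dtype=np.uint8)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(np.uint8), k, mode="constant") * skel


def _prune_spurs(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Delete endpoint branches shorter than prune_px that end at a junction.

    Free open paths (no junction) are never shortened; only thinning
    artifacts hanging off a longer centerline are removed.
    """
    if prune_px <= 0:
        return skel
    skel = skel.copy()
    H, W = skel.shape

    def deg(r, c):
        return sum(
            skel[r + dr, c + dc]
            for dr, dc in _NB8
            if 0 <= r + dr < H and 0 <= c + dc < W
        )

    changed = True
    while changed:
        changed = False
        dmap = _degree(skel)
        for r, c in np.argwhere(skel & (dmap == 1)):
            if not skel[r, c] or deg(r, c) != 1:
                continue
            branch = [(int(r), int(c))]
            prev, cur = None, (int(r), int(c))
            hit_junction = False
            while len(branch) <= prune_px:
                nxts = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _NB8
                    if 0 <= cur[0] + dr < H
                    and 0 <= cur[1] + dc < W
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if not nxts:
                    break
                if len(nxts) > 1:
                    hit_junction = True
                    break
                nxt = nxts[0]
                if deg(*nxt) >= 3:
                    hit_junction = True
                    break
                prev, cur = cur, nxt
                branch.append(cur)
            if hit_junction and len(branch) <= prune_px:
                for p in branch:
                    skel[p] = False
                changed = True
                # the stop pixel may now be a redundant stub: if its
                # remaining neighbours are mutually connected without it,
                # dropping it cannot disconnect anything
                stop = nxts[0] if nxts else None
                while stop is not None:
                    nb = [
                        (stop[0] + dr, stop[1] + dc)
                        for dr, dc in _NB8
                        if 0 <= stop[0] + dr < H
                        and 0 <= stop[1] + dc < W
                        and skel[stop[0] + dr, stop[1] + dc]
                    ]
                    if len(nb) >= 2 and _mutually_connected(nb):
                        skel[stop] = False
                        stop = None  # neighbours were a single arc; done
                    else:
                        stop = None
    return skel


def _mutually_connected(coords) -> bool:
    """True if the pixels form one 8-connected component among themselves."""
    remaining = set(coords)
    stack = [next(iter(remaining))]
    remaining.discard(stack[0])
    while stack:
        r, c = stack.pop()
        for dr, dc in _NB8:
            q = (r + dr, c + dc)
            if q in remaining:
                remaining.discard(q)
                stack.append(q)
    return not remaining


def skeletonize_mask(mask: FiberMask | np.ndarray, prune_px: int = 5) -> FiberSkeleton:
    """Topology-preserving thinning of a fiber mask to 1-px centerlines.

    Spur branches shorter than ``prune_px`` (thinning artifacts at fiber
    edges and junctions) are removed.  An empty mask yields an empty
    skeleton with zero length, not an error.
    """
    if prune_px < 0:
        raise ValidationError("prune_px must be non-negative")
    m, _ = _as_mask(mask)
    skel = morphology.skeletonize(m)
    skel = _prune_spurs(skel, prune_px)
    dmap = _degree(skel)
    border = np.zeros_like(skel)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return FiberSkeleton(
        pixels=skel,
        endpoints=skel & (dmap == 1),
        junctions=skel & (dmap >= 3),
        border_flagged=skel & ndi.binary_dilation(border, np.ones((3, 3))),
        total_length_px=_chain_length_px(skel),
        prune_px=prune_px,
    )


# Vossepoel-Smeulders weights: the minimum-bias linear estimator of digital
# straight-line length from axial/diagonal step counts.
_VS_AXIAL, _VS_DIAG = 0.948, 1.340


def _chain_length_px(skel: np.ndarray, metric: str = "chain") -> float:
    if metric == "pixel_count":
        return float(skel.sum())
    if metric == "chain":
        wa, wd = 1.0, _SQRT2
    elif metric == "corrected":
        wa, wd = _VS_AXIAL, _VS_DIAG
    else:
        raise ValidationError(f"unsupported length metric {metric!r}")
    ax = (skel[:, :-1] & skel[:, 1:]).sum() + (skel[:-1, :] & skel[1:, :]).sum()
    # A diagonal step is a path edge only when it is not a shortcut across
    # an axial corner: if the two pixels share an axial neighbour that is
    # itself on the skeleton, the axial edges already cover the step.
    d1 = skel[:-1, :-1] & skel[1:, 1:] & ~(skel[:-1, 1:] | skel[1:, :-1])
    d2 = skel[:-1, 1:] & skel[1:, :-1] & ~(skel[:-1, :-1] | skel[1:, 1:])
    return wa * float(ax) + wd * (float(d1.sum()) + float(d2.sum()))


def total_length(
    skeleton: FiberSkeleton, calibration: Calibration, metric: str = "chain"
) -> float:
    """Total centerline length in microns.

    ``chain`` sums each 8-adjacency edge once (1 px axial, sqrt(2) px
    diagonal); it is exact on axial and 45-degree digital lines but
    overestimates oblique ones by up to 8.2% (worst case at 22.5 degrees).
    ``corrected`` uses Vossepoel-Smeulders weights (0.948 / 1.340), the
    standard minimum-bias digital length estimator over orientations.
    ``pixel_count`` counts skeleton pixels at 1 px each, a compatibility
    convention some image-analysis workflows report.
    """
    return _chain_length_px(skeleton.pixels, metric) * calibration.um_per_px


def export_skeleton_json(skeleton: FiberSkeleton, path) -> None:
    """Write the skeleton as a JSON graph of typed nodes and weighted edges."""
    coords = np.argwhere(skeleton.pixels)
    index = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    nodes = []
    for r, c in map(tuple, coords):
        if skeleton.junctions[r, c]:
            kind = "junction"
        elif skeleton.endpoints[r, c]:
            kind = "end"
        else:
            kind = "regular"
        nodes.append({"row": int(r), "col": int(c), "type": kind})
    edges = []
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # each edge once
            j = index.get((r + dr, c + dc))
            if j is not None:
                edges.append([i, j, 1.0 if dr * dc == 0 else _SQRT2])
    Path(path).write_text(
        json.dumps(
            {"nodes": nodes, "edges": edges, "total_length_px": skeleton.total_length_px},
            sort_keys=True,
        )
    )


def export_skeleton_overlay(skeleton: FiberSkeleton, path) -> None:
    """Write the skeleton as a binary TIFF overlay (255 = centerline)."""
    tifffile.imwrite(path, skeleton.pixels.astype(np.uint8) * 255)
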