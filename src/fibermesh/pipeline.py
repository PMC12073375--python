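"""End-to-end measurement pipeline: image -> mask -> skeleton -> metrics.

run_measure chains calibration, binarization, cleanup, skeletonization,
local diameters, diameter statistics, pore distribution and surface-area
estimation with one validated, persisted configuration, so a measurement is
reproducible from its config.json alone.  run_compare puts two measured
samples side by side (normalized surface-area ratio, pore class fractions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from . import morphometry, segmentation
from .errors import ValidationError

__all__ = ["RunConfig", "MetricsBundle", "run_measure", "run_compare", "write_bundle"]

log = logging.getLogger("fibermesh")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one measurement run; persisted verbatim beside outputs."""

    um_per_px: float | None = None
    bar_length_px: float | None = None
    bar_label_um: float | None = None
    method: str = "otsu"
    fixed_threshold: float | None = None
    min_object_px: int = 16
    closing_radius_px: int = 0
    prune_px: int = 5
    radius_correction_px: float = 0.0
    mode: str = "mean_diameter"
    bin_width_um: float = 0.1
    pore_bins_um: tuple = morphometry.DEFAULT_PORE_BINS_UM
    min_n: int = 100
    length_metric: str = "chain"
    sample_id: str = "sample"
    seed: int = 0

    def calibration(self) -> fio.Calibration:
        if self.um_per_px is not None:
            return fio.Calibration(um_per_px=self.um_per_px)
        if self.bar_length_px is not None and self.bar_label_um is not None:
            return fio.calibrate(self.bar_length_px, self.bar_label_um)
        raise ValidationError(
            "config needs um_per_px or both bar_length_px and bar_label_um"
        )

    def validate(self) -> None:
        self.calibration()
        if self.method not in ("otsu", "fixed"):
            raise ValidationError(f"unsupported binarization method {self.method!r}")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed_threshold is required with method='fixed'")
        if self.min_object_px < 0 or self.closing_radius_px < 0 or self.prune_px < 0:
            raise ValidationError("cleanup/prune parameters must be non-negative")
        if self.mode not in ("mean_diameter", "per_pixel"):
            raise ValidationError(f"unsupported surface-area mode {self.mode!r}")
        if self.length_metric not in ("chain", "corrected", "pixel_count"):
            raise ValidationError(f"unsupported length metric {self.length_metric!r}")
        if not self.bin_width_um > 0:
            raise ValidationError("bin_width_um must be positive")
        if self.min_n < 1:
            raise ValidationError("min_n must be >= 1")


@dataclass
class MetricsBundle:
    """Everything one measurement run produced."""

    sample_id: str
    calibration: fio.Calibration
    config: RunConfig
    mask: segmentation.FiberMask
    skeleton: segmentation.FiberSkeleton
    diameters: morphometry.DiameterSamples
    fiber_stats: morphometry.FiberStats
    pore_table: morphometry.PoreTable
    surface: morphometry.SurfaceAreaEstimate


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
                raise

        return wrapped

    return deco


def run_measure(
    image, config: RunConfig, out_dir: str | Path | None = None
) -> MetricsBundle:
    """Measure one micrograph end to end.

    ``image`` is a path or an in-memory [0,1] array.  Deterministic for
    fixed inputs; if ``out_dir`` is given, all metric files plus the
    verbatim config are written there atomically.
    """
    config.validate()
    cal = config.calibration()
    if isinstance(image, (str, Path)):
        img, meta = _stage("load_image")(fio.load_image)(image)
        log.info("loaded %s %s", meta["path"], meta["shape"])
    else:
        img = np.asarray(image, dtype=float)

    mask = _stage("binarize")(segmentation.binarize)(
        img, method=config.method, fixed_threshold=config.fixed_threshold
    )
    log.info("binarized: threshold=%s", mask.provenance.get("threshold"))
    mask = _stage("clean_mask")(segmentation.clean_mask)(
        mask, config.min_object_px, config.closing_radius_px
    )
    skel = _stage("skeletonize")(segmentation.skeletonize_mask)(
        mask, prune_px=config.prune_px
    )
    diam = _stage("local_diameters")(morphometry.local_diameters)(
        mask, skel, cal, radius_correction_px=config.radius_correction_px
    )
    stats = _stage("fiber_stats")(morphometry.fiber_stats)(
        diam, min_n=config.min_n, bin_width_um=config.bin_width_um
    )
    pores = _stage("pore_distribution")(morphometry.pore_distribution)(
        mask, cal, bins_um=config.pore_bins_um
    )
    surface = _stage("total_surface_area")(morphometry.total_surface_area)(
        skel, diam, cal, mode=config.mode
    )
    if config.length_metric != "chain":
        length = segmentation.total_length(skel, cal, metric=config.length_metric)
        surface = dataclasses.replace(surface, total_length_um=length)
    bundle = MetricsBundle(
        sample_id=config.sample_id,
        calibration=cal,
        config=config,
        mask=mask,
        skeleton=skel,
        diameters=diam,
        fiber_stats=stats,
        pore_table=pores,
        surface=surface,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: MetricsBundle, out_dir: str | Path) -> None:
    """Persist a metrics bundle: config, fiber stats, pores, surface."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(bundle.config)
    cfg["pore_bins_um"] = list(bundle.config.pore_bins_um)
    fio._atomic_write_text(out / "config.json", json.dumps(cfg, sort_keys=True))

    st = bundle.fiber_stats
    fio.write_metrics(
        [
            {
                "sample_id": bundle.sample_id,
                "n": st.n,
                "mean_um": st.mean_um,
                "sd_um": st.sd_um,
                "median_um": st.median_um,
                "positively_skewed": st.positively_skewed,
                "n_excluded": st.n_excluded,
                "min_n_warning": st.min_n_warning,
            }
        ],
        out / "fiber_stats.csv",
        columns=fio.FIBER_STATS_COLUMNS,
    )
    hist = {
        "bin_edges_um": st.bin_edges_um.tolist(),
        "counts": st.counts.tolist(),
    }
    fio._atomic_write_text(out / "fiber_histogram.json", json.dumps(hist, sort_keys=True))

    pt = bundle.pore_table
    fio.write_metrics(
        [
            {"area_um2": float(a), "equivalent_diameter_um": float(d)}
            for a, d in zip(pt.areas_um2, pt.equivalent_diameters_um)
        ],
        out / "pores.csv",
        columns=["area_um2", "equivalent_diameter_um"],
    )
    fio._atomic_write_text(
        out / "pore_classes.json",
        json.dumps(
            {
                "bins_um": list(pt.bins_um),
                "class_area_fractions": pt.class_area_fractions.tolist(),
                "border_excluded_count": pt.border_excluded_count,
                "border_excluded_area_px": pt.border_excluded_area_px,
                "included_area_px": pt.included_area_px,
                "fiber_area_px": pt.fiber_area_px,
            },
            sort_keys=True,
        ),
    )
    sf = bundle.surface
    fio._atomic_write_text(
        out / "surface.json",
        json.dumps(
            {
                "A_star_um": sf.A_star_um,
                "total_length_um": sf.total_length_um,
                "total_area_um2": sf.total_area_um2,
                "normalized": sf.normalized,
                "mode": sf.mode,
                "um_per_px": sf.um_per_px,
            },
            sort_keys=True,
        ),
    )


def run_compare(bundle_a: MetricsBundle, bundle_b: MetricsBundle) -> dict:
    """Side-by-side report of two measured samples.

    Requires matching calibrations (same um/px) so all columns share units.
    """
    ua, ub = bundle_a.calibration.um_per_px, bundle_b.calibration.um_per_px
    if not np.isclose(ua, ub, rtol=1e-9):
        raise ValidationError(
            f"unit mismatch: calibrations differ ({ua} vs {ub} um/px)"
        )
    if tuple(bundle_a.pore_table.bins_um) != tuple(bundle_b.pore_table.bins_um):
        raise ValidationError("unit mismatch: pore class bins differ")
    ratio = morphometry.compare_surface_areas(bundle_a.surface, bundle_b.surface)
    return {
        "surface_area_ratio": ratio,
        "samples": {
            "a": _summary(bundle_a),
            "b": _summary(bundle_b),
        },
        "pore_bins_um": list(bundle_a.pore_table.bins_um),
    }


def _summary(b: MetricsBundle) -> dict:
    return {
        "sample_id": b.sample_id,
        "n": b.fiber_stats.n,
        "mean_um": b.fiber_stats.mean_um,
        "sd_um": b.fiber_stats.sd_um,
        "median_um": b.fiber_stats.median_um,
        "positively_skewed": bool(b.fiber_stats.positively_skewed),
        "normalized_surface_area": b.surface.normalized,
        "total_length_um": b.surface.total_length_um,
        "pore_class_area_fractions": b.pore_table.class_area_fractions.tolist(),
    }
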