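"""VRI measurement from a single OCT B-scan.

The pipeline mirrors the automated vitreous-analysis procedure used with
Spectralis macular scans:

1. binarise the image (Otsu by default) and apply a morphological opening
   to segment the retina/RPE complex as one bright band;
2. take the lowest rows of the segmented band per column as the RPE;
3. build a vitreous patch: everything above the inner retinal boundary
   (with a safety margin), restricted to the central columns, excluding
   any tissue;
4. VRI = mean vitreous-patch intensity / mean RPE intensity.

Normalising by the RPE makes the ratio invariant to global signal-strength
changes (e.g. media opacity): scaling the whole image by a constant leaves
the VRI unchanged.  Every stage reports failure through the result object
instead of raising, so a batch run never aborts on a single bad scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, opening

from .synthetic import AcquisitionSetting, BScan

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "VRIMeasurement",
    "segment_retina",
    "locate_rpe",
    "build_vitreous_patch",
    "compute_vri",
    "analyse_bscan",
    "analyse_batch",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Free parameters of the segmentation and patch construction.

    threshold_method : "otsu" or "fixed" (with ``threshold_value``).
    opening_radius : radius (px) of the disc structuring element; removes
        speckle islands smaller than retinal structures.
    min_column_coverage : fraction of image columns the segmented band must
        span for the segmentation to count as successful.
    rpe_band_thickness : rows taken from the lower edge of the tissue mask
        per column as the RPE band.
    patch_margin : rows kept clear above the inner retinal boundary.
    lateral_crop_fraction : central fraction of columns retained for the
        vitreous patch.
    min_patch_pixels : minimum patch size for a valid measurement.
    max_foreground_fraction : a thresholded foreground larger than this
        fraction of the image means the threshold separated the two dark
        classes (frame background vs vitreous) rather than dark from
        tissue; Otsu is then re-applied within the foreground.  The retina
        band never fills half a macular B-scan.
    inverse_gamma : optional exponent g; when set, pixel values are mapped
        through ``x**g`` before analysis to undo display gamma encoding.
    """

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    opening_radius: int = 5
    min_column_coverage: float = 0.6
    rpe_band_thickness: int = 6
    patch_margin: int = 10
    lateral_crop_fraction: float = 0.6
    min_patch_pixels: int = 500
    max_foreground_fraction: float = 0.5
    inverse_gamma: float | None = None

    def __post_init__(self) -> None:
        if self.opening_radius < 1:
            raise ValueError("opening_radius must be >= 1")
        if not 0 < self.lateral_crop_fraction <= 1:
            raise ValueError("lateral_crop_fraction must be in (0, 1]")
        if not 0 < self.min_column_coverage <= 1:
            raise ValueError("min_column_coverage must be in (0, 1]")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")


@dataclass
class SegmentationResult:
    """Masks and per-column inner boundary produced by the segmentation."""

    tissue_mask: np.ndarray
    rpe_mask: np.ndarray | None = None
    vitreous_patch_mask: np.ndarray | None = None
    inner_boundary: np.ndarray | None = None  # -1 where a column has no tissue
    success: bool = True
    failure_reason: str = ""


@dataclass(frozen=True)
class VRIMeasurement:
    """One VRI measurement; ``vri = vitreous_mean / rpe_mean`` when ok."""

    vitreous_mean: float = float("nan")
    rpe_mean: float = float("nan")
    vri: float = float("nan")
    status: str = "ok"  # "ok" | "failed"
    reason: str = ""
    subject: int = 0
    setting: AcquisitionSetting | None = None
    repetition: int = 1
    section: int = 1

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _prepare(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if cfg.inverse_gamma is not None:
        image = np.clip(image, 0.0, None) ** cfg.inverse_gamma
    return image


def segment_retina(image: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> SegmentationResult:
    """Segment the retina/RPE band: threshold, opening, largest component."""
    image = _prepare(image, cfg)
    h, w = image.shape
    empty = np.zeros((h, w), dtype=bool)

    if image.max() == image.min():
        return SegmentationResult(empty, success=False, failure_reason="no tissue detected")

    if cfg.threshold_method == "otsu":
        thr = threshold_otsu(image)
        for _ in range(3):  # guard: threshold must isolate tissue, not vitreous
            fg = image[image > thr]
            if fg.size / image.size <= cfg.max_foreground_fraction or fg.max() == fg.min():
                break
            thr = threshold_otsu(fg)
    else:
        thr = float(cfg.threshold_value)
    binary = image > thr
    opened = opening(binary, disk(cfg.opening_radius))
    if not opened.any():
        return SegmentationResult(empty, success=False, failure_reason="no tissue detected")

    labels = label(opened)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    tissue = labels == largest

    column_has_tissue = tissue.any(axis=0)
    coverage = column_has_tissue.mean()
    inner = np.where(column_has_tissue, tissue.argmax(axis=0), -1)

    if coverage < cfg.min_column_coverage:
        return SegmentationResult(
            tissue,
            inner_boundary=inner,
            success=False,
            failure_reason=f"tissue spans only {coverage:.0%} of columns",
        )
    return SegmentationResult(tissue, inner_boundary=inner)


def locate_rpe(seg: SegmentationResult, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """RPE band: the lowest ``rpe_band_thickness`` tissue rows per column."""
    if not seg.success:
        raise ValueError("cannot locate RPE on a failed segmentation")
    tissue = seg.tissue_mask
    if not tissue.any():
        raise ValueError("cannot locate RPE in an empty tissue mask")
    # rank of each tissue pixel counted from the bottom of its column
    from_bottom = np.cumsum(tissue[::-1], axis=0)[::-1]
    rpe = tissue & (from_bottom <= cfg.rpe_band_thickness)
    seg.rpe_mask = rpe
    return rpe


def build_vitreous_patch(
    image: np.ndarray,
    seg: SegmentationResult,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Vitreous patch: above the inner boundary minus a margin, centre columns only.

    Sets ``seg.success = False`` (with a reason) when fewer than
    ``cfg.min_patch_pixels`` pixels survive.
    """
    if not seg.success:
        raise ValueError("cannot build a patch on a failed segmentation")
    h, w = seg.tissue_mask.shape
    inner = seg.inner_boundary
    rows = np.arange(h)[:, None]

    ceiling = np.where(inner >= 0, inner - cfg.patch_margin, 0)
    patch = rows < ceiling[None, :]

    c0 = int(round(w * (1 - cfg.lateral_crop_fraction) / 2))
    c1 = w - c0
    keep = np.zeros(w, dtype=bool)
    keep[c0:c1] = True
    patch &= keep[None, :]
    patch &= ~seg.tissue_mask

    if patch.sum() < cfg.min_patch_pixels:
        seg.success = False
        seg.failure_reason = (
            f"vitreous patch too small ({int(patch.sum())} < {cfg.min_patch_pixels} px)"
        )
    seg.vitreous_patch_mask = patch
    return patch


def compute_vri(image: np.ndarray, seg: SegmentationResult) -> VRIMeasurement:
    """Mean patch and RPE intensities and their ratio."""
    if seg.rpe_mask is None or seg.vitreous_patch_mask is None:
        raise ValueError("segmentation is missing RPE or patch masks")
    image = np.asarray(image, dtype=float)
    if not seg.vitreous_patch_mask.any() or not seg.rpe_mask.any():
        return VRIMeasurement(status="failed", reason="empty patch or RPE mask")
    vit = float(image[seg.vitreous_patch_mask].mean())
    rpe = float(image[seg.rpe_mask].mean())
    if rpe == 0:
        return VRIMeasurement(vitreous_mean=vit, rpe_mean=rpe, status="failed",
                              reason="zero RPE signal")
    return VRIMeasurement(vitreous_mean=vit, rpe_mean=rpe, vri=vit / rpe)


def analyse_bscan(
    scan: BScan | np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> VRIMeasurement:
    """Full measurement on one B-scan; failures are reported, never raised."""
    if isinstance(scan, BScan):
        image = scan.pixels
        meta = dict(subject=scan.subject, setting=scan.setting,
                    repetition=scan.repetition, section=scan.section)
    else:
        image = scan
        meta = {}

    seg = segment_retina(image, cfg)
    if not seg.success:
        return VRIMeasurement(status="failed", reason=seg.failure_reason, **meta)
    locate_rpe(seg, cfg)
    build_vitreous_patch(image, seg, cfg)
    if not seg.success:
        return VRIMeasurement(status="failed", reason=seg.failure_reason, **meta)
    m = compute_vri(_prepare(image, cfg), seg)
    if not m.ok:
        return VRIMeasurement(status="failed", reason=m.reason, **meta)
    return VRIMeasurement(vitreous_mean=m.vitreous_mean, rpe_mean=m.rpe_mean,
                          vri=m.vri, **meta)


def analyse_batch(
    scans: Iterable[BScan | np.ndarray],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[VRIMeasurement]:
    """Analyse a batch; always returns exactly one measurement per scan."""
    return [analyse_bscan(s, cfg) for s in scans]
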