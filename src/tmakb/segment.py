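"""Epithelial masking (ROI #1) and nuclear segmentation (ROI #2).

The analysis region is built in two steps, mirroring the staining design:

1. the CK18/CK19/PSA cocktail channel defines the epithelial mask (ROI #1) —
   Gaussian smoothing, Otsu thresholding, morphological closing, small-hole
   filling and small-object removal;
2. DAPI is thresholded *inside* the mask and touching nuclei are split with a
   distance-transform watershed, yielding labeled nuclear objects (ROI #2)
   filtered to a plausible area range.

Per-nucleus mean intensities for the RelB and p65 channels are measured over
each nucleus's pixels; these feed the positivity scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import regionprops_table

from tmakb.images import CoreImage

__all__ = [
    "MaskConfig",
    "SegConfig",
    "QCConfig",
    "EpithelialMask",
    "NucleusSet",
    "QCReport",
    "build_epithelial_mask",
    "segment_nuclei",
    "qc_core",
]


@dataclass
class MaskConfig:
    """Epithelial-mask parameters.

    ``max_hole_area`` deliberately stays small so gland lumens — genuine
    non-epithelial space — are not swallowed into the mask.
    """

    sigma: float = 2.0
    closing_radius: int = 2
    max_hole_area: int = 64
    min_area: int = 200


@dataclass
class SegConfig:
    """Nuclear segmentation parameters (areas in px for ~0.3 µm pixels)."""

    dapi_sigma: float = 1.0
    min_area: int = 10
    max_area: int = 500
    min_peak_distance: int = 4


@dataclass
class QCConfig:
    """Automated core-level quality gates (inclusive bounds)."""

    min_nuclei: int = 20
    min_epith_fraction: float = 0.02


@dataclass
class EpithelialMask:
    """ROI #1: boolean epithelial raster."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class NucleusSet:
    """ROI #2: labeled nuclei plus per-nucleus measurements.

    ``labels`` is an integer raster (0 background, k > 0 nucleus k, labels
    consecutive from 1).  ``records`` has one row per nucleus with columns
    ``nucleus_id, row, col, area_px, mean_dapi, mean_relb, mean_p65``.
    """

    labels: np.ndarray
    records: pd.DataFrame

    @property
    def n_nuclei(self) -> int:
        return int(len(self.records))

    def mean_intensities(self, channel: str) -> np.ndarray:
        return self.records[f"mean_{channel}"].to_numpy(dtype=float)


@dataclass
class QCReport:
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    n_nuclei: int = 0
    epith_fraction: float | None = None


_EMPTY_RECORDS = pd.DataFrame(
    columns=["nucleus_id", "row", "col", "area_px", "mean_dapi", "mean_relb", "mean_p65"]
)


def build_epithelial_mask(core: CoreImage, cfg: MaskConfig | None = None) -> EpithelialMask:
    """Derive ROI #1 from the epithelial-cocktail channel.

    Pipeline: Gaussian smooth → Otsu threshold → binary closing → fill holes
    up to ``max_hole_area`` → drop components below ``min_area``.  A channel
    with no contrast (e.g. all zero) yields an empty mask.
    """
    cfg = cfg or MaskConfig()
    if "epithelium" not in core.channels:
        raise ValueError("core image lacks an 'epithelium' channel")
    img = core.channels["epithelium"]
    smoothed = ndimage.gaussian_filter(img, cfg.sigma) if cfg.sigma > 0 else img
    if np.ptp(smoothed) < 1e-9:
        return EpithelialMask(mask=np.zeros(img.shape, dtype=bool))
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    if cfg.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(cfg.closing_radius))
    if cfg.max_hole_area > 0:
        mask = morphology.remove_small_holes(mask, max_size=cfg.max_hole_area)
    if cfg.min_area > 1:
        mask = morphology.remove_small_objects(mask, max_size=cfg.min_area - 1)
    return EpithelialMask(mask=mask)


def segment_nuclei(
    core: CoreImage, mask: EpithelialMask, cfg: SegConfig | None = None
) -> NucleusSet:
    """Segment DAPI nuclei restricted to ROI #1.

    Touching nuclei are split by a watershed seeded at distance-transform
    maxima; boundary pixels belong to the label the watershed assigns (ties
    resolved by lower label id through the deterministic flooding order).
    Components outside ``[min_area, max_area]`` are discarded and the
    remaining labels are renumbered consecutively from 1.

    An empty mask returns an empty :class:`NucleusSet` rather than an error.
    """
    cfg = cfg or SegConfig()
    if mask.shape != core.shape:
        raise ValueError("mask dimensions do not match image")
    dapi = core.channels["dapi"]
    empty = NucleusSet(
        labels=np.zeros(core.shape, dtype=np.int32), records=_EMPTY_RECORDS.copy()
    )
    if mask.area_px == 0:
        return empty

    smoothed = ndimage.gaussian_filter(dapi, cfg.dapi_sigma) if cfg.dapi_sigma > 0 else dapi
    inside = smoothed[mask.mask]
    if np.ptp(inside) < 1e-9:
        return empty
    thr = filters.threshold_otsu(inside)
    binary = (smoothed > thr) & mask.mask
    if not binary.any():
        return empty

    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=cfg.min_peak_distance, labels=binary, exclude_border=False
    )
    if len(peaks) == 0:
        markers, _ = ndimage.label(binary)
    else:
        seed_mask = np.zeros_like(binary, dtype=bool)
        seed_mask[tuple(peaks.T)] = True
        markers, _ = ndimage.label(seed_mask)
    labels = segmentation.watershed(-distance, markers, mask=binary)

    # area filter, then relabel consecutively
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(counts >= cfg.min_area) & (counts <= cfg.max_area)]
    filtered = np.where(np.isin(labels, keep), labels, 0)
    relabeled = np.zeros_like(filtered, dtype=np.int32)
    for new_id, old_id in enumerate(sorted(keep), start=1):
        relabeled[filtered == old_id] = new_id
    if relabeled.max() == 0:
        return empty

    props = regionprops_table(
        relabeled,
        properties=("label", "centroid", "area"),
    )
    records = pd.DataFrame(
        {
            "nucleus_id": props["label"],
            "row": props["centroid-0"],
            "col": props["centroid-1"],
            "area_px": props["area"].astype(int),
        }
    )
    index = np.arange(1, relabeled.max() + 1)
    for channel in ("dapi", "relb", "p65"):
        if channel in core.channels:
            means = ndimage.mean(core.channels[channel], labels=relabeled, index=index)
            records[f"mean_{channel}"] = np.asarray(means, dtype=float)
        else:
            records[f"mean_{channel}"] = np.nan
    records = records.sort_values("nucleus_id", ignore_index=True)
    return NucleusSet(labels=relabeled, records=records)


def qc_core(
    nuclei: NucleusSet,
    cfg: QCConfig | None = None,
    mask: EpithelialMask | None = None,
    core_area_px: int | None = None,
) -> QCReport:
    """Automated surrogate for the manual core review.

    Cores are excluded when they carry fewer than ``min_nuclei`` nuclei
    (inclusive bound: exactly ``min_nuclei`` passes) or, when the mask is
    supplied, when the epithelial area is below ``min_epith_fraction`` of the
    core area.
    """
    cfg = cfg or QCConfig()
    reasons: list[str] = []
    if nuclei.n_nuclei < cfg.min_nuclei:
        reasons.append("insufficient_nuclei")
    epith_fraction = None
    if mask is not None:
        total = core_area_px if core_area_px is not None else mask.mask.size
        epith_fraction = mask.area_px / total if total else 0.0
        if epith_fraction < cfg.min_epith_fraction:
            reasons.append("insufficient_epithelium")
    return QCReport(
        excluded=bool(reasons),
        reasons=reasons,
        n_nuclei=nuclei.n_nuclei,
        epith_fraction=epith_fraction,
    )
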