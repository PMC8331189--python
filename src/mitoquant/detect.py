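"""Puncta detection and classification.

The detection scheme mirrors standard ratio-image double thresholding:

1. both reporter channels are despeckled with a fine (median) filter;
2. a red/green ratio image is built with a +1 pseudocount and a hard cap;
3. *mitolysosomes* are pixels with a high ratio AND a high red intensity,
   inside the region of interest, grouped into connected components;
4. for the general-autophagy reporter, high-intensity red components are
   split by their mean ratio into *autophagosomes* (low ratio) and
   *autolysosomes* (high ratio).

Thresholds are held in one :class:`ThresholdConfig`, frozen per experiment
set; defaults are calibrated against the synthetic scenes, not taken from
any dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from mitoquant.images import ChannelImage, RatioImage, RegionMask

CLASS_MITOLYSOSOME = "mitolysosome"
CLASS_AUTOPHAGOSOME = "autophagosome"
CLASS_AUTOLYSOSOME = "autolysosome"


@dataclass
class ThresholdConfig:
    """Detection thresholds, frozen per organ / experiment set.

    green_thr
        Tissue/region detection threshold on the green channel.
    red_thr
        Second (red-intensity) threshold applied to high-ratio pixels.
    red_high_thr
        Candidate threshold on the red channel for the general-autophagy
        reporter.
    ratio_thr_high
        Ratio above which a pixel/object counts as acidified (red-only).
    """

    green_thr: float = 25.0
    red_thr: float = 100.0
    red_high_thr: float = 120.0
    ratio_thr_high: float = 2.0
    ratio_cap: float = 100.0
    min_area_px: int = 6
    connectivity: int = 8
    fine_filter_radius: int = 1

    def __post_init__(self) -> None:
        for name in ("green_thr", "red_thr", "red_high_thr", "ratio_thr_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.ratio_cap <= 1:
            raise ValueError("ratio_cap must be > 1")
        if self.fine_filter_radius < 1:
            raise ValueError("fine_filter_radius must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        return cls(**d)


@dataclass
class Punctum:
    """One detected object."""

    object_id: int
    pixels: np.ndarray  # (n, 2) row/col indices
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    mean_red: float
    mean_green: float
    mean_ratio: float
    object_class: str = CLASS_MITOLYSOSOME


@dataclass
class PunctaSet:
    """Detected objects plus provenance."""

    puncta: list[Punctum]
    pixel_size: float
    image_id: str = ""
    config: Optional[ThresholdConfig] = None
    region_role: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def count(self, object_class: Optional[str] = None) -> int:
        if object_class is None:
            return len(self.puncta)
        return sum(1 for p in self.puncta if p.object_class == object_class)

    def subset(self, object_class: str) -> "PunctaSet":
        return PunctaSet(
            puncta=[p for p in self.puncta if p.object_class == object_class],
            pixel_size=self.pixel_size,
            image_id=self.image_id,
            config=self.config,
            region_role=self.region_role,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": self.image_id,
                "object_id": p.object_id,
                "object_class": p.object_class,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "area_px": p.area_px,
                "area_um2": p.area_um2,
                "mean_red": p.mean_red,
                "mean_green": p.mean_green,
                "mean_ratio": p.mean_ratio,
            }
            for p in self.puncta
        ]
        columns = ["image_id", "object_id", "object_class", "centroid_row",
                   "centroid_col", "area_px", "area_um2", "mean_red",
                   "mean_green", "mean_ratio"]
        return pd.DataFrame(rows, columns=columns)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pixel-level operations
# ---------------------------------------------------------------------------


def fine_filter(channel: ChannelImage, radius: int = 1) -> ChannelImage:
    """Despeckle with a (2*radius+1)^2 median filter, edges replicated."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    smoothed = ndimage.median_filter(channel.data, size=size, mode="nearest")
    return channel.with_data(smoothed)


def compute_ratio_image(
    red: ChannelImage, green: ChannelImage, cap: float = 100.0
) -> RatioImage:
    """Pixelwise (red + 1) / (green + 1), capped at ``cap``.

    The pseudocount keeps the ratio finite and monotone where the green
    channel hits zero.
    """
    if red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {red.shape} vs {green.shape}")
    values = (red.data + 1.0) / (green.data + 1.0)
    np.minimum(values, cap, out=values)
    return RatioImage(values=values, pixel_size=red.pixel_size, cap=cap)


def threshold_mask(
    channel: ChannelImage, thr: float, role: str = "tissue"
) -> RegionMask:
    """Boolean mask of pixels >= ``thr``."""
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    return RegionMask(
        mask=channel.data >= thr,
        pixel_size=channel.pixel_size,
        role=role,
        source=f"{channel.role}>={thr:g}",
    )


def _label(candidates: np.ndarray, connectivity: int) -> np.ndarray:
    # skimage connectivity: 1 = 4-neighbour, 2 = 8-neighbour
    return measure.label(candidates, connectivity=1 if connectivity == 4 else 2)


def _components_to_puncta(
    labels: np.ndarray,
    red: ChannelImage,
    green: Optional[ChannelImage],
    ratio: Optional[RatioImage],
    min_area_px: int,
) -> list[Punctum]:
    puncta: list[Punctum] = []
    px = red.pixel_size
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        coords = region.coords
        rr, cc = coords[:, 0], coords[:, 1]
        mean_red = float(red.data[rr, cc].mean())
        mean_green = float(green.data[rr, cc].mean()) if green is not None else float("nan")
        mean_ratio = float(ratio.values[rr, cc].mean()) if ratio is not None else float("nan")
        puncta.append(Punctum(
            object_id=len(puncta),
            pixels=coords,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            area_px=int(region.area),
            area_um2=float(region.area) * px**2,
            mean_red=mean_red,
            mean_green=mean_green,
            mean_ratio=mean_ratio,
        ))
    return puncta


def _check_registration(*shapes: tuple[int, int]) -> None:
    if len({s for s in shapes}) > 1:
        raise ValueError(f"inputs are not co-registered: shapes {shapes}")


def detect_mitolysosomes(
    ratio: RatioImage,
    red: ChannelImage,
    region: RegionMask,
    cfg: ThresholdConfig,
    green: Optional[ChannelImage] = None,
    image_id: str = "",
) -> PunctaSet:
    """Double-threshold mitolysosome detection.

    Candidate pixels satisfy ``ratio >= ratio_thr_high`` AND
    ``red >= red_thr`` inside ``region``; connected components at
    ``cfg.connectivity`` with at least ``min_area_px`` pixels become
    mitolysosome puncta.  An empty region yields an empty set with a
    warning record rather than an exception.
    """
    _check_registration(ratio.shape, red.shape, region.shape)
    warnings: list[str] = []
    if not region.mask.any():
        warnings.append("empty region mask: no pixels eligible for detection")
    candidates = (
        (ratio.values >= cfg.ratio_thr_high)
        & (red.data >= cfg.red_thr)
        & region.mask
    )
    labels = _label(candidates, cfg.connectivity)
    puncta = _components_to_puncta(labels, red, green, ratio, cfg.min_area_px)
    for p in puncta:
        p.object_class = CLASS_MITOLYSOSOME
    return PunctaSet(
        puncta=puncta,
        pixel_size=red.pixel_size,
        image_id=image_id,
        config=cfg,
        region_role=region.role,
        warnings=warnings,
    )


def detect_and_classify_auto_puncta(
    red: ChannelImage,
    ratio: RatioImage,
    region: RegionMask,
    cfg: ThresholdConfig,
    green: Optional[ChannelImage] = None,
    image_id: str = "",
    pixelwise: bool = False,
) -> PunctaSet:
    """Detect high-red objects and split them by acidification.

    Candidates are pixels with ``red >= red_high_thr`` inside ``region``.
    By default each connected component is classed as a whole: autolysosome
    if its mean ratio >= ``ratio_thr_high``, else autophagosome, so one
    object can never be counted in both classes.  ``pixelwise=True``
    instead partitions the candidate *pixels* by ratio before labelling,
    matching a strictly pixel-level thresholding workflow.
    """
    _check_registration(red.shape, ratio.shape, region.shape)
    warnings: list[str] = []
    if not region.mask.any():
        warnings.append("empty region mask: no pixels eligible for detection")
    candidates = (red.data >= cfg.red_high_thr) & region.mask

    puncta: list[Punctum] = []
    if pixelwise:
        high = candidates & (ratio.values >= cfg.ratio_thr_high)
        low = candidates & ~ (ratio.values >= cfg.ratio_thr_high)
        for mask, object_class in ((low, CLASS_AUTOPHAGOSOME),
                                   (high, CLASS_AUTOLYSOSOME)):
            labels = _label(mask, cfg.connectivity)
            part = _components_to_puncta(labels, red, green, ratio, cfg.min_area_px)
            for p in part:
                p.object_class = object_class
                p.object_id = len(puncta)
                puncta.append(p)
    else:
        labels = _label(candidates, cfg.connectivity)
        puncta = _components_to_puncta(labels, red, green, ratio, cfg.min_area_px)
        for p in puncta:
            p.object_class = (
                CLASS_AUTOLYSOSOME
                if p.mean_ratio >= cfg.ratio_thr_high
                else CLASS_AUTOPHAGOSOME
            )
    return PunctaSet(
        puncta=puncta,
        pixel_size=red.pixel_size,
        image_id=image_id,
        config=cfg,
        region_role=region.role,
        warnings=warnings,
    )


def count_per_cell(
    puncta: PunctaSet, cell_rois: Iterable[RegionMask]
) -> pd.DataFrame:
    """Assign puncta to cells by centroid membership.

    ROIs must be pairwise disjoint.  Returns one row per ROI (``cell_id``,
    ``n_puncta``) plus a final ``cell_id = -1`` row counting puncta outside
    every ROI.
    """
    rois = list(cell_rois)
    if rois:
        stack = np.zeros(rois[0].shape, dtype=np.int32)
        for roi in rois:
            if roi.shape != rois[0].shape:
                raise ValueError("ROI shapes differ")
            stack += roi.mask
        if stack.max() > 1:
            raise ValueError("cell ROIs overlap; they must be pairwise disjoint")
    counts = [0] * len(rois)
    outside = 0
    for p in puncta:
        row = int(round(p.centroid[0]))
        col = int(round(p.centroid[1]))
        for i, roi in enumerate(rois):
            if roi.mask[row, col]:
                counts[i] += 1
                break
        else:
            outside += 1
    rows = [{"cell_id": i, "n_puncta": c} for i, c in enumerate(counts)]
    rows.append({"cell_id": -1, "n_puncta": outside})
    return pd.DataFrame(rows, columns=["cell_id", "n_puncta"])
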