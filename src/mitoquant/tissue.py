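"""Cell-type-resolved measurement and normalization.

Takes detected puncta plus immunolabel channels and produces per-image
records: counts restricted to a stained population, densities per um^2 of
staining, counts per cell body, and object-based colocalization
percentages.  Missing denominators (zero stained area, zero cells, empty
puncta sets) are flagged as missing values (NaN), never raised as
division errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from skimage import measure

from mitoquant.detect import (
    CLASS_AUTOLYSOSOME,
    CLASS_AUTOPHAGOSOME,
    PunctaSet,
)
from mitoquant.images import ChannelImage, RegionMask


@dataclass
class QuantRecord:
    """Per-image quantitation row."""

    image_id: str
    subject_id: str = ""
    genotype: str = "WT"
    treatment: str = "none"
    cell_type: str = ""
    n_mitolysosomes: int = 0
    n_autophagosomes: int = 0
    n_autolysosomes: int = 0
    stained_area_um2: float = float("nan")
    n_cell_bodies: int = 0
    mitolysosomes_per_um2: float = float("nan")
    mitolysosomes_per_cell: float = float("nan")
    autophagosomes_per_um2: float = float("nan")
    autolysosomes_per_um2: float = float("nan")
    pct_autophagosomes_colocalized: float = float("nan")
    pct_autolysosomes_colocalized: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "subject_id": self.subject_id,
            "genotype": self.genotype,
            "treatment": self.treatment,
            "cell_type": self.cell_type,
            "n_mitolysosomes": self.n_mitolysosomes,
            "n_autophagosomes": self.n_autophagosomes,
            "n_autolysosomes": self.n_autolysosomes,
            "stained_area_um2": self.stained_area_um2,
            "n_cell_bodies": self.n_cell_bodies,
            "mitolysosomes_per_um2": self.mitolysosomes_per_um2,
            "mitolysosomes_per_cell": self.mitolysosomes_per_cell,
            "autophagosomes_per_um2": self.autophagosomes_per_um2,
            "autolysosomes_per_um2": self.autolysosomes_per_um2,
            "pct_autophagosomes_colocalized": self.pct_autophagosomes_colocalized,
            "pct_autolysosomes_colocalized": self.pct_autolysosomes_colocalized,
        }


def records_to_dataframe(records: Iterable[QuantRecord]) -> pd.DataFrame:
    rows = [r.to_dict() for r in records]
    columns = list(QuantRecord("x").to_dict().keys())
    return pd.DataFrame(rows, columns=columns)


@dataclass
class OverlapRule:
    """Object-level colocalization rule.

    An object colocalizes with a mask when it shares at least
    ``min_pixels`` pixels with it, and (if set) at least ``min_fraction``
    of its own area.
    """

    min_pixels: int = 1
    min_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.min_fraction is not None and not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")

    def matches(self, overlap_px: int, area_px: int) -> bool:
        if overlap_px < self.min_pixels:
            return False
        if self.min_fraction is not None and overlap_px < self.min_fraction * area_px:
            return False
        return True


def cell_type_mask(label: ChannelImage, thr: float) -> RegionMask:
    """Label-positive pixels as a ``cell_type_stain`` mask."""
    if label is None:
        raise ValueError("label channel is missing")
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    return RegionMask(
        mask=label.data >= thr,
        pixel_size=label.pixel_size,
        role="cell_type_stain",
        source=f"label>={thr:g}",
    )


def count_cell_bodies(
    mask: RegionMask,
    min_soma_area_um2: float = 30.0,
    max_soma_area_um2: float = 700.0,
    connectivity: int = 8,
) -> int:
    """Connected stain components with soma-scale area.

    Components whose calibrated area lies in
    [``min_soma_area_um2``, ``max_soma_area_um2``] are counted as cell
    bodies.
    """
    if mask.role not in ("cell_type_stain", "cell_body"):
        raise ValueError(f"mask role {mask.role!r} is not a stain/cell-body mask")
    if min_soma_area_um2 > max_soma_area_um2:
        raise ValueError("min_soma_area_um2 exceeds max_soma_area_um2")
    labels = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    px2 = mask.pixel_size**2
    n = 0
    for region in measure.regionprops(labels):
        area = region.area * px2
        if min_soma_area_um2 <= area <= max_soma_area_um2:
            n += 1
    return n


def normalize_per_area(count: int, mask: RegionMask) -> float:
    """Objects per um^2 of the mask; NaN when the mask is empty."""
    if count < 0:
        raise ValueError("count must be >= 0")
    area = mask.area_um2
    if area <= 0:
        return float("nan")
    return count / area


def normalize_per_cell(count: int, n_cells: int) -> float:
    """Objects per cell body; NaN when no cells were found."""
    if count < 0 or n_cells < 0:
        raise ValueError("count and n_cells must be >= 0")
    if n_cells == 0:
        return float("nan")
    return count / n_cells


def colocalize_puncta_with_mask(
    puncta: PunctaSet,
    mito_mask: RegionMask,
    rule: Optional[OverlapRule] = None,
    classes: tuple[str, ...] = (CLASS_AUTOPHAGOSOME, CLASS_AUTOLYSOSOME),
) -> pd.DataFrame:
    """Object-based colocalization against a thresholded mask.

    Returns one row per class: ``object_class``, ``n_total``,
    ``n_colocalized``, ``pct_colocalized`` (= 100 * colocalized / total,
    NaN when the class has no objects).
    """
    rule = rule or OverlapRule()
    rows = []
    for object_class in classes:
        total = 0
        coloc = 0
        for p in puncta:
            if p.object_class != object_class:
                continue
            total += 1
            rr, cc = p.pixels[:, 0], p.pixels[:, 1]
            overlap = int(mito_mask.mask[rr, cc].sum())
            if rule.matches(overlap, p.area_px):
                coloc += 1
        pct = 100.0 * coloc / total if total > 0 else float("nan")
        rows.append({
            "object_class": object_class,
            "n_total": total,
            "n_colocalized": coloc,
            "pct_colocalized": pct,
        })
    return pd.DataFrame(
        rows, columns=["object_class", "n_total", "n_colocalized", "pct_colocalized"]
    )
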