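"""Raster containers shared by every pipeline stage.

All rasters are 2D, row-major, 0-based.  Calibration (``pixel_size`` in
micrometres per pixel) travels with every raster so areas can always be
reported in both px and um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHANNEL_ROLES = ("red", "green", "label", "nuclei")
MASK_ROLES = ("tissue", "cell_type_stain", "cell_body", "single_cell_roi")


@dataclass
class ChannelImage:
    """A single fluorescence channel with calibration.

    Parameters
    ----------
    data:
        2D array of non-negative, finite intensities.
    pixel_size:
        Micrometres per pixel (> 0), identical in both axes.
    role:
        One of ``red``, ``green``, ``label``, ``nuclei``.
    """

    data: np.ndarray
    pixel_size: float
    role: str = "red"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"channel must be 2D, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("channel is empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("channel contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("channel contains negative intensities")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ChannelImage":
        """Same calibration/role, new raster."""
        return ChannelImage(data=data, pixel_size=self.pixel_size, role=self.role)


@dataclass
class ReporterImage:
    """Co-registered reporter channels plus experiment metadata.

    ``red`` and ``green`` are mandatory (the tandem tag); ``label`` is the
    optional immunostain channel and ``nuclei`` the optional counterstain.
    """

    red: ChannelImage
    green: ChannelImage
    label: Optional[ChannelImage] = None
    nuclei: Optional[ChannelImage] = None
    image_id: str = ""
    subject_id: str = ""
    genotype: str = "WT"
    treatment: str = "none"

    def __post_init__(self) -> None:
        for ch in self.channels().values():
            if ch.shape != self.red.shape:
                raise ValueError("all channels must share one shape")
            if ch.pixel_size != self.red.pixel_size:
                raise ValueError("all channels must share one pixel size")

    def channels(self) -> dict[str, ChannelImage]:
        out = {"red": self.red, "green": self.green}
        if self.label is not None:
            out["label"] = self.label
        if self.nuclei is not None:
            out["nuclei"] = self.nuclei
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def pixel_size(self) -> float:
        return self.red.pixel_size


@dataclass
class RatioImage:
    """Red/green ratio raster, bounded above by ``cap``."""

    values: np.ndarray
    pixel_size: float
    cap: float = 100.0
    rule: str = "pseudocount_plus1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratio image must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio image contains non-finite values")
        if np.any(self.values <= 0):
            raise ValueError("ratio image must be strictly positive")
        if np.any(self.values > self.cap + 1e-12):
            raise ValueError("ratio image exceeds its declared cap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class RegionMask:
    """Boolean region with a role and a calibrated area."""

    mask: np.ndarray
    pixel_size: float
    role: str = "tissue"
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    def intersect(self, other: "RegionMask", role: Optional[str] = None) -> "RegionMask":
        if other.shape != self.shape:
            raise ValueError("mask shapes differ")
        return RegionMask(
            mask=self.mask & other.mask,
            pixel_size=self.pixel_size,
            role=role or self.role,
            source=f"{self.source}&{other.source}",
        )
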