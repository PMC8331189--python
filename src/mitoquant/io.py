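"""Formats, configuration and reproducibility plumbing.

Scenes travel as OME-TIFF (channels in a declared order, calibration in
the OME pixel-size fields); tables as TSV/CSV; configuration as YAML; and
every pipeline run emits a manifest with a config hash and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from mitoquant.detect import ThresholdConfig
from mitoquant.images import ChannelImage, ReporterImage
from mitoquant.synthetic import SceneSpec

CHANNEL_WRITE_ORDER = ("red", "green", "label", "nuclei")


# ---------------------------------------------------------------------------
# OME-TIFF
# ---------------------------------------------------------------------------


def write_reporter_image(path, image: ReporterImage) -> list[str]:
    """Write the scene as one OME-TIFF, channels in declared order.

    Returns the channel-role order actually written.
    """
    channels = image.channels()
    order = [role for role in CHANNEL_WRITE_ORDER if role in channels]
    stack = np.stack([channels[role].data for role in order]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": image.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": order},
        },
    )
    return order


def _pixel_size_from_ome(tf: tifffile.TiffFile) -> Optional[float]:
    if not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            ps = el.get("PhysicalSizeX")
            if ps is not None:
                return float(ps)
    return None


def read_reporter_image(
    path,
    channel_order: Optional[dict[str, int]] = None,
    pixel_size: Optional[float] = None,
    image_id: str = "",
    subject_id: str = "",
    genotype: str = "WT",
    treatment: str = "none",
) -> ReporterImage:
    """Read a multi-channel TIFF/OME-TIFF into a :class:`ReporterImage`.

    ``channel_order`` maps roles to plane indices; when omitted, OME
    channel names are used.  Calibration comes from the OME pixel-size
    metadata unless ``pixel_size`` overrides it; an image with neither is
    a hard error (there is no silent default).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_pixel_size = _pixel_size_from_ome(tf)
        ome_names: list[str] = []
        if tf.ome_metadata:
            try:
                root = ET.fromstring(tf.ome_metadata)
                ome_names = [
                    el.get("Name", "")
                    for el in root.iter()
                    if el.tag.endswith("Channel")
                ]
            except ET.ParseError:
                pass

    if data.ndim == 2:
        raise ValueError(f"{path} has a single channel; need at least red and green")
    if data.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")

    if channel_order is None:
        if not ome_names:
            raise ValueError(
                f"{path}: no channel_order given and no OME channel names present"
            )
        channel_order = {name: i for i, name in enumerate(ome_names)}

    ps = pixel_size if pixel_size is not None else meta_pixel_size
    if ps is None:
        raise ValueError(
            f"{path}: no pixel-size calibration in metadata and no override given"
        )

    def _channel(role: str, required: bool) -> Optional[ChannelImage]:
        if role not in channel_order:
            if required:
                raise ValueError(f"{path}: channel role {role!r} missing from config")
            return None
        idx = channel_order[role]
        if idx >= data.shape[0]:
            raise ValueError(
                f"{path}: config maps {role!r} to plane {idx} but file has "
                f"{data.shape[0]} planes"
            )
        return ChannelImage(data[idx].astype(float), ps, role)

    return ReporterImage(
        red=_channel("red", required=True),
        green=_channel("green", required=True),
        label=_channel("label", required=False),
        nuclei=_channel("nuclei", required=False),
        image_id=image_id or path.stem,
        subject_id=subject_id,
        genotype=genotype,
        treatment=treatment,
    )


def write_mask_tiff(path, mask: np.ndarray) -> None:
    """Export a boolean mask as an 8-bit single-channel TIFF for audit."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class ArmSpec:
    """One experimental arm of a simulated study."""

    genotype: str = "WT"
    treatment: str = "none"
    n_subjects: int = 4
    n_images_per_subject: int = 3
    mito_count_mean: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_images_per_subject < 1:
            raise ValueError("arm needs >= 1 subject and >= 1 image per subject")
        if self.mito_count_mean < 0:
            raise ValueError("mito_count_mean must be >= 0")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML round-trips losslessly."""

    channel_order: dict[str, int] = field(
        default_factory=lambda: {"red": 0, "green": 1}
    )
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    trim_fraction: float = 0.2
    coloc_min_pixels: int = 1
    coloc_min_fraction: Optional[float] = None
    min_soma_area_um2: float = 30.0
    max_soma_area_um2: float = 700.0
    seed: int = 0
    out_dir: str = "results"
    scene: SceneSpec = field(default_factory=SceneSpec)
    arms: list[ArmSpec] = field(
        default_factory=lambda: [
            ArmSpec(genotype="WT"),
            ArmSpec(genotype="G2019S", mito_count_mean=1.5),
        ]
    )

    def __post_init__(self) -> None:
        for role in self.channel_order:
            if role not in CHANNEL_WRITE_ORDER:
                raise ValueError(f"unknown channel role {role!r} in channel_order")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if self.min_soma_area_um2 > self.max_soma_area_um2:
            raise ValueError("soma area window inverted")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        d["scene"] = self.scene.to_dict()
        d["arms"] = [dataclasses.asdict(a) for a in self.arms]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and not isinstance(d["thresholds"], ThresholdConfig):
            d["thresholds"] = ThresholdConfig.from_dict(d["thresholds"])
        if "scene" in d and not isinstance(d["scene"], SceneSpec):
            d["scene"] = SceneSpec.from_dict(d["scene"])
        if "arms" in d:
            d["arms"] = [
                a if isinstance(a, ArmSpec) else ArmSpec(**a) for a in d["arms"]
            ]
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    inputs: list[dict]  # {"path": ..., "sha256": ...}
    timestamp: Optional[str] = None  # omitted by default so runs stay byte-identical

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
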