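"""Synthetic reporter micrographs with per-object ground truth.

Renders the appearance of a tandem red/green reporter: structures emit in
both channels, but compartments that have been delivered to an acidic
organelle retain only a fraction ``quench_factor`` of their green signal.
Three scene flavours are provided:

- :func:`render_mef_scene` — cultured cells carrying a mitochondrial
  reporter: curvilinear mitochondrial networks plus red-only
  ("mitolysosome") puncta;
- :func:`render_tissue_scene` — the same, plus an immunolabel channel
  painting a subset of cell somata;
- :func:`render_autoqc_scene` — the general-autophagy reporter: diffuse
  cytosolic signal, red+green autophagosome puncta, red-only autolysosome
  puncta, and an optional mitochondria-immunolabel channel with a designed
  per-class overlap fraction.

Every object is recorded in a :class:`GroundTruth` table *before* optical
degradation (PSF blur, then Poisson + Gaussian noise); each degradation
stage can be switched off independently.  All randomness flows from
``SceneSpec.seed`` through named substreams (see :mod:`mitoquant.rng`);
per-cell object counts are drawn in a single vectorized call per class so
they can be re-drawn independently by an oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from mitoquant.images import ChannelImage, RegionMask, ReporterImage
from mitoquant.rng import substream

CLASS_NETWORK = "mitochondrion-network"
CLASS_MITOLYSOSOME = "mitolysosome"
CLASS_AUTOPHAGOSOME = "autophagosome"
CLASS_AUTOLYSOSOME = "autolysosome"

# substream names; oracles re-draw from these
STREAM_CELLS = "cells"
STREAM_NETWORK = "network"
STREAM_MITO_COUNTS = "mito_counts"
STREAM_AP_COUNTS = "autophagosome_counts"
STREAM_AL_COUNTS = "autolysosome_counts"
STREAM_PUNCTA = "puncta"
STREAM_LABEL = "label"
STREAM_OVERLAP = "overlap"
STREAM_NOISE = "noise"


class PlacementError(RuntimeError):
    """Requested objects cannot be placed in the given image."""


@dataclass
class CountDistribution:
    """Non-negative count distribution by mean and dispersion.

    ``dispersion`` is the variance-to-mean ratio.  ``None`` or 1 gives a
    Poisson; > 1 gives a negative binomial with matching mean/variance.
    ``mean`` may also encode a deterministic count when ``dispersion == 0``.
    """

    mean: float
    dispersion: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or self.mean < 0:
            raise ValueError(f"count mean must be finite and >= 0, got {self.mean}")
        if self.dispersion is not None and (
            not np.isfinite(self.dispersion) or self.dispersion < 0
        ):
            raise ValueError("dispersion must be finite and >= 0")
        if self.dispersion == 0 and self.mean != int(self.mean):
            raise ValueError("deterministic counts require an integer mean")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` counts in one vectorized call."""
        if self.dispersion == 0:
            return np.full(n, int(self.mean), dtype=int)
        if self.dispersion is None or self.dispersion == 1 or self.mean == 0:
            return rng.poisson(self.mean, n).astype(int)
        if self.dispersion < 1:
            raise ValueError("under-dispersed counts are not supported")
        # NB with mean m, var = m * dispersion: p = 1/dispersion, r = m p/(1-p)
        p = 1.0 / self.dispersion
        r = self.mean * p / (1.0 - p)
        return rng.negative_binomial(r, p, n).astype(int)


@dataclass
class NoiseModel:
    """Poisson shot noise (photon scaling) followed by Gaussian read noise.

    ``poisson_scale`` is photons per intensity unit; 0 disables the Poisson
    stage.  ``gaussian_sd`` is in intensity units; 0 disables it.
    """

    poisson_scale: float = 0.0
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gaussian_sd > 0


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic scene.

    Geometry defaults (cell radius, punctum radii, stroke widths) are
    calibration knobs of the benchmark, not claims about any dataset.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    n_cells: int = 6
    cell_radius_px: int = 26
    mito_density: float = 0.12
    n_mitolysosomes_per_cell: CountDistribution = field(
        default_factory=lambda: CountDistribution(3.0)
    )
    n_autophagosomes_per_cell: Optional[CountDistribution] = None
    n_autolysosomes_per_cell: Optional[CountDistribution] = None
    quench_factor: float = 0.05
    label_fraction: float = 0.0
    mito_overlap_fraction: float = 0.0
    n_distractor_mito_blobs_per_cell: int = 2
    background_level: float = 10.0
    cytosol_intensity: float = 40.0
    network_intensity: float = 120.0
    punctum_intensity: float = 200.0
    label_intensity: float = 150.0
    red_gain: float = 1.0
    green_gain: float = 1.0
    punctum_radius_px: tuple[int, int] = (2, 5)
    psf_sigma: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.image_shape, list):
            self.image_shape = tuple(self.image_shape)
        if isinstance(self.punctum_radius_px, list):
            self.punctum_radius_px = tuple(self.punctum_radius_px)
        for name in (
            "pixel_size", "mito_density", "quench_factor", "label_fraction",
            "mito_overlap_fraction", "background_level", "cytosol_intensity",
            "network_intensity", "punctum_intensity", "label_intensity",
            "red_gain", "green_gain", "psf_sigma",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 <= self.quench_factor <= 1.0:
            raise ValueError("quench_factor must lie in [0, 1]")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in [0, 1]")
        if not 0.0 <= self.mito_overlap_fraction <= 1.0:
            raise ValueError("mito_overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.mito_density < 1.0:
            raise ValueError("mito_density must lie in [0, 1)")
        if self.n_cells < 0 or self.cell_radius_px < 4:
            raise ValueError("n_cells must be >= 0 and cell_radius_px >= 4")
        if self.n_distractor_mito_blobs_per_cell < 0:
            raise ValueError("distractor count must be >= 0")
        rmin, rmax = self.punctum_radius_px
        if rmin < 1 or rmax < rmin:
            raise ValueError("punctum radius range invalid")
        if self.background_level < 0 or self.psf_sigma < 0:
            raise ValueError("background_level and psf_sigma must be >= 0")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["punctum_radius_px"] = list(self.punctum_radius_px)
        for key in ("n_mitolysosomes_per_cell", "n_autophagosomes_per_cell",
                    "n_autolysosomes_per_cell"):
            if d[key] is not None:
                d[key] = dict(d[key])
        d["noise"] = dict(d["noise"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for key in ("n_mitolysosomes_per_cell", "n_autophagosomes_per_cell",
                    "n_autolysosomes_per_cell"):
            if d.get(key) is not None and not isinstance(d[key], CountDistribution):
                d[key] = CountDistribution(**d[key])
        if d.get("noise") is not None and not isinstance(d["noise"], NoiseModel):
            d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class GroundTruth:
    """Per-object and per-cell truth recorded before degradation.

    ``objects`` columns: object_id, cell_id, object_class, centroid_row,
    centroid_col, area_px, inside_label_mask.
    ``cells`` columns: cell_id, n_mitolysosomes, n_autophagosomes,
    n_autolysosomes, label_positive.
    """

    objects: pd.DataFrame
    cells: pd.DataFrame

    OBJECT_COLUMNS = (
        "object_id", "cell_id", "object_class",
        "centroid_row", "centroid_col", "area_px", "inside_label_mask",
    )

    def count(self, object_class: str) -> int:
        return int((self.objects["object_class"] == object_class).sum())

    def per_cell_counts(self, object_class: str) -> pd.Series:
        sub = self.objects[self.objects["object_class"] == object_class]
        counts = sub.groupby("cell_id").size()
        return counts.reindex(self.cells["cell_id"], fill_value=0)

    def to_tsv(self, path) -> None:
        self.objects.to_csv(path, sep="\t", index=False)

    @classmethod
    def objects_from_tsv(cls, path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    keep = rr**2 + cc**2 <= radius**2
    return rr[keep], cc[keep]


def _stamp_disk(canvas: np.ndarray, row: int, col: int, radius: int,
                value: float = 1.0, additive: bool = False) -> None:
    rr, cc = _disk_offsets(radius)
    rr = rr + row
    cc = cc + col
    keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    if additive:
        canvas[rr[keep], cc[keep]] += value
    else:
        canvas[rr[keep], cc[keep]] = value


def _disk_mask(shape: tuple[int, int], row: int, col: int, radius: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    _stamp_disk(m, row, col, radius, True)
    return m


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping cell centres by rejection sampling."""
    h, w = spec.image_shape
    r = spec.cell_radius_px
    gap = 4
    if h < 2 * r + 2 or w < 2 * r + 2:
        raise PlacementError(
            f"image {spec.image_shape} too small for cells of radius {r}"
        )
    centres: list[tuple[int, int]] = []
    max_tries = 400 * max(spec.n_cells, 1)
    tries = 0
    while len(centres) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_cells} cells of radius {r} "
                f"in image {spec.image_shape}"
            )
        tries += 1
        row = int(rng.integers(r, h - r))
        col = int(rng.integers(r, w - r))
        ok = all(
            (row - pr) ** 2 + (col - pc) ** 2 >= (2 * r + gap) ** 2
            for pr, pc in centres
        )
        if ok:
            centres.append((row, col))
    return centres


def _draw_network(spec: SceneSpec, cell_mask: np.ndarray,
                  centre: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Curvilinear strokes (persistent random walks) filling ``mito_density``
    of the cell area, clipped to the cell."""
    target = spec.mito_density * cell_mask.sum()
    net = np.zeros(spec.image_shape, dtype=bool)
    if target <= 0:
        return net
    r = spec.cell_radius_px
    guard = 0
    while net.sum() < target and guard < 200:
        guard += 1
        # start near the centre so strokes stay mostly inside the cell
        row = centre[0] + rng.uniform(-0.6 * r, 0.6 * r)
        col = centre[1] + rng.uniform(-0.6 * r, 0.6 * r)
        theta = rng.uniform(0, 2 * np.pi)
        width = int(rng.integers(2, 5))  # stroke width 2-4 px
        n_steps = int(rng.integers(r, 3 * r))
        for _ in range(n_steps):
            theta += rng.normal(0, 0.35)
            row += np.sin(theta)
            col += np.cos(theta)
            ir, ic = int(round(row)), int(round(col))
            if not (0 <= ir < net.shape[0] and 0 <= ic < net.shape[1]):
                break
            _stamp_disk(net, ir, ic, max(width // 2, 1), True)
    net &= cell_mask
    return net


def _place_puncta_in_cell(
    spec: SceneSpec,
    centre: tuple[int, int],
    n: int,
    rng: np.random.Generator,
    forbidden: np.ndarray,
    min_gap_px: int = 3,
) -> list[tuple[int, int, int]]:
    """Rejection-sample ``n`` disjoint puncta (row, col, radius) inside the
    cell, avoiding ``forbidden`` pixels (network + previously placed puncta).

    ``forbidden`` is updated in place with each placed punctum dilated by
    ``min_gap_px`` so puncta never touch after PSF blur.
    """
    rmin, rmax = spec.punctum_radius_px
    placed: list[tuple[int, int, int]] = []
    max_tries = 500
    for _ in range(n):
        for attempt in range(max_tries):
            radius = int(rng.integers(rmin, rmax + 1))
            rho = (spec.cell_radius_px - radius - 2) * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            row = int(round(centre[0] + rho * np.sin(phi)))
            col = int(round(centre[1] + rho * np.cos(phi)))
            rr, cc = _disk_offsets(radius)
            rr = rr + row
            cc = cc + col
            if (rr.min() < 0 or rr.max() >= spec.image_shape[0]
                    or cc.min() < 0 or cc.max() >= spec.image_shape[1]):
                continue
            if forbidden[rr, cc].any():
                continue
            placed.append((row, col, radius))
            _stamp_disk(forbidden, row, col, radius + min_gap_px, True)
            break
        else:
            raise PlacementError(
                f"could not place punctum {len(placed) + 1}/{n} in cell at "
                f"{centre}; scene too crowded"
            )
    return placed


def _degrade(spec: SceneSpec, canvas: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """PSF blur then shot + read noise; each stage independently togglable."""
    out = canvas
    if spec.psf_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.psf_sigma)
    if spec.noise.poisson_scale > 0:
        out = rng.poisson(out * spec.noise.poisson_scale) / spec.noise.poisson_scale
    if spec.noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.noise.gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


def _finalize_channels(
    spec: SceneSpec,
    red: np.ndarray,
    green: np.ndarray,
    label: Optional[np.ndarray],
    rng_noise: np.random.Generator,
    meta: dict,
) -> ReporterImage:
    red_out = _degrade(spec, spec.red_gain * red, rng_noise)
    green_out = _degrade(spec, spec.green_gain * green, rng_noise)
    label_ch = None
    if label is not None:
        label_ch = ChannelImage(
            _degrade(spec, label, rng_noise), spec.pixel_size, "label"
        )
    return ReporterImage(
        red=ChannelImage(red_out, spec.pixel_size, "red"),
        green=ChannelImage(green_out, spec.pixel_size, "green"),
        label=label_ch,
        **meta,
    )


def _object_record(object_id: int, cell_id: int, object_class: str,
                   row: int, col: int, area_px: int,
                   inside_label: bool = False) -> dict:
    return {
        "object_id": object_id,
        "cell_id": cell_id,
        "object_class": object_class,
        "centroid_row": row,
        "centroid_col": col,
        "area_px": area_px,
        "inside_label_mask": bool(inside_label),
    }


def _ground_truth(records: list[dict], cell_rows: list[dict]) -> GroundTruth:
    objects = pd.DataFrame(records, columns=list(GroundTruth.OBJECT_COLUMNS))
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "n_mitolysosomes", "n_autophagosomes",
                 "n_autolysosomes", "label_positive"],
    )
    return GroundTruth(objects=objects, cells=cells)


# ---------------------------------------------------------------------------
# scene renderers
# ---------------------------------------------------------------------------


def render_mef_scene(
    spec: SceneSpec, meta: Optional[dict] = None
) -> tuple[ReporterImage, list[RegionMask], GroundTruth]:
    """Cultured-cell mitophagy-reporter scene.

    Returns the degraded two-channel image, one single-cell ROI mask per
    cell, and the pre-degradation ground truth.  The red channel carries
    network + puncta at full intensity; the green channel carries the same
    structures with punctum intensity scaled by ``quench_factor``.
    """
    meta = dict(meta or {})
    rng_cells = substream(spec.seed, STREAM_CELLS)
    rng_net = substream(spec.seed, STREAM_NETWORK)
    rng_counts = substream(spec.seed, STREAM_MITO_COUNTS)
    rng_puncta = substream(spec.seed, STREAM_PUNCTA)
    rng_noise = substream(spec.seed, STREAM_NOISE)

    centres = _place_cells(spec, rng_cells)
    counts = spec.n_mitolysosomes_per_cell.sample(rng_counts, spec.n_cells)

    red = np.full(spec.image_shape, spec.background_level, dtype=float)
    green = np.full(spec.image_shape, spec.background_level, dtype=float)

    rois: list[RegionMask] = []
    records: list[dict] = []
    cell_rows: list[dict] = []
    object_id = 0

    for cell_id, centre in enumerate(centres):
        cell_mask = _disk_mask(spec.image_shape, *centre, spec.cell_radius_px)
        rois.append(
            RegionMask(cell_mask, spec.pixel_size, "single_cell_roi",
                       source=f"cell_{cell_id}")
        )
        if spec.cytosol_intensity > 0:
            red[cell_mask] += spec.cytosol_intensity
            green[cell_mask] += spec.cytosol_intensity

        net = _draw_network(spec, cell_mask, centre, rng_net)
        red[net] += spec.network_intensity
        green[net] += spec.network_intensity
        if net.any():
            nr, nc = np.nonzero(net)
            records.append(_object_record(
                object_id, cell_id, CLASS_NETWORK,
                int(round(nr.mean())), int(round(nc.mean())), int(net.sum()),
            ))
            object_id += 1

        forbidden = ndimage.binary_dilation(net, iterations=3)
        puncta = _place_puncta_in_cell(
            spec, centre, int(counts[cell_id]), rng_puncta, forbidden
        )
        for row, col, radius in puncta:
            disk = _disk_mask(spec.image_shape, row, col, radius)
            red[disk] += spec.punctum_intensity
            green[disk] += spec.quench_factor * spec.punctum_intensity
            records.append(_object_record(
                object_id, cell_id, CLASS_MITOLYSOSOME,
                row, col, int(disk.sum()),
            ))
            object_id += 1
        cell_rows.append({
            "cell_id": cell_id,
            "n_mitolysosomes": int(counts[cell_id]),
            "n_autophagosomes": 0,
            "n_autolysosomes": 0,
            "label_positive": False,
        })

    truth = _ground_truth(records, cell_rows)
    image = _finalize_channels(spec, red, green, None, rng_noise, meta)
    return image, rois, truth


def render_tissue_scene(
    spec: SceneSpec, meta: Optional[dict] = None
) -> tuple[ReporterImage, GroundTruth]:
    """Tissue scene: MEF geometry plus an immunolabel channel.

    A Bernoulli(``label_fraction``) draw per cell (substream ``"label"``,
    one vectorized call in cell order) selects label-positive cells, whose
    somata are painted into the label channel.  Ground truth flags each
    punctum whose centroid falls inside the painted label mask.
    """
    meta = dict(meta or {})
    rng_cells = substream(spec.seed, STREAM_CELLS)
    rng_net = substream(spec.seed, STREAM_NETWORK)
    rng_counts = substream(spec.seed, STREAM_MITO_COUNTS)
    rng_puncta = substream(spec.seed, STREAM_PUNCTA)
    rng_label = substream(spec.seed, STREAM_LABEL)
    rng_noise = substream(spec.seed, STREAM_NOISE)

    centres = _place_cells(spec, rng_cells)
    counts = spec.n_mitolysosomes_per_cell.sample(rng_counts, spec.n_cells)
    label_positive = rng_label.uniform(size=spec.n_cells) < spec.label_fraction

    red = np.full(spec.image_shape, spec.background_level, dtype=float)
    green = np.full(spec.image_shape, spec.background_level, dtype=float)
    label = np.full(spec.image_shape, spec.background_level, dtype=float)
    label_mask = np.zeros(spec.image_shape, dtype=bool)

    records: list[dict] = []
    cell_rows: list[dict] = []
    object_id = 0
    soma_radius = max(int(round(0.85 * spec.cell_radius_px)), 4)

    for cell_id, centre in enumerate(centres):
        cell_mask = _disk_mask(spec.image_shape, *centre, spec.cell_radius_px)
        if spec.cytosol_intensity > 0:
            red[cell_mask] += spec.cytosol_intensity
            green[cell_mask] += spec.cytosol_intensity

        if label_positive[cell_id]:
            soma = _disk_mask(spec.image_shape, *centre, soma_radius)
            label[soma] += spec.label_intensity
            label_mask |= soma

        net = _draw_network(spec, cell_mask, centre, rng_net)
        red[net] += spec.network_intensity
        green[net] += spec.network_intensity
        if net.any():
            nr, nc = np.nonzero(net)
            records.append(_object_record(
                object_id, cell_id, CLASS_NETWORK,
                int(round(nr.mean())), int(round(nc.mean())), int(net.sum()),
                inside_label=label_mask[int(round(nr.mean())), int(round(nc.mean()))],
            ))
            object_id += 1

        forbidden = ndimage.binary_dilation(net, iterations=3)
        puncta = _place_puncta_in_cell(
            spec, centre, int(counts[cell_id]), rng_puncta, forbidden
        )
        for row, col, radius in puncta:
            disk = _disk_mask(spec.image_shape, row, col, radius)
            red[disk] += spec.punctum_intensity
            green[disk] += spec.quench_factor * spec.punctum_intensity
            records.append(_object_record(
                object_id, cell_id, CLASS_MITOLYSOSOME,
                row, col, int(disk.sum()),
                inside_label=label_mask[row, col],
            ))
            object_id += 1
        cell_rows.append({
            "cell_id": cell_id,
            "n_mitolysosomes": int(counts[cell_id]),
            "n_autophagosomes": 0,
            "n_autolysosomes": 0,
            "label_positive": bool(label_positive[cell_id]),
        })

    truth = _ground_truth(records, cell_rows)
    image = _finalize_channels(spec, red, green, label, rng_noise, meta)
    return image, truth


def render_autoqc_scene(
    spec: SceneSpec, meta: Optional[dict] = None
) -> tuple[ReporterImage, GroundTruth]:
    """General-autophagy reporter scene with optional mitochondria label.

    Autophagosomes emit at full intensity in both channels; autolysosomes
    emit full red but only ``quench_factor`` green.  Each punctum is flagged
    mitochondria-overlapping by a Bernoulli(``mito_overlap_fraction``) draw
    (substream ``"overlap"``, one vectorized call over all puncta in
    placement order); flagged puncta get a covering blob painted into the
    label channel, and a few distractor blobs per cell are painted away from
    every punctum.
    """
    meta = dict(meta or {})
    if spec.n_autophagosomes_per_cell is None and spec.n_autolysosomes_per_cell is None:
        raise ValueError(
            "autoqc scene requires autophagosome and/or autolysosome counts"
        )
    ap_dist = spec.n_autophagosomes_per_cell or CountDistribution(0.0, 0)
    al_dist = spec.n_autolysosomes_per_cell or CountDistribution(0.0, 0)

    rng_cells = substream(spec.seed, STREAM_CELLS)
    rng_ap = substream(spec.seed, STREAM_AP_COUNTS)
    rng_al = substream(spec.seed, STREAM_AL_COUNTS)
    rng_puncta = substream(spec.seed, STREAM_PUNCTA)
    rng_overlap = substream(spec.seed, STREAM_OVERLAP)
    rng_noise = substream(spec.seed, STREAM_NOISE)

    centres = _place_cells(spec, rng_cells)
    ap_counts = ap_dist.sample(rng_ap, spec.n_cells)
    al_counts = al_dist.sample(rng_al, spec.n_cells)

    red = np.full(spec.image_shape, spec.background_level, dtype=float)
    green = np.full(spec.image_shape, spec.background_level, dtype=float)
    label = np.full(spec.image_shape, spec.background_level, dtype=float)

    # first pass: geometry only, so the overlap draw can be one vectorized call
    placements: list[tuple[int, str, int, int, int]] = []  # cell, class, r, c, rad
    all_puncta_mask = np.zeros(spec.image_shape, dtype=bool)
    cell_masks: list[np.ndarray] = []
    for cell_id, centre in enumerate(centres):
        cell_mask = _disk_mask(spec.image_shape, *centre, spec.cell_radius_px)
        cell_masks.append(cell_mask)
        forbidden = np.zeros(spec.image_shape, dtype=bool)
        forbidden |= all_puncta_mask
        for object_class, n in (
            (CLASS_AUTOPHAGOSOME, int(ap_counts[cell_id])),
            (CLASS_AUTOLYSOSOME, int(al_counts[cell_id])),
        ):
            pts = _place_puncta_in_cell(spec, centre, n, rng_puncta, forbidden)
            for row, col, radius in pts:
                placements.append((cell_id, object_class, row, col, radius))
                _stamp_disk(all_puncta_mask, row, col, radius, True)

    overlap_flags = rng_overlap.uniform(size=len(placements)) < spec.mito_overlap_fraction

    records: list[dict] = []
    label_mask = np.zeros(spec.image_shape, dtype=bool)
    for (cell_id, object_class, row, col, radius), flagged in zip(
        placements, overlap_flags
    ):
        disk = _disk_mask(spec.image_shape, row, col, radius)
        red[disk] += spec.punctum_intensity
        gfactor = 1.0 if object_class == CLASS_AUTOPHAGOSOME else spec.quench_factor
        green[disk] += gfactor * spec.punctum_intensity
        if flagged:
            blob = _disk_mask(spec.image_shape, row, col, radius + 2)
            label[blob & ~label_mask] += spec.label_intensity
            label_mask |= blob
        records.append(_object_record(
            len(records), cell_id, object_class, row, col, int(disk.sum()),
            inside_label=bool(flagged),
        ))

    # cytosol + distractor mito blobs kept clear of every punctum
    keep_clear = ndimage.binary_dilation(all_puncta_mask, iterations=4)
    for cell_id, (centre, cell_mask) in enumerate(zip(centres, cell_masks)):
        if spec.cytosol_intensity > 0:
            red[cell_mask] += spec.cytosol_intensity
            green[cell_mask] += spec.cytosol_intensity
        for _ in range(spec.n_distractor_mito_blobs_per_cell):
            for _attempt in range(200):
                rho = (spec.cell_radius_px - 5) * np.sqrt(rng_puncta.uniform())
                phi = rng_puncta.uniform(0, 2 * np.pi)
                row = int(round(centre[0] + rho * np.sin(phi)))
                col = int(round(centre[1] + rho * np.cos(phi)))
                blob = _disk_mask(spec.image_shape, row, col, 3)
                if not (blob & keep_clear).any():
                    label[blob & ~label_mask] += spec.label_intensity
                    label_mask |= blob
                    break

    cell_rows = [
        {
            "cell_id": cid,
            "n_mitolysosomes": 0,
            "n_autophagosomes": int(ap_counts[cid]),
            "n_autolysosomes": int(al_counts[cid]),
            "label_positive": False,
        }
        for cid in range(spec.n_cells)
    ]
    truth = _ground_truth(records, cell_rows)
    image = _finalize_channels(spec, red, green, label, rng_noise, meta)
    return image, truth
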