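"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at the level the analysis code cares about, the four
kinds of raw material the quantifications consume:

* 2D maximum-intensity projections of trunk FISH stacks: two roughly
  parallel vessel bands (dorsal aorta and posterior cardinal vein) plus
  non-endothelial background, round diffraction-limited spots planted at
  region-specific densities, smooth background, Poisson photon noise
  followed by Gaussian read noise;
* single cortical-ring cells for the F-actin enrichment ratio;
* protrusion-length tracks sampled every 20 min for sprout timing;
* cells x genes expression matrices with a known fraction of expressing
  cells per cluster;
* tidy per-embryo measurement tables from named distribution families for
  exercising the group statistics.

Everything is deterministic for a fixed seed, and noise-off images are exact
closed-form renders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack
from .regions import RegionAnnotationSet, rasterize_regions
from .morphometry import ProtrusionTrack
from .stats import ExpressionMatrix


@dataclass
class FishSimParams:
    """Conditions for one synthetic trunk FISH projection.

    Defaults give a 256x256 px field at 0.2 um/px with two 37-px-wide vessel
    bands, sigma = 1.5 px spots and a peak signal-to-noise ratio of about 7
    (amplitude over the background shot + read noise scale).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.2  # um/px
    vessel_bands: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("DA", 80, 18), ("PCV", 176, 18)]
    )  # (name, y_center px, half_width px)
    spot_density_per_region: dict[str, float] = field(
        default_factory=lambda: {"DA": 10.0, "PCV": 10.0, "outside": 2.0}
    )  # spots per 1000 px^2
    spot_sigma: float = 1.5  # px
    spot_amplitude: float = 30.0  # photons at peak
    background_level: float = 10.0  # photons
    gaussian_read_noise_sd: float = 2.0  # photons
    poisson_noise: bool = True
    exact_spot_counts: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be > 0")
        if any(d < 0 for d in self.spot_density_per_region.values()):
            raise ValueError("spot densities must be >= 0")
        spans = sorted((yc - hw, yc + hw, name) for name, yc, hw in self.vessel_bands)
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"vessel bands {n1!r} and {n2!r} overlap")

    @property
    def snr(self) -> float:
        """Peak amplitude over the noise scale at background."""
        noise = np.sqrt(self.background_level + self.gaussian_read_noise_sd**2)
        return self.spot_amplitude / noise


@dataclass
class SpotGroundTruth:
    """Planted spot centers, their region labels, and per-region tallies.

    The "true spot area" bookkeeping uses the disk-of-radius-2*sigma
    convention, pi * (2 sigma)^2 px^2 per spot; it is a ground-truth
    reference only, not what the segmenter is expected to reproduce exactly.
    """

    table: pd.DataFrame  # columns x, y, region
    counts: dict[str, int]
    spot_area_px2: float
    cumulative_area_px2: dict[str, float]


def default_bands(image_shape: tuple[int, int]) -> list[tuple[str, int, int]]:
    """DA/PCV bands at the default fractional positions for any frame height."""
    h = image_shape[0]
    hw = max(2, round(h * 18 / 256))
    return [("DA", round(h * 80 / 256), hw), ("PCV", round(h * 176 / 256), hw)]


def _band_polygon(yc: int, hw: int, width: int) -> np.ndarray:
    """Counter-clockwise rectangle whose pixel-center interior is the band rows."""
    ylo, yhi = yc - hw - 0.5, yc + hw + 0.5
    return np.array([[-0.5, ylo], [width - 0.5, ylo],
                     [width - 0.5, yhi], [-0.5, yhi]])


def generate_fish_image(
    params: FishSimParams,
) -> tuple[ImageStack, RegionAnnotationSet, SpotGroundTruth]:
    """Render one synthetic FISH projection with vessel-band annotations.

    Spots are isotropic Gaussians truncated at 4 sigma; per-region counts are
    Poisson(density x region area / 1000) unless ``params.exact_spot_counts``
    pins them.  Returns a two-channel stack (FISH + vessel/GFP), the exact
    band polygons, and the planted ground truth.  Every planted center lies
    strictly inside its region's polygon.
    """
    h, w = params.image_shape
    rng = np.random.default_rng(params.seed)

    polygons = [(name, _band_polygon(yc, hw, w))
                for name, yc, hw in params.vessel_bands]
    annots = rasterize_regions(polygons, (h, w), params.pixel_size)

    areas = {r.name: r.area_px2 for r in annots.regions}
    areas["outside"] = float(annots.outside_mask().sum())

    band_intervals = [(yc - hw, yc + hw) for _, yc, hw in params.vessel_bands]

    centers: list[tuple[float, float, str]] = []
    region_order = [name for name, _, _ in params.vessel_bands] + ["outside"]
    counts: dict[str, int] = {}
    for name in region_order:
        density = params.spot_density_per_region.get(name, 0.0)
        if params.exact_spot_counts is not None and name in params.exact_spot_counts:
            n = int(params.exact_spot_counts[name])
        else:
            n = int(rng.poisson(density * areas[name] / 1000.0))
        counts[name] = n
        for _ in range(n):
            x = rng.uniform(0.0, w - 1.0)
            if name == "outside":
                while True:
                    y = rng.uniform(0.0, h - 1.0)
                    if not any(lo - 0.5 <= y <= hi + 0.5 for lo, hi in band_intervals):
                        break
            else:
                _, yc, hw = next(b for b in params.vessel_bands if b[0] == name)
                y = rng.uniform(yc - hw, yc + hw)
            centers.append((x, y, name))

    clean = np.full((h, w), params.background_level, dtype=np.float64)
    _render_spots(clean, centers, params.spot_sigma, params.spot_amplitude)

    fish = _apply_noise(clean, params, rng)

    vessel_clean = np.full((h, w), 5.0)
    for r in annots.regions:
        vessel_clean[r.mask] = 50.0
    vessel = _apply_noise(vessel_clean, params, rng)

    stack = ImageStack(data=np.stack([fish, vessel]),
                       channels=["FISH", "vessel"],
                       pixel_size=params.pixel_size)
    table = pd.DataFrame(centers, columns=["x", "y", "region"])
    spot_area = float(np.pi * (2 * params.spot_sigma) ** 2)
    cum = {name: counts[name] * spot_area for name in counts}
    truth = SpotGroundTruth(table=table, counts=counts,
                            spot_area_px2=spot_area, cumulative_area_px2=cum)
    return stack, annots, truth


def _render_spots(image: np.ndarray, centers, sigma: float, amplitude: float) -> None:
    """Add truncated (4 sigma) isotropic Gaussian spots in place."""
    h, w = image.shape
    r = int(np.ceil(4 * sigma))
    for x, y, _ in centers:
        x0, y0 = int(round(x)), int(round(y))
        ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
        xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
        yy, xx = np.mgrid[ys, xs]
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        patch = amplitude * np.exp(-d2 / (2 * sigma**2))
        patch[d2 > (4 * sigma) ** 2] = 0.0
        image[ys, xs] += patch


def _apply_noise(clean: np.ndarray, params: FishSimParams, rng) -> np.ndarray:
    out = clean
    if params.poisson_noise:
        out = rng.poisson(out).astype(np.float64)
    if params.gaussian_read_noise_sd > 0:
        out = out + rng.normal(0.0, params.gaussian_read_noise_sd, out.shape)
    return np.ascontiguousarray(out)


def generate_cortical_cell(
    ring_ratio: float,
    cell_radius: int = 30,
    ring_width: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    interior_level: float = 100.0,
    pad: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk-shaped cell whose outer ring is ``ring_ratio`` x brighter.

    Before noise, mean(ring) / mean(interior) equals ``ring_ratio`` exactly by
    construction (interior pixels at ``interior_level``, ring pixels at
    ``ring_ratio * interior_level``).  Returns (image, cell mask).
    """
    if ring_ratio <= 0:
        raise ValueError("ring_ratio must be > 0")
    if ring_width >= cell_radius:
        raise ValueError("ring_width must be smaller than cell_radius")
    size = 2 * (cell_radius + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
    mask = r <= cell_radius
    interior = r <= cell_radius - ring_width
    image = np.zeros((size, size), dtype=np.float64)
    image[mask] = ring_ratio * interior_level
    image[interior] = interior_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, image.shape)
    return image, mask


def generate_protrusion_track(
    first_exceed_frame: int | None,
    contact_frame: int | None,
    frame_interval: float = 20.0,
    threshold: float = 15.0,
    n_frames: int | None = None,
    seed: int = 0,
) -> ProtrusionTrack:
    """Protrusion-length series crossing ``threshold`` at a known frame.

    ``first_exceed_frame=None`` produces a track that never exceeds the
    threshold (the "no sprout" condition).  Raises if the contact frame
    precedes the first crossing.
    """
    rng = np.random.default_rng(seed)
    if first_exceed_frame is not None and contact_frame is not None \
            and contact_frame < first_exceed_frame:
        raise ValueError("contact_frame precedes first_exceed_frame")
    if n_frames is None:
        last = max(f for f in (first_exceed_frame, contact_frame, 5) if f is not None)
        n_frames = last + 3
    lengths = rng.uniform(0.0, 0.8 * threshold, n_frames)
    if first_exceed_frame is not None:
        if not 0 <= first_exceed_frame < n_frames:
            raise ValueError("first_exceed_frame outside track")
        lengths[first_exceed_frame:] = threshold + rng.uniform(1.0, 6.0,
                                                               n_frames - first_exceed_frame)
    return ProtrusionTrack(lengths=lengths, frame_interval=frame_interval,
                           contact_frame=contact_frame)


def generate_expression_matrix(
    clusters: list[tuple[str, int]],
    params: dict[str, list[tuple[float, float]]] | list[tuple[float, float]],
    seed: int = 0,
    stages: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cells x genes matrix with a known expressing fraction per cluster.

    ``params`` maps gene -> per-cluster (fraction_expressing,
    mean_when_expressed) aligned with ``clusters``; a bare list is treated as
    a single gene ``"gene1"``.  Expressing cells are Bernoulli draws and
    their values Gamma(2, mean/2) (positive, with the requested mean); the
    realized percent-expressing per cluster is returned as ground truth.
    """
    if not isinstance(params, dict):
        params = {"gene1": list(params)}
    genes = list(params)
    for gene, per_cluster in params.items():
        if len(per_cluster) != len(clusters):
            raise ValueError(f"gene {gene!r}: params do not match clusters")
        for frac, _ in per_cluster:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction_expressing must be in [0, 1]")
    if any(n < 1 for _, n in clusters):
        raise ValueError("each cluster needs n_cells >= 1")
    if stages is not None and len(stages) != len(clusters):
        raise ValueError("stages must align with clusters")

    rng = np.random.default_rng(seed)
    blocks, labels, stage_labels, truth_rows = [], [], [], []
    for ci, (name, n) in enumerate(clusters):
        block = np.zeros((n, len(genes)))
        for gi, gene in enumerate(genes):
            frac, mean = params[gene][ci]
            expressing = rng.random(n) < frac
            k = int(expressing.sum())
            if k and mean > 0:
                block[expressing, gi] = rng.gamma(2.0, mean / 2.0, k)
            truth_rows.append({"cluster": name, "gene": gene,
                               "n_cells": n,
                               "true_fraction": frac,
                               "realized_percent": 100.0 * k / n})
        blocks.append(block)
        labels.extend([name] * n)
        if stages is not None:
            stage_labels.extend([stages[ci]] * n)
    expr = ExpressionMatrix(
        values=np.vstack(blocks), genes=genes,
        clusters=np.array(labels),
        stages=np.array(stage_labels) if stages is not None else None,
    )
    return expr, pd.DataFrame(truth_rows)


#: distribution families accepted by generate_measurement_table
_FAMILIES = ("normal", "shifted-normal", "lognormal", "binomial")


def generate_measurement_table(
    group_specs: list[tuple[str, int, str, dict]],
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy (unit_id, group, value) table from named distribution families.

    Families: ``normal`` (loc, scale), ``shifted-normal`` (loc, scale, shift),
    ``lognormal`` (mean, sigma of the underlying normal), ``binomial``
    (n_trials, p).
    """
    rng = np.random.default_rng(seed)
    rows = []
    uid = 0
    for label, n, family, kw in group_specs:
        if n < 1:
            raise ValueError(f"group {label!r}: need n >= 1")
        if family == "normal":
            vals = rng.normal(kw.get("loc", 0.0), kw.get("scale", 1.0), n)
        elif family == "shifted-normal":
            vals = rng.normal(kw.get("loc", 0.0) + kw.get("shift", 0.0),
                              kw.get("scale", 1.0), n)
        elif family == "lognormal":
            vals = rng.lognormal(kw.get("mean", 0.0), kw.get("sigma", 1.0), n)
        elif family == "binomial":
            vals = rng.binomial(kw.get("n_trials", 1), kw.get("p", 0.5), n).astype(float)
        else:
            raise ValueError(f"unknown distribution family {family!r}; "
                             f"choose from {_FAMILIES}")
        for v in vals:
            rows.append({"unit_id": uid, "group": label, "value": float(v)})
            uid += 1
    return pd.DataFrame(rows)
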