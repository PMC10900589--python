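"""Readers/writers and the end-to-end pipeline driver.

Conventions, used everywhere: 0-based (x, y) pixel coordinates, pixel-center
convention; physical pixel size in um/px; images as TIFF (single- or
multi-page), regions as JSON polygon files (with optional ImageJ .roi/.zip
import), tables as CSV with unit-bearing column names.
"""

from __future__ import annotations

import json
import struct
import sys
import tomllib
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import wavelet as wv
from . import spots as sp
from . import regions as rg


@dataclass
class ImageStack:
    """Pixel data with channel labels and physical spacing.

    ``data`` is (H, W) or (C, H, W); ``channels`` names the leading axis.
    """

    data: np.ndarray
    channels: list[str] | None = None
    pixel_size: float | None = None  # um/px

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("image data must be 2D or 3D (C, H, W)")
        if self.data.ndim == 3 and self.channels is not None and \
                len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names do not match pages")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    def channel(self, name: str) -> np.ndarray:
        if self.data.ndim == 2:
            return self.data
        if self.channels is None:
            raise KeyError("stack has unnamed channels; index numerically")
        return self.data[self.channels.index(name)]

    def max_projection(self) -> np.ndarray:
        """Element-wise maximum over pages (identity for 2D)."""
        return self.data if self.data.ndim == 2 else self.data.max(axis=0)


class FormatError(ValueError):
    """Raised for files that are not in an expected format."""


def read_image(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Read a single- or multi-page TIFF; pixel size from metadata or override."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = _parse_description(tif.pages[0].description)
    except (tifffile.TiffFileError, struct.error) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValueError(
            f"{path} carries no pixel-size metadata; pass pixel_size explicitly"
        )
    return ImageStack(data=data, channels=meta.get("channels"), pixel_size=float(ps))


def write_image(path: str | Path, stack: ImageStack) -> None:
    meta = {"pixel_size_um": stack.pixel_size, "channels": stack.channels}
    tifffile.imwrite(path, stack.data, description=json.dumps(meta),
                     photometric="minisblack")


def _parse_description(desc: str) -> dict:
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                return parsed
        except json.JSONDecodeError:
            pass
    return {}


# --------------------------------------------------------------------------
# Region files: native JSON schema and ImageJ .roi / .zip import
# --------------------------------------------------------------------------

def write_regions(path: str | Path,
                  polygons: list[tuple[str, np.ndarray]],
                  frame_shape: tuple[int, int] | None = None,
                  pixel_size: float = 1.0) -> None:
    """Write the native JSON region schema: name + (x, y) vertex lists."""
    payload = {
        "pixel_size_um": pixel_size,
        "frame_shape": list(frame_shape) if frame_shape else None,
        "regions": [
            {"name": name, "vertices": np.asarray(v, dtype=float).tolist()}
            for name, v in polygons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_region_polygons(path: str | Path) -> tuple[list[tuple[str, np.ndarray]], dict]:
    """Read named polygons from native JSON or ImageJ .roi/.zip files."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return [read_imagej_roi(path)], {}
    if path.suffix.lower() == ".zip":
        polys = []
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                name = Path(info.filename).stem
                polys.append(_decode_imagej_roi(zf.read(info), name))
        return polys, {}
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a region JSON file: {exc}") from exc
    polys = []
    seen = set()
    for entry in payload["regions"]:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate region name {name!r} in {path}")
        seen.add(name)
        verts = np.asarray(entry["vertices"], dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError(f"region {name!r}: malformed vertices")
        polys.append((name, verts))
    meta = {k: payload.get(k) for k in ("pixel_size_um", "frame_shape")}
    return polys, meta


def read_regions(path: str | Path,
                 frame_shape: tuple[int, int] | None = None,
                 pixel_size: float | None = None) -> rg.RegionAnnotationSet:
    """Read and rasterize a region file to a validated annotation set."""
    polys, meta = read_region_polygons(path)
    if frame_shape is None:
        if not meta.get("frame_shape"):
            raise ValueError(f"{path} has no frame_shape; pass one explicitly")
        frame_shape = tuple(meta["frame_shape"])
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um") or 1.0
    return rg.rasterize_regions(polys, frame_shape, pixel_size)


#: ImageJ ROI type codes for the shapes we import.
_IJ_POLYGON, _IJ_RECT = 0, 1


def read_imagej_roi(path: str | Path) -> tuple[str, np.ndarray]:
    path = Path(path)
    return _decode_imagej_roi(path.read_bytes(), path.stem)


def _decode_imagej_roi(buf: bytes, name: str) -> tuple[str, np.ndarray]:
    """Decode an ImageJ .roi rectangle or polygon to pixel-center vertices.

    ImageJ stores integer pixel-boundary coordinates: a rectangle
    (top, left, bottom, right) covers pixel indices left..right-1 /
    top..bottom-1.  Shifting by -0.5 converts boundary coordinates to this
    package's pixel-center-inside convention so the rasterized mask matches
    ImageJ's pixel membership.
    """
    if buf[:4] != b"Iout":
        raise FormatError(f"{name}: not an ImageJ ROI (bad magic)")
    roi_type = buf[6]
    top, left, bottom, right = struct.unpack(">4h", buf[8:16])
    if roi_type == _IJ_RECT:
        verts = np.array([[left, top], [right, top], [right, bottom], [left, bottom]],
                         dtype=float)
    elif roi_type == _IJ_POLYGON:
        (n,) = struct.unpack(">H", buf[16:18])
        coords = np.frombuffer(buf[64:64 + 4 * n], dtype=">i2").astype(float)
        verts = np.column_stack([coords[:n] + left, coords[n:] + top])
    else:
        raise FormatError(f"{name}: unsupported ImageJ ROI type {roi_type}")
    return name, verts - 0.5


def write_imagej_roi(path: str | Path, name: str, *, rect=None, polygon=None) -> None:
    """Write a minimal ImageJ-compatible .roi (rectangle or integer polygon)."""
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # version
    if rect is not None:
        top, left, bottom, right = rect
        header[6] = _IJ_RECT
        struct.pack_into(">4h", header, 8, top, left, bottom, right)
        body = b""
    elif polygon is not None:
        pts = np.asarray(polygon, dtype=int)
        left, top = pts.min(axis=0)
        right, bottom = pts.max(axis=0)
        header[6] = _IJ_POLYGON
        struct.pack_into(">4h", header, 8, top, left, bottom, right)
        struct.pack_into(">H", header, 16, len(pts))
        rel = np.concatenate([pts[:, 0] - left, pts[:, 1] - top])
        body = rel.astype(">i2").tobytes()
    else:
        raise ValueError("pass rect=(top, left, bottom, right) or polygon=[(x, y), ...]")
    Path(path).write_bytes(bytes(header) + body)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to run simulate -> detect -> enrich on a set of images."""

    images: list[str]
    regions: list[str]  # one region file per image
    output_dir: str
    fish_channel: str = "FISH"
    pixel_size: float | None = None  # um/px; overrides TIFF metadata
    levels: int = 4
    k: float = 3.0
    noise_estimator: str = "mad"
    spot_diameter: float = 0.8  # um
    multiscale: bool = False
    threshold_strategy: str = "positive"
    declump: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            cfg = tomllib.loads(path.read_text())
        else:
            cfg = json.loads(path.read_text())
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def detect_spots(image: np.ndarray, pixel_size: float,
                 levels: int = 4, k: float = 3.0, noise_estimator: str = "mad",
                 spot_diameter: float = 0.8, multiscale: bool = False,
                 threshold_strategy: str | float = "positive",
                 declump: bool = True) -> sp.SpotSet:
    """Wavelet-filter an image and segment FISH spots (one-call front door)."""
    planes = wv.decompose(image, levels=levels)
    planes = wv.threshold_planes(planes, wv.ThresholdPolicy(k=k, estimator=noise_estimator))
    response = wv.spot_response(planes, spot_diameter, pixel_size, multiscale=multiscale)
    mask = sp.global_threshold(response, threshold_strategy)
    spots = sp.identify_primary_objects(mask, image, declump=declump,
                                        declump_image=response)
    spots.scale = wv.select_scale(spot_diameter, pixel_size, levels)
    spots.params.update({"levels": levels, "k": k, "spot_diameter_um": spot_diameter})
    return spots


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run detection + enrichment over all configured images.

    Writes ``results.csv`` (one row per region per image, unit-suffixed
    columns), a 16-bit spot label TIFF per image, and ``run_log.json``
    recording versions, parameters and seed.  Deterministic for a fixed
    config.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(config.images) != len(config.regions):
        raise ValueError("need one region file per image")

    all_rows = []
    for img_path, reg_path in zip(config.images, config.regions):
        stage = f"image {img_path}"
        try:
            stack = read_image(img_path, pixel_size=config.pixel_size)
            fish = stack.channel(config.fish_channel) if stack.data.ndim == 3 \
                else stack.max_projection()
            fish = np.asarray(fish, dtype=np.float64)
            stage = f"regions {reg_path}"
            annots = read_regions(reg_path, frame_shape=fish.shape,
                                  pixel_size=stack.pixel_size)
            stage = f"detection on {img_path}"
            spots = detect_spots(
                fish, stack.pixel_size, levels=config.levels, k=config.k,
                noise_estimator=config.noise_estimator,
                spot_diameter=config.spot_diameter, multiscale=config.multiscale,
                threshold_strategy=config.threshold_strategy, declump=config.declump,
            )
            tifffile.imwrite(out_dir / f"{Path(img_path).stem}_labels.tif",
                             spots.labels.astype(np.uint16))
            stage = f"enrichment on {img_path}"
            enr = rg.enrichment_index(spots, annots) if len(annots.regions) else None
            summary = rg.region_summary(spots, annots)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc

        ps = stack.pixel_size
        for _, row in summary.iterrows():
            rec = {
                "image": Path(img_path).name,
                "region": row["region"],
                "region_area_px2": row["region_area_px2"],
                "region_area_um2": row["region_area_px2"] * ps**2,
                "n_spots": row["n_spots"],
                "cumulative_spot_area_px2": row["cumulative_spot_area_px2"],
                "cumulative_spot_area_um2": row["cumulative_spot_area_px2"] * ps**2,
                "spot_density_fraction": row["spot_density"],
                "enrichment_index": np.nan,
            }
            if enr is not None and row["region"] != "outside" and not enr.undefined:
                rec["enrichment_index"] = enr.index_of(row["region"])
            all_rows.append(rec)

    results = pd.DataFrame(all_rows)
    results.to_csv(out_dir / "results.csv", index=False)
    log = {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": asdict(config),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return results
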