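"""Image / table I/O, run configuration and logging.

Conventions
-----------
* Images are 2D (row, column) or 3D (plane, row, column) numpy arrays,
  0-based, with pixel centers at integer coordinates.
* All physical quantities are micrometres (µm) or µm²; pixel-unit output
  exists only behind explicit flags in the measurement routines.
* Pixel size is an explicit, required calibration — nothing about the
  acquisition magnification fixes it, so there is no silent default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("ptcmorph")


class ConfigError(ValueError):
    """A run-configuration value violates its documented constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibratedImage2D:
    """A single-channel 2D intensity grid with isotropic µm/pixel calibration."""

    pixels: np.ndarray
    pixel_size: float  # µm / pixel
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, name: str | None = None) -> "CalibratedImage2D":
        return CalibratedImage2D(pixels, self.pixel_size, self.name if name is None else name)


@dataclass(frozen=True)
class RegionOfInterest:
    """Boolean mask congruent with its parent image, e.g. an injury region."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("roi mask must be 2D")
        if not m.any():
            raise ValueError("roi mask must contain at least one true pixel")
        object.__setattr__(self, "mask", m)

    def area_um2(self, pixel_size: float) -> float:
        return float(self.mask.sum()) * pixel_size**2


_THRESHOLD_METHODS = ("bernsen", "phansalkar")


@dataclass
class RunConfig:
    """All tunable parameters of the 2D pipeline plus oxygen/3D settings.

    Defaults follow the published workflow: Gaussian σ = 2.5 px, local
    threshold window radius r = 35 px, particle size filter 10–8000 µm²,
    round-capillary cutoffs roundness ≥ 0.47 / circularity ≥ 0.60
    (per-capillary) and mean circularity ≥ 0.51 (per-region).
    """

    pixel_size: float = 1.0                    # µm / pixel
    threshold_method: str = "bernsen"          # bernsen | phansalkar
    window_radius: int = 35                    # pixels
    gaussian_sigma: float = 2.5                # pixels
    contrast_percentiles: tuple[float, float] = (0.35, 99.65)
    background_black_point: bool = True
    boundary_bias_px: int = 1      # erosion compensating the blurred-wall offset
    bernsen_contrast: float = 15.0
    phansalkar_k: float = 0.25
    phansalkar_r: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    size_min: float = 10.0                     # µm²
    size_max: float = 8000.0                   # µm²
    roundness_cutoff: float = 0.47
    circularity_cutoff: float = 0.60
    mean_circularity_cutoff: float = 0.51
    # oxygen unit-cell model
    oxygen_alpha: float = 1.53e-6              # mol O2 L^-1 mmHg^-1
    oxygen_diffusivity: float = 2.4e-5         # cm^2 s^-1
    oxygen_consumption: float = 13.2e-5        # mol O2 L^-1 s^-1
    oxygen_p0: float = 45.0                    # mmHg
    # 3D pipeline
    tubeness_sigma_um: float = 4.0
    tubeness_threshold: float = 100.0          # on the 8-bit-scaled score
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def positive(name: str) -> None:
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"{name} must be > 0, got {v!r}")

        for name in (
            "pixel_size", "window_radius", "gaussian_sigma", "size_min",
            "oxygen_alpha", "oxygen_diffusivity", "oxygen_consumption",
            "oxygen_p0", "tubeness_sigma_um",
        ):
            positive(name)
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ConfigError(
                f"threshold_method must be one of {_THRESHOLD_METHODS}, "
                f"got {self.threshold_method!r}"
            )
        if not (self.size_min < self.size_max):
            raise ConfigError(
                f"size_min must be < size_max, got {self.size_min} >= {self.size_max}"
            )
        lo, hi = self.contrast_percentiles
        if not (0 <= lo < hi <= 100):
            raise ConfigError(
                f"contrast_percentiles must satisfy 0 <= low < high <= 100, got {lo}, {hi}"
            )
        for name in ("roundness_cutoff", "circularity_cutoff", "mean_circularity_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["contrast_percentiles"] = list(self.contrast_percentiles)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        kw = dict(d)
        if "contrast_percentiles" in kw:
            kw["contrast_percentiles"] = tuple(kw["contrast_percentiles"])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    pixel_size: float | None = None,
    channel: int | None = None,
    name: str | None = None,
) -> CalibratedImage2D:
    """Read a single-channel 2D TIFF/PNG as a calibrated image.

    ``pixel_size`` is taken from TIFF resolution metadata when present and
    expressed in µm; otherwise it is a required argument.  Multi-channel
    input needs an explicit ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            if pixel_size is None:
                pixel_size = _pixel_size_from_tiff(tf)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name}: multi-channel image; select a channel explicitly"
            )
        ax = int(np.argmin(arr.shape))  # channel axis = smallest dimension
        arr = np.take(arr, channel, axis=ax)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D image, got shape {arr.shape}")
    if pixel_size is None:
        raise ValueError(
            f"{path.name}: no calibration in metadata; pixel_size (µm/px) is required"
        )
    if not (pixel_size > 0):
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    return CalibratedImage2D(arr, float(pixel_size), name or path.stem)


def _pixel_size_from_tiff(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" in tags and tags["XResolution"].value:
        num, den = tags["XResolution"].value
        if num:
            unit = tags.get("ResolutionUnit")
            per_unit = num / den
            # ResolutionUnit 3 = cm -> px/cm; report µm/px
            if unit is not None and getattr(unit, "value", None) == 3:
                return 1e4 / per_unit
    return None


def write_image(image: CalibratedImage2D | np.ndarray, path: str | Path,
                pixel_size: float | None = None) -> None:
    """Write a 2D grid as an uncompressed grayscale TIFF (or PNG by suffix)."""
    path = Path(path)
    if isinstance(image, CalibratedImage2D):
        arr, px = image.pixels, image.pixel_size
    else:
        arr, px = np.asarray(image), pixel_size
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        kwargs: dict[str, Any] = {}
        if px:
            kwargs["resolution"] = (1e4 / px, 1e4 / px)
            kwargs["resolutionunit"] = "CENTIMETER"
        tifffile.imwrite(path, arr, **kwargs)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_volume(path: str | Path, voxel_size: Sequence[float]) -> np.ndarray:
    """Read a TIFF stack as a (z, y, x) volume; voxel_size is (x, y, z) µm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D stack, got shape {arr.shape}")
    if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
        raise ValueError(f"voxel_size must be three positive values, got {voxel_size}")
    return arr


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a sequence of dataclass records to a DataFrame (one row each)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for k, v in list(d.items()):
            if isinstance(v, (tuple, list, np.ndarray)):
                for i, vi in enumerate(v):
                    d[f"{k}_{i}"] = vi
                del d[k]
        rows.append(d)
    return pd.DataFrame(rows)


def write_records_csv(records: Sequence, path: str | Path,
                      schema: Sequence[str] | None = None) -> pd.DataFrame:
    """Write per-capillary records to CSV: one row per particle, µm/µm² units.

    With zero records and a ``schema``, a header-only file is written.
    """
    df = records_to_frame(records)
    if df.empty and schema is not None:
        df = pd.DataFrame(columns=list(schema))
    df.to_csv(path, index=False, float_format="%.8g")
    return df


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
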