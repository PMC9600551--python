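"""Image, A-scan profile and result-table I/O.

The pipeline works on 8-bit grayscale anterior-segment B-scans (PNG/TIFF),
single-beam axial intensity profiles (CSV with columns ``depth_mm`` and
``intensity_au``), and per-eye result records (CSV/JSON).  All readers
validate their input and raise on anything out of contract rather than
silently coercing it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image


class ImageFormatError(ValueError):
    """Raised when an on-disk image violates the 8-bit grayscale contract."""


class ProfileFormatError(ValueError):
    """Raised when an A-scan CSV violates the profile contract."""


@dataclass
class BScan:
    """A 2D anterior-segment cross-section.

    Rows index axial depth (row 0 is most anterior), columns index lateral
    position.  Intensities live on the 0-255 pixel-intensity-unit (PIU)
    scale; they are stored as floats so that noise models and densitometry
    do not quantize prematurely.

    Parameters
    ----------
    pixels
        2D array, values in [0, 255].
    axial_px_mm, lateral_px_mm
        Pixel pitch in pixels per millimetre.  Densitometry itself is
        scale-free; the scale is only needed to report physical extents.
    meridian_deg
        Meridian of the radial scan pattern this section was taken at,
        in [0, 180).
    source_id
        Free-form provenance tag (file stem, phantom seed, ...).
    """

    pixels: np.ndarray
    axial_px_mm: float = 1.0
    lateral_px_mm: float = 1.0
    meridian_deg: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if not 0 <= self.meridian_deg < 180:
            self.meridian_deg = float(self.meridian_deg) % 180.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AScanProfile:
    """A single axial backscatter profile.

    ``depth_mm`` is strictly increasing; ``intensity_au`` is on the
    device-style normalized [0, 1] arbitrary-unit scale.
    """

    depth_mm: np.ndarray
    intensity_au: np.ndarray

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.intensity_au = np.asarray(self.intensity_au, dtype=float)
        if self.depth_mm.ndim != 1 or self.intensity_au.ndim != 1:
            raise ProfileFormatError("profile columns must be 1D")
        if len(self.depth_mm) != len(self.intensity_au):
            raise ProfileFormatError("depth and intensity lengths differ")
        if len(self.depth_mm) == 0:
            raise ProfileFormatError("empty profile")
        if not np.all(np.diff(self.depth_mm) > 0):
            raise ProfileFormatError("depth_mm must be strictly increasing")
        if self.intensity_au.min() < 0 or self.intensity_au.max() > 1:
            raise ProfileFormatError(
                "intensity_au must lie in [0, 1] "
                f"(found range [{self.intensity_au.min():g}, {self.intensity_au.max():g}])"
            )

    def __len__(self) -> int:
        return len(self.depth_mm)


def read_bscan(
    path: str | Path,
    axial_px_mm: float = 1.0,
    lateral_px_mm: float = 1.0,
    meridian_deg: float = 0.0,
) -> BScan:
    """Read an 8-bit grayscale PNG or TIFF as a :class:`BScan`.

    Multi-channel images whose channels are all identical are collapsed to
    one channel; genuinely colored images are rejected.  Pixel scale is not
    stored in PNG, so it is supplied by the caller (sidecar metadata or CLI
    flags); the default of 1 px per unit is safe because densitometry is
    scale-free.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"expected 8-bit image, got dtype {arr.dtype} ({arr.dtype.itemsize * 8}-bit)"
        )
    if arr.ndim == 3:
        if np.all(arr == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise ImageFormatError("color image with unequal channels is not a valid B-scan")
    if arr.ndim != 2:
        raise ImageFormatError(f"expected 2D image, got shape {arr.shape}")
    return BScan(
        pixels=arr.astype(float),
        axial_px_mm=axial_px_mm,
        lateral_px_mm=lateral_px_mm,
        meridian_deg=meridian_deg,
        source_id=path.stem,
    )


def write_bscan(bscan: BScan, path: str | Path) -> Path:
    """Write a B-scan as an 8-bit grayscale PNG or TIFF (values rounded)."""
    path = Path(path)
    arr = np.clip(np.rint(bscan.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr, mode="L").save(path)
    return path


def read_ascan_csv(path: str | Path) -> AScanProfile:
    """Read an A-scan profile CSV with header ``depth_mm,intensity_au``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"A-scan CSV not found: {path}")
    df = pd.read_csv(path)
    missing = {"depth_mm", "intensity_au"} - set(df.columns)
    if missing:
        raise ProfileFormatError(f"missing column(s): {sorted(missing)}")
    return AScanProfile(df["depth_mm"].to_numpy(), df["intensity_au"].to_numpy())


def write_ascan_csv(profile: AScanProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"depth_mm": profile.depth_mm, "intensity_au": profile.intensity_au}
    ).to_csv(path, index=False)
    return path


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        d = dataclasses.asdict(record)
    elif isinstance(record, dict):
        d = dict(record)
    else:
        raise TypeError(f"record must be a dataclass or mapping, got {type(record)!r}")
    out = {}
    for k, v in d.items():
        if isinstance(v, np.generic):
            v = v.item()
        out[k] = v
    return out


def write_results(records: Sequence, path: str | Path, format: str = "csv") -> Path:
    """Write result records (dataclasses or dicts) losslessly to CSV or JSON.

    Floats are serialized with ``repr`` round-trip precision, so a
    write/read cycle preserves every density value bit-exactly.
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    if format not in {"csv", "json"}:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
    path = Path(path)
    rows = [_record_to_dict(r) for r in records]
    if format == "json":
        path.write_text(json.dumps(rows, indent=2, default=str))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> list[dict]:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path).to_dict(orient="records")
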