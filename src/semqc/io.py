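"""Reading and writing the toolkit's standard formats.

Images are grayscale TIFF or PNG, 8- or 16-bit, carried in-memory as a
:class:`GrayscaleImage`.  Tabular inputs are plain comma-separated UTF-8 CSV
with a mandatory header and ``.`` decimal separator; each file must match one
of the named :data:`SCHEMAS`.  Intensities are kept on their stored scale —
a 16-bit image is never silently rescaled to 8 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "GrayscaleImage",
    "SCHEMAS",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class GrayscaleImage:
    """A single-channel micrograph on its stored intensity scale.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities.
    bit_depth
        8 or 16; every intensity must be < ``2**bit_depth``.
    pixel_size_nm
        Optional physical pixel size metadata.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_nm: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("image must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}; expected 8 or 16")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError("image intensities must be integers")
        if px.min() < 0 or px.max() >= 2**self.bit_depth:
            raise ValidationError(
                f"intensities must lie in [0, {2**self.bit_depth - 1}] for {self.bit_depth}-bit"
            )
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def n_levels(self) -> int:
        return 2**self.bit_depth


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array whose color channels are identical to 2-D."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb == rgb[..., :1]).all():
            raise FormatError("multi-channel image with differing channels is not grayscale")
        return rgb[..., 0]
    raise FormatError(f"unsupported image dimensionality {arr.ndim}")


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> GrayscaleImage:
    """Read a grayscale TIFF or PNG micrograph.

    The bit depth is inferred from the file's sample format (uint8 → 8,
    uint16 → 16).  RGB files whose channels are identical are collapsed to a
    single channel; genuinely colored files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(PILImage.open(path))
    else:
        raise FormatError(f"unsupported image format {suffix!r}; expected TIFF or PNG")
    arr = _collapse_channels(np.asarray(arr))
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"unsupported sample format {arr.dtype}; expected uint8 or uint16")
    return GrayscaleImage(pixels=arr, bit_depth=depth, pixel_size_nm=pixel_size_nm)


def write_image(image: GrayscaleImage, path: str | Path) -> None:
    """Write a :class:`GrayscaleImage` to TIFF or PNG, bit-exactly."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        PILImage.fromarray(arr).save(path)
    else:
        raise FormatError(f"unsupported image format {suffix!r}; expected TIFF or PNG")


# --- CSV schemas -----------------------------------------------------------
#
# required: ordered column names; integer / positive constraints are enforced
# on load and on save so a round trip can never launder an invalid table.

SCHEMAS: dict[str, dict] = {
    "histogram": {
        "required": ["gray_level", "count"],
        "integer": ["gray_level", "count"],
        "non_negative": ["gray_level", "count"],
        "positive": [],
    },
    "depth_histogram": {
        "required": ["depth_bin_start_nm", "count"],
        "integer": [],
        "non_negative": ["depth_bin_start_nm", "count"],
        "positive": [],
    },
    "bouton": {
        "required": ["bouton_id", "section_id", "particle_count", "area_um2"],
        "optional": ["label"],
        "integer": ["particle_count"],
        "non_negative": ["particle_count"],
        "positive": ["area_um2"],
    },
    "sheet_resistance": {
        "required": ["sample_id", "rs_ohm_per_sq"],
        "integer": [],
        "non_negative": [],
        "positive": ["rs_ohm_per_sq"],
    },
    "acquisition": {
        "required": ["name", "current_A", "dwell_s", "pixel_nm", "n_beams", "n_exposures"],
        "integer": ["n_beams", "n_exposures"],
        "non_negative": [],
        "positive": ["current_A", "dwell_s", "pixel_nm", "n_beams", "n_exposures"],
    },
}

_NON_NUMERIC = {"bouton_id", "section_id", "sample_id", "name", "label"}


def _validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing column(s) {missing}")
    cols = list(spec["required"]) + [
        c for c in spec.get("optional", []) if c in df.columns
    ]
    df = df[cols].copy()
    for col in cols:
        if col in _NON_NUMERIC:
            if df[col].isna().any() and col in spec["required"]:
                raise ValidationError(f"schema {schema!r}: missing values in {col!r}")
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise ValidationError(f"schema {schema!r}: non-numeric or missing values in {col!r}")
        if col in spec["integer"]:
            if not np.allclose(values, np.round(values), rtol=0, atol=0):
                raise ValidationError(f"schema {schema!r}: fractional value in integer column {col!r}")
            values = values.astype(np.int64)
        if col in spec["non_negative"] and (values < 0).any():
            raise ValidationError(f"schema {schema!r}: negative value in column {col!r}")
        if col in spec["positive"] and (values <= 0).any():
            raise ValidationError(f"schema {schema!r}: non-positive value in column {col!r}")
        df[col] = values
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns a DataFrame with exactly the schema's columns (plus any declared
    optional columns present), numeric columns parsed, row order preserved.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    return _validate_table(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Validate a table against a schema and write it as CSV."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    df = _validate_table(pd.DataFrame(df), schema)
    df.to_csv(path, index=False)


def _round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (used for report formatting)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
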