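"""Image and table I/O with schema validation, plus the run manifest.

Images are 8- or 16-bit grayscale TIFF (single or multi-page) or PNG;
tables are comma- or tab-separated text with a header row, validated
against named column schemas before any pipeline stage sees them.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import FormatError, SchemaError

_ALLOWED_DTYPES = (np.dtype("uint8"), np.dtype("uint16"))

#: Column schemas for the delimited tables the pipelines accept.
TABLE_SCHEMAS: dict = {
    "grades": {
        "columns": {"bead_id": str, "area_grade": int, "thickness_grade": int},
        "ranges": {"area_grade": (0, 4), "thickness_grade": (0, 6)},
    },
    "cells": {
        "columns": {
            "cell_id": int,
            "type": str,
            "area": float,
            "circularity": float,
            "defects": int,
            "spread": bool,
            "engulfed": int,
        },
        "ranges": {"engulfed": (0, None), "defects": (0, None)},
    },
    "factin": {
        "columns": {"group": str, "intensity": float},
        "ranges": {"intensity": (0, None)},
    },
    "poses": {
        "columns": {"ligand": str, "conformer": int, "binding_energy_kcal_mol": float},
        "ranges": {},
    },
}


def read_image(path) -> "list[np.ndarray]":
    """Read a grayscale 8/16-bit TIFF (any page count) or PNG.

    Returns a list of 2-D arrays in page order (length 1 for single-page
    files), dtype preserved.  Color images and unsupported formats are
    rejected with a format error naming the file.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    elif suffix == ".png":
        pages = [iio.imread(path)]
    else:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")
    out = []
    for arr in pages:
        if arr.ndim != 2:
            raise FormatError(f"expected grayscale 2-D image, got shape {arr.shape}: {path}")
        if arr.dtype not in _ALLOWED_DTYPES:
            raise FormatError(f"unsupported bit depth {arr.dtype}: {path}")
        out.append(arr)
    return out


def write_image(path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a float image on the 0-255 rendering scale as 8/16-bit grayscale."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.clip(np.rint(image * 257.0), 0, 65535).astype(np.uint16)
    else:
        raise FormatError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported image format {path.suffix!r}")


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV/TSV against a named schema.

    The delimiter follows the extension (``.tsv`` → tab, otherwise comma).
    Missing columns raise a schema error listing the missing names;
    non-coercible values raise with the offending rows.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; "
                          f"known: {sorted(TABLE_SCHEMAS)}")
    schema = TABLE_SCHEMAS[schema_name]
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(schema["columns"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    for col, typ in schema["columns"].items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad or coerced.isna().any():
                raise SchemaError(f"{path.name}: non-numeric values in {col!r}, rows {bad}")
            if typ is int and not np.allclose(coerced, np.round(coerced)):
                raise SchemaError(f"{path.name}: non-integer values in {col!r}")
            df[col] = coerced.astype(typ)
        elif typ is bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
        else:
            df[col] = df[col].astype(str)
    for col, (lo, hi) in schema["ranges"].items():
        vals = df[col]
        if lo is not None and (vals < lo).any():
            raise SchemaError(f"{path.name}: {col!r} below {lo}")
        if hi is not None and (vals > hi).any():
            raise SchemaError(f"{path.name}: {col!r} above {hi}")
    return df


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, seed: int, inputs=()) -> dict:
    """Write a machine-readable run manifest (config, seed, versions, hashes)."""
    manifest = {
        "package": "immunoquant",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
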