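"""Image reading, measurement-log import, and the canonical 14-column table.

Two data paths converge on the same table: the automated pipeline
(segmentation + morphometry) and the manual workflow, in which an
operator masks each fiber and its lumen in an image editor and exports
a tab-delimited measurement log with columns Document, Area, Perimeter,
Circularity, Height, Width — one row per recorded mask, in pixels.

The canonical table has exactly these columns, in order::

    Name, Lumen Area, Lumen Perimeter, Lumen Circularity, Lumen Height,
    Lumen Width, Outer Area, Outer True Area, Outer Perimeter,
    Outer Circularity, Outer Height, Outer Width, Outer/Lumen, Line

with all areas in μm² and lengths in μm after calibration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .morphometry import CalibrationScale, FiberMetrics

__all__ = [
    "IOFormatError",
    "CANONICAL_COLUMNS",
    "LOG_COLUMNS",
    "read_image",
    "import_measurement_log",
    "write_table",
    "read_table",
    "metrics_to_row",
    "table_from_metrics",
    "load_config",
]


class IOFormatError(ValueError):
    pass


CANONICAL_COLUMNS = [
    "Name",
    "Lumen Area",
    "Lumen Perimeter",
    "Lumen Circularity",
    "Lumen Height",
    "Lumen Width",
    "Outer Area",
    "Outer True Area",
    "Outer Perimeter",
    "Outer Circularity",
    "Outer Height",
    "Outer Width",
    "Outer/Lumen",
    "Line",
]

LOG_COLUMNS = ["Document", "Area", "Perimeter", "Circularity", "Height", "Width"]

PathLike = Union[str, Path]


def read_image(path: PathLike) -> tuple[np.ndarray, dict]:
    """Load a TIFF or PNG micrograph; returns (array, metadata).

    Metadata records dtype, bit depth, and shape. 16-bit values are
    preserved; RGB is left for downstream luminance collapse.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 — surface a clear error with the path
        raise IOFormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise IOFormatError(f"cannot read image {path}: empty or truncated file")
    meta = {
        "path": str(path),
        "dtype": str(arr.dtype),
        "bit_depth": arr.dtype.itemsize * 8,
        "shape": arr.shape,
    }
    return arr, meta


def _log_row_to_um(row: pd.Series, s: float) -> dict:
    return {
        "Area": float(row["Area"]) * s * s,
        "Perimeter": float(row["Perimeter"]) * s,
        "Circularity": float(row["Circularity"]),
        "Height": float(row["Height"]) * s,
        "Width": float(row["Width"]) * s,
    }


def _merge_pair(name: str, line: str, lum: dict, out: dict) -> dict:
    if out["Area"] <= lum["Area"]:
        raise IOFormatError(
            f"fiber {name!r}: outer area {out['Area']:g} ≤ lumen area "
            f"{lum['Area']:g} after pairing — are the lumen/outer rows swapped?"
        )
    a_true = out["Area"] - lum["Area"]
    return {
        "Name": name,
        "Lumen Area": lum["Area"],
        "Lumen Perimeter": lum["Perimeter"],
        "Lumen Circularity": lum["Circularity"],
        "Lumen Height": lum["Height"],
        "Lumen Width": lum["Width"],
        "Outer Area": out["Area"],
        "Outer True Area": a_true,
        "Outer Perimeter": out["Perimeter"],
        "Outer Circularity": out["Circularity"],
        "Outer Height": out["Height"],
        "Outer Width": out["Width"],
        "Outer/Lumen": a_true / lum["Area"],
        "Line": line,
    }


def import_measurement_log(
    path: PathLike,
    scale: CalibrationScale,
    pairing: str = "alternating",
    line: str = "",
) -> pd.DataFrame:
    """Parse a manual measurement log into the canonical table.

    ``pairing='alternating'``: within each Document, rows alternate
    lumen, outer, lumen, outer … in recording order (the lumen mask is
    recorded first); fibers are lettered A, B, … per document and named
    ``<document>_<letter>``. An odd row count for a document is an
    error naming that document.

    ``pairing='by-label'``: each Document value ends in ``_lumen`` or
    ``_outer``; rows are matched on the shared stem, which becomes the
    fiber name (intended as image id + letter).

    Pixel values are converted with ``scale`` (areas by um_per_px²,
    lengths by um_per_px); circularity is dimensionless and passes
    through. Extra columns in the log are ignored by name.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"measurement log not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise IOFormatError(f"measurement log {path} lacks columns: {missing}")
    num = df[LOG_COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any() or (num <= 0).any().any():
        raise IOFormatError(f"measurement log {path}: non-numeric or non-positive values")
    df = pd.concat([df[["Document"]].astype(str), num], axis=1)
    s = scale.um_per_px

    from .segmentation import candidate_letter_sequence

    rows = []
    if pairing == "alternating":
        for doc in df["Document"].unique():
            sub = df[df["Document"] == doc]
            if len(sub) % 2 != 0:
                raise IOFormatError(
                    f"document {doc!r}: odd number of rows ({len(sub)}) in "
                    "alternating mode — each fiber needs a lumen and an outer row"
                )
            n_fib = len(sub) // 2
            letters = candidate_letter_sequence(n_fib)
            for k in range(n_fib):
                lum = _log_row_to_um(sub.iloc[2 * k], s)
                out = _log_row_to_um(sub.iloc[2 * k + 1], s)
                rows.append(_merge_pair(f"{doc}_{letters[k]}", line, lum, out))
    elif pairing == "by-label":
        pairs: dict[str, dict[str, dict]] = {}
        order: list[str] = []
        for _, r in df.iterrows():
            doc = str(r["Document"])
            stem, _, role = doc.rpartition("_")
            role = role.lower()
            if role not in ("lumen", "outer") or not stem:
                raise IOFormatError(
                    f"document {doc!r}: by-label mode expects names ending in "
                    "'_lumen' or '_outer'"
                )
            if stem not in pairs:
                pairs[stem] = {}
                order.append(stem)
            if role in pairs[stem]:
                raise IOFormatError(f"document {doc!r}: duplicate {role} row for {stem!r}")
            pairs[stem][role] = _log_row_to_um(r, s)
        for stem in order:
            got = pairs[stem]
            if set(got) != {"lumen", "outer"}:
                raise IOFormatError(f"fiber {stem!r}: missing {'outer' if 'outer' not in got else 'lumen'} row")
            rows.append(_merge_pair(stem, line, got["lumen"], got["outer"]))
    else:
        raise IOFormatError(f"unknown pairing mode {pairing!r}")
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def metrics_to_row(fm: FiberMetrics) -> dict:
    """One canonical-table row from a :class:`FiberMetrics` record."""
    return {
        "Name": fm.name,
        "Lumen Area": fm.lumen.area,
        "Lumen Perimeter": fm.lumen.perimeter,
        "Lumen Circularity": fm.lumen.circularity,
        "Lumen Height": fm.lumen.height,
        "Lumen Width": fm.lumen.width,
        "Outer Area": fm.outer.area,
        "Outer True Area": fm.outer_true_area,
        "Outer Perimeter": fm.outer.perimeter,
        "Outer Circularity": fm.outer.circularity,
        "Outer Height": fm.outer.height,
        "Outer Width": fm.outer.width,
        "Outer/Lumen": fm.outer_lumen_ratio,
        "Line": fm.line,
    }


def table_from_metrics(metrics: list[FiberMetrics]) -> pd.DataFrame:
    return pd.DataFrame([metrics_to_row(m) for m in metrics], columns=CANONICAL_COLUMNS)


def write_table(table: pd.DataFrame, path: PathLike, report: bool = False) -> None:
    """Write the canonical table as CSV with the exact 14-column header.

    ``report=True`` rounds numeric columns to 2 decimal places for
    publication-style output; by default full precision is kept.
    Decimal separator is always '.', independent of locale.
    """
    if list(table.columns) != CANONICAL_COLUMNS:
        raise IOFormatError(
            f"table columns must be exactly the canonical 14: got {list(table.columns)}"
        )
    out = table.copy()
    if report:
        num_cols = [c for c in CANONICAL_COLUMNS if c not in ("Name", "Line")]
        out[num_cols] = out[num_cols].round(2)
    try:
        out.to_csv(path, index=False, float_format="%.10g" if not report else "%.2f")
    except OSError as exc:
        raise IOFormatError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: PathLike) -> pd.DataFrame:
    """Read back a canonical-table CSV, validating the header."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"table not found: {path}")
    df = pd.read_csv(path, dtype={"Name": str, "Line": str})
    if list(df.columns) != CANONICAL_COLUMNS:
        raise IOFormatError(f"{path} is not a canonical table: columns {list(df.columns)}")
    df["Name"] = df["Name"].fillna("")
    df["Line"] = df["Line"].fillna("")
    return df


def load_config(path: PathLike) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"config file not found: {path}")
    cfg: dict[str, str] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise IOFormatError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg
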