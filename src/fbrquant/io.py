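"""Plain-text and TIFF readers/writers for the pipeline's file formats.

Images are single-channel grayscale TIFF (16-bit unsigned by default);
contours are CSV with ``x_px``/``y_px`` vertex columns; count matrices and
signatures are TSV with genes in rows and the gene symbol in the first
column; Ct tables are tidy CSV. Writing and re-reading an integer image or
a text table reproduces the values exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import AnnotatedImage, Contour

__all__ = [
    "read_image",
    "write_image",
    "read_contour",
    "write_contour",
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_ct",
    "write_ct",
    "read_signature",
    "read_grouping",
    "read_manifest",
]


class InputError(ValueError):
    """Malformed or invalid input file."""


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a single-channel image as 16-bit grayscale TIFF.

    Float images are rounded and clipped into the uint16 range; integer
    images round-trip bitwise.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise InputError(f"{path}: expected a 2-D single-channel image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.unsignedinteger):
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_image(path: str | Path, pixel_size_um: float = 1.0, name: str = "image") -> AnnotatedImage:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise InputError(f"{path}: expected a 2-D single-channel image, got shape {arr.shape}")
    return AnnotatedImage(channels={name: arr}, pixel_size_um=pixel_size_um)


def write_contour(path: str | Path, contour: Contour) -> None:
    pd.DataFrame(contour.vertices, columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_contour(path: str | Path, pixel_size_um: float = 1.0) -> Contour:
    df = pd.read_csv(path)
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise InputError(f"{path}: missing contour column {col!r}")
    if len(df) < 3:
        raise InputError(f"{path}: contour needs at least 3 vertices, found {len(df)}")
    try:
        return Contour(vertices=df[["x_px", "y_px"]].to_numpy(dtype=float),
                       pixel_size_um=pixel_size_um)
    except ValueError as e:
        raise InputError(f"{path}: {e}") from e


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InputError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise InputError(f"{path}: duplicate sample ids")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise InputError(f"{path}: non-numeric count at gene {bad[0]!r}, sample {col!r}")
        neg = df.index[vals < 0]
        if len(neg):
            raise InputError(f"{path}: negative count at gene {neg[0]!r}, sample {col!r}")
        df[col] = vals
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise InputError(f"{path}: sample metadata must have a 'group' column")
    return df


def write_ct(path: str | Path, ct_table: pd.DataFrame) -> None:
    ct_table.to_csv(path, index=False)


def read_ct(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample", "group", "gene", "ct"):
        if col not in df.columns:
            raise InputError(f"{path}: Ct table missing column {col!r}")
    if not np.isfinite(pd.to_numeric(df["ct"], errors="coerce")).all():
        raise InputError(f"{path}: non-numeric Ct values")
    return df


def read_signature(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise InputError(f"{path}: signature expression must be non-negative")
    zero_cols = df.columns[(df == 0).all()]
    if len(zero_cols):
        raise InputError(f"{path}: all-zero signature column(s): {list(zero_cols)}")
    return df


def read_grouping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    for col in ("fine_type", "major_type"):
        if col not in df.columns:
            raise InputError(f"{path}: grouping table missing column {col!r}")
    if df["fine_type"].duplicated().any():
        raise InputError(f"{path}: a fine type maps to more than one major type")
    return dict(zip(df["fine_type"], df["major_type"]))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Per-subject image manifest: subject_id, group, stain, image_path,
    contour paths and pixel size, with paths resolved relative to the
    manifest's directory."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "stain", "image_path", "pixel_size_um"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: manifest missing columns {sorted(missing)}")
    base = Path(path).parent
    for col in df.columns:
        if col.endswith("_path"):
            df[col] = df[col].map(lambda p: str(base / p) if pd.notna(p) else p)
    return df
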