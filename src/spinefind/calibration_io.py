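"""Image, label, and feature-table I/O plus the shared coordinate conventions.

Every module in the package uses the same conventions, fixed here once:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the top,
* the calibration is a single positive scalar in pixels per micrometer,
* intensities are grayscale floats min-max normalized into ``[0, 1]``.

Label files produced by tools with 1-based origins must be converted at this
boundary; nothing downstream ever re-converts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage",
    "LabelSet",
    "CalibrationError",
    "normalize_intensity",
    "load_image",
    "save_image",
    "load_labels",
    "load_label_file",
    "save_labels",
    "save_feature_table",
    "load_feature_table",
]

MIN_SIDE_PX = 32


class CalibrationError(ValueError):
    """Raised for images, scales, or labels violating the shared conventions."""


def normalize_intensity(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize a grayscale array to [0, 1].

    A constant array maps to all zeros (the degenerate case has no contrast
    to preserve).
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise CalibrationError("image contains non-finite values")
    lo = arr.min()
    span = arr.max() - lo
    if span == 0:
        return np.zeros_like(arr)
    return (arr - lo) / span


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D grayscale image in [0, 1] with a pixels-per-micrometer scale."""

    pixels: np.ndarray
    scale: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise CalibrationError(f"expected a 2D image, got ndim={px.ndim}")
        if min(px.shape) < MIN_SIDE_PX:
            raise CalibrationError(
                f"image sides must be >= {MIN_SIDE_PX} px, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise CalibrationError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise CalibrationError("intensities must lie in [0, 1]; normalize first")
        if not (self.scale > 0):
            raise CalibrationError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_um(self, px: float) -> float:
        """Convert a pixel distance to micrometers."""
        return px / self.scale

    def to_px(self, um: float) -> float:
        """Convert a micrometer distance to pixels (exact inverse of to_um)."""
        return um * self.scale


@dataclass
class LabelSet:
    """Point annotations (spine clicks) for one image, in pixel coordinates."""

    image_id: str
    points: list[tuple[int, int]] = field(default_factory=list)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        for r, c in self.points:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise CalibrationError(
                    f"label point ({r}, {c}) outside image of shape {shape} "
                    f"for image {self.image_id!r}"
                )


def load_image(
    path: str | Path,
    scale: float,
    plane: int | str = 0,
) -> CalibratedImage:
    """Load a single-channel 2D TIFF (or one plane of a stack), normalized.

    Parameters
    ----------
    plane:
        For a 3D stack: a plane index, or ``"mip"`` for a maximum-intensity
        projection over planes. Multi-channel (RGB-like) input is rejected.
    """
    if not (scale > 0):
        raise CalibrationError(f"scale must be positive, got {scale}")
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
            raise CalibrationError(
                "multi-channel image; provide a single-channel TIFF"
            )
        if plane == "mip":
            arr = arr.max(axis=0)
        else:
            arr = arr[int(plane)]
    if arr.ndim != 2:
        raise CalibrationError(f"expected 2D image data, got shape {arr.shape}")
    return CalibratedImage(
        normalize_intensity(arr), scale, source_id=Path(path).stem
    )


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF."""
    arr = np.asarray(pixels, dtype=np.float64)
    data = np.round(np.clip(arr, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), data)


# ---------------------------------------------------------------------------
# labels


def _labels_from_rows(rows: Iterable[tuple[str, int, int]]) -> dict[str, LabelSet]:
    out: dict[str, LabelSet] = {}
    for image_id, r, c in rows:
        out.setdefault(image_id, LabelSet(image_id)).points.append((int(r), int(c)))
    return out


def load_label_file(path: str | Path) -> dict[str, LabelSet]:
    """Load all label sets from a CSV (``image_id,row,col`` per line) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            payload = [payload]
        rows = [
            (entry["image_id"], int(p[0]), int(p[1]))
            for entry in payload
            for p in entry.get("points", [])
        ]
        out = _labels_from_rows(rows)
        # preserve empty label sets present in the JSON
        for entry in payload:
            out.setdefault(entry["image_id"], LabelSet(entry["image_id"]))
        return out
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0].lower() == "image_id":  # optional header
            continue
        if len(parts) != 3:
            raise CalibrationError(f"malformed label line: {line!r}")
        rows.append((parts[0], int(parts[1]), int(parts[2])))
    return _labels_from_rows(rows)


def load_labels(
    path: str | Path,
    image_id: str | None = None,
    shape: tuple[int, int] | None = None,
) -> LabelSet:
    """Load the label set for one image from a CSV or JSON label file.

    If the file holds labels for several images, ``image_id`` selects one.
    ``shape`` (optional) enables bounds checking, rejecting out-of-bounds
    points with the offending coordinate named.
    """
    table = load_label_file(path)
    if not table:
        ls = LabelSet(image_id or Path(path).stem)
    elif image_id is not None:
        ls = table.get(image_id, LabelSet(image_id))
    elif len(table) == 1:
        ls = next(iter(table.values()))
    else:
        raise CalibrationError(
            f"label file holds {len(table)} images; pass image_id to select one"
        )
    if shape is not None:
        ls.validate_bounds(shape)
    return ls


def save_labels(labels: LabelSet | Sequence[LabelSet], path: str | Path) -> None:
    """Write label sets as CSV ``image_id,row,col`` rows (or JSON by suffix)."""
    sets = [labels] if isinstance(labels, LabelSet) else list(labels)
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {"image_id": ls.image_id, "points": [[int(r), int(c)] for r, c in ls.points]}
            for ls in sets
        ]
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = ["image_id,row,col"]
    for ls in sets:
        for r, c in ls.points:
            lines.append(f"{ls.image_id},{int(r)},{int(c)}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tables

N_PD = 100
N_PS = 100
N_IS = 20
N_FEATURES = N_PD + N_PS + N_IS + 1  # 221

FEATURE_COLUMNS = (
    [f"pd_{i:03d}" for i in range(1, N_PD + 1)]
    + [f"ps_{i:03d}" for i in range(1, N_PS + 1)]
    + [f"is_{i:03d}" for i in range(1, N_IS + 1)]
    + ["is_length"]
)
META_COLUMNS = ["image_id", "origin_row", "origin_col", "label"]


def save_feature_table(candidates: Sequence, path: str | Path) -> None:
    """Write candidate feature vectors as a CSV with named columns.

    Each candidate must expose ``combined`` (221 values) and ``origin``; an
    optional ``label`` and ``image_id`` are carried through. Round-trips
    through :func:`load_feature_table` to <= 1e-9 relative error.
    """
    records = []
    for cand in candidates:
        vec = np.asarray(cand.combined, dtype=np.float64)
        if vec.shape != (N_FEATURES,):
            raise CalibrationError(
                f"candidate feature vector has shape {vec.shape}, "
                f"expected ({N_FEATURES},)"
            )
        rec = {
            "image_id": getattr(cand, "image_id", ""),
            "origin_row": int(cand.origin[0]),
            "origin_col": int(cand.origin[1]),
            "label": getattr(cand, "label", ""),
        }
        rec.update(dict(zip(FEATURE_COLUMNS, vec)))
        records.append(rec)
    df = pd.DataFrame(records, columns=META_COLUMNS + FEATURE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def load_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame (221 feature + meta columns)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise CalibrationError(f"feature table missing columns: {missing[:3]}...")
    return df


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 221) feature matrix from a loaded feature table."""
    return df[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
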