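"""From click labels to per-candidate spine / non-spine classes.

A user (or the synthetic ground truth) marks each spine with one click. A
1x1 um box is drawn around the click; a candidate whose origin falls inside
an active box is a spine row, any other candidate is a non-spine row. Boxes
are deactivated near the image border (edge artifacts) or when they overlap
an object that became detached from the dendrite; candidates inside
deactivated boxes are dropped rather than mislabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration_io import LabelSet, N_FEATURES
from .detached import DetachedObject
from .features import CandidateFeature

__all__ = [
    "LabelBox",
    "LabeledDataset",
    "build_boxes",
    "assign_classes",
    "split_dataset",
    "concat_datasets",
    "dataset_from_runs",
]

SPINE = 1
NON_SPINE = 0


@dataclass(frozen=True)
class LabelBox:
    """Axis-aligned 1x1 um box around one spine click."""

    center: tuple[int, int]
    half_width_um: float = 0.5
    status: str = "active"   # active | border_excluded | detached_excluded


@dataclass
class LabeledDataset:
    """Per-candidate feature rows with classes; X is (n, 221), y in {0, 1}."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_spine(self) -> int:
        return int((self.y == SPINE).sum())

    @property
    def n_non_spine(self) -> int:
        return int((self.y == NON_SPINE).sum())


def build_boxes(
    labels: LabelSet,
    shape: tuple[int, int],
    scale: float,
    detached: list[DetachedObject] = (),
    box_um: float = 1.0,
    border_margin_um: float = 1.5,
) -> list[LabelBox]:
    """One box per click, with the exclusion rules applied.

    A box whose nearest edge lies within ``border_margin_um`` of any image
    border is ``border_excluded``; a box overlapping any detached object's
    pixels is ``detached_excluded``; the rest are ``active``.
    """
    labels.validate_bounds(shape)
    H, W = shape
    h = (box_um / 2.0) * scale
    margin = border_margin_um * scale
    boxes: list[LabelBox] = []
    for r, c in labels.points:
        edge = min(r - h, c - h, (H - 1) - (r + h), (W - 1) - (c + h))
        if edge < margin:
            status = "border_excluded"
        elif any(
            np.any(
                (np.abs(obj.coords[:, 0] - r) <= h)
                & (np.abs(obj.coords[:, 1] - c) <= h)
            )
            for obj in detached
        ):
            status = "detached_excluded"
        else:
            status = "active"
        boxes.append(LabelBox((int(r), int(c)), box_um / 2.0, status))
    return boxes


def _inside(origin: tuple[int, int], box: LabelBox, scale: float) -> bool:
    h = box.half_width_um * scale
    return (
        abs(origin[0] - box.center[0]) <= h
        and abs(origin[1] - box.center[1]) <= h
    )


def assign_classes(
    candidates: list[CandidateFeature],
    boxes: list[LabelBox],
    scale: float,
) -> LabeledDataset:
    """Label candidates by box membership (boundary inclusive).

    Inside >= 1 active box -> spine; inside only excluded boxes -> dropped;
    otherwise non-spine. A candidate inside several active boxes is still a
    single spine row.
    """
    X_rows, y_rows, meta_rows = [], [], []
    active = [b for b in boxes if b.status == "active"]
    excluded = [b for b in boxes if b.status != "active"]
    for cand in candidates:
        if any(_inside(cand.origin, b, scale) for b in active):
            cls = SPINE
        elif any(_inside(cand.origin, b, scale) for b in excluded):
            continue
        else:
            cls = NON_SPINE
        cand.label = "spine" if cls == SPINE else "non_spine"
        X_rows.append(cand.combined)
        y_rows.append(cls)
        meta_rows.append(
            {
                "image_id": cand.image_id,
                "origin_row": cand.origin[0],
                "origin_col": cand.origin[1],
                "label": cand.label,
            }
        )
    X = np.array(X_rows, dtype=np.float64).reshape(len(y_rows), N_FEATURES)
    return LabeledDataset(X, np.array(y_rows, dtype=int), pd.DataFrame(meta_rows))


def concat_datasets(parts: list[LabeledDataset]) -> LabeledDataset:
    """Stack per-image datasets into one corpus-level dataset."""
    parts = [p for p in parts if len(p)]
    if not parts:
        return LabeledDataset(np.empty((0, N_FEATURES)), np.empty(0, dtype=int))
    return LabeledDataset(
        np.vstack([p.X for p in parts]),
        np.concatenate([p.y for p in parts]),
        pd.concat([p.meta for p in parts], ignore_index=True),
    )


def dataset_from_runs(runs, scale: float) -> LabeledDataset:
    """Label a corpus of pipeline results.

    ``runs`` pairs each image's :class:`~spinefind.features.PipelineResult`
    with its :class:`~spinefind.calibration_io.LabelSet`; boxes are built per
    image with that image's detached objects, then classes are assigned and
    all rows stacked.
    """
    parts = []
    for result, labels in runs:
        boxes = build_boxes(
            labels, result.image.shape, scale, detached=result.detached
        )
        parts.append(assign_classes(result.features, boxes, scale))
    return concat_datasets(parts)


def _take(ds: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    meta = ds.meta.iloc[idx].reset_index(drop=True) if len(ds.meta) else ds.meta
    return LabeledDataset(ds.X[idx], ds.y[idx], meta)


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratify: bool = True,
    by_image: bool = False,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Seeded train/validation/test partition (default 60/20/20).

    Candidate-level by default, stratified by class so the class ratio of
    each split tracks the full set. ``by_image=True`` partitions whole
    images instead (no candidate leakage between splits; class balance is
    then only approximate).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(ds)
    tr_idx, va_idx, te_idx = [], [], []
    if by_image:
        if "image_id" not in ds.meta.columns:
            raise ValueError("by_image split needs image_id metadata")
        images = ds.meta["image_id"].to_numpy()
        uniq = np.array(sorted(set(images.tolist())))
        perm = rng.permutation(len(uniq))
        n_tr = int(round(fractions[0] * len(uniq)))
        n_va = int(round(fractions[1] * len(uniq)))
        groups = (
            set(uniq[perm[:n_tr]]),
            set(uniq[perm[n_tr : n_tr + n_va]]),
            set(uniq[perm[n_tr + n_va :]]),
        )
        for i, img in enumerate(images):
            (tr_idx if img in groups[0] else va_idx if img in groups[1] else te_idx).append(i)
    else:
        classes = np.unique(ds.y) if stratify else [None]
        for cls in classes:
            pool = np.arange(n) if cls is None else np.flatnonzero(ds.y == cls)
            perm = pool[rng.permutation(len(pool))]
            n_tr = int(round(fractions[0] * len(pool)))
            n_va = int(round(fractions[1] * len(pool)))
            tr_idx.extend(perm[:n_tr].tolist())
            va_idx.extend(perm[n_tr : n_tr + n_va].tolist())
            te_idx.extend(perm[n_tr + n_va :].tolist())
    return (
        _take(ds, np.array(sorted(tr_idx), dtype=int)),
        _take(ds, np.array(sorted(va_idx), dtype=int)),
        _take(ds, np.array(sorted(te_idx), dtype=int)),
    )
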