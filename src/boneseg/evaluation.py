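"""Sorensen-Dice evaluation and batch result tabulation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io_types import BinaryMask

__all__ = ["dice", "EvalRecord", "summarize"]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Sorensen-Dice overlap 2|A∩B| / (|A| + |B|).

    Two empty masks are identical, so the score is defined as 1.0.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    am, bm = a.astype_bool(), b.astype_bool()
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


@dataclass
class EvalRecord:
    """Per-image segmentation score, before and after postprocessing."""

    image_id: str
    method: str
    dice_pre: float
    dice_post: float
    group: str  # {normal, edema, hill_sachs}

    def __post_init__(self) -> None:
        for v in (self.dice_pre, self.dice_post):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"dice out of [0,1]: {v}")


def summarize(records: Iterable[EvalRecord]) -> pd.DataFrame:
    """Mean/min/max Dice per (method, group, stage), long format.

    Mirrors the usual before/after result tables: one row per method x
    group x {pre, post} with columns mean, min, max, n.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    rows = []
    for rec in records:
        rows.append({"method": rec.method, "group": rec.group, "stage": "pre",
                     "dice": rec.dice_pre, "image_id": rec.image_id})
        rows.append({"method": rec.method, "group": rec.group, "stage": "post",
                     "dice": rec.dice_post, "image_id": rec.image_id})
    df = pd.DataFrame(rows)
    out = (df.groupby(["method", "group", "stage"])["dice"]
             .agg(["mean", "min", "max", "count"])
             .rename(columns={"count": "n"})
             .reset_index())
    return out
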