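"""Slide-level class areas and the SIP / LIP / TIP fractions.

Given a stitched ternary classification map and the ROI, the module counts
pixels per class and derives the stromal area by subtraction:

    A_Stroma = A_ROI − (A_Tumor + A_Lymphocytes)

Fractions of the ROI area follow: SIP (stroma in percentage) =
A_Stroma / A_ROI, LIP = A_Lymphocytes / A_ROI, TIP = A_Tumor / A_ROI, so
SIP + LIP + TIP = 1 exactly (integer pixel arithmetic before division).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import LYMPHOCYTE, STROMA, TUMOR
from .tiling import IGNORE, rasterize_polygon


@dataclass(frozen=True)
class SlideQuantification:
    """Per-slide pixel areas and area fractions."""

    a_roi: int
    a_tumor: int
    a_lymph: int
    a_stroma: int
    sip: float
    lip: float
    tip: float

    def __post_init__(self) -> None:
        if self.a_roi <= 0:
            raise ValueError("a_roi must be positive")
        if self.a_stroma != self.a_roi - (self.a_tumor + self.a_lymph):
            raise ValueError("stromal area must equal a_roi - (a_tumor + a_lymph)")
        if min(self.a_tumor, self.a_lymph, self.a_stroma) < 0:
            raise ValueError("areas must be non-negative")


def quantify(
    mask: np.ndarray,
    roi_polygon: Sequence[Sequence[float]] | None = None,
) -> SlideQuantification:
    """Quantify class areas of a ternary mask within the ROI.

    ``mask`` holds classes {0: stroma, 1: tumor, 2: lymphocyte} with the
    ignore sentinel outside the ROI.  If ``roi_polygon`` is given, ROI
    membership is its even-odd rasterization; otherwise every non-ignored
    pixel counts as ROI.
    """
    mask = np.asarray(mask)
    if roi_polygon is not None:
        roi = rasterize_polygon(roi_polygon, mask.shape)
    else:
        roi = mask != IGNORE
    inside = mask[roi]
    if inside.size == 0:
        raise ValueError("empty ROI")
    bad = ~np.isin(inside, [STROMA, TUMOR, LYMPHOCYTE])
    if bad.any():
        raise ValueError(
            f"mask contains {int(bad.sum())} ROI pixels outside classes {{0,1,2}}"
        )
    a_roi = int(inside.size)
    a_tumor = int((inside == TUMOR).sum())
    a_lymph = int((inside == LYMPHOCYTE).sum())
    a_stroma = a_roi - (a_tumor + a_lymph)
    sip = a_stroma / a_roi
    lip = a_lymph / a_roi
    # complement keeps sip + lip + tip == 1 exact in floating point;
    # tip equals a_tumor / a_roi to within one ulp
    return SlideQuantification(
        a_roi=a_roi,
        a_tumor=a_tumor,
        a_lymph=a_lymph,
        a_stroma=a_stroma,
        sip=sip,
        lip=lip,
        tip=1.0 - (sip + lip),
    )


def quantify_cohort(
    slides: Sequence[tuple[str, np.ndarray, Sequence[Sequence[float]] | None]],
) -> pd.DataFrame:
    """Per-patient SIP/LIP/TIP from one or more slides per patient.

    ``slides`` holds ``(patient_id, mask, roi_polygon)`` triples.  Patients
    with several slides are aggregated by ROI-area-weighted averaging of the
    fractions (equivalently, pooling the pixel counts).
    """
    if len(slides) == 0:
        raise ValueError("no slides given")
    acc: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for patient_id, mask, roi in slides:
        q = quantify(mask, roi)
        if patient_id not in acc:
            acc[patient_id] = {"a_roi": 0, "a_tumor": 0, "a_lymph": 0}
            order.append(patient_id)
        acc[patient_id]["a_roi"] += q.a_roi
        acc[patient_id]["a_tumor"] += q.a_tumor
        acc[patient_id]["a_lymph"] += q.a_lymph
    rows = []
    for pid in order:
        a = acc[pid]
        a_stroma = a["a_roi"] - (a["a_tumor"] + a["a_lymph"])
        sip = a_stroma / a["a_roi"]
        lip = a["a_lymph"] / a["a_roi"]
        rows.append(
            {
                "patient_id": pid,
                "a_roi": a["a_roi"],
                "a_tumor": a["a_tumor"],
                "a_lymph": a["a_lymph"],
                "a_stroma": a_stroma,
                "sip": sip,
                "lip": lip,
                "tip": 1.0 - (sip + lip),
            }
        )
    return pd.DataFrame(rows)
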