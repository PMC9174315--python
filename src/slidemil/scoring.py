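"""Score aggregation up the hierarchy and the positivity call.

checkpoints -> magnification ensemble (mean of five) -> WSI score (mean of
the three magnification ensembles) -> patient score (mean of WSI scores) ->
label by the 0.58 cutoff, with a score exactly at the cutoff called
positive. A slide missing tumor patches at some magnification is scored
from the magnifications available and flagged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 0.58
DEFAULT_MAGNIFICATIONS = (5, 10, 20)


def score_wsi(mag_scores: dict) -> tuple[float, str]:
    """Unweighted mean of the magnification ensemble scores for one slide.

    ``mag_scores`` maps magnification -> score, with NaN/None marking a
    magnification that had no tumor patches. Returns (score, flags) where
    flags names missing magnifications (empty string when complete).
    """
    present, missing = [], []
    for m, s in sorted(mag_scores.items()):
        if s is None or (isinstance(s, float) and math.isnan(s)):
            missing.append(m)
        else:
            present.append(float(s))
    if not present:
        raise ValueError("no magnification produced a score for this slide")
    flags = "" if not missing else "missing_mags:" + ",".join(
        str(m) for m in missing
    )
    return float(np.mean(present)), flags


def score_patient(wsi_scores, cutoff: float = DEFAULT_CUTOFF
                  ) -> tuple[float, str]:
    """Mean of the patient's WSI scores and the >= cutoff call."""
    scores = [float(s) for s in wsi_scores]
    if not scores:
        raise ValueError("patient has no WSI scores")
    score = float(np.mean(scores))
    label = "positive" if score >= cutoff else "negative"
    return score, label


def build_score_table(mag_scores: dict, manifest,
                      magnifications=DEFAULT_MAGNIFICATIONS,
                      cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Assemble the per-slide / per-patient ScoreTable.

    ``mag_scores`` maps (slide_id, magnification) -> score (NaN allowed).
    Slides absent at every magnification are dropped with a flag on the
    patient; patients with no scored slide are omitted.
    """
    rows = []
    for _, rec in manifest.frame.iterrows():
        sid = rec["slide_id"]
        per_mag = {
            m: mag_scores.get((sid, m), float("nan")) for m in magnifications
        }
        if all(
            v is None or (isinstance(v, float) and math.isnan(v))
            for v in per_mag.values()
        ):
            continue
        wsi, flags = score_wsi(per_mag)
        row = {
            "patient_id": rec["patient_id"],
            "slide_id": sid,
            "wsi_score": wsi,
            "flags": flags,
        }
        for m in magnifications:
            row[f"mag{m}"] = per_mag[m]
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no slide produced a score")
    patient = (
        table.groupby("patient_id")["wsi_score"].mean().rename("patient_score")
    )
    table = table.merge(patient, on="patient_id")
    table["predicted_label"] = np.where(
        table["patient_score"] >= cutoff, "positive", "negative"
    )
    table["cutoff"] = cutoff
    cols = (["patient_id", "slide_id"]
            + [f"mag{m}" for m in magnifications]
            + ["wsi_score", "patient_score", "predicted_label", "cutoff",
               "flags"])
    return table[cols]


def patient_scores(table: pd.DataFrame) -> pd.Series:
    """One score per patient from a ScoreTable."""
    return table.groupby("patient_id")["patient_score"].first()
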