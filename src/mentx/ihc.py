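"""Immunohistochemistry scoring.

LEPR staining is quantified by a modified H-score (range 0-300): percent of
weakly stained cells + 2 x percent moderate + 3 x percent strong. PTTG1
shows single-cell staining and is scored as the positive-cell count in the
40x high-power field with the highest density (hot spot). The combined
marker score is PTTG1 x 100 / LEPR-H-score, undefined when the section is
LEPR-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import IhcTable, SampleAnnotation, ValidationError


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> float:
    """Modified H-score: weak + 2*moderate + 3*strong, bounded by [0, 300]."""
    pcts = (pct_weak, pct_moderate, pct_strong)
    for p in pcts:
        if not (0 <= p <= 100):
            raise ValidationError(f"staining percentage {p} outside [0, 100]")
    if sum(pcts) > 100 + 1e-9:
        raise ValidationError(f"staining percentages sum to {sum(pcts)} > 100")
    return float(pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong)


def pttg1_hotspot_count(per_field_counts: Sequence[int]) -> int:
    """Positive-cell count in the densest high-power field (max over fields)."""
    counts = list(per_field_counts)
    if not counts:
        raise ValidationError("need at least one high-power field count")
    for c in counts:
        if c < 0 or int(c) != c:
            raise ValidationError(f"field count must be a non-negative integer, got {c}")
    return int(max(counts))


def combined_ihc_score(pttg1_count: float, lepr_h_score: float) -> float | None:
    """PTTG1 x 100 / LEPR H-score; None (undefined) for LEPR-negative sections."""
    if pttg1_count < 0 or lepr_h_score < 0:
        raise ValidationError("scores must be non-negative")
    if lepr_h_score == 0:
        return None
    return float(pttg1_count * 100.0 / lepr_h_score)


@dataclass
class IhcScore:
    sample_id: str
    h_score: float
    pttg1_count: int
    combined_score: float | None


def score_table(table: IhcTable) -> pd.DataFrame:
    """Score every sample of an IHC table.

    Returns columns sample_id, h_score, pttg1_count, combined_score
    (NaN where the LEPR H-score is zero).
    """
    rows = []
    for _, r in table.data.iterrows():
        hs = h_score(r["pct_weak"], r["pct_moderate"], r["pct_strong"])
        cnt = int(r["pttg1_count"])
        combined = combined_ihc_score(cnt, hs)
        rows.append({
            "sample_id": r["sample_id"],
            "h_score": hs,
            "pttg1_count": cnt,
            "combined_score": math.nan if combined is None else combined,
        })
    return pd.DataFrame(rows)


def subgroup_summary(
    scores: pd.DataFrame, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Mean combined score per clinico-pathological subgroup with SEM.

    Per-sample combined scores are averaged within each WHO x subgroup
    category; the standard error of the mean quantifies subgroup spread.
    """
    cat = {a.sample_id: a.category for a in annotations}
    df = scores.copy()
    df["category"] = df["sample_id"].map(cat).fillna("unknown")
    df = df.dropna(subset=["combined_score"])
    rows = []
    for category, grp in df.groupby("category", sort=True):
        v = grp["combined_score"].to_numpy(float)
        rows.append({
            "category": category,
            "n": len(v),
            "mean_combined_score": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else math.nan,
        })
    return pd.DataFrame(rows)
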