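"""Expression change in matched primary/recurrent tumor pairs.

Per gene and patient, the recurrent-to-primary expression ratio is
classified as increase (ratio >= 2), decrease (ratio <= 0.5) or stable,
and category counts are summarized separately for patients whose WHO grade
stayed stable versus those undergoing malignant progression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

INCREASE = "increase"
DECREASE = "decrease"
STABLE = "stable"

STABLE_WHO = "stable_who"
INCREASING_WHO = "increasing_who"

FOLD_UP = 2.0
FOLD_DOWN = 0.5


@dataclass
class PairChange:
    patient_id: str
    gene: str
    ratio: float
    category: str
    progression_group: str


def classify_ratio(ratio: float) -> str:
    """Inclusive fold-change thresholds: >= 2 up, <= 0.5 down."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValidationError(f"ratio must be positive and finite, got {ratio}")
    if ratio >= FOLD_UP:
        return INCREASE
    if ratio <= FOLD_DOWN:
        return DECREASE
    return STABLE


def classify_pair_change(
    primary_value: float,
    recurrent_value: float,
    log2_scale: bool = False,
) -> tuple[float, str]:
    """Classify one (primary, recurrent) value pair.

    Values are linear-scale relative expression by default; with
    ``log2_scale`` the ratio is 2**(recurrent − primary).
    """
    if log2_scale:
        ratio = float(2.0 ** (recurrent_value - primary_value))
    else:
        if primary_value <= 0 or recurrent_value <= 0:
            raise ValidationError("expression values must be positive")
        ratio = float(recurrent_value / primary_value)
    return ratio, classify_ratio(ratio)


def pair_table(
    long: pd.DataFrame,
    progression_groups: dict[str, str],
    pairing: str = "consecutive",
    log2_scale: bool = False,
) -> list[PairChange]:
    """Build pair classifications from a long (patient, timepoint, gene, value) frame.

    ``progression_groups`` maps patient_id to 'stable_who' or
    'increasing_who'. Patients with more than two surgical time points are
    paired consecutively (t1 vs t2, t2 vs t3, ...) by default, or first vs
    last with ``pairing='first_last'``. Pairs missing either value for a
    gene are skipped (the summary reports them as missing).
    """
    need = {"patient_id", "timepoint", "gene", "value"}
    if not need.issubset(long.columns):
        raise ValidationError(f"pair table needs columns {sorted(need)}")
    if pairing not in ("consecutive", "first_last"):
        raise ValueError("pairing must be 'consecutive' or 'first_last'")
    out: list[PairChange] = []
    for (patient, gene), grp in long.groupby(["patient_id", "gene"], sort=True):
        grp = grp.sort_values("timepoint")
        vals = grp["value"].to_numpy(float)
        times = grp["timepoint"].to_numpy()
        if len(vals) < 2:
            continue
        if pairing == "first_last":
            steps = [(0, len(vals) - 1)]
        else:
            steps = [(i, i + 1) for i in range(len(vals) - 1)]
        group = progression_groups.get(str(patient))
        if group not in (STABLE_WHO, INCREASING_WHO):
            raise ValidationError(f"patient {patient!r} lacks a progression group")
        for i, j in steps:
            if not (np.isfinite(vals[i]) and np.isfinite(vals[j])):
                continue
            ratio, category = classify_pair_change(vals[i], vals[j], log2_scale)
            out.append(PairChange(str(patient), str(gene), ratio, category, group))
    return out


def summarize_patterns(
    pairs: list[PairChange], genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene x progression-group category counts.

    Returns a frame indexed by (gene, progression_group) with columns
    increase / stable / decrease / n_pairs; counts partition the pairs with
    data for that gene.
    """
    if genes is None:
        genes = sorted({p.gene for p in pairs})
    rows = []
    df = pd.DataFrame(
        [(p.gene, p.progression_group, p.category) for p in pairs],
        columns=["gene", "progression_group", "category"],
    )
    for gene in genes:
        for group in (STABLE_WHO, INCREASING_WHO):
            sub = df[(df["gene"] == gene) & (df["progression_group"] == group)]
            counts = sub["category"].value_counts()
            rows.append({
                "gene": gene,
                "progression_group": group,
                INCREASE: int(counts.get(INCREASE, 0)),
                STABLE: int(counts.get(STABLE, 0)),
                DECREASE: int(counts.get(DECREASE, 0)),
                "n_pairs": int(len(sub)),
            })
    return pd.DataFrame(rows).set_index(["gene", "progression_group"])
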