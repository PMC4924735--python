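"""qPCR relative quantification against dual housekeeping genes.

Relative expression is ΔCq-based: value = E^(ref_Cq − target_Cq) with
amplification efficiency E (default 2, one doubling per cycle) and
ref_Cq = arithmetic mean of the per-housekeeper replicate means — on the
linear scale this is geometric-mean normalization against both reference
genes (typically ACTB and GNB1). Group comparisons use the Mann-Whitney
U test (exact for small samples, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrTable, ValidationError


@dataclass
class RelativeExpression:
    sample_id: str
    gene: str
    value: float | None              # None when all replicates are missing
    replicate_cv: float | None = None

    def __post_init__(self) -> None:
        if self.value is not None and self.value <= 0:
            raise ValidationError("relative expression must be positive")


def _clean(reps: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(reps), dtype=float)
    return arr[np.isfinite(arr)]


def relative_expression(
    target_cq: Sequence[float],
    hk_cq: Sequence[Sequence[float]],
    efficiency: float = 2.0,
    use_median: bool = False,
) -> RelativeExpression | float | None:
    """Relative expression of a target from replicate Cq values.

    ``hk_cq`` is one replicate list per housekeeping gene. Returns
    efficiency**(ref − mean(target)); None when every target replicate is
    missing. ``use_median`` switches the replicate summary from mean to
    median (outlier-robust mode).
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    if not hk_cq:
        raise ValidationError("at least one housekeeping gene required")
    summ = np.median if use_median else np.mean
    tgt = _clean(target_cq)
    if tgt.size == 0:
        return None
    hk_means = []
    for reps in hk_cq:
        r = _clean(reps)
        if r.size == 0:
            return None
        hk_means.append(summ(r))
    ref = float(np.mean(hk_means))
    value = float(efficiency ** (ref - summ(tgt)))
    cv = float(np.std(tgt, ddof=1) / np.mean(tgt)) if tgt.size > 1 else None
    return RelativeExpression("", "", value, cv)


def relative_expression_table(
    table: QpcrTable, efficiency: float = 2.0, use_median: bool = False
) -> pd.DataFrame:
    """Per (sample, gene) relative expression for all non-housekeeping genes.

    Returns a frame with columns sample_id, gene, value, replicate_cv; rows
    with unquantifiable values (all replicates missing for the target or a
    housekeeper) carry NaN.
    """
    hk = table.housekeeping
    rows = []
    for sample_id, grp in table.data.groupby("sample_id", sort=True):
        genes = grp["gene"].tolist()
        missing_hk = [h for h in hk if h not in genes]
        hk_reps = (
            None if missing_hk else [table.replicates(sample_id, h) for h in hk]
        )
        for gene in genes:
            if gene in hk:
                continue
            if hk_reps is None:
                rows.append({"sample_id": sample_id, "gene": gene,
                             "value": math.nan, "replicate_cv": math.nan})
                continue
            res = relative_expression(
                table.replicates(sample_id, gene), hk_reps, efficiency, use_median
            )
            rows.append({
                "sample_id": sample_id,
                "gene": gene,
                "value": math.nan if res is None else res.value,
                "replicate_cv": math.nan if res is None or res.replicate_cv is None
                else res.replicate_cv,
            })
    return pd.DataFrame(rows, columns=["sample_id", "gene", "value", "replicate_cv"])


def mann_whitney_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p when both groups have n <= 8 and no cross-group ties; otherwise
    the tie-corrected normal approximation. All-tied input returns p = 1.
    Returns (U of group A, two-sided p).
    """
    a = _clean(values_a)
    b = _clean(values_b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = a.size * b.size / 2.0
        return u, 1.0
    small = a.size <= 8 and b.size <= 8
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    expr: pd.DataFrame,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison per gene between two sample groups.

    ``expr`` is the long frame from :func:`relative_expression_table`.
    """
    sel = expr.dropna(subset=["value"])
    genes = genes if genes is not None else sorted(sel["gene"].unique())
    rows = []
    for gene in genes:
        sub = sel[sel["gene"] == gene].set_index("sample_id")["value"]
        va = sub.reindex([s for s in group_a_samples if s in sub.index]).dropna()
        vb = sub.reindex([s for s in group_b_samples if s in sub.index]).dropna()
        if va.empty or vb.empty:
            rows.append({"gene": gene, "n_a": len(va), "n_b": len(vb),
                         "median_a": math.nan, "median_b": math.nan,
                         "u_statistic": math.nan, "p_value": math.nan})
            continue
        u, p = mann_whitney_compare(va.to_numpy(), vb.to_numpy())
        rows.append({"gene": gene, "n_a": len(va), "n_b": len(vb),
                     "median_a": float(va.median()), "median_b": float(vb.median()),
                     "u_statistic": u, "p_value": p})
    return pd.DataFrame(rows)
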