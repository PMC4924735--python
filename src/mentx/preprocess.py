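"""Normalization chain for raw array intensities.

The pipeline mirrors the usual treatment of bead-array meningioma profiles:

1. qspline inter-array normalization on the linear scale — each array is
   mapped through a monotone spline fitted between its quantiles and those of
   a geometric-mean reference pseudo-array;
2. median probe-set summarization (one row per gene);
3. log2 transformation;
4. batch-effect removal by a per-gene linear model on batch indicators;
5. per-array median-centering.

Steps 4-5 operate on the log2 scale so that "additive batch effect" and
"centered data" mean what a linear model assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import LINEAR, LOG2, ExpressionMatrix, ValidationError


@dataclass
class NormalizationReport:
    """Per-array quantile summaries before/after each stage plus batch terms."""

    pre_quantiles: pd.DataFrame | None = None
    post_quantiles: pd.DataFrame | None = None
    reference_note: str = ""
    batch_coefficients: pd.DataFrame | None = None
    dropped_probes: int = 0
    stages: list[str] = field(default_factory=list)

    def log(self, stage: str) -> None:
        self.stages.append(stage)


_SUMMARY_QS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


def _array_quantiles(values: np.ndarray) -> pd.DataFrame:
    qs = np.nanquantile(values, _SUMMARY_QS, axis=0)
    return pd.DataFrame(qs.T, columns=[f"q{int(q * 100)}" for q in _SUMMARY_QS])


def qspline_normalize(
    m: ExpressionMatrix,
    n_anchors: int = 14,
    report: NormalizationReport | None = None,
) -> ExpressionMatrix:
    """Quantile-spline inter-array normalization (linear-scale intensities).

    A reference pseudo-array is built as the geometric mean of the sorted
    arrays; for each array a monotone piecewise-cubic mapping (PCHIP) is
    fitted through ``n_anchors`` matched quantile anchors against the
    reference and applied to every intensity. Values outside the anchor range
    are mapped by linear extension of the boundary slope, keeping the full
    transform monotone.
    """
    m.require_scale(LINEAR, "qspline_normalize")
    X = m.values.to_numpy(float)
    if np.nanmin(X) <= 0:
        raise ValidationError("qspline_normalize requires strictly positive intensities")
    if m.n_samples < 2:
        warnings.warn("single array: qspline normalization is the identity")
        return m.with_values(m.values.copy())
    if n_anchors < 3:
        raise ValueError("need at least 3 quantile anchors")

    # interior anchor quantiles; extremes excluded for spline stability
    probs = np.linspace(0, 1, n_anchors + 2)[1:-1]
    Q = np.nanquantile(X, probs, axis=0)          # anchors x samples
    ref = np.exp(np.nanmean(np.log(Q), axis=1))   # geometric-mean pseudo-array

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        x_anchor = Q[:, j]
        # collapse duplicated anchor abscissae (heavily tied arrays)
        x_u, idx = np.unique(x_anchor, return_index=True)
        y_u = ref[idx]
        if x_u.size < 2:
            out[:, j] = X[:, j] * (y_u[0] / x_u[0])
            continue
        spline = PchipInterpolator(x_u, y_u, extrapolate=False)
        col = X[:, j]
        res = spline(col)
        below = col < x_u[0]
        above = col > x_u[-1]
        # multiplicative extension below the lowest anchor keeps the mapping
        # positive, continuous and monotone for arbitrarily small intensities
        res[below] = col[below] * (y_u[0] / x_u[0])
        hi_slope = (y_u[-1] - y_u[-2]) / (x_u[-1] - x_u[-2])
        res[above] = y_u[-1] + (col[above] - x_u[-1]) * max(hi_slope, 1e-12)
        out[:, j] = res

    if report is not None:
        report.pre_quantiles = _array_quantiles(X)
        report.post_quantiles = _array_quantiles(out)
        report.reference_note = (
            f"geometric-mean pseudo-array over {m.n_samples} arrays, "
            f"{n_anchors} quantile anchors, monotone cubic (PCHIP) mapping"
        )
        report.log("qspline")
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def summarize_probes(
    m: ExpressionMatrix,
    probe_to_gene: pd.Series | None = None,
    report: NormalizationReport | None = None,
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by the per-sample median.

    Probes without a gene mapping are dropped (and counted in the report).
    """
    mapping = probe_to_gene if probe_to_gene is not None else m.probe_to_gene
    if mapping is None:
        raise ValidationError("summarize_probes needs a probe-to-gene mapping")
    mapping = mapping.astype(str)
    keep = m.values.index.isin(mapping.index)
    dropped = int((~keep).sum())
    vals = m.values.loc[keep]
    genes = mapping.reindex(vals.index).to_numpy()
    summarized = vals.groupby(genes, sort=True).median()
    if report is not None:
        report.dropped_probes = dropped
        report.log(f"probe summarization ({dropped} unmapped probes dropped)")
    return ExpressionMatrix(summarized, scale=m.scale)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    m.require_scale(LINEAR, "log2_transform")
    X = m.values.to_numpy(float)
    bad = np.argwhere(X <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive value at ({m.values.index[i]}, {m.values.columns[j]}) "
            "cannot be log2-transformed"
        )
    return m.with_values(np.log2(m.values), scale=LOG2)


def batch_correct(
    m: ExpressionMatrix,
    batches: pd.Series | dict[str, str],
    report: NormalizationReport | None = None,
) -> ExpressionMatrix:
    """Remove additive per-batch offsets gene-wise, preserving grand means.

    Per gene a linear model ``value ~ intercept + batch`` is fitted by least
    squares (treatment coding, reference batch = alphabetically first label);
    the fitted batch deviations from the per-gene grand mean are subtracted,
    which leaves the per-gene grand mean untouched on balanced designs and
    makes post-correction batch means equal by construction.
    """
    m.require_scale(LOG2, "batch_correct")
    b = pd.Series(batches).reindex(m.col_ids)
    if b.isna().any():
        raise ValidationError(f"samples without batch label: {b[b.isna()].index.tolist()}")
    labels = sorted(b.unique())
    if len(labels) == 1:
        return m.with_values(m.values.copy())
    counts = b.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"batches with a single sample (noisy estimates): {singletons}")

    X = m.values.to_numpy(float)
    grand = X.mean(axis=1, keepdims=True)
    out = X.copy()
    coef_rows = {}
    for lab in labels:
        cols = np.asarray(b == lab)
        offset = X[:, cols].mean(axis=1, keepdims=True) - grand
        out[:, cols] -= offset
        coef_rows[lab] = offset.ravel()
    if report is not None:
        report.batch_coefficients = pd.DataFrame(coef_rows, index=m.values.index)
        report.log(f"batch correction ({len(labels)} batches)")
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def median_center_log2(
    m: ExpressionMatrix, report: NormalizationReport | None = None
) -> ExpressionMatrix:
    """Per-array median-centering; linear input is log2-transformed first."""
    if m.scale == LINEAR:
        m = log2_transform(m)
    centered = m.values - m.values.median(axis=0)
    if report is not None:
        report.log("median-centering")
    return m.with_values(centered, scale=LOG2)


def normalize_pipeline(
    m: ExpressionMatrix,
    probe_to_gene: pd.Series | None = None,
    batches: pd.Series | dict[str, str] | None = None,
    n_anchors: int = 14,
    skip_qspline: bool = False,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Run the full chain: qspline -> summarize -> log2 -> batch -> center."""
    report = NormalizationReport()
    if not skip_qspline:
        m = qspline_normalize(m, n_anchors=n_anchors, report=report)
    mapping = probe_to_gene if probe_to_gene is not None else m.probe_to_gene
    if mapping is not None:
        m = summarize_probes(m, mapping, report=report)
    if m.scale == LINEAR:
        m = log2_transform(m)
        report.log("log2")
    if batches is not None:
        m = batch_correct(m, batches, report=report)
    m = median_center_log2(m, report=report)
    return m, report
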