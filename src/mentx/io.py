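"""Typed data model and text-format readers/writers.

Expression matrices are tab-separated (first column = probe/gene id, header
row = sample ids, rows = features, columns = samples). Clinical annotation,
qPCR Cq and IHC staining tables are CSV. A tolerant reader for GEO
series-matrix text files is provided for accession-level reanalysis.

Missing values are encoded by the single sentinel token ``NA`` in every
table and surface as ``None``/``NaN`` downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

WHO_GRADES = ("I", "II", "III")
SUBGROUPS = ("NR", "R", "M", "NA")
GENDERS = ("male", "female")

LINEAR = "linear"
LOG2 = "log2"


class ParseError(ValueError):
    """Malformed input file (bad header, non-numeric cell, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a data-model invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples intensity matrix.

    Rows are probes or genes (duplicate row ids are legal: several probes may
    interrogate one gene), columns are samples (duplicates rejected). The
    ``scale`` flag records whether values are raw linear intensities or log2;
    operations that require one scale refuse the other.
    """

    values: pd.DataFrame
    scale: str = LOG2
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        cols = pd.Index(self.values.columns)
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.values.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_scale(self, scale: str, op: str = "operation") -> None:
        if self.scale != scale:
            raise ValidationError(
                f"{op} requires a {scale}-scale matrix, got {self.scale}"
            )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, scale or self.scale, self.probe_to_gene)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return self.with_values(self.values.loc[:, list(sample_ids)])


def read_expression_matrix(
    path: str | Path,
    scale: str = LOG2,
    probe_to_gene: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a tab-separated features x samples matrix.

    Raises :class:`ParseError` with a line number for malformed headers or
    non-numeric cells, and rejects duplicated sample columns.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty header line")
        cols = header.rstrip("\n").split("\t")[1:]
        if not cols:
            raise ParseError(f"{path}:1: header has no sample columns")
        seen: set[str] = set()
        for c in cols:
            if c in seen:
                raise ParseError(f"{path}:1: duplicate sample id {c!r}")
            seen.add(c)
        index: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols) + 1} fields, got {len(parts)}"
                )
            index.append(parts[0])
            row: list[float] = []
            for j, tok in enumerate(parts[1:], start=2):
                if tok == MISSING_TOKEN or tok == "":
                    row.append(math.nan)
                    continue
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {tok!r} in field {j}"
                    ) from None
            rows.append(row)
    values = pd.DataFrame(rows, index=index, columns=cols)
    return ExpressionMatrix(values, scale=scale, probe_to_gene=probe_to_gene)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="id")


# ---------------------------------------------------------------------------
# Sample annotation
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """One clinical record per profiled sample.

    ``subgroup`` encodes future clinical behaviour within the WHO grade:
    NR = no recurrence within >= 36 months of follow-up, R = recurrence at
    the same grade, M = recurrence at a higher grade (malignant progression),
    NA = no usable follow-up or incomplete resection.
    """

    sample_id: str
    who_grade: str
    subgroup: str
    patient_id: str | None = None
    simpson: int | None = None
    followup_months: float | None = None
    pfs_months: float | None = None
    progression_event: bool | None = None
    gender: str | None = None
    age_years: float | None = None
    treatment_naive: bool = True
    is_primary: bool = True
    batch: str = "b0"
    center: str = "c0"

    def __post_init__(self) -> None:
        if self.who_grade not in WHO_GRADES:
            raise ValidationError(
                f"{self.sample_id}: unknown WHO grade {self.who_grade!r}"
            )
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(
                f"{self.sample_id}: unknown subgroup {self.subgroup!r}"
            )
        if self.simpson is not None and self.simpson not in range(1, 6):
            raise ValidationError(f"{self.sample_id}: Simpson grade must be 1-5")
        for name in ("followup_months", "pfs_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: negative {name}")
        if (
            self.pfs_months is not None
            and self.followup_months is not None
            and self.pfs_months > self.followup_months + 1e-9
        ):
            raise ValidationError(
                f"{self.sample_id}: pfs_months {self.pfs_months} exceeds "
                f"followup_months {self.followup_months}"
            )
        if self.gender is not None and self.gender not in GENDERS:
            raise ValidationError(f"{self.sample_id}: unknown gender {self.gender!r}")
        if self.subgroup == "NA":
            if self.followup_months is not None and (self.simpson or 0) < 4:
                raise ValidationError(
                    f"{self.sample_id}: subgroup NA requires missing follow-up "
                    "or Simpson grade >= 4"
                )

    @property
    def category(self) -> str:
        """Compact WHO x subgroup label, e.g. '1NR', '3NA'."""
        return f"{WHO_GRADES.index(self.who_grade) + 1}{self.subgroup}"


ANNOTATION_COLUMNS = [
    "sample_id", "patient_id", "who_grade", "subgroup", "simpson",
    "followup_months", "pfs_months", "progression_event", "gender",
    "age_years", "treatment_naive", "is_primary", "batch", "center",
]
_MANDATORY = ["sample_id", "who_grade", "subgroup"]

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_bool(tok: str, where: str) -> bool:
    t = tok.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ParseError(f"{where}: cannot interpret {tok!r} as boolean")


def read_annotation(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation CSV into validated records."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")
    records: list[SampleAnnotation] = []
    for i, row in df.iterrows():
        where = f"{path}:{i + 2}"

        def get(col: str) -> str | None:
            if col not in df.columns:
                return None
            v = str(row[col]).strip()
            return None if v in ("", MISSING_TOKEN) else v

        def num(col: str) -> float | None:
            v = get(col)
            if v is None:
                return None
            try:
                return float(v)
            except ValueError:
                raise ParseError(f"{where}: non-numeric {col} {v!r}") from None

        try:
            simpson_raw = get("simpson")
            rec = SampleAnnotation(
                sample_id=str(row["sample_id"]).strip(),
                patient_id=get("patient_id"),
                who_grade=str(row["who_grade"]).strip(),
                subgroup=str(row["subgroup"]).strip(),
                simpson=int(float(simpson_raw)) if simpson_raw is not None else None,
                followup_months=num("followup_months"),
                pfs_months=num("pfs_months"),
                progression_event=(
                    _parse_bool(get("progression_event"), where)
                    if get("progression_event") is not None else None
                ),
                gender=get("gender"),
                age_years=num("age_years"),
                treatment_naive=(
                    _parse_bool(get("treatment_naive"), where)
                    if get("treatment_naive") is not None else True
                ),
                is_primary=(
                    _parse_bool(get("is_primary"), where)
                    if get("is_primary") is not None else True
                ),
                batch=get("batch") or "b0",
                center=get("center") or "c0",
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        records.append(rec)
    return records


def annotations_to_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({c: getattr(a, c) for c in ANNOTATION_COLUMNS})
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# qPCR and IHC tables
# ---------------------------------------------------------------------------

@dataclass
class QpcrTable:
    """Long-format Cq table: one row per (sample, gene) with replicate Cq values.

    ``data`` columns: sample_id, gene, then cq_1..cq_k (NaN-padded; every row
    needs at least one finite, positive replicate).
    """

    data: pd.DataFrame
    housekeeping: tuple[str, ...] = ("ACTB", "GNB1")

    def __post_init__(self) -> None:
        need = {"sample_id", "gene"}
        if not need.issubset(self.data.columns):
            raise ValidationError(f"qPCR table needs columns {sorted(need)}")
        reps = self.replicate_columns
        if not reps:
            raise ValidationError("qPCR table has no cq_* replicate columns")
        vals = self.data[reps].to_numpy(float)
        if np.all(np.isnan(vals), axis=1).any():
            raise ValidationError("qPCR row with no replicate values")
        finite = vals[np.isfinite(vals)]
        if (finite <= 0).any():
            raise ValidationError("Cq values must be positive and finite")

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cq_")]

    def replicates(self, sample_id: str, gene: str) -> np.ndarray:
        sel = self.data[
            (self.data["sample_id"] == sample_id) & (self.data["gene"] == gene)
        ]
        if sel.empty:
            raise KeyError(f"no Cq row for ({sample_id}, {gene})")
        vals = sel[self.replicate_columns].to_numpy(float).ravel()
        return vals[np.isfinite(vals)]


def read_qpcr(path: str | Path, housekeeping: Sequence[str] = ("ACTB", "GNB1")) -> QpcrTable:
    df = pd.read_csv(path)
    return QpcrTable(df, tuple(housekeeping))


def write_qpcr(table: QpcrTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, na_rep=MISSING_TOKEN)


@dataclass
class IhcTable:
    """Manual IHC scoring inputs per sample.

    Columns: sample_id, pct_weak, pct_moderate, pct_strong (LEPR staining
    fractions, percent of cells) and pttg1_count (positive cells in the
    densest 40x high-power field).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "pct_weak", "pct_moderate", "pct_strong", "pttg1_count"}
        if not need.issubset(self.data.columns):
            raise ValidationError(f"IHC table needs columns {sorted(need)}")
        pct = self.data[["pct_weak", "pct_moderate", "pct_strong"]].to_numpy(float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("staining percentages must lie in [0, 100]")
        if (pct.sum(axis=1) > 100 + 1e-9).any():
            raise ValidationError("staining percentages sum above 100")
        counts = self.data["pttg1_count"].to_numpy(float)
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValidationError("pttg1_count must be non-negative integers")


def read_ihc(path: str | Path) -> IhcTable:
    return IhcTable(pd.read_csv(path))


def write_ihc(table: IhcTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# GEO series matrix
# ---------------------------------------------------------------------------

def read_geo_series_matrix(
    path: str | Path, scale: str = LINEAR
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a GEO series-matrix text file.

    Returns the expression matrix and a sample-metadata frame built from the
    ``!Sample_*`` header lines (one row per sample, one column per metadata
    key; repeated keys such as ``characteristics_ch1`` are suffixed). The
    parser tolerates absent clinical metadata — mapping metadata onto
    :class:`SampleAnnotation` is the caller's responsibility since accession
    annotations are free-text.
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                key = key[len("!Sample_"):]
                vals = [v.strip().strip('"') for v in vals]
                base, n = key, 1
                while key in meta:
                    n += 1
                    key = f"{base}_{n}"
                meta[key] = vals
    if not table_lines:
        raise ParseError(f"{path}: no series_matrix_table section found")
    header = [t.strip('"') for t in table_lines[0].split("\t")]
    cols = header[1:]
    index, rows = [], []
    for lineno, line in enumerate(table_lines[1:], start=2):
        parts = [t.strip('"') for t in line.split("\t")]
        index.append(parts[0])
        rows.append(
            [math.nan if t in ("", "null", MISSING_TOKEN) else float(t) for t in parts[1:]]
        )
    values = pd.DataFrame(rows, index=index, columns=cols)
    n = len(cols)
    meta_df = pd.DataFrame(
        {k: (v if len(v) == n else v + [""] * (n - len(v))) for k, v in meta.items()},
        index=cols,
    )
    return ExpressionMatrix(values, scale=scale), meta_df
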