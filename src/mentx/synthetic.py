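"""Synthetic meningioma cohorts with planted structure.

The generator emulates the statistical skeleton of a three-grade meningioma
expression study: WHO grades I-III split into clinico-pathological
subgroups (NR / R / M / NA), a shared block of up- and downregulated genes
in every aggressive subgroup (R + M tumors and all of WHO III), additive
per-batch intensity offsets, progression-free survival driven through a
proportional-hazards model by two planted biomarker genes (one
hazard-increasing "PTTG1-like", one protective "LEPR-like"), matched
primary/recurrent tumor pairs, qPCR Cq triplicates and IHC staining
fractions. Identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleAnnotation, IhcTable, QpcrTable, LINEAR, LOG2

PTTG1_LIKE = "PTTG1L"
LEPR_LIKE = "LEPRL"

#: discovery-set structure: per-grade totals 20 / 14 / 28
DEFAULT_SUBGROUP_SIZES: dict[str, int] = {
    "1NR": 10, "1R": 6, "1M": 4,
    "2NR": 6, "2R": 5, "2M": 3,
    "3NR": 4, "3R": 11, "3NA": 13,
}

AGGRESSIVE_CATEGORIES = {"1R", "1M", "2R", "2M", "3NR", "3R", "3NA"}

# grade-scaled effect multipliers for the gradient (PCA-spectrum) mode
GRADIENT_WEIGHTS = {
    "1NR": 0.0, "1R": 0.45, "1M": 0.55,
    "2NR": 0.25, "2R": 0.70, "2M": 0.80,
    "3NR": 1.0, "3R": 1.0, "3NA": 1.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator (defaults mirror the study design)."""

    subgroup_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES)
    )
    n_genes: int = 5000
    n_planted_up: int = 208
    n_planted_down: int = 124
    delta_log2: float = 1.0
    residual_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    gradient_mode: bool = False

    n_batches: int = 2
    batch_offset_sd: float = 0.3

    baseline_hazard: float = 0.02          # events per month
    log_hr_pttg1_like: float = math.log(2.0)
    log_hr_lepr_like: float = -math.log(2.0)
    censoring_rate: float = 0.006          # independent censoring, per month
    followup_horizon: float = 120.0        # administrative censoring, months

    n_pairs_stable: int = 6
    n_pairs_increasing: int = 7

    qpcr_noise_sd: float = 0.2
    hk_baselines: tuple[float, float] = (20.0, 22.0)   # ACTB, GNB1 Cq

    ihc_pttg1_base_count: float = 4.0
    ihc_pttg1_aggressive_count: float = 28.0
    ihc_h_benign: float = 220.0
    ihc_h_aggressive: float = 90.0
    ihc_h_sd: float = 30.0

    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.subgroup_sizes.values()):
            raise ValueError("subgroup sizes must be non-negative")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.residual_sd < 0 or self.batch_offset_sd < 0 or self.qpcr_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth planted into a simulated cohort."""

    up_genes: list[str]
    down_genes: list[str]
    biomarker_log_hr: dict[str, float]
    effect_per_sample: pd.Series        # aggressiveness multiplier actually applied
    batch_offsets: pd.DataFrame | None  # genes x batches

    @property
    def planted(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)


@dataclass
class Cohort:
    """A simulated cohort bundle.

    ``matrix`` holds the clean log2 data (signal + residual noise, no batch
    effect); ``raw_matrix`` the linear-scale intensities with batch offsets
    applied, for exercising the normalization chain.
    """

    matrix: ExpressionMatrix
    raw_matrix: ExpressionMatrix
    annotations: list[SampleAnnotation]
    truth: CohortTruth
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]


def _gene_names(n: int) -> list[str]:
    names = [f"G{i:05d}" for i in range(n)]
    return names


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Simulate expression, clinical annotation and survival for one cohort.

    Expression: per-gene baseline ~ N(baseline_mean, baseline_sd); planted
    up/down genes shift by ±delta_log2 in aggressive samples (grade-scaled
    in gradient mode); residual noise N(0, residual_sd); per-(gene, batch)
    additive offsets N(0, batch_offset_sd) enter only the raw matrix. PFS is
    exponential with hazard baseline_hazard * exp(beta_P z_P + beta_L z_L)
    on the standardized planted biomarker expressions, censored by an
    independent exponential time truncated at the follow-up horizon.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    categories = [c for c, n in sorted(cfg.subgroup_sizes.items()) for _ in range(n)]
    n_samples = len(categories)
    if n_samples < 4:
        raise ValueError("cohort too small to be useful")
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    genes = _gene_names(cfg.n_genes)
    up = genes[: cfg.n_planted_up]
    down = genes[cfg.n_planted_up: cfg.n_planted_up + cfg.n_planted_down]
    # dedicated biomarker genes: first planted up / down gene, renamed
    if up:
        genes[0] = PTTG1_LIKE
        up = [PTTG1_LIKE] + up[1:]
    if down:
        genes[cfg.n_planted_up] = LEPR_LIKE
        down = [LEPR_LIKE] + down[1:]

    weights = np.array([
        (GRADIENT_WEIGHTS[c] if cfg.gradient_mode
         else float(c in AGGRESSIVE_CATEGORIES))
        for c in categories
    ])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    effect = np.zeros(cfg.n_genes)
    effect[: cfg.n_planted_up] = cfg.delta_log2
    effect[cfg.n_planted_up: cfg.n_planted_up + cfg.n_planted_down] = -cfg.delta_log2

    X = (
        baseline[:, None]
        + effect[:, None] * weights[None, :]
        + rng.normal(0.0, cfg.residual_sd, size=(cfg.n_genes, n_samples))
    )
    values = pd.DataFrame(X, index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(values, scale=LOG2)

    batches = np.array([f"b{i % cfg.n_batches}" for i in range(n_samples)])
    rng.shuffle(batches)
    batch_labels = sorted(set(batches))
    offsets = pd.DataFrame(
        rng.normal(0.0, cfg.batch_offset_sd, size=(cfg.n_genes, len(batch_labels))),
        index=genes, columns=batch_labels,
    )
    raw_log2 = values.add(
        pd.DataFrame(offsets.to_numpy()[:, [batch_labels.index(b) for b in batches]],
                     index=genes, columns=sample_ids)
    )
    raw_matrix = ExpressionMatrix(np.exp2(raw_log2), scale=LINEAR)

    # --- survival via proportional hazards on the two biomarker genes -----
    zp = values.loc[PTTG1_LIKE].to_numpy() if PTTG1_LIKE in values.index else np.zeros(n_samples)
    zl = values.loc[LEPR_LIKE].to_numpy() if LEPR_LIKE in values.index else np.zeros(n_samples)
    zp = (zp - zp.mean()) / (zp.std() or 1.0)
    zl = (zl - zl.mean()) / (zl.std() or 1.0)
    hazard = cfg.baseline_hazard * np.exp(
        cfg.log_hr_pttg1_like * zp + cfg.log_hr_lepr_like * zl
    )
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.minimum(
        rng.exponential(1.0 / cfg.censoring_rate, size=n_samples),
        cfg.followup_horizon,
    )
    observed = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    annotations: list[SampleAnnotation] = []
    for i, (sid, cat) in enumerate(zip(sample_ids, categories)):
        grade = {"1": "I", "2": "II", "3": "III"}[cat[0]]
        subgroup = cat[1:]
        if subgroup == "NA":
            followup = pfs = None
            ev = None
            simpson = None
        else:
            pfs = float(round(observed[i], 2))
            ev = bool(event[i])
            # NR labels require >= 36 months of event-free observation
            if subgroup == "NR":
                ev = False
                pfs = float(round(max(observed[i], 36.0 + 4.0 * rng.random()), 2))
            followup = pfs
            simpson = int(rng.integers(1, 4))
        annotations.append(SampleAnnotation(
            sample_id=sid,
            patient_id=f"P{i:03d}",
            who_grade=grade,
            subgroup=subgroup,
            simpson=simpson,
            followup_months=followup,
            pfs_months=pfs,
            progression_event=ev,
            gender="male" if rng.random() < 0.4 else "female",
            age_years=float(np.clip(rng.normal(57.0, 13.0), 18, 87).round(1)),
            treatment_naive=bool(rng.random() < 0.85),
            is_primary=bool(rng.random() < 0.9 or subgroup == "NR"),
            batch=str(batches[i]),
            center="c1" if rng.random() < 0.6 else "c2",
        ))

    truth = CohortTruth(
        up_genes=list(up),
        down_genes=list(down),
        biomarker_log_hr={
            PTTG1_LIKE: cfg.log_hr_pttg1_like,
            LEPR_LIKE: cfg.log_hr_lepr_like,
        },
        effect_per_sample=pd.Series(weights, index=sample_ids),
        batch_offsets=offsets,
    )
    return Cohort(matrix, raw_matrix, annotations, truth, cfg)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(
    cohort: Cohort,
    genes: list[str] | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 3,
) -> QpcrTable:
    """Cq triplicates consistent with the cohort's expression truth.

    Target Cq = mean housekeeping baseline − log2(relative expression) +
    noise, where relative expression is 2**(log2 value − per-gene cohort
    mean). Housekeeper replicates are exactly constant across samples, so
    zero-noise tables invert exactly under ΔCq quantification.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1)
    sd = cfg.qpcr_noise_sd if noise_sd is None else noise_sd
    genes = genes or [PTTG1_LIKE, LEPR_LIKE]
    vals = cohort.matrix.values
    ref = float(np.mean(cfg.hk_baselines))
    rows = []
    for sid in cohort.sample_ids:
        for gene in genes:
            rel_log2 = vals.loc[gene, sid] - vals.loc[gene].mean()
            base_cq = ref - rel_log2
            reps = base_cq + rng.normal(0.0, sd, size=n_replicates)
            rows.append({"sample_id": sid, "gene": gene,
                         **{f"cq_{k + 1}": reps[k] for k in range(n_replicates)}})
        for hk, cq in zip(("ACTB", "GNB1"), cfg.hk_baselines):
            rows.append({"sample_id": sid, "gene": hk,
                         **{f"cq_{k + 1}": cq for k in range(n_replicates)}})
    return QpcrTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Matched pairs
# ---------------------------------------------------------------------------

def generate_pairs(
    config: SimulationConfig | None = None,
    genes: list[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Matched primary/recurrent relative-expression pairs.

    Patients whose recurrence carries a higher WHO grade receive a planted
    upward shift for hazard-associated genes (and downward for protective
    genes); stable-grade patients drift around no change. Returns the long
    (patient_id, timepoint, gene, value) frame and the patient ->
    progression-group map.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed + 2)
    genes = genes or [PTTG1_LIKE, LEPR_LIKE]
    directions = {g: (-1.0 if g == LEPR_LIKE else 1.0) for g in genes}

    groups: dict[str, str] = {}
    rows = []
    n_total = cfg.n_pairs_stable + cfg.n_pairs_increasing
    for i in range(n_total):
        pid = f"MP{i:02d}"
        increasing = i >= cfg.n_pairs_stable
        groups[pid] = "increasing_who" if increasing else "stable_who"
        for gene in genes:
            primary = float(2.0 ** rng.normal(0.0, 0.5))
            shift_mean = 1.4 * directions[gene] if increasing else 0.0
            fold = 2.0 ** rng.normal(shift_mean, 0.5)
            rows.append({"patient_id": pid, "timepoint": 1, "gene": gene,
                         "value": primary})
            rows.append({"patient_id": pid, "timepoint": 2, "gene": gene,
                         "value": primary * fold})
    return pd.DataFrame(rows), groups


# ---------------------------------------------------------------------------
# IHC
# ---------------------------------------------------------------------------

def generate_ihc(cohort: Cohort) -> IhcTable:
    """Staining tables tracking planted aggressiveness.

    PTTG1 hot-spot counts rise and the LEPR H-score falls with the sample's
    aggressiveness multiplier; staining fractions are derived from the
    target H-score with a fixed strong:moderate:weak split so they always
    stay within [0, 100] and sum to at most 100.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    for a in cohort.annotations:
        w = float(cohort.truth.effect_per_sample[a.sample_id])
        lam = cfg.ihc_pttg1_base_count + w * (
            cfg.ihc_pttg1_aggressive_count - cfg.ihc_pttg1_base_count
        )
        count = int(rng.poisson(max(lam, 0.1)))
        h_target = float(np.clip(
            rng.normal(cfg.ihc_h_benign + w * (cfg.ihc_h_aggressive - cfg.ihc_h_benign),
                       cfg.ihc_h_sd),
            0.0, 300.0,
        ))
        # decompose H = w + 2m + 3s with fixed fraction ratios w:m:s = 1:1:1
        # of stained cells -> stained share t solves t/3 * (1+2+3) = H
        t = min(h_target / 2.0, 100.0)
        pct = t / 3.0
        rows.append({
            "sample_id": a.sample_id,
            "pct_weak": pct, "pct_moderate": pct, "pct_strong": pct,
            "pttg1_count": count,
        })
    return IhcTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Plain proportional-hazards simulation (parameter-recovery studies)
# ---------------------------------------------------------------------------

def simulate_ph_cohort(
    n: int,
    log_hr: float,
    baseline_hazard: float = 0.02,
    censoring_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Single standard-normal covariate, exponential PH event times.

    Censoring is an independent exponential clock whose rate is chosen so
    that roughly ``censoring_fraction`` of subjects are censored. Returns a
    frame with columns time, event, x.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    hazard = baseline_hazard * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / hazard)
    c_rate = baseline_hazard * censoring_fraction / max(1.0 - censoring_fraction, 1e-9)
    t_cens = rng.exponential(1.0 / c_rate, size=n)
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame({
        "time": time,
        "event": t_event <= t_cens,
        "x": x,
    })
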