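"""Synthetic single-cell, cohort, and ROI data with known ground truth.

Every downstream stage of the pipeline is testable without external
accessions because this module generates its inputs with controllable
effect sizes:

* patient-clustered embeddings (patient centroids i.i.d. spherical normal,
  cells normal around their centroid) for the heterogeneity test;
* single-cell expression with patient-specific glycolytic programs (half
  the patients, rounded down, get ``glyco_shift`` added to the signature
  genes) for score/stratification recovery;
* bulk cohorts in which tertile membership of a continuous glycolytic
  score multiplies an exponential survival hazard, plus categorical
  clinical covariates with documented marginal frequencies;
* ROI quality-control records with planted threshold violations.

Expression noise is normal on the log scale (the matrices stand in for
log-normalized values, which is what every consumer expects), with a fixed
unit noise sd so ``glyco_shift`` reads directly in noise-sd units.
Determinism contract: identical (config, seed) gives bit-identical output;
each generator draws from its own fixed sub-stream of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .heterogeneity import CellTable
from .io import ROIRecord
from .signatures import ExpressionMatrix, GeneSet

__all__ = [
    "SimConfig",
    "CohortSimConfig",
    "gen_embedding",
    "gen_single_cell",
    "gen_cohort",
    "gen_roi_records",
]

# fixed sub-stream ids so one seed drives independent generator calls
_STREAM_EMBED = 101
_STREAM_EXPR = 202
_STREAM_COHORT = 303
_STREAM_ROI = 404

#: sd of log-scale background expression noise (glyco_shift is in these units)
NOISE_SD = 1.0
#: mean of log-scale background expression
NOISE_MEAN = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell / embedding simulator."""

    n_patients: int
    cells_per_patient: int
    embed_dim: int = 2
    between_sd: float = 1.0
    within_sd: float = 0.3
    glyco_shift: float = 0.0
    n_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "cells_per_patient", "embed_dim", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the bulk-cohort survival simulator.

    ``baseline_hazard`` is the exponential event rate per month in the low
    tertile; the high tertile's hazard is ``baseline_hazard *
    hazard_ratio_high_vs_low`` with the intermediate tertile at the
    geometric midpoint, so the log-hazard is linear in the 0/1/2 group
    code. Follow-up is administratively censored at ``censor_time``.
    """

    n_samples: int
    hazard_ratio_high_vs_low: float = 2.0
    # ln(2)/20: exponential hazard giving the ~20-month median OS typical of PDAC
    baseline_hazard: float = 0.035
    censor_time: float = 36.0
    seed: int = 0
    kras_mutant_freq: float = 0.7
    stage_freqs: tuple[float, ...] = (0.05, 0.25, 0.5, 0.2)  # T1..T4, T3 at 50%
    basal_freq: float = 0.35

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if self.hazard_ratio_high_vs_low <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard ratio and baseline hazard must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if abs(sum(self.stage_freqs) - 1.0) > 1e-9:
            raise ValueError("stage_freqs must sum to 1")


def _patient_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def gen_embedding(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Patient-clustered embedding coordinates and per-cell patient labels.

    Patient centroids ~ N(0, between_sd^2 I_k) i.i.d.; each cell ~
    N(centroid, within_sd^2 I_k). The label array has exactly
    ``cells_per_patient`` occurrences of each patient id.
    """
    rng = np.random.default_rng([_STREAM_EMBED, config.seed])
    cents = rng.normal(0.0, config.between_sd, (config.n_patients, config.embed_dim))
    n_cells = config.n_patients * config.cells_per_patient
    labels = np.repeat(_patient_ids(config.n_patients), config.cells_per_patient)
    coords = np.repeat(cents, config.cells_per_patient, axis=0)
    coords = coords + rng.normal(0.0, config.within_sd, (n_cells, config.embed_dim))
    return coords, np.asarray(labels, dtype=object)


def gen_single_cell(
    config: SimConfig, signature: GeneSet
) -> tuple[ExpressionMatrix, CellTable, dict[str, str]]:
    """Single-cell expression with patient-specific glycolytic programs.

    The gene universe is the signature plus filler genes up to ``n_genes``.
    The first floor(n_patients/2) patients (by index, before any noise) are
    ground-truth "high" and receive ``+glyco_shift`` on every signature gene
    in every one of their cells. Returns the matrix (genes x cells), the
    cell table with embedding coordinates, and the truth map for recovery
    tests.
    """
    if len(signature) > config.n_genes:
        raise ValueError(
            f"signature has {len(signature)} genes but n_genes={config.n_genes}"
        )
    rng = np.random.default_rng([_STREAM_EXPR, config.seed])
    sig_genes = list(signature.genes)
    n_filler = config.n_genes - len(sig_genes)
    genes = sig_genes + [f"FILLER{i + 1:04d}" for i in range(n_filler)]

    coords, labels = gen_embedding(config)
    n_cells = len(labels)
    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]

    values = rng.normal(NOISE_MEAN, NOISE_SD, (config.n_genes, n_cells))
    patients = _patient_ids(config.n_patients)
    n_high = config.n_patients // 2
    truth = {p: ("high" if i < n_high else "low") for i, p in enumerate(patients)}
    high_cells = np.isin(labels, patients[:n_high])
    values[np.ix_(np.arange(len(sig_genes)), np.flatnonzero(high_cells))] += config.glyco_shift

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cell_ids),
        normalization_tag="synthetic-lognormal",
    )
    cells = CellTable(cell_ids=cell_ids, patient_ids=labels, coords=coords)
    return expr, cells, truth


def gen_cohort(config: CohortSimConfig) -> CohortTable:
    """Bulk cohort with a glycolytic score that modulates survival hazard.

    Scores are standard normal; tertile groups are cut at the 1/3 and 2/3
    quantiles; survival times are exponential with hazard baseline *
    HR^(code/2) (code 0/1/2 for Low/Intermediate/High) and administratively
    censored at ``censor_time``. Covariate marginal frequencies are recorded
    in the returned table's metadata.
    """
    from .signatures import ScoreVector, stratify_by_tertiles

    rng = np.random.default_rng([_STREAM_COHORT, config.seed])
    n = config.n_samples
    ids = [f"S{i + 1:04d}" for i in range(n)]
    scores = rng.normal(0.0, 1.0, n)

    if n >= 3:
        groups = stratify_by_tertiles(
            ScoreVector(ids, scores, "glycolytic", [], [])
        ).labels
    else:
        groups = ["Low"] * n
    code = np.array([{"Low": 0, "Intermediate": 1, "High": 2}[g] for g in groups])
    hazard = config.baseline_hazard * config.hazard_ratio_high_vs_low ** (code / 2.0)
    raw_t = rng.exponential(1.0 / hazard)
    event = (raw_t < config.censor_time).astype(int)
    time = np.minimum(raw_t, config.censor_time)

    kras = np.where(rng.random(n) < config.kras_mutant_freq, "mutant", "wild-type")
    stage = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=config.stage_freqs)
    purity = rng.uniform(20.0, 95.0, n)
    subtype = np.where(rng.random(n) < config.basal_freq, "Basal-like", "Classical")
    purity_bin = np.select([purity < 50, purity <= 75], ["low", "mid"], default="high")

    df = pd.DataFrame(
        {
            "sample_id": ids,
            "score": scores,
            "group": pd.Categorical(
                groups, categories=["Low", "Intermediate", "High"], ordered=True
            ),
            "time_months": time,
            "event": event,
            "kras": kras,
            "stage": stage,
            "purity": purity,
            "purity_bin": pd.Categorical(
                purity_bin, categories=["low", "mid", "high"], ordered=True
            ),
            "subtype": subtype,
        }
    )
    meta = {
        "kras_mutant_freq": config.kras_mutant_freq,
        "stage_freqs": dict(zip(["T1", "T2", "T3", "T4"], config.stage_freqs)),
        "basal_freq": config.basal_freq,
        "hazard_ratio_high_vs_low": config.hazard_ratio_high_vs_low,
        "baseline_hazard_per_month": config.baseline_hazard,
        "censor_time_months": config.censor_time,
        "seed": config.seed,
    }
    return CohortTable(df, metadata=meta)


def gen_roi_records(
    n: int, violation_rate: float = 0.3, seed: int = 0
) -> list[ROIRecord]:
    """ROI QC records, a fraction of which violate one random threshold.

    Clean records clear every threshold with margin; each violating record
    fails exactly one randomly chosen rule (by construction), which makes
    the expected per-rule failure report easy to derive in tests.
    """
    if not 0 <= violation_rate <= 1:
        raise ValueError("violation_rate must lie in [0, 1]")
    rng = np.random.default_rng([_STREAM_ROI, seed])
    clean = dict(
        reads=5000, pct_aligned=95.0, saturation=80.0,
        min_neg_control=20, ntc_count=100, nuclei=500, area_um2=5000.0,
    )
    # one planted value per rule, just on the failing side of its threshold
    violations = dict(
        reads=1000, pct_aligned=80.0, saturation=50.0,
        min_neg_control=5, ntc_count=3000, nuclei=100, area_um2=1000.0,
    )
    rules = list(violations)
    records = []
    for i in range(n):
        fields = dict(clean)
        if rng.random() < violation_rate:
            rule = rules[rng.integers(len(rules))]
            fields[rule] = violations[rule]
        records.append(ROIRecord(roi_id=f"ROI{i + 1:03d}", **fields))
    return records
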