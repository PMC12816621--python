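"""File formats, the ROI QC filter, and the end-to-end pipeline runner.

Formats are deliberately plain: expression matrices as TSV (genes as rows)
or MatrixMarket triplet + row/column name files; cell and cohort tables as
headered TSV; gene sets as standard GMT; run configuration as YAML. The
spatial-profiling ROI quality filter applies seven strict-inequality
thresholds conjunctively per region of interest and reports per-rule
failure counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .signatures import ExpressionMatrix, GeneSet

__all__ = [
    "ROIRecord",
    "RunConfig",
    "roi_qc_filter",
    "QC_RULES",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_cell_table",
    "write_cell_table",
    "read_cohort_table",
    "write_cohort_table",
    "run_pipeline",
]

logger = logging.getLogger("glycostrat")


# ---------------------------------------------------------------------------
# ROI quality control


@dataclass(frozen=True)
class ROIRecord:
    """One region of interest's sequencing QC metrics."""

    roi_id: str
    reads: int
    pct_aligned: float  # % of reads successfully trimmed, stitched and aligned
    saturation: float  # sequencing saturation, %
    min_neg_control: int
    ntc_count: int  # no-template control counts
    nuclei: int
    area_um2: float

    def __post_init__(self) -> None:
        for name in ("reads", "min_neg_control", "ntc_count", "nuclei", "area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"ROI {self.roi_id}: {name} must be non-negative")
        for name in ("pct_aligned", "saturation"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"ROI {self.roi_id}: {name} must lie in [0, 100]")


#: the seven QC rules; every inequality is strict, and a record must pass all
QC_RULES: dict[str, callable] = {
    "reads>1000": lambda r: r.reads > 1000,
    "pct_aligned>80": lambda r: r.pct_aligned > 80,
    "saturation>50": lambda r: r.saturation > 50,
    "min_neg_control>5": lambda r: r.min_neg_control > 5,
    "ntc_count<3000": lambda r: r.ntc_count < 3000,
    "nuclei>100": lambda r: r.nuclei > 100,
    "area_um2>1000": lambda r: r.area_um2 > 1000,
}


def roi_qc_filter(
    records: list[ROIRecord],
) -> tuple[list[ROIRecord], dict[str, int]]:
    """Filter ROIs on the seven sequencing QC thresholds.

    A record passes iff it satisfies every rule; the report counts failures
    per rule, so a record failing k rules contributes k to the totals.
    """
    report = {rule: 0 for rule in QC_RULES}
    passed = []
    for rec in records:
        ok = True
        for rule, check in QC_RULES.items():
            if not check(rec):
                report[rule] += 1
                ok = False
        if ok:
            passed.append(rec)
    return passed, report


def read_roi_records(path: str | Path) -> list[ROIRecord]:
    """Read ROI QC records from a headered TSV (columns = ROIRecord fields)."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "roi_id", "reads", "pct_aligned", "saturation",
        "min_neg_control", "ntc_count", "nuclei", "area_um2",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table missing column(s): {missing}")
    return [ROIRecord(**{k: row[k] for k in required}) for _, row in df.iterrows()]


def write_roi_records(records: list[ROIRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file (name <tab> description <tab> symbols...)."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g.strip()]
        sets[name] = GeneSet(name, genes)
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gs in sets:
            desc = descriptions.get(gs.name, "")
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def _orient(df: pd.DataFrame, orientation: str) -> pd.DataFrame:
    """Ensure genes are rows.

    Heuristic for ``auto``: expression matrices almost always have (far)
    more genes than samples, so if the table is wider than it is tall it is
    taken as samples-by-genes and transposed. Override with
    ``orientation='genes_by_samples'`` or ``'samples_by_genes'``.
    """
    if orientation == "genes_by_samples":
        return df
    if orientation == "samples_by_genes":
        return df.T
    if orientation == "auto":
        return df if df.shape[0] >= df.shape[1] else df.T
    raise ValueError(f"unknown orientation {orientation!r}")


def read_expression(
    path: str | Path,
    format: Literal["tsv", "mtx_triplet"] = "tsv",
    orientation: Literal["genes_by_samples", "samples_by_genes", "auto"] = "genes_by_samples",
    strict: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MTX triplet.

    TSV: genes as rows, first column gene symbols, header row of sample
    ids. MTX triplet: ``<stem>.mtx`` plus ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` name files (one identifier per line). Duplicate
    identifiers raise under ``strict``; otherwise duplicates are suffixed.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = _orient(df, orientation)
    elif format == "mtx_triplet":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mat = mmread(str(stem) + ".mtx")
        genes = Path(str(stem) + ".genes.txt").read_text().split()
        samples = Path(str(stem) + ".samples.txt").read_text().split()
        dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX dimensions {dense.shape} do not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")

    for axis, kind in ((df.index, "gene"), (df.columns, "sample")):
        if axis.duplicated().any():
            if strict:
                raise ValueError(
                    f"duplicate {kind} identifiers: "
                    f"{sorted(axis[axis.duplicated()].unique())}"
                )
    if not strict:
        df.index = _dedupe(df.index)
        df.columns = _dedupe(df.columns)
    return ExpressionMatrix(df, normalization_tag=f"read:{path.name}")


def _dedupe(index: pd.Index) -> pd.Index:
    seen: dict[str, int] = {}
    out = []
    for name in index.astype(str):
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return pd.Index(out)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    format: Literal["tsv", "mtx_triplet"] = "tsv",
) -> None:
    """Write an expression matrix as TSV (genes as rows) or MTX triplet."""
    path = Path(path)
    if format == "tsv":
        expr.values.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mmwrite(str(stem) + ".mtx", coo_matrix(expr.values.to_numpy()))
        Path(str(stem) + ".genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
        Path(str(stem) + ".samples.txt").write_text("\n".join(expr.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cell / cohort tables


def read_cell_table(path: str | Path):
    """Read a cell table TSV (cell_id, patient_id, [cell_type], dim1..dimk)."""
    from .heterogeneity import CellTable

    return CellTable.from_frame(pd.read_csv(path, sep="\t"))


def write_cell_table(cells, path: str | Path) -> None:
    cells.to_frame().to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path):
    """Read a cohort TSV (sample_id, group, [score, time_months, event, ...])."""
    from .cohort import CohortTable

    df = pd.read_csv(path, sep="\t")
    if "group" in df.columns:
        cats = [c for c in ("Low", "Intermediate", "High") if c in set(df["group"].dropna())]
        if cats:
            df["group"] = pd.Categorical(df["group"], categories=cats, ordered=True)
    return CohortTable(df)


def write_cohort_table(cohort, path: str | Path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (mirrors the CLI flags)."""

    expression_path: str
    output_dir: str
    signature_path: str | None = None  # default: packaged glycolytic signature
    signature_name: str | None = None
    cell_table_path: str | None = None  # enables the heterogeneity stage
    cohort_path: str | None = None  # enables association + survival stages
    scheme: Literal["median_2group", "tertile_3group"] = "median_2group"
    n_perm: int = 1000
    seed: int = 0
    horizon: float = 36.0
    min_fraction: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Score -> stratify -> (heterogeneity) -> (associations, survival).

    Writes a JSON report plus TSV outputs under ``config.output_dir`` and
    returns the report dict. Any stage failure raises
    :class:`StageError` tagged with the stage name.
    """
    from . import __version__
    from .cohort import association_test, contingency, km_fit, rank_associations
    from .heterogeneity import permutation_test
    from .signatures import (
        glycolytic_signature,
        signature_score,
        stratify_by_median,
        stratify_by_tertiles,
    )

    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "glycostrat",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
    }

    def stage(name: str):
        logger.info("stage %s starting (seed=%d)", name, config.seed)

    # -- score ------------------------------------------------------------
    stage("score")
    try:
        expr = read_expression(config.expression_path)
        if config.signature_path:
            sets = read_gmt(config.signature_path)
            name = config.signature_name or next(iter(sets))
            if name not in sets:
                raise ValueError(f"signature {name!r} not in {config.signature_path}")
            signature = sets[name]
        else:
            signature = glycolytic_signature()
        scores = signature_score(expr, signature, config.min_fraction)
    except Exception as exc:
        raise StageError("score", str(exc)) from exc
    scores.to_series().rename("score").to_csv(out / "scores.tsv", sep="\t")
    report["score"] = {
        "signature": signature.name,
        "n_samples": len(scores.sample_ids),
        "genes_used": len(scores.genes_used),
        "genes_missing": scores.genes_missing,
    }

    # -- stratify ----------------------------------------------------------
    stage("stratify")
    try:
        strat = (
            stratify_by_median(scores)
            if config.scheme == "median_2group"
            else stratify_by_tertiles(scores)
        )
    except Exception as exc:
        raise StageError("stratify", str(exc)) from exc
    strat.to_series().rename("group").to_csv(out / "groups.tsv", sep="\t")
    counts = pd.Series(strat.labels).value_counts().to_dict()
    report["stratify"] = {
        "scheme": strat.scheme,
        "thresholds": strat.thresholds,
        "group_sizes": {str(k): int(v) for k, v in counts.items()},
    }

    # -- heterogeneity ------------------------------------------------------
    if config.cell_table_path:
        stage("heterogeneity")
        try:
            cells = read_cell_table(config.cell_table_path)
            perm = permutation_test(cells, n_perm=config.n_perm, seed=config.seed)
        except Exception as exc:
            raise StageError("heterogeneity", str(exc)) from exc
        pd.DataFrame({"null_stat": perm.null_stats}).to_csv(
            out / "null_distribution.tsv", sep="\t", index=False
        )
        report["heterogeneity"] = {
            "observed": perm.observed,
            "p_empirical": perm.p_empirical,
            "p_conservative": perm.p_conservative,
            "n_perm": perm.n_perm,
            "seed": perm.seed,
        }

    # -- associations + survival -------------------------------------------
    if config.cohort_path:
        stage("associate")
        try:
            cohort = read_cohort_table(config.cohort_path)
            results = []
            for var in cohort.covariate_names():
                try:
                    results.append(association_test(contingency(cohort, var), var))
                except ValueError as exc:
                    logger.warning("skipping %s: %s", var, exc)
            results = rank_associations(results)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("associate", str(exc)) from exc
        report["associations"] = [
            {
                "variable": r.variable,
                "p_primary": r.p_primary,
                "test_used": r.test_used,
                "significant": r.significant,
                "rank": r.rank,
            }
            for r in results
        ]

        if {"time_months", "event"} <= set(cohort.df.columns):
            stage("survival")
            try:
                fit = km_fit(cohort, horizon=config.horizon)
            except Exception as exc:
                raise StageError("survival", str(exc)) from exc
            fit.curves.to_csv(out / "survival_curves.tsv", sep="\t", index=False)
            report["survival"] = {
                "logrank_p": fit.logrank_p,
                "trend_p": fit.trend_p,
                "horizon": fit.horizon,
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "report.json")
    return report
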