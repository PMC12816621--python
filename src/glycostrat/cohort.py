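"""Clinical/molecular association testing and 3-year survival endpoints.

Associations between the glycolytic group and categorical cohort variables
(hypoxia group, KRAS mutation status, tumor purity bin, molecular subtype,
stage) are tested on contingency tables with both a chi-square test and
Fisher's exact test; the primary p value follows the usual small-expected-
count rule, is rounded to four decimal places for reporting, and results
are ranked by significance at the 0.05 level. Overall survival is analyzed
as 3-year OS: follow-up is administratively censored at a 36-month horizon,
Kaplan-Meier curves are fit per glycolytic group, groups are compared with
the (unweighted) log-rank test, and a trend across ordered groups is tested
with a Cox proportional-hazards fit on the 0/1/2 group code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortTable",
    "AssociationResult",
    "SurvivalFit",
    "contingency",
    "association_test",
    "rank_associations",
    "bh_adjust",
    "km_fit",
    "fisher_exact_rxc",
]

#: maximum number of fixed-margin tables enumerated for the r x c exact test
MAX_EXACT_TABLES = 2_000_000


def comb_bound(total: int, parts: int) -> float:
    """Number of compositions of ``total`` into ``parts`` non-negative parts."""
    from math import comb

    return float(comb(total + parts - 1, parts - 1))


@dataclass
class CohortTable:
    """Per-sample glycolytic score, group label, survival, and covariates.

    Backed by a DataFrame with columns ``sample_id``, ``group`` and
    optionally ``score``, ``time_months``, ``event`` plus named categorical
    covariate columns. ``metadata`` carries simulation or provenance
    information and is never interpreted by the statistics.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValueError("cohort table requires 'sample_id' and 'group' columns")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if "time_months" in df.columns and (df["time_months"].dropna() < 0).any():
            raise ValueError("survival times must be non-negative")
        if "event" in df.columns:
            ev = df["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.df)

    def covariate_names(self) -> list[str]:
        """Categorical covariate columns (continuous columns are excluded)."""
        reserved = {"sample_id", "score", "group", "time_months", "event"}
        out = []
        for c in self.df.columns:
            if c in reserved or pd.api.types.is_float_dtype(self.df[c]):
                continue
            out.append(c)
        return out


@dataclass
class AssociationResult:
    """One variable's group-association test.

    ``p_primary`` is the chooser's pick rounded to 4 decimals (the reported
    scale); ``p_primary_exact`` keeps full precision for downstream use.
    """

    variable: str
    table: pd.DataFrame
    p_chisq: float | None
    p_fisher: float | None
    p_primary: float
    p_primary_exact: float
    test_used: str
    significant: bool
    rank: int | None = None


@dataclass
class SurvivalFit:
    """Per-group product-limit curves plus the group-comparison tests.

    ``curves`` is tidy: one row per (group, event/censor time) with the
    number at risk, events, and the survival estimate. ``logrank_p`` and
    ``trend_p`` are ``None`` when no events occurred.
    """

    curves: pd.DataFrame
    logrank_p: float | None
    trend_p: float | None
    horizon: float


def _factor_levels(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        declared = list(series.cat.categories)
    else:
        declared = sorted(series.dropna().unique())
    observed = set(series.dropna().unique())
    return [lv for lv in declared if lv in observed]


def contingency(cohort: CohortTable, variable: str) -> pd.DataFrame:
    """Cross-tabulate glycolytic group against one categorical variable.

    Rows are groups, columns are variable levels, both in declared level
    order (categorical order if declared, else sorted). Samples missing
    either value are excluded; the count is recorded in
    ``table.attrs["n_excluded"]``.
    """
    if variable not in cohort.df.columns:
        raise KeyError(f"variable {variable!r} not in cohort table")
    sub = cohort.df[["group", variable]]
    complete = sub.dropna()
    n_excluded = len(sub) - len(complete)
    rows = _factor_levels(complete["group"])
    cols = _factor_levels(complete[variable])
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError(
            f"degenerate table for {variable!r}: group has {len(rows)} observed "
            f"level(s), variable has {len(cols)}"
        )
    tab = pd.crosstab(complete["group"], complete[variable], dropna=True)
    tab = tab.reindex(index=rows, columns=cols, fill_value=0)
    tab.attrs["n_excluded"] = n_excluded
    tab.attrs["variable"] = variable
    return tab


def _enumerate_exact_p(observed: np.ndarray) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration.

    Tables with the observed margins are enumerated recursively; the p
    value sums the (hypergeometric/multinomial) probabilities of all tables
    no more probable than the observed one — the probability-ordering
    two-sided convention, matching the classical 2x2 definition.
    """
    row_sums = observed.sum(axis=1)
    col_sums = observed.sum(axis=0)
    n = observed.sum()
    log_const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)

    def log_p(table: np.ndarray) -> float:
        return log_const - gammaln(table + 1).sum()

    lp_obs = log_p(observed)
    cutoff = lp_obs + 1e-7  # tolerate float noise in the "no more probable" rule
    r, c = observed.shape
    # upper bound on the number of fixed-margin tables: compositions per row
    bound = 1.0
    for rs in row_sums[:-1]:
        bound *= comb_bound(int(rs), c)
        if bound > MAX_EXACT_TABLES:
            raise RuntimeError("exact enumeration exceeds feasibility bound")
    total = 0.0
    count = 0

    def recurse(row: int, remaining_cols: np.ndarray, partial: list[np.ndarray]) -> None:
        nonlocal total, count
        if row == r - 1:
            last = remaining_cols
            count += 1
            if count > MAX_EXACT_TABLES:
                raise RuntimeError("exact enumeration exceeds feasibility bound")
            table = np.vstack(partial + [last])
            if log_p(table) <= cutoff:
                total += np.exp(log_p(table))
            return
        target = row_sums[row]

        def fill(col: int, left: int, current: list[int]) -> None:
            if col == c - 1:
                if left <= remaining_cols[c - 1]:
                    rowvec = np.array(current + [left])
                    recurse(row + 1, remaining_cols - rowvec, partial + [rowvec])
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, current + [v])

        fill(0, int(target), [])

    recurse(0, col_sums.copy(), [])
    return min(1.0, float(total))


def fisher_exact_rxc(table: np.ndarray | pd.DataFrame) -> float:
    """Two-sided Fisher exact p for any r x c count table.

    2x2 tables go through the standard hypergeometric routine; larger
    tables are enumerated exactly (feasible for the small clinical tables
    this pipeline produces). Raises ``RuntimeError`` past the enumeration
    feasibility bound.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape == (2, 2):
        return float(stats.fisher_exact(arr.astype(int))[1])
    return _enumerate_exact_p(arr.astype(int))


def association_test(table: pd.DataFrame | np.ndarray, variable: str | None = None) -> AssociationResult:
    """Chi-square + Fisher tests of independence on one contingency table.

    The chi-square p is always computed (Yates continuity correction for
    2x2 only). Fisher's exact p is computed for every 2x2 table, and for
    larger tables when any expected count is < 5 and the total is <= 500
    (exact-enumeration feasibility). The primary p is Fisher's when the
    standard small-sample rule fires — any expected count < 5, or a 2x2
    table with n < 40 — otherwise chi-square; it is reported rounded to
    four decimal places, with full precision kept alongside.
    """
    if isinstance(table, pd.DataFrame):
        name = variable or table.attrs.get("variable", "variable")
        arr = table.to_numpy()
        tab_df = table
    else:
        arr = np.asarray(table)
        name = variable or "variable"
        tab_df = pd.DataFrame(arr)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has an empty row or column margin")

    n = int(arr.sum())
    is_2x2 = arr.shape == (2, 2)
    chi2_res = stats.chi2_contingency(arr, correction=is_2x2)
    p_chisq = float(chi2_res.pvalue)
    expected = chi2_res.expected_freq
    small_expected = bool((expected < 5).any())

    p_fisher: float | None = None
    if is_2x2:
        p_fisher = fisher_exact_rxc(arr)
    elif small_expected and n <= 500:
        try:
            p_fisher = fisher_exact_rxc(arr)
        except RuntimeError:
            warnings.warn(
                f"{name}: exact enumeration infeasible for this table; "
                "falling back to chi-square"
            )

    fisher_appropriate = small_expected or (is_2x2 and n < 40)
    if fisher_appropriate and p_fisher is not None:
        p_exact, used = p_fisher, "fisher"
    else:
        p_exact, used = p_chisq, "chi-square"
    p_primary = round(p_exact, 4)
    return AssociationResult(
        variable=name,
        table=tab_df,
        p_chisq=p_chisq,
        p_fisher=p_fisher,
        p_primary=p_primary,
        p_primary_exact=p_exact,
        test_used=used,
        significant=p_primary < 0.05,
    )


def rank_associations(results: list[AssociationResult]) -> list[AssociationResult]:
    """Rank association results by significance (smallest primary p first)."""
    ordered = sorted(results, key=lambda r: (r.p_primary_exact, r.variable))
    for i, res in enumerate(ordered, start=1):
        res.rank = i
    return ordered


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1) | ~np.isfinite(arr)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


_GROUP_ORDERS = (["Low", "Intermediate", "High"], ["Low", "High"])


def _ordered_codes(groups: pd.Series) -> np.ndarray | None:
    levels = _factor_levels(groups)
    for order in _GROUP_ORDERS:
        if set(levels) <= set(order):
            mapping = {g: i for i, g in enumerate(order) if g in levels}
            # re-rank to consecutive codes over observed levels
            mapping = {g: rank for rank, g in enumerate(sorted(mapping, key=mapping.get))}
            return groups.map(mapping).to_numpy(dtype=float)
    return None


def km_fit(cohort: CohortTable, horizon: float = 36.0) -> SurvivalFit:
    """Kaplan-Meier 3-year overall survival by glycolytic group.

    Observations beyond ``horizon`` months are administratively censored at
    the horizon before fitting (events after the horizon become censorings
    at the horizon). Group curves are compared with the unweighted log-rank
    test; when groups are ordered (Low < Intermediate < High) a trend p is
    added from a Cox proportional-hazards fit on the integer group code.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = cohort.df.dropna(subset=["group", "time_months", "event"]).copy()
    levels = _factor_levels(df["group"])
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with survival data")
    over = df["time_months"] > horizon
    df.loc[over, "event"] = 0
    df.loc[over, "time_months"] = horizon

    rows = []
    for g in levels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"], label=str(g))
        et = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        for t in et.index:
            rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "at_risk": int(et.loc[t, "at_risk"]),
                    "events": int(et.loc[t, "observed"]),
                    "survival": float(surv.loc[t]),
                }
            )
    curves = pd.DataFrame(rows, columns=["group", "time", "at_risk", "events", "survival"])

    if int(df["event"].sum()) == 0:
        return SurvivalFit(curves=curves, logrank_p=None, trend_p=None, horizon=horizon)

    lr = multivariate_logrank_test(df["time_months"], df["group"].astype(str), df["event"])
    logrank_p = float(lr.p_value)

    trend_p = None
    codes = _ordered_codes(df["group"])
    if codes is not None and len(np.unique(codes)) >= 2:
        fit_df = pd.DataFrame(
            {"T": df["time_months"].to_numpy(), "E": df["event"].to_numpy(), "code": codes}
        )
        try:
            cph = CoxPHFitter()
            cph.fit(fit_df, duration_col="T", event_col="E")
            trend_p = float(cph.summary.loc["code", "p"])
        except Exception as exc:  # degenerate fits (e.g., all events in one group)
            warnings.warn(f"trend test unavailable: {exc}")
    return SurvivalFit(curves=curves, logrank_p=logrank_p, trend_p=trend_p, horizon=horizon)
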