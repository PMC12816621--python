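"""Gene-signature scoring and cohort stratification.

The central quantity is the *glycolytic score*: the arithmetic mean of the
normalized expression of a 14-gene glycolytic signature (HK1, HK2, PGAM4,
LDHA, SLC2A1, PKM2, ALDOA, ENO1, ALDOC, GPI, PGAM1, GAPDH, TPI1, PKLR),
computed per sample or per cell. Cohorts are then stratified either by the
cohort median (High/Low, single-cell cohorts) or by tertiles
(Low/Intermediate/High, bulk cohorts). The same machinery scores hypoxia
(median over a signature built by intersecting tumor-upregulated genes with
HIF-1a transcriptional targets), calls Basal-like vs Classical molecular
subtypes by argmax of two signature means, and bins ESTIMATE-style tumor
purity percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ScoreVector",
    "GroupAssignment",
    "SignatureCoverageError",
    "load_alias_table",
    "canonical_symbol",
    "glycolytic_signature",
    "log_normalize",
    "signature_score",
    "stratify_by_median",
    "stratify_by_tertiles",
    "build_hypoxia_signature",
    "hypoxia_score",
    "call_subtype",
    "bin_purity",
]


class SignatureCoverageError(ValueError):
    """Raised when too few signature genes are present in a matrix."""


# ---------------------------------------------------------------------------
# symbol reconciliation

_ALIAS_CACHE: dict[str, str] | None = None


def load_alias_table() -> dict[str, str]:
    """Packaged gene-symbol alias table (e.g. PKM2 -> PKM).

    Matching is case-insensitive after whitespace trimming; aliases map a
    legacy symbol to the canonical locus symbol.
    """
    global _ALIAS_CACHE
    if _ALIAS_CACHE is None:
        text = (resources.files("glycostrat") / "data" / "aliases.tsv").read_text()
        table: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            table[old.strip().upper()] = new.strip().upper()
        _ALIAS_CACHE = table
    return _ALIAS_CACHE


def canonical_symbol(symbol: str, aliases: dict[str, str] | None = None) -> str:
    """Trim, uppercase and alias-resolve a gene symbol."""
    if aliases is None:
        aliases = load_alias_table()
    s = symbol.strip().upper()
    return aliases.get(s, s)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols (duplicates rejected after aliasing)."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes) -> None:
        genes = tuple(str(g).strip() for g in genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        canon = [canonical_symbol(g) for g in genes]
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise ValueError(f"gene set {name!r} has duplicate symbols: {dupes}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def canonical(self) -> tuple[str, ...]:
        return tuple(canonical_symbol(g) for g in self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples (or cells) normalized expression.

    ``values`` is a DataFrame indexed by gene symbol with sample/cell
    identifiers as columns. Identifiers must be unique in both dimensions.
    ``normalization_tag`` records provenance (e.g. the normalization applied
    upstream) and is carried through, never interpreted.
    """

    values: pd.DataFrame
    normalization_tag: str = ""

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            raise ValueError(
                f"duplicate gene identifiers: {sorted(idx[idx.duplicated()].unique())}"
            )
        if cols.duplicated().any():
            raise ValueError(
                f"duplicate sample identifiers: {sorted(cols[cols.duplicated()].unique())}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ScoreVector:
    """Per-sample signature scores plus the coverage bookkeeping."""

    sample_ids: list[str]
    scores: np.ndarray
    signature_name: str
    genes_used: list[str]
    genes_missing: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.sample_ids) != len(self.scores):
            raise ValueError("one score per sample required")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.signature_name)


#: fixed label vocabularies per stratification scheme
SCHEME_LABELS = {
    "median_2group": ("Low", "High"),
    "tertile_3group": ("Low", "Intermediate", "High"),
    "purity_bins": ("low", "mid", "high"),
    "subtype": ("Classical", "Basal-like"),
}


@dataclass
class GroupAssignment:
    """Categorical group label per sample under a named scheme."""

    sample_ids: list[str]
    labels: list[str]
    scheme: Literal["median_2group", "tertile_3group", "purity_bins", "subtype"]
    thresholds: list[float] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("every sample must be labeled")
        vocab = set(SCHEME_LABELS[self.scheme])
        bad = set(self.labels) - vocab
        if bad:
            raise ValueError(f"labels {sorted(bad)} outside scheme vocabulary {sorted(vocab)}")

    def to_series(self) -> pd.Series:
        return pd.Series(
            pd.Categorical(self.labels, categories=list(SCHEME_LABELS[self.scheme]), ordered=True),
            index=self.sample_ids,
            name=self.scheme,
        )


# ---------------------------------------------------------------------------
# operations


def log_normalize(
    counts: pd.DataFrame,
    scale: float = 1e4,
    log_base: Literal["2", "e", 2] = "e",
) -> ExpressionMatrix:
    """Library-size normalize and log-transform a count matrix.

    Each column (sample) is divided by its total, multiplied by ``scale``
    and transformed as log(1 + x) in the chosen base. Columns summing to
    zero are rejected by name.
    """
    counts = pd.DataFrame(counts)
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero-sum count column(s): {list(zero.index)}")
    scaled = counts.div(colsums, axis=1) * scale
    base = str(log_base)
    if base == "2":
        vals = np.log2(1.0 + scaled)
    elif base == "e":
        vals = np.log1p(scaled)
    else:
        raise ValueError(f"log_base must be 2 or e, got {log_base!r}")
    tag = f"lognorm(scale={scale:g},base={base})"
    return ExpressionMatrix(vals, normalization_tag=tag)


def _match_signature(
    expr: ExpressionMatrix, signature: GeneSet, min_fraction: float
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Rows of ``expr`` matching the signature, plus used/missing bookkeeping."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    gene_canon = np.array([canonical_symbol(g) for g in expr.gene_ids])
    used, missing, rows = [], [], []
    for sym, canon in zip(signature.genes, signature.canonical()):
        mask = gene_canon == canon
        if mask.any():
            used.append(sym)
            rows.append(expr.values.loc[mask].mean(axis=0))
        else:
            missing.append(sym)
    frac = len(used) / len(signature)
    if frac < min_fraction:
        raise SignatureCoverageError(
            f"signature {signature.name!r}: only {len(used)}/{len(signature)} genes "
            f"present (min_fraction={min_fraction}); missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} gene(s) missing from "
            f"matrix: {missing}",
            stacklevel=3,
        )
    return pd.DataFrame(rows), used, missing


def signature_score(
    expr: ExpressionMatrix, signature: GeneSet, min_fraction: float = 0.5
) -> ScoreVector:
    """Mean normalized expression of the signature genes, per sample.

    Missing genes are reported, never imputed; a present-gene fraction below
    ``min_fraction`` raises :class:`SignatureCoverageError`.
    """
    sub, used, missing = _match_signature(expr, signature, min_fraction)
    scores = sub.mean(axis=0).to_numpy()
    return ScoreVector(expr.sample_ids, scores, signature.name, used, missing)


def hypoxia_score(
    expr: ExpressionMatrix, signature: GeneSet, min_fraction: float = 0.5
) -> ScoreVector:
    """Per-sample *median* expression over the hypoxia signature genes.

    Group-level summaries (the hypoxia score of a glycolytic group) are the
    median of the member samples' scores, taken downstream.
    """
    sub, used, missing = _match_signature(expr, signature, min_fraction)
    scores = sub.median(axis=0).to_numpy()
    return ScoreVector(expr.sample_ids, scores, signature.name, used, missing)


def build_hypoxia_signature(upregulated: GeneSet, tf_targets: GeneSet) -> GeneSet:
    """Intersect tumor-upregulated genes with HIF-1a transcriptional targets.

    Symbols are alias-normalized before intersecting; order follows
    ``upregulated``. An empty intersection is an error, not an empty set.
    """
    target_canon = set(tf_targets.canonical())
    genes = [g for g, c in zip(upregulated.genes, upregulated.canonical()) if c in target_canon]
    if not genes:
        raise ValueError(
            f"no overlap between {upregulated.name!r} and {tf_targets.name!r}; "
            "cannot build a hypoxia signature"
        )
    return GeneSet(f"{upregulated.name}&{tf_targets.name}", genes)


def stratify_by_median(scores: ScoreVector) -> GroupAssignment:
    """High/Low split at the cohort median glycolytic score.

    A sample is High iff its score *strictly exceeds* the median; ties at
    the median go Low (so an all-equal cohort is all Low).
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("median stratification needs at least 2 samples")
    med = float(np.median(scores.scores))
    labels = ["High" if s > med else "Low" for s in scores.scores]
    return GroupAssignment(scores.sample_ids, labels, "median_2group", thresholds=[med])


def stratify_by_tertiles(scores: ScoreVector) -> GroupAssignment:
    """Low/Intermediate/High split at the tertiles of the score distribution.

    Thresholds are the 1/3 and 2/3 linear-interpolation quantiles; bins are
    upper-closed (score <= q1 -> Low; q1 < score <= q2 -> Intermediate;
    score > q2 -> High).
    """
    if len(scores.sample_ids) < 3:
        raise ValueError("tertile stratification needs at least 3 samples")
    q1, q2 = np.quantile(scores.scores, [1 / 3, 2 / 3])
    labels = [
        "Low" if s <= q1 else ("Intermediate" if s <= q2 else "High") for s in scores.scores
    ]
    return GroupAssignment(
        scores.sample_ids, labels, "tertile_3group", thresholds=[float(q1), float(q2)]
    )


def call_subtype(
    expr: ExpressionMatrix,
    basal: GeneSet,
    classical: GeneSet,
    min_fraction: float = 0.5,
) -> GroupAssignment:
    """Basal-like vs Classical call: argmax of the two signature means.

    Exact ties go Classical (with a warning); both score vectors are kept in
    ``extras`` so the margin of each call can be inspected.
    """
    b = signature_score(expr, basal, min_fraction)
    c = signature_score(expr, classical, min_fraction)
    n_ties = int(np.sum(b.scores == c.scores))
    if n_ties:
        warnings.warn(f"{n_ties} sample(s) with exactly tied subtype scores -> Classical")
    labels = ["Basal-like" if bs > cs else "Classical" for bs, cs in zip(b.scores, c.scores)]
    return GroupAssignment(
        expr.sample_ids, labels, "subtype", extras={"basal_scores": b, "classical_scores": c}
    )


def bin_purity(purity: pd.Series | np.ndarray, sample_ids: list[str] | None = None) -> GroupAssignment:
    """Bin tumor purity percentages into <50 (low), 50-75 (mid), >75 (high).

    Both boundaries belong to the middle bin, making the bins exhaustive and
    disjoint. Values outside [0, 100] are rejected.
    """
    if isinstance(purity, pd.Series):
        ids = list(purity.index) if sample_ids is None else list(sample_ids)
        vals = purity.to_numpy(dtype=float)
    else:
        vals = np.asarray(purity, dtype=float)
        ids = [f"S{i}" for i in range(len(vals))] if sample_ids is None else list(sample_ids)
    bad = vals[(vals < 0) | (vals > 100) | ~np.isfinite(vals)]
    if bad.size:
        raise ValueError(f"purity values outside [0, 100]: {bad.tolist()}")
    labels = ["low" if v < 50 else ("mid" if v <= 75 else "high") for v in vals]
    return GroupAssignment(ids, labels, "purity_bins", thresholds=[50.0, 75.0])


def glycolytic_signature() -> GeneSet:
    """The packaged 14-gene glycolytic signature."""
    from .io import read_gmt  # local import: io depends on this module

    path = resources.files("glycostrat") / "data" / "glycolysis.gmt"
    sets = read_gmt(str(path))
    return sets["GLYCOLYTIC_14"]
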