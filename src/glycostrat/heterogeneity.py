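"""Interpatient heterogeneity in an embedding: centroid statistic + permutation test.

Given per-cell embedding coordinates (typically 2-D UMAP, but any k >= 1)
and patient labels, the heterogeneity statistic is the mean of all pairwise
Euclidean distances between per-patient centroids (the mean coordinates of
each patient's cells). Significance is assessed by uniformly shuffling the
patient-label multiset across cells, recomputing the statistic for each of
``n_perm`` shuffles, and reporting the empirical p value: the fraction of
permuted statistics >= the observed one. Ties count toward the numerator,
and the empirical p may be exactly zero; the conventional (b+1)/(n+1)
estimate is carried alongside as ``p_conservative``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "CellTable",
    "PermutationResult",
    "centroids",
    "mean_intercentroid_distance",
    "permutation_test",
]


@dataclass
class CellTable:
    """Per-cell patient label, optional cell-type label, and k-D coordinates."""

    cell_ids: list[str]
    patient_ids: np.ndarray
    coords: np.ndarray
    cell_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.cell_ids)
        if n == 0:
            raise ValueError("cell table is empty")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell identifiers must be unique")
        if self.coords.shape[0] != n or len(self.patient_ids) != n:
            raise ValueError("one coordinate row and one patient label per cell required")
        if self.coords.shape[1] < 1:
            raise ValueError("embedding must have at least one dimension")
        if pd.isna(self.patient_ids).any():
            raise ValueError("patient label missing for some cells")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != n:
                raise ValueError("one cell-type label per cell required")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def embed_dim(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"dim{i + 1}" for i in range(self.embed_dim)]
        )
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(0, "cell_id", self.cell_ids)
        if self.cell_type is not None:
            df.insert(2, "cell_type", self.cell_type)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTable":
        dim_cols = [c for c in df.columns if c.startswith("dim")]
        if not dim_cols:
            raise ValueError("no embedding columns (dim1..dimk) found")
        ct = df["cell_type"].to_numpy() if "cell_type" in df.columns else None
        return cls(
            cell_ids=df["cell_id"].astype(str).tolist(),
            patient_ids=df["patient_id"].to_numpy(),
            coords=df[dim_cols].to_numpy(dtype=float),
            cell_type=ct,
        )


@dataclass
class PermutationResult:
    """Observed statistic, permutation null, and the empirical p value."""

    observed: float
    null_stats: np.ndarray
    p_empirical: float
    n_perm: int
    seed: int
    p_conservative: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if len(self.null_stats) != self.n_perm:
            raise ValueError("null_stats length must equal n_perm")
        recomputed = float(np.mean(self.null_stats >= self.observed))
        if abs(recomputed - self.p_empirical) > 1e-12:
            raise ValueError("p_empirical inconsistent with null_stats")


def centroids(cells: CellTable) -> dict[str, np.ndarray]:
    """Per-patient mean embedding coordinates."""
    if cells.n_cells == 0:
        raise ValueError("empty cell table")
    df = pd.DataFrame(cells.coords)
    out = df.groupby(pd.Series(cells.patient_ids), sort=True).mean()
    return {str(pid): row.to_numpy() for pid, row in out.iterrows()}


def mean_intercentroid_distance(cents: dict[str, np.ndarray]) -> float:
    """Mean of all pairwise Euclidean distances between group centroids."""
    if len(cents) < 2:
        raise ValueError("need at least 2 groups to measure separation")
    mat = np.vstack([cents[k] for k in sorted(cents)])
    return float(pdist(mat).mean())


def _stat_from_codes(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Mean intercentroid distance with integer-coded labels (vectorized path)."""
    sums = np.zeros((n_groups, coords.shape[1]))
    np.add.at(sums, codes, coords)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    cents = sums / counts[:, None]
    return float(pdist(cents).mean())


def permutation_test(
    cells: CellTable, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Label-shuffling permutation test of interpatient centroid separation.

    Coordinates stay fixed; each permutation uniformly shuffles the patient
    label multiset across all cells (group sizes are conserved exactly) and
    the statistic is recomputed. One seeded generator drives all shuffles
    sequentially, so a (cells, n_perm, seed) triple replays bit-identically.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    labels = pd.Series(cells.patient_ids)
    codes, uniques = pd.factorize(labels, sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least 2 patient groups for a permutation test")
    observed = _stat_from_codes(cells.coords, codes, n_groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _stat_from_codes(cells.coords, rng.permutation(codes), n_groups)
    b = int(np.sum(null >= observed))
    return PermutationResult(
        observed=observed,
        null_stats=null,
        p_empirical=b / n_perm,
        n_perm=n_perm,
        seed=seed,
        p_conservative=(b + 1) / (n_perm + 1),
    )
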