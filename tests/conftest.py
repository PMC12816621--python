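import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import glycostrat as g

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def glyco_sig() -> g.GeneSet:
    return g.glycolytic_signature()


@pytest.fixture
def small_expr() -> g.ExpressionMatrix:
    """3 genes x 4 samples with hand-set values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 6.0, 0.0], [6.0, 2.0, 0.0, 2.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return g.ExpressionMatrix(df)


@pytest.fixture
def synthetic_cells() -> g.CellTable:
    coords, labels = g.gen_embedding(
        g.SimConfig(n_patients=5, cells_per_patient=20, between_sd=3.0, within_sd=0.5, seed=7)
    )
    return g.CellTable(
        cell_ids=[f"c{i}" for i in range(len(labels))], patient_ids=labels, coords=coords
    )


@pytest.fixture
def toy_survival_cohort() -> g.CohortTable:
    """Two groups, hand-enumerable times/events for the log-rank oracle."""
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "group": ["Low"] * 4 + ["High"] * 4,
            "time_months": [1.0, 2.0, 3.0, 4.0, 2.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 0, 1, 1, 0],
        }
    )
    return g.CohortTable(df)


def patient_median_split(expr, cells, signature):
    """Per-patient mean signature score, then median High/Low split."""
    sv = g.signature_score(expr, signature)
    per_patient = (
        pd.Series(sv.scores, index=cells.patient_ids).groupby(level=0).mean()
    )
    psv = g.ScoreVector(list(per_patient.index), per_patient.to_numpy(), "glyco", [], [])
    ga = g.stratify_by_median(psv)
    return dict(zip(ga.sample_ids, ga.labels))
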