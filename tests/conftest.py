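import numpy as np
import pytest

from screenrich import ActivityTable, LabeledRanking, RankedScreen
from screenrich.ranking import REDUNDANT


def make_ranking(labels, scores=None, parent_ids=None, treatment=REDUNDANT, **kw):
    """LabeledRanking from a best-first 0/1 label sequence.

    Scores default to strictly decreasing values (no ties); pass explicit
    scores to create tie blocks.
    """
    labels = np.asarray(labels, dtype=bool)
    N = labels.size
    if scores is None:
        scores = np.arange(N, 0, -1, dtype=float)
    ids = np.array([f"s{i}" for i in range(N)], dtype=object)
    if parent_ids is None:
        parent_ids = np.array([f"p{i}" for i in range(N)], dtype=object)
    else:
        parent_ids = np.asarray(parent_ids, dtype=object)
    return LabeledRanking(
        ids=ids,
        parent_ids=parent_ids,
        labels=labels,
        scores=np.asarray(scores, dtype=float),
        treatment=treatment,
        **kw,
    )


def random_tied_ranking(rng, max_n=50):
    """Random two-class ranking with integer scores (forcing tie blocks)."""
    N = int(rng.integers(3, max_n + 1))
    n = int(rng.integers(1, N))
    labels = np.zeros(N, dtype=bool)
    labels[rng.choice(N, size=n, replace=False)] = True
    scores = rng.integers(0, max(2, N // 2), size=N).astype(float)
    order = np.argsort(-scores, kind="stable")
    return make_ranking(labels[order], scores=scores[order])


@pytest.fixture
def make_labeled_ranking():
    return make_ranking


# Residual kinase activities (%) of the four confirmed potent inhibitors of
# the primary kinase, with their off-target panel.
TABLE1_CSV = """\
compound_id,CK1d/e,GSK3a/b,CDK5/p25,DYRK1a
NSC45572,7,82,77,94
NSC252777,18,96,98,72
NSC71866,14,74,25,72
NSC105827,20,33,7,12
"""


@pytest.fixture
def table1_csv(tmp_path):
    p = tmp_path / "table1_activity.csv"
    p.write_text(TABLE1_CSV)
    return p


@pytest.fixture
def table1_activity():
    residuals = {
        "NSC45572": {"CK1d/e": 7.0, "GSK3a/b": 82.0, "CDK5/p25": 77.0, "DYRK1a": 94.0},
        "NSC252777": {"CK1d/e": 18.0, "GSK3a/b": 96.0, "CDK5/p25": 98.0, "DYRK1a": 72.0},
        "NSC71866": {"CK1d/e": 14.0, "GSK3a/b": 74.0, "CDK5/p25": 25.0, "DYRK1a": 72.0},
        "NSC105827": {"CK1d/e": 20.0, "GSK3a/b": 33.0, "CDK5/p25": 7.0, "DYRK1a": 12.0},
    }
    return ActivityTable.from_mapping(residuals, primary_kinase="CK1d/e")


@pytest.fixture
def two_class_screen():
    """Tiny docking-like screen: two parents with several states each."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "state_id": ["a1", "a2", "b1", "b2", "b3"],
            "parent_id": ["A", "A", "B", "B", "B"],
            "score": [-9.0, -7.0, -8.0, -6.5, -6.0],
        }
    )
    return RankedScreen.from_frame(frame, direction="lower_better", name="tiny")
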