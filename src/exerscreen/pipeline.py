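"""End-to-end convenience pipeline: cohort → telemetry → scores → features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Participant, generate_cohort, participants_frame
from .config import CohortConfig
from .discrimination import ROCResult, roc_curve
from .features import feature_table
from .modelsel import cross_validate
from .scoring import score_sessions
from .telemetry import SessionRecord, simulate_sessions


@dataclass
class StudyData:
    """Everything a downstream analysis needs, in one object."""

    config: CohortConfig
    cohort: list[Participant]
    sessions: dict[str, list[SessionRecord]]
    participants: pd.DataFrame  # one row per participant
    domain_scores: pd.DataFrame  # long format
    features: pd.DataFrame  # wide, one row per participant


def run_study(config: CohortConfig | None = None) -> StudyData:
    """Simulate a full trial and derive the per-participant feature matrix."""
    config = config or CohortConfig()
    cohort = generate_cohort(config)
    sessions = {p.id: simulate_sessions(p, config) for p in cohort}
    all_sessions = [s for recs in sessions.values() for s in recs]
    scores = score_sessions(all_sessions)
    features = feature_table(cohort, scores)
    return StudyData(
        config=config,
        cohort=cohort,
        sessions=sessions,
        participants=participants_frame(cohort),
        domain_scores=scores,
        features=features,
    )


def classifier_screen(
    features: pd.DataFrame,
    positive: str = "MCI",
    negative: str = "CN",
    k: int = 10,
    seed: int = 0,
    selection: str = "nested",
) -> ROCResult:
    """ROC of the classifier's out-of-fold positive-class probability for a
    two-group screen (default MCI vs CN).

    Restricts the feature table to the two groups, cross-validates the
    feedforward classifier on them, and sweeps the pooled out-of-fold
    P(positive) as the screening score.
    """
    sub = features[features.label.isin([negative, positive])].reset_index(drop=True)
    X = sub.drop(columns=["participant_id", "label"])
    y = sub["label"].to_numpy()
    report = cross_validate(X, y, k=k, seed=seed, selection=selection,
                            classes=(negative, positive))
    scores = report.oof_proba[:, 1]
    return roc_curve(scores, (y == positive).astype(int),
                     direction="higher_is_positive",
                     score_name=f"classifier P({positive})")
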