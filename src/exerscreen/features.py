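"""Longitudinal trend features.

For every exercise domain, the session-by-session score series is reduced
to mean, slope and intercept of an ordinary least-squares line
``y = a x + b`` — once over the whole training period (x = global session
index) and once per difficulty level (x = within-level session ordinal,
reset to 1 at each level entry so per-level intercepts estimate
level-entry performance). The slope is the performance change speed within
a period; a higher slope means faster session-to-session improvement.

Feature names follow the ``"<Domain> <Stat><Period>"`` convention, e.g.
``"HRMG MeanTotal"``, ``"HeartRate SlopeLevel3"``. Missing level blocks
(a participant promoted past a level) are explicit NaNs, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Participant
from .scoring import DomainScore

#: domains entering the default feature set (balance is scored but excluded)
FEATURE_DOMAINS = ("strength", "aerobic", "flexibility", "hrmg", "heart_rate", "borg")

_DOMAIN_LABEL = {
    "strength": "Strength",
    "aerobic": "Aerobic",
    "flexibility": "Flexibility",
    "balance": "Balance",
    "hrmg": "HRMG",
    "heart_rate": "HeartRate",
    "borg": "Borg",
}

STATS = ("Mean", "Slope", "Intercept")
PERIODS = ("Total", "Level1", "Level2", "Level3", "Level4")


def feature_names(domains: Sequence[str] = FEATURE_DOMAINS) -> list[str]:
    """All feature-column names for the given domains, in canonical order."""
    return [
        f"{_DOMAIN_LABEL[d]} {stat}{period}"
        for d in domains
        for period in PERIODS
        for stat in STATS
    ]


@dataclass
class TrendFeatures:
    """Mean / slope / intercept summary of one score series."""

    mean: float
    slope: Optional[float]
    intercept: Optional[float]
    n_sessions: int


@dataclass
class FeatureVector:
    participant_id: str
    age: float
    entries: dict[str, float] = field(default_factory=dict)
    label: Optional[str] = None


def fit_trend(series: Sequence[tuple[float, float]]) -> TrendFeatures:
    """OLS line fit of score on session index.

    ``series`` is a list of (session_index, score) pairs with strictly
    increasing indices. With a single observation the slope and intercept
    are undefined and returned as None.
    """
    if len(series) == 0:
        raise ValueError("empty score series")
    x = np.asarray([s[0] for s in series], dtype=float)
    y = np.asarray([s[1] for s in series], dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("session indices must be strictly increasing")
    mean = float(np.mean(y))
    if len(series) < 2:
        return TrendFeatures(mean=mean, slope=None, intercept=None, n_sessions=1)
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFeatures(
        mean=mean, slope=float(slope), intercept=float(intercept), n_sessions=len(series)
    )


def build_feature_vector(
    scores: Sequence[DomainScore],
    participant: Participant,
    domains: Sequence[str] = FEATURE_DOMAINS,
) -> FeatureVector:
    """Trend features of one participant across all periods and domains.

    Total-period fits use the global session index as x; per-level fits use
    the within-level ordinal (1, 2, ...). Levels the participant never
    played yield NaN entries.
    """
    rows = [d for d in scores if d.participant_id == participant.id]
    if not rows:
        raise ValueError(f"no sessions for participant {participant.id}")
    rows.sort(key=lambda d: d.session_index)

    entries: dict[str, float] = {}
    for domain in domains:
        label = _DOMAIN_LABEL[domain]
        dom_rows = [d for d in rows if d.domain == domain]
        _fill(entries, label, "Total", [(d.session_index, d.score) for d in dom_rows])
        for level in (1, 2, 3, 4):
            lvl = [d for d in dom_rows if d.level == level]
            series = [(i + 1, d.score) for i, d in enumerate(lvl)]
            _fill(entries, label, f"Level{level}", series)
    return FeatureVector(
        participant_id=participant.id,
        age=participant.age,
        entries=entries,
        label=participant.group,
    )


def _fill(entries: dict, label: str, period: str, series: list) -> None:
    if not series:
        tf = TrendFeatures(np.nan, np.nan, np.nan, 0)
    else:
        tf = fit_trend(series)
    entries[f"{label} Mean{period}"] = tf.mean
    entries[f"{label} Slope{period}"] = np.nan if tf.slope is None else tf.slope
    entries[f"{label} Intercept{period}"] = (
        np.nan if tf.intercept is None else tf.intercept
    )


def feature_table(
    cohort: Sequence[Participant],
    scores: pd.DataFrame | Sequence[DomainScore],
    domains: Sequence[str] = FEATURE_DOMAINS,
) -> pd.DataFrame:
    """Wide feature matrix: one row per participant.

    Columns: ``participant_id``, ``label``, ``Age`` and one column per
    trend feature. ``scores`` may be the long-format domain-score table or
    a flat list of :class:`DomainScore`.
    """
    if isinstance(scores, pd.DataFrame):
        score_objs = [
            DomainScore(
                r.participant_id, int(r.session_index), int(r.level), r.domain, float(r.score)
            )
            for r in scores.itertuples(index=False)
        ]
    else:
        score_objs = list(scores)
    by_pid: dict[str, list[DomainScore]] = {}
    for d in score_objs:
        by_pid.setdefault(d.participant_id, []).append(d)

    records = []
    for p in cohort:
        fv = build_feature_vector(by_pid.get(p.id, []), p, domains=domains)
        records.append(
            {"participant_id": p.id, "label": fv.label, "Age": fv.age, **fv.entries}
        )
    return pd.DataFrame(records)
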