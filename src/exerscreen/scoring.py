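"""Game scoring and per-session domain aggregation.

Each game play yields a unit score in [0, 1] from its raw telemetry:

==========  ==============================================================
game        unit score
==========  ==============================================================
aerobic     distance_travelled / total_distance
strength,
stretch,
steps       correct_iterations / total_iterations
apple       0.8 * (time_limit - finish_time)/time_limit
            + 0.2 * apples_gathered/total_apples
arkanoid    0.4 * hit_targets/total_targets
            + 0.6 * remaining_lives/total_lives
fishing     caught_fish / total_fish
golf        0.7 * optimal_path/max(distance_travelled, optimal_path)
            + 0.2 * [ball_scored]
            + 0.1 * (total_time - time_to_score)/total_time (0 if missed)
ski         distance_travelled / max_possible_distance
==========  ==============================================================

Time terms are remaining-time fractions (faster completion scores higher)
and the golf path term penalizes deviation from the optimal path. The
weights of every multi-term equation sum to 1, so perfect play scores
exactly 1 before the 10-point normalization. A session's domain score is
the unweighted mean of the normalized scores of that domain's games;
heart rate and Borg are the session means of their readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .telemetry import GAME_DOMAIN, RawGameMetrics, SessionRecord

DOMAINS = ("aerobic", "strength", "flexibility", "balance", "hrmg", "heart_rate", "borg")


class ScoringError(ValueError):
    """Raised when raw metrics cannot be scored (e.g. a zero denominator)."""


@dataclass(frozen=True)
class DomainScore:
    participant_id: str
    session_index: int
    level: int
    domain: str
    score: float


def _ratio(num, den, symbol: str) -> float:
    if den is None or den == 0:
        raise ScoringError(f"zero or missing denominator: {symbol}")
    if num is None:
        raise ScoringError(f"missing numerator for {symbol}")
    return float(num) / float(den)


def score_game(raw: RawGameMetrics, game_id: str) -> float:
    """Unit score in [0, 1] of one game play."""
    if game_id in ("cycling", "hiking"):
        unit = _ratio(raw.distance_travelled, raw.total_distance, "total_distance")
    elif game_id in ("strength", "stretching", "steps"):
        unit = _ratio(raw.correct_iterations, raw.total_iterations, "total_iterations")
    elif game_id == "fishing":
        unit = _ratio(raw.caught_fish, raw.total_fish, "total_fish")
    elif game_id == "ski":
        unit = _ratio(
            raw.distance_travelled, raw.max_possible_distance, "max_possible_distance"
        )
    elif game_id == "apple":
        time_term = 1.0 - _ratio(raw.finish_time, raw.time_limit, "time_limit")
        unit = 0.8 * time_term + 0.2 * _ratio(
            raw.apples_gathered, raw.total_apples, "total_apples"
        )
    elif game_id == "arkanoid":
        unit = 0.4 * _ratio(raw.hit_targets, raw.total_targets, "total_targets") + \
            0.6 * _ratio(raw.remaining_lives, raw.total_lives, "total_lives")
    elif game_id == "golf":
        if raw.optimal_path_distance is None or raw.optimal_path_distance == 0:
            raise ScoringError("zero or missing denominator: optimal_path_distance")
        travelled = raw.distance_travelled if raw.distance_travelled is not None else 0.0
        path_term = raw.optimal_path_distance / max(travelled, raw.optimal_path_distance)
        scored = bool(raw.ball_scored)
        if scored:
            time_term = 1.0 - _ratio(raw.time_to_score, raw.total_time, "total_time")
        else:
            time_term = 0.0
        unit = 0.7 * path_term + 0.2 * scored + 0.1 * time_term
    else:
        raise ScoringError(f"unknown game id: {game_id!r}")
    return float(np.clip(unit, 0.0, 1.0))


def normalize_score(unit: float) -> float:
    """Map a unit score onto the 10-point scale."""
    return 10.0 * float(np.clip(unit, 0.0, 1.0))


def aggregate_session(session: SessionRecord) -> list[DomainScore]:
    """Per-domain scores of one session.

    Game domains get the mean normalized score of their games; domains with
    no plays are absent from the output (never zero-filled). Heart rate is
    the session mean of its readings; Borg is the session rating.
    """
    if not session.plays:
        raise ScoringError("session has no plays")
    by_domain: dict[str, list[float]] = {}
    for game_id, raw in session.plays:
        domain = GAME_DOMAIN.get(game_id)
        if domain is None:
            raise ScoringError(f"unknown game id: {game_id!r}")
        by_domain.setdefault(domain, []).append(normalize_score(score_game(raw, game_id)))

    out = [
        DomainScore(
            session.participant_id,
            session.session_index,
            session.level,
            domain,
            float(np.mean(scores)),
        )
        for domain, scores in by_domain.items()
    ]
    if session.heart_rates:
        out.append(
            DomainScore(
                session.participant_id,
                session.session_index,
                session.level,
                "heart_rate",
                float(np.mean(session.heart_rates)),
            )
        )
    if session.borg is not None:
        out.append(
            DomainScore(
                session.participant_id,
                session.session_index,
                session.level,
                "borg",
                float(session.borg),
            )
        )
    return out


def score_sessions(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Domain-score table for a stream of sessions (long format)."""
    rows = [ds for s in sessions for ds in aggregate_session(s)]
    return pd.DataFrame(
        {
            "participant_id": d.participant_id,
            "session_index": d.session_index,
            "level": d.level,
            "domain": d.domain,
            "score": d.score,
        }
        for d in rows
    )
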