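"""Session telemetry simulation.

Raw per-play telemetry (distances, counts, times, lives) is emitted so that
the *expected* unit score of each game under the scoring equations equals a
given latent ability in [0, 1]: count-type achievements are binomial
(e.g. fish caught ~ Binomial(total fish, ability)) and continuous ratio
terms (distances, remaining-time fractions) are Beta-distributed with mean
equal to ability. For Mini Golf, whose score mixes a path term, a scored
flag and a conditional time bonus, the path-term mean is adjusted to
a(8 - a)/7 so the total expected score is exactly the ability.

The latent expected domain score at within-level session t is
``baseline + slope * (t - 1)`` plus Gaussian session noise, clipped to the
10-point scale — linear in the session index so that downstream trend
(slope/intercept) recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError
from .cohort import Participant, participant_rng

#: game id -> exercise domain
GAME_DOMAIN = {
    "cycling": "aerobic",
    "hiking": "aerobic",
    "strength": "strength",
    "stretching": "flexibility",
    "steps": "balance",
    "ski": "hrmg",
    "apple": "hrmg",
    "arkanoid": "hrmg",
    "fishing": "hrmg",
    "golf": "hrmg",
}

_BETA_CONCENTRATION = 12.0


@dataclass
class RawGameMetrics:
    """Raw telemetry of a single game play (game-dependent subset)."""

    distance_travelled: Optional[float] = None
    total_distance: Optional[float] = None
    optimal_path_distance: Optional[float] = None
    max_possible_distance: Optional[float] = None
    finish_time: Optional[float] = None
    time_limit: Optional[float] = None
    time_to_score: Optional[float] = None
    total_time: Optional[float] = None
    apples_gathered: Optional[int] = None
    total_apples: Optional[int] = None
    hit_targets: Optional[int] = None
    total_targets: Optional[int] = None
    remaining_lives: Optional[int] = None
    total_lives: Optional[int] = None
    caught_fish: Optional[int] = None
    total_fish: Optional[int] = None
    correct_iterations: Optional[int] = None
    total_iterations: Optional[int] = None
    ball_scored: Optional[bool] = None

    def validate(self) -> None:
        """Check the metric invariants for every populated field pair."""
        for got, total in (
            (self.apples_gathered, self.total_apples),
            (self.hit_targets, self.total_targets),
            (self.remaining_lives, self.total_lives),
            (self.caught_fish, self.total_fish),
            (self.correct_iterations, self.total_iterations),
        ):
            if got is not None and total is not None:
                if got < 0 or got > total:
                    raise ValueError(f"count {got} outside [0, {total}]")
        if self.finish_time is not None and self.time_limit is not None:
            if not 0 <= self.finish_time <= self.time_limit:
                raise ValueError("finish_time outside [0, time_limit]")
        if self.time_to_score is not None and self.total_time is not None:
            if not 0 <= self.time_to_score <= self.total_time:
                raise ValueError("time_to_score outside [0, total_time]")
        for d in (
            self.distance_travelled,
            self.total_distance,
            self.optimal_path_distance,
            self.max_possible_distance,
        ):
            if d is not None and d < 0:
                raise ValueError("distances must be non-negative")

    def to_items(self) -> dict[str, float]:
        out = {}
        for name, value in self.__dict__.items():
            if value is not None:
                out[name] = float(value)
        return out


@dataclass
class SessionRecord:
    """One training session of one participant."""

    participant_id: str
    session_index: int  # 1-based, chronological
    level: int  # difficulty level 1-4
    plays: list[tuple[str, RawGameMetrics]] = field(default_factory=list)
    heart_rates: list[float] = field(default_factory=list)
    systolic: list[float] = field(default_factory=list)
    diastolic: list[float] = field(default_factory=list)
    borg: float = 7.0


def _beta_mean(rng: np.random.Generator, mean: float, conc: float = _BETA_CONCENTRATION) -> float:
    """Beta variate with the given mean on [0, 1]; degenerate at 0 and 1."""
    mean = float(np.clip(mean, 0.0, 1.0))
    if mean in (0.0, 1.0):
        return mean
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def emit_raw_metrics(
    ability: float, game_id: str, level: int, rng: np.random.Generator
) -> RawGameMetrics:
    """Draw raw telemetry whose expected unit score equals ``ability``."""
    if not 0.0 <= ability <= 1.0:
        raise ValueError(f"ability must be in [0, 1], got {ability}")
    a = float(ability)
    step = max(int(level) - 1, 0)

    if game_id in ("cycling", "hiking"):
        total = 1000.0 + 200.0 * step
        return RawGameMetrics(
            distance_travelled=total * _beta_mean(rng, a), total_distance=total
        )
    if game_id in ("strength", "stretching", "steps"):
        total = 10 + 2 * step
        return RawGameMetrics(
            correct_iterations=int(rng.binomial(total, a)), total_iterations=total
        )
    if game_id == "ski":
        maxdist = 100.0 * (1 + step)
        return RawGameMetrics(
            distance_travelled=maxdist * _beta_mean(rng, a),
            max_possible_distance=maxdist,
        )
    if game_id == "fishing":
        total = 10 + 2 * step
        return RawGameMetrics(caught_fish=int(rng.binomial(total, a)), total_fish=total)
    if game_id == "apple":
        limit = 120.0
        total = 10
        return RawGameMetrics(
            finish_time=limit * (1.0 - _beta_mean(rng, a)),
            time_limit=limit,
            apples_gathered=int(rng.binomial(total, a)),
            total_apples=total,
        )
    if game_id == "arkanoid":
        targets = 12 + 2 * step
        lives = 5
        return RawGameMetrics(
            hit_targets=int(rng.binomial(targets, a)),
            total_targets=targets,
            remaining_lives=int(rng.binomial(lives, a)),
            total_lives=lives,
        )
    if game_id == "golf":
        optimal = 20.0 + 5.0 * step
        total_time = 90.0
        scored = bool(rng.random() < a)
        # path-term mean a(8-a)/7 compensates the conditional time bonus so
        # that E[0.7*path + 0.2*scored + 0.1*time] = ability exactly
        path = _beta_mean(rng, a * (8.0 - a) / 7.0)
        travelled = optimal / max(path, 1e-9)
        tts = total_time * (1.0 - _beta_mean(rng, a)) if scored else total_time
        return RawGameMetrics(
            distance_travelled=travelled,
            optimal_path_distance=optimal,
            ball_scored=scored,
            time_to_score=tts,
            total_time=total_time,
        )
    raise ValueError(f"unknown game id: {game_id!r}")


def simulate_sessions(
    participant: Participant, config: CohortConfig | None = None
) -> list[SessionRecord]:
    """Simulate the full longitudinal session stream of one participant.

    Session count is ``sessions_per_week * n_weeks`` (default 24); the
    difficulty level increments at the configured promotion sessions and is
    non-decreasing. Raw metrics are emitted via :func:`emit_raw_metrics`
    from a per-session latent ability per domain.
    """
    config = config or CohortConfig()
    rng = participant_rng(config.seed, participant.id, stream="sessions")
    slope = config.learning_slope.get(participant.group, 0.0)
    n_readings = config.vitals_readings_per_session

    sessions: list[SessionRecord] = []
    for t in range(1, config.n_sessions + 1):
        level = config.level_of_session(t)
        t_within = config.within_level_ordinal(t)
        rec = SessionRecord(
            participant_id=participant.id, session_index=t, level=level
        )
        for domain, games in config.roster.items():
            latent = (
                participant.baseline[domain]
                + slope * (t_within - 1)
                + rng.normal(0.0, config.noise_sd.get(domain, 0.0))
            )
            ability = float(np.clip(latent / 10.0, 0.0, 1.0))
            for game_id in games:
                rec.plays.append((game_id, emit_raw_metrics(ability, game_id, level, rng)))
        hr_sd = config.noise_sd.get("heart_rate", 0.0)
        rec.heart_rates = [
            float(np.clip(participant.heart_rate_mean + rng.normal(0.0, hr_sd), 30, 220))
            for _ in range(n_readings)
        ]
        rec.systolic = [float(rng.normal(130.0, 12.0)) for _ in range(n_readings)]
        rec.diastolic = [float(rng.normal(80.0, 8.0)) for _ in range(n_readings)]
        rec.borg = float(
            np.clip(
                participant.borg_mean + rng.normal(0.0, config.noise_sd.get("borg", 0.0)),
                6.0,
                20.0,
            )
        )
        sessions.append(rec)
    return sessions


# ----------------------------------------------------------------------
# long-format CSV interchange
# ----------------------------------------------------------------------

def sessions_to_frame(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Long-format telemetry table: one row per (play, metric). Vitals and
    Borg appear under the pseudo-game ids ``vitals`` and ``borg``."""
    rows = []
    for s in sessions:
        base = {
            "participant_id": s.participant_id,
            "session_index": s.session_index,
            "level": s.level,
        }
        for i, (game_id, raw) in enumerate(s.plays):
            for name, value in raw.to_items().items():
                rows.append({**base, "game_id": game_id, "play": i,
                             "metric_name": name, "metric_value": value})
        for i, hr in enumerate(s.heart_rates):
            rows.append({**base, "game_id": "vitals", "play": i,
                         "metric_name": "heart_rate", "metric_value": hr})
        for i, (sys_, dia) in enumerate(zip(s.systolic, s.diastolic)):
            rows.append({**base, "game_id": "vitals", "play": i,
                         "metric_name": "systolic", "metric_value": sys_})
            rows.append({**base, "game_id": "vitals", "play": i,
                         "metric_name": "diastolic", "metric_value": dia})
        rows.append({**base, "game_id": "borg", "play": 0,
                     "metric_name": "borg", "metric_value": s.borg})
    return pd.DataFrame(rows)


def frame_to_sessions(frame: pd.DataFrame) -> list[SessionRecord]:
    """Rebuild :class:`SessionRecord` objects from the long-format table."""
    sessions = []
    grouped = frame.groupby(["participant_id", "session_index"], sort=True)
    for (pid, t), block in grouped:
        rec = SessionRecord(
            participant_id=pid,
            session_index=int(t),
            level=int(block["level"].iloc[0]),
        )
        for (game_id, play), sub in block.groupby(["game_id", "play"], sort=True):
            metrics = dict(zip(sub["metric_name"], sub["metric_value"]))
            if game_id == "vitals":
                if "heart_rate" in metrics:
                    rec.heart_rates.append(float(metrics["heart_rate"]))
                if "systolic" in metrics:
                    rec.systolic.append(float(metrics["systolic"]))
                if "diastolic" in metrics:
                    rec.diastolic.append(float(metrics["diastolic"]))
            elif game_id == "borg":
                rec.borg = float(metrics["borg"])
            else:
                kwargs = {}
                for name, value in metrics.items():
                    if name == "ball_scored":
                        kwargs[name] = bool(value)
                    elif name in RawGameMetrics.__dataclass_fields__:
                        f = RawGameMetrics.__dataclass_fields__[name]
                        kwargs[name] = int(value) if "int" in str(f.type) else float(value)
                rec.plays.append((str(game_id), RawGameMetrics(**kwargs)))
        sessions.append(rec)
    return sessions
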