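"""Cohort and trial configuration.

The defaults encode the published description of the trial cohort: three
clinically diagnosed groups — cognitively normal (CN, n=38), mild cognitive
impairment (MCI, n=64) and mild dementia (MD, n=14) — with group-level
mean ± SD for demographics, neuropsychological screening scores (MMSE, MoCA,
Trail Making Test A/B), baseline in-game domain scores on the 10-point scale
(strength, aerobic, HRMG, flexibility), heart rate and Borg exertion rating.
Participants trained 3–4 sessions per week for 7–8 weeks across 4 difficulty
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

GROUPS = ("CN", "MCI", "MD")

#: Exercise domains whose games yield a 10-point score.
GAME_DOMAINS = ("aerobic", "strength", "flexibility", "balance", "hrmg")

#: Per-session physiological / subjective measures aggregated like scores.
VITAL_DOMAINS = ("heart_rate", "borg")

#: Games played in every session, per domain. The high-resolution
#: monitoring games (HRMG) are the five games carrying the cognitive signal.
DEFAULT_ROSTER: dict[str, tuple[str, ...]] = {
    "aerobic": ("cycling",),
    "strength": ("strength",),
    "flexibility": ("stretching",),
    "balance": ("steps",),
    "hrmg": ("ski", "apple", "arkanoid", "fishing", "golf"),
}

#: Hard instrument/scale bounds used for truncation when sampling.
INSTRUMENT_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (55.0, 110.0),
    "education": (0.0, 25.0),
    "mmse": (0.0, 30.0),
    "moca": (0.0, 30.0),
    "tmt_a": (10.0, 600.0),
    "tmt_b": (10.0, 600.0),
    "strength": (0.0, 10.0),
    "aerobic": (0.0, 10.0),
    "flexibility": (0.0, 10.0),
    "balance": (0.0, 10.0),
    "hrmg": (0.0, 10.0),
    "heart_rate": (30.0, 220.0),
    "borg": (6.0, 20.0),  # classic Borg RPE scale
}

# Published group calibration: quantity -> (mean, sd) per group.
# The balance baseline is not part of the published table; its default sits
# between the strength and flexibility baselines (see docs/methods.md).
DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CN": {
        "age": (67.1, 5.2),
        "education": (8.5, 2.6),
        "mmse": (28.1, 1.2),
        "moca": (26.2, 2.4),
        "tmt_a": (70.0, 32.3),
        "tmt_b": (141.9, 64.1),
        "strength": (7.6, 1.2),
        "aerobic": (6.8, 1.6),
        "hrmg": (5.2, 1.2),
        "flexibility": (8.7, 1.0),
        "balance": (8.0, 1.1),
        "heart_rate": (74.0, 10.2),
        "borg": (6.9, 1.2),
    },
    "MCI": {
        "age": (69.3, 6.4),
        "education": (7.6, 2.8),
        "mmse": (26.5, 2.2),
        "moca": (22.43, 2.9),
        "tmt_a": (86.9, 36.3),
        "tmt_b": (189.7, 76.5),
        "strength": (7.6, 0.9),
        "aerobic": (6.4, 1.4),
        "hrmg": (4.7, 0.8),
        "flexibility": (8.9, 0.4),
        "balance": (8.1, 0.9),
        "heart_rate": (72.6, 9.8),
        "borg": (7.1, 1.2),
    },
    "MD": {
        "age": (77.7, 3.4),
        "education": (5.8, 4.3),
        "mmse": (21.7, 1.5),
        "moca": (16.0, 2.3),
        "tmt_a": (178.1, 90.4),
        "tmt_b": (298.9, 80.1),
        "strength": (6.5, 1.7),
        "aerobic": (5.8, 1.7),
        "hrmg": (3.3, 0.7),
        "flexibility": (8.3, 0.9),
        "balance": (7.4, 1.2),
        "heart_rate": (72.0, 9.2),
        "borg": (7.2, 1.0),
    },
}

#: Observed female counts per group (30/38, 54/64, 11/14).
DEFAULT_FEMALE_FRACTION = {"CN": 30 / 38, "MCI": 54 / 64, "MD": 11 / 14}

# Expected per-session score gain within a difficulty level, per group.
# Small by design: the trial found no significant slope differences between
# groups, so the generator preserves that null structure.
DEFAULT_LEARNING_SLOPE = {"CN": 0.05, "MCI": 0.03, "MD": 0.02}

# Session-to-session noise SD on the latent domain score (10-point scale)
# and on vitals readings around the participant's own mean.
DEFAULT_NOISE_SD = {
    "aerobic": 0.75,
    "strength": 0.75,
    "flexibility": 0.75,
    "balance": 0.75,
    "hrmg": 0.75,
    "heart_rate": 3.0,
    "borg": 0.5,
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Full specification of a simulated trial.

    Parameters
    ----------
    group_sizes
        Participants per diagnostic group.
    group_params
        Per group, ``quantity -> (mean, sd)`` calibration targets; sampled
        as truncated normals whose *truncated* mean equals the target.
    sessions_per_week, n_weeks
        Training schedule; 3–4 sessions/week over 7–8 weeks.
    promotion_schedule
        Session indices (1-based) at which the difficulty level increments;
        at most 3 increments (4 levels).
    learning_slope
        Expected score gain per session within a level, per group (applied
        to every game domain).
    noise_sd
        Session-level noise SD per domain.
    latent_rho
        Correlation between the participant's shared cognitive factor and
        each cognition-linked quantity (neuropsych tests, HRMG baseline).
    seed
        Root seed; per-participant substreams are derived by stable hashing
        of the participant id, so generation order is irrelevant.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CN": 38, "MCI": 64, "MD": 14}
    )
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(q) for g, q in DEFAULT_GROUP_PARAMS.items()
        }
    )
    female_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_FRACTION)
    )
    sessions_per_week: int = 3
    n_weeks: int = 8
    promotion_schedule: tuple[int, ...] = (7, 13, 19)
    learning_slope: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEARNING_SLOPE)
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    roster: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {d: tuple(g) for d, g in DEFAULT_ROSTER.items()}
    )
    latent_rho: float = 0.6
    vitals_readings_per_session: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.group_sizes.items():
            if n <= 0 or int(n) != n:
                raise ConfigurationError(
                    f"group size for {group!r} must be a positive integer, got {n}"
                )
        for group, params in self.group_params.items():
            for q, (_, sd) in params.items():
                if sd < 0:
                    raise ConfigurationError(
                        f"SD for {group}/{q} must be non-negative, got {sd}"
                    )
        if not 3 <= self.sessions_per_week <= 4:
            raise ConfigurationError("sessions_per_week must be 3 or 4")
        if not 7 <= self.n_weeks <= 8:
            raise ConfigurationError("n_weeks must be 7 or 8")
        sched = tuple(self.promotion_schedule)
        if len(sched) == 0:
            raise ConfigurationError("promotion schedule must not be empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("promotion schedule must be strictly increasing")
        if len(sched) > 3:
            raise ConfigurationError("at most 4 difficulty levels (3 promotions)")
        if sched[0] < 2 or sched[-1] > self.n_sessions:
            raise ConfigurationError(
                "promotion sessions must lie within (1, n_sessions]"
            )
        if not 0.0 <= self.latent_rho <= 1.0:
            raise ConfigurationError("latent_rho must be in [0, 1]")

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_week * self.n_weeks

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes.values())

    def level_of_session(self, session_index: int) -> int:
        """Difficulty level (1–4) of a 1-based session index."""
        level = 1
        for s in self.promotion_schedule:
            if session_index >= s:
                level += 1
        return level

    def within_level_ordinal(self, session_index: int) -> int:
        """1-based position of a session within its difficulty level."""
        starts = (1,) + tuple(self.promotion_schedule)
        level = self.level_of_session(session_index)
        return session_index - starts[level - 1] + 1

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "promotion_schedule" in raw:
            raw["promotion_schedule"] = tuple(raw["promotion_schedule"])
        if "group_params" in raw:
            raw["group_params"] = {
                g: {q: tuple(v) for q, v in params.items()}
                for g, params in raw["group_params"].items()
            }
        if "roster" in raw:
            raw["roster"] = {d: tuple(g) for d, g in raw["roster"].items()}
        return cls(**raw)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj
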