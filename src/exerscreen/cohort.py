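"""Synthetic cohort generation.

Each participant belongs to a diagnostic group (CN / MCI / MD) and carries
demographics, neuropsychological screening scores and baseline in-game
domain scores. Continuous quantities are drawn from truncated normal
distributions at the instrument bounds; the location parameter is solved so
that the *truncated* mean equals the configured group mean, which keeps
group-level sample means calibrated even when a bound is close (e.g. the
Borg floor of 6, MMSE ceiling of 30).

Cognition-linked quantities (MMSE, MoCA, TMT-A/B and the HRMG baseline)
share a per-participant latent factor through a Gaussian copula with
loading ``latent_rho`` — positive for the screening scores and the HRMG
baseline, negative for the timed Trail Making tests (longer = worse). The
copula perturbs ranks only, so the calibrated marginals are untouched.

Reproducibility: every participant draws from a substream keyed by the root
seed and a stable hash of the participant id, so cohorts are identical
across runs and independent of generation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats

from .config import (
    GAME_DOMAINS,
    INSTRUMENT_BOUNDS,
    CohortConfig,
    ConfigurationError,
)

# Sign of each quantity's loading on the shared cognitive factor.
_FACTOR_SIGN = {"mmse": 1.0, "moca": 1.0, "tmt_a": -1.0, "tmt_b": -1.0, "hrmg": 1.0}

_QUANTITIES = (
    "age",
    "education",
    "mmse",
    "moca",
    "tmt_a",
    "tmt_b",
    "strength",
    "aerobic",
    "hrmg",
    "flexibility",
    "balance",
    "heart_rate",
    "borg",
)

_INTEGER_QUANTITIES = {"age", "education", "mmse", "moca"}


@dataclass
class Participant:
    """One simulated study subject."""

    id: str
    group: str
    age: float
    sex: str
    education: float
    mmse: float
    moca: float
    tmt_a: float
    tmt_b: float
    #: baseline expected session score per game domain, 10-point scale
    baseline: dict[str, float] = field(default_factory=dict)
    #: participant-level mean heart rate (bpm) and Borg rating
    heart_rate_mean: float = 70.0
    borg_mean: float = 7.0

    def __post_init__(self) -> None:
        if self.tmt_a <= 0 or self.tmt_b <= 0:
            raise ValueError("TMT times must be positive")
        if not (0 <= self.mmse <= 30 and 0 <= self.moca <= 30):
            raise ValueError("MMSE/MoCA must lie in [0, 30]")

    @property
    def latent_ability(self) -> dict[str, float]:
        """Per-domain latent ability on [0, 1] (baseline score / 10)."""
        return {d: min(max(s / 10.0, 0.0), 1.0) for d, s in self.baseline.items()}


@lru_cache(maxsize=512)
def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal with scale ``sd`` on [lo, hi] whose
    truncated mean equals ``mean``."""
    if not lo < mean < hi:
        raise ConfigurationError(
            f"target mean {mean} must lie strictly inside the bounds ({lo}, {hi})"
        )

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = 12.0 * sd
    return optimize.brentq(
        lambda loc: trunc_mean(loc) - mean, lo - span, hi + span, xtol=1e-10
    )


def sample_calibrated(
    u: np.ndarray | float, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray | float:
    """Map uniform variates through the mean-calibrated truncated normal."""
    if sd == 0.0:
        return np.full_like(np.asarray(u, dtype=float), mean) if np.ndim(u) else mean
    loc = _calibrated_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def participant_rng(seed: int, participant_id: str, stream: str = "cohort") -> np.random.Generator:
    """Substream keyed by (root seed, stable hash of id, stream label)."""
    digest = hashlib.sha256(f"{participant_id}/{stream}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _participant_noise(pid: str, config: CohortConfig) -> tuple[float, np.ndarray, float]:
    """Standard-normal noise of one participant from its own substream:
    the shared factor z, one deviate per quantity, and the sex uniform."""
    rng = participant_rng(config.seed, pid)
    z = rng.standard_normal()
    eps = rng.standard_normal(len(_QUANTITIES))
    return z, eps, rng.random()


def _draw_group(group: str, pids: list[str], config: CohortConfig) -> list[Participant]:
    params = config.group_params[group]
    rho = config.latent_rho
    noise = [_participant_noise(pid, config) for pid in pids]
    z = np.array([n[0] for n in noise])
    eps = np.array([n[1] for n in noise])  # (n, n_quantities)
    sex_u = np.array([n[2] for n in noise])

    values: dict[str, np.ndarray] = {}
    for j, q in enumerate(_QUANTITIES):
        mean, sd = params[q]
        sign = _FACTOR_SIGN.get(q, 0.0)
        if sign and rho:
            w = sign * rho * z + np.sqrt(1.0 - rho**2) * eps[:, j]
        else:
            w = eps[:, j]
        u = stats.norm.cdf(w)
        lo, hi = INSTRUMENT_BOUNDS[q]
        v = np.asarray(sample_calibrated(u, mean, sd, lo, hi), dtype=float)
        if q in _INTEGER_QUANTITIES:
            v = np.clip(np.round(v), lo, hi)
        values[q] = v

    female = sex_u < config.female_fraction.get(group, 0.5)
    return [
        Participant(
            id=pid,
            group=group,
            age=float(values["age"][i]),
            sex="F" if female[i] else "M",
            education=float(values["education"][i]),
            mmse=float(values["mmse"][i]),
            moca=float(values["moca"][i]),
            tmt_a=float(values["tmt_a"][i]),
            tmt_b=float(values["tmt_b"][i]),
            baseline={d: float(values[d][i]) for d in GAME_DOMAINS},
            heart_rate_mean=float(values["heart_rate"][i]),
            borg_mean=float(values["borg"][i]),
        )
        for i, pid in enumerate(pids)
    ]


def generate_cohort(config: CohortConfig | None = None) -> list[Participant]:
    """Generate the full synthetic cohort defined by ``config``.

    Returns one :class:`Participant` per configured slot, in group order
    (CN, MCI, MD by default), deterministically for a given seed: each
    participant's randomness comes from a substream keyed by its id, so
    the draw is independent of generation order and of the other groups.
    """
    config = config or CohortConfig()
    cohort: list[Participant] = []
    for group, n in config.group_sizes.items():
        pids = [f"{group}-{i:03d}" for i in range(1, n + 1)]
        cohort.extend(_draw_group(group, pids, config))
    return cohort


def participants_frame(cohort: list[Participant]) -> pd.DataFrame:
    """Tabulate a cohort (one row per participant)."""
    return pd.DataFrame(
        {
            "id": p.id,
            "group": p.group,
            "age": p.age,
            "sex": p.sex,
            "education_years": p.education,
            "mmse": p.mmse,
            "moca": p.moca,
            "tmt_a_s": p.tmt_a,
            "tmt_b_s": p.tmt_b,
            **{f"baseline_{d}": p.baseline[d] for d in GAME_DOMAINS},
        }
        for p in cohort
    )
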