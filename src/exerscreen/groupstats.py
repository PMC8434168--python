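"""Group-difference and correlation statistics.

The screening battery treats the three diagnostic groups non-parametrically:
a tie-corrected Kruskal–Wallis omnibus per feature with the rank
epsilon-squared effect size ε² = H/(n−1), followed by Dunn's pairwise
z-tests on the pooled ranks with Bonferroni adjustment. Associations
between the HRMG features and the neuropsychological screening scores are
Pearson product–moment correlations. Normality annotations use
Shapiro–Wilk or the Lilliefors Kolmogorov–Smirnov test against a fitted
normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


class DegenerateDataError(ValueError):
    """Raised for inputs on which a statistic is undefined."""


@dataclass
class KWResult:
    feature_name: str
    H: float
    df: int
    p: float
    epsilon_sq: float
    n: int
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class CorrResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int


def kruskal_wallis(
    values_by_group: Mapping[str, Sequence[float]], feature_name: str = ""
) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with ε² effect size.

    p comes from the chi-square approximation with k−1 degrees of freedom;
    ε² = H/(n−1) lies in [0, 1] and reaches 1 for perfectly separated
    groups without ties. All-identical observations give H = 0, p = 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise DegenerateDataError("need at least two groups")
    for g, v in groups.items():
        if v.size == 0:
            raise DegenerateDataError(f"group {g!r} has no observations")
    n = sum(v.size for v in groups.values())
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups.values())
    eps2 = float(np.clip(H / (n - 1), 0.0, 1.0))
    return KWResult(
        feature_name=feature_name,
        H=float(H),
        df=len(groups) - 1,
        p=float(p),
        epsilon_sq=eps2,
        n=n,
    )


def pairwise_posthoc(
    values_by_group: Mapping[str, Sequence[float]], method: str = "dunn_bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's z-tests on pooled mid-ranks, Bonferroni-adjusted.

    The z statistic for groups i, j uses the tie-corrected rank variance
    ``(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)`` with ``T = Σ(t³ − t)``
    over tie groups; two-sided p-values are multiplied by the number of
    pairs and capped at 1.
    """
    if method != "dunn_bonferroni":
        raise ValueError(f"unknown post hoc method: {method!r}")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size == 0:
            raise DegenerateDataError(f"group {g!r} has no observations")
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_rank[g] = float(np.mean(ranks[start : start + k]))
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    base_var = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))

    n_pairs = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            p_raw = 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, p_raw * n_pairs))
    return out


def pearson_corr(
    x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y"
) -> CorrResult:
    """Pearson product–moment correlation with the two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateDataError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrResult(x_name=x_name, y_name=y_name, r=float(r), p=float(p), n=x.size)


def normality_check(values: Sequence[float], test: str = "shapiro_wilk") -> tuple[float, float]:
    """Normality test statistic and p-value.

    ``shapiro_wilk`` uses the Shapiro–Wilk W; ``kolmogorov_smirnov`` uses
    the Lilliefors KS distance against a normal with fitted mean and SD.
    Used only to annotate which analysis branch (parametric or not) applies.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DegenerateDataError("need at least 3 observations")
    if np.all(v == v[0]):
        raise DegenerateDataError("normality test undefined for constant input")
    if test == "shapiro_wilk":
        res = stats.shapiro(v)
        return float(res.statistic), float(res.pvalue)
    if test == "kolmogorov_smirnov":
        stat, p = lilliefors(v, dist="norm")
        return float(stat), float(p)
    raise ValueError(f"unknown normality test: {test!r}")


# ----------------------------------------------------------------------
# feature-table conveniences
# ----------------------------------------------------------------------

def screen_features(
    features: pd.DataFrame, label_col: str = "label", posthoc: bool = True
) -> pd.DataFrame:
    """Kruskal–Wallis screen of every feature column against the group label.

    Rows missing a feature (e.g. unplayed level blocks) are dropped per
    feature; features with an empty group or no variation across <2 groups
    are skipped. The result is sorted by omnibus p.
    """
    meta = {label_col, "participant_id"}
    results = []
    for col in features.columns:
        if col in meta or not np.issubdtype(features[col].dtype, np.number):
            continue
        sub = features[[label_col, col]].dropna()
        by_group = {g: b[col].to_numpy() for g, b in sub.groupby(label_col)}
        if len(by_group) < 2 or any(v.size == 0 for v in by_group.values()):
            continue
        res = kruskal_wallis(by_group, feature_name=col)
        row = {
            "feature": col,
            "H": res.H,
            "df": res.df,
            "p": res.p,
            "epsilon_sq": res.epsilon_sq,
            "n": res.n,
        }
        if posthoc:
            for (a, b), padj in pairwise_posthoc(by_group).items():
                row[f"p_{a}_{b}"] = padj
        results.append(row)
    return pd.DataFrame(results).sort_values("p", kind="stable").reset_index(drop=True)


def neuropsych_correlations(
    features: pd.DataFrame,
    participants: pd.DataFrame,
    feature_col: str = "HRMG MeanTotal",
    tests: Sequence[str] = ("mmse", "moca", "tmt_a_s", "tmt_b_s"),
) -> pd.DataFrame:
    """Pearson correlations of one game feature with the screening tests."""
    merged = features.merge(
        participants[["id", *tests]], left_on="participant_id", right_on="id"
    )
    rows = []
    for t in tests:
        sub = merged[[feature_col, t]].dropna()
        res = pearson_corr(sub[feature_col], sub[t], feature_col, t)
        rows.append({"x": res.x_name, "y": res.y_name, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
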