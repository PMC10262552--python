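"""Randomized-trial statistics: 2x2 effect estimates with the interval
methods used in the trial report (log-Wald for relative risks, plain Wald and
Newcombe hybrid Wilson-score for risk differences), Pearson chi-square and
Fisher exact tests, Kaplan-Meier / log-rank / Cox machinery, and
two-proportion sample-size and Monte-Carlo power calculations.

Proportions and risk differences are kept on the probability scale here;
report layers multiply by 100 where tables print percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "EffectEstimate",
    "SurvivalDatum",
    "relative_risk",
    "risk_difference_wald",
    "risk_difference_newcombe",
    "wilson_ci",
    "chi_square_test",
    "fisher_exact",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "sample_size_two_proportions",
    "empirical_power",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Event counts for two arms (a = first / exposed, b = second / reference)."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int

    def __post_init__(self) -> None:
        for events, n, label in (
            (self.events_a, self.n_a, "a"),
            (self.events_b, self.n_b, "b"),
        ):
            if n <= 0:
                raise ValueError(f"n_{label} must be > 0")
            if not 0 <= events <= n:
                raise ValueError(f"need 0 <= events_{label} <= n_{label}")

    @property
    def p_a(self) -> float:
        return self.events_a / self.n_a

    @property
    def p_b(self) -> float:
        return self.events_b / self.n_b

    def swapped(self) -> "TwoByTwo":
        return TwoByTwo(self.events_b, self.n_b, self.events_a, self.n_a)


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "RR" | "RD" | "HR"
    point: float
    ci_low: float | None
    ci_high: float | None
    method: str
    alpha: float = 0.05


@dataclass(frozen=True)
class SurvivalDatum:
    time: float
    event: bool
    arm: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")


def _z(alpha: float) -> float:
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def relative_risk(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Risk ratio with the log-Wald interval.

    With a zero event count in arm a the point estimate is 0 and the interval
    is omitted (flagged via method); zero events in arm b leave the ratio
    undefined and raise.
    """
    if t.events_b == 0:
        raise ZeroDivisionError("relative risk undefined with zero events in reference arm")
    point = t.p_a / t.p_b
    if t.events_a == 0:
        return EffectEstimate("RR", point, None, None, "wald_log:zero_cell", alpha)
    se = math.sqrt(1 / t.events_a - 1 / t.n_a + 1 / t.events_b - 1 / t.n_b)
    half = _z(alpha) * se
    return EffectEstimate(
        "RR", point, point * math.exp(-half), point * math.exp(half), "wald_log", alpha
    )


def risk_difference_wald(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Difference of proportions with the plain Wald interval (probability scale)."""
    point = t.p_a - t.p_b
    se = math.sqrt(t.p_a * (1 - t.p_a) / t.n_a + t.p_b * (1 - t.p_b) / t.n_b)
    half = _z(alpha) * se
    return EffectEstimate("RD", point, point - half, point + half, "wald", alpha)


def wilson_ci(events: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for one proportion."""
    if n <= 0 or not 0 <= events <= n:
        raise ValueError("invalid counts")
    z = _z(alpha)
    p = events / n
    z2n = z * z / n
    center = p + z2n / 2.0
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4.0 * n * n))
    denom = 1.0 + z2n
    return (center - half) / denom, (center + half) / denom


def risk_difference_newcombe(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Difference of proportions with Newcombe's hybrid Wilson-score interval."""
    point = t.p_a - t.p_b
    l_a, u_a = wilson_ci(t.events_a, t.n_a, alpha)
    l_b, u_b = wilson_ci(t.events_b, t.n_b, alpha)
    lower = point - math.sqrt((t.p_a - l_a) ** 2 + (u_b - t.p_b) ** 2)
    upper = point + math.sqrt((u_a - t.p_a) ** 2 + (t.p_b - l_b) ** 2)
    return EffectEstimate("RD", point, lower, upper, "newcombe_hybrid", alpha)


def chi_square_test(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    a, b = t.events_a, t.n_a - t.events_a
    c, d = t.events_b, t.n_b - t.events_b
    n = t.n_a + t.n_b
    margins = [(a + c), (b + d), t.n_a, t.n_b]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate 2x2 table: zero margin")
    stat = n * (a * d - b * c) ** 2 / ((a + c) * (b + d) * t.n_a * t.n_b)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided exact hypergeometric p value."""
    table = [[t.events_a, t.n_a - t.events_a], [t.events_b, t.n_b - t.events_b]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def _survival_frame(data: Sequence[SurvivalDatum]) -> pd.DataFrame:
    if not data:
        raise ValueError("empty survival data")
    return pd.DataFrame(
        {
            "time": [d.time for d in data],
            "event": [int(d.event) for d in data],
            "arm": [d.arm for d in data],
        }
    )


def km_estimate(data: Sequence[SurvivalDatum]) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per arm.

    Returns ``{arm: frame}`` with columns ``time`` and ``survival`` (the
    right-continuous step values after each event time, starting from S(0)=1).
    """
    from lifelines import KaplanMeierFitter

    df = _survival_frame(data)
    out: dict[str, pd.DataFrame] = {}
    for arm, grp in df.groupby("arm", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        sf = kmf.survival_function_
        out[str(arm)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        ).reset_index(drop=True)
    return out


def logrank_test(data: Sequence[SurvivalDatum]) -> tuple[float, float]:
    """Two-sample log-rank chi-square statistic (1 df) and p value."""
    from lifelines.statistics import logrank_test as ll_logrank

    df = _survival_frame(data)
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"log-rank needs exactly two arms, got {arms}")
    if df["event"].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    g0 = df[df["arm"] == arms[0]]
    g1 = df[df["arm"] == arms[1]]
    res = ll_logrank(g0["time"], g1["time"], g0["event"], g1["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(data: Sequence[SurvivalDatum], alpha: float = 0.05, ref_arm: str = "LD") -> EffectEstimate:
    """Hazard ratio (non-reference vs ``ref_arm``) from a Cox model, Efron ties."""
    from lifelines import CoxPHFitter

    df = _survival_frame(data)
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"Cox HR needs exactly two arms, got {arms}")
    if ref_arm not in arms:
        raise ValueError(f"ref_arm {ref_arm!r} not present in data")
    other = next(a for a in arms if a != ref_arm)
    df["x"] = (df["arm"] == other).astype(float)
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", "x"]], duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    half = _z(alpha) * se
    return EffectEstimate(
        "HR", math.exp(beta), math.exp(beta - half), math.exp(beta + half), "cox", alpha
    )


def sample_size_two_proportions(
    control_rate: float,
    rr: float,
    alpha: float = 0.05,
    power: float = 0.80,
    allocation_ratio: float = 1.0,
) -> int:
    """Total sample size for a two-sided two-proportion comparison.

    Classical normal-approximation formula with pooled variance under the
    null, per-arm sizes rounded up. ``allocation_ratio`` = n_treatment /
    n_control.
    """
    if not 0 < control_rate < 1:
        raise ValueError("control_rate must be in (0, 1)")
    p1 = control_rate * rr
    if p1 >= 1:
        raise ValueError("treatment rate control_rate * rr must be < 1")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be > 0")
    r = allocation_ratio
    p2 = control_rate
    z_a = _z(alpha)
    z_b = float(sps.norm.ppf(power))
    pbar = (r * p1 + p2) / (r + 1.0)
    qbar = 1.0 - pbar
    delta = abs(p1 - p2)
    n2 = (
        z_a * math.sqrt(pbar * qbar * (1.0 + 1.0 / r))
        + z_b * math.sqrt(p1 * (1 - p1) / r + p2 * (1 - p2))
    ) ** 2 / delta**2
    n2 = math.ceil(n2)
    n1 = math.ceil(r * n2)
    return n1 + n2


def empirical_power(
    n_a: int,
    n_b: int,
    rate_a: float,
    rate_b: float,
    alpha: float = 0.05,
    replications: int = 10_000,
    rng_seed=0,
) -> float:
    """Monte-Carlo rejection fraction of the Pearson chi-square test.

    Simulates ``replications`` trials with independent binomial arms and
    applies the 1-df chi-square test (no continuity correction) at ``alpha``.
    Degenerate tables (a zero margin) are never rejections.
    """
    if replications < 1000:
        raise ValueError("use at least 1000 replications")
    rng = np.random.default_rng(rng_seed)
    a = rng.binomial(n_a, rate_a, size=replications).astype(float)
    c = rng.binomial(n_b, rate_b, size=replications).astype(float)
    b = n_a - a
    d = n_b - c
    n = float(n_a + n_b)
    col1 = a + c
    col2 = b + d
    ok = (col1 > 0) & (col2 > 0)
    stat = np.zeros(replications)
    np.divide(
        n * (a * d - b * c) ** 2,
        col1 * col2 * n_a * n_b,
        out=stat,
        where=ok,
    )
    crit = float(sps.chi2.ppf(1.0 - alpha, df=1))
    reject = ok & (stat > crit)
    return float(reject.mean())
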