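"""Two-compartment intravenous-infusion pharmacokinetic model.

Linear disposition with zero-order infusion input, solved analytically as a
sum of exponentials, so both concentrations and windowed AUCs are exact.
With ``intercompartmental_clearance = 0`` the model collapses to the
one-compartment closed form.

All times are hours from the first dose, amounts are mg, volumes L,
clearances L/h, concentrations mg/L and AUCs mg·h/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "concentration_at",
    "true_auc_window",
    "sample_concentrations",
]


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters for one subject.

    ``crrt_clearance_multiplier`` scales clearance when the subject is on
    continuous hemofiltration; ``scr_exponent`` is the covariate exponent
    linking serum creatinine to clearance. Both are carried here so that an
    individualized parameter set is self-describing.
    """

    clearance: float
    central_volume: float
    intercompartmental_clearance: float = 0.0
    peripheral_volume: float = 1.0
    crrt_clearance_multiplier: float = 1.0
    scr_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.clearance <= 0:
            raise ValueError(f"clearance must be > 0, got {self.clearance}")
        if self.central_volume <= 0:
            raise ValueError(f"central_volume must be > 0, got {self.central_volume}")
        if self.intercompartmental_clearance < 0:
            raise ValueError("intercompartmental_clearance must be >= 0")
        if self.peripheral_volume <= 0:
            raise ValueError(f"peripheral_volume must be > 0, got {self.peripheral_volume}")
        if self.crrt_clearance_multiplier < 1:
            raise ValueError("crrt_clearance_multiplier must be >= 1")


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion."""

    start_time: float
    amount: float
    infusion_duration: float

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.amount <= 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if self.infusion_duration <= 0:
            raise ValueError(f"infusion_duration must be > 0, got {self.infusion_duration}")


@dataclass(frozen=True)
class Regimen:
    """Loading dose followed by fixed q12h maintenance dosing."""

    loading_dose: float
    maintenance_dose: float
    dosing_interval: float = 12.0
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.dosing_interval != 12.0:
            raise ValueError("protocol dosing interval is fixed at 12 h")
        if self.loading_dose <= 0 or self.maintenance_dose <= 0:
            raise ValueError("doses must be > 0")

    @property
    def daily_dose(self) -> float:
        return 2.0 * self.maintenance_dose

    def doses(self, n_doses: int) -> list[DoseEvent]:
        """Schedule of the first ``n_doses`` doses (dose 1 = loading)."""
        out = []
        for k in range(n_doses):
            amount = self.loading_dose if k == 0 else self.maintenance_dose
            out.append(DoseEvent(k * self.dosing_interval, amount, self.infusion_duration))
        return out


def _validate_doses(doses: Sequence[DoseEvent]) -> None:
    for prev, cur in zip(doses, doses[1:]):
        if cur.start_time < prev.start_time:
            raise ValueError("dose events must be sorted by start_time")
        if cur.start_time < prev.start_time + prev.infusion_duration:
            raise ValueError("overlapping infusions are not allowed")


def _disposition_terms(params: PKParameters) -> tuple[tuple[float, float], ...]:
    """Unit-bolus impulse response as ((coef, rate), ...): C(t) = D * sum a_i exp(-l_i t)."""
    cl, v1 = params.clearance, params.central_volume
    q, v2 = params.intercompartmental_clearance, params.peripheral_volume
    if q == 0.0:
        return ((1.0 / v1, cl / v1),)
    k10, k12, k21 = cl / v1, q / v1, q / v2
    s = k10 + k12 + k21
    # discriminant = (k10+k12-k21)^2 + 4 k12 k21 > 0, so roots are real and distinct
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    lam1 = (s + disc) / 2.0
    lam2 = (s - disc) / 2.0
    a1 = (lam1 - k21) / (v1 * (lam1 - lam2))
    a2 = (k21 - lam2) / (v1 * (lam1 - lam2))
    return ((a1, lam1), (a2, lam2))


def concentration_at(params: PKParameters, doses: Sequence[DoseEvent], t) -> float | np.ndarray:
    """Plasma concentration at time(s) ``t`` by superposition over all doses."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    _validate_doses(doses)
    terms = _disposition_terms(params)
    c = np.zeros_like(t_arr)
    for dose in doses:
        tau = t_arr - dose.start_time
        active = tau > 0
        if not np.any(active):
            continue
        rate = dose.amount / dose.infusion_duration
        te = np.minimum(tau, dose.infusion_duration)
        post = np.maximum(tau - dose.infusion_duration, 0.0)
        for a, lam in terms:
            g = rate * a / lam
            contrib = g * (1.0 - np.exp(-lam * te)) * np.exp(-lam * post)
            c = np.where(active, c + contrib, c)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(c)
    return c


def _cumulative_auc_one_dose(terms, dose: DoseEvent, tau) -> np.ndarray:
    """AUC of one dose's concentration from its start to local time ``tau`` (analytic)."""
    tau = np.asarray(tau, dtype=float)
    rate = dose.amount / dose.infusion_duration
    T = dose.infusion_duration
    out = np.zeros_like(tau)
    pos = tau > 0
    te = np.clip(tau, 0.0, T)
    post = np.maximum(tau - T, 0.0)
    for a, lam in terms:
        g = rate * a / lam
        during = g * (te - (1.0 - np.exp(-lam * te)) / lam)
        tail = g * (1.0 - np.exp(-lam * te)) * (1.0 - np.exp(-lam * post)) / lam
        out = np.where(pos, out + during + tail, out)
    return out


def true_auc_window(
    params: PKParameters, doses: Sequence[DoseEvent], t0: float, t1: float
) -> float:
    """Exact AUC of :func:`concentration_at` over ``[t0, t1]``.

    Additive over adjacent windows; for an empty dose list it is 0.
    """
    if t1 <= t0:
        raise ValueError(f"need t1 > t0, got t0={t0}, t1={t1}")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    _validate_doses(doses)
    terms = _disposition_terms(params)
    total = 0.0
    for dose in doses:
        hi = _cumulative_auc_one_dose(terms, dose, t1 - dose.start_time)
        lo = _cumulative_auc_one_dose(terms, dose, t0 - dose.start_time)
        total += float(hi - lo)
    return total


def sample_concentrations(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    occasion_dose_index: int,
    residual_cv: float,
    rng_seed,
) -> tuple[float, float]:
    """Simulated (C0h, C2h) pair for the indexed dose (1-based).

    C0h is the model concentration immediately before the infusion starts and
    C2h the concentration 2 h after the start of the infusion; each is
    perturbed by an independent lognormal error with median 1 and coefficient
    of variation ``residual_cv``. Deterministic given the seed.
    """
    if not 1 <= occasion_dose_index <= len(doses):
        raise ValueError(
            f"occasion_dose_index {occasion_dose_index} out of range 1..{len(doses)}"
        )
    if residual_cv < 0:
        raise ValueError("residual_cv must be >= 0")
    dose = doses[occasion_dose_index - 1]
    c0 = float(np.asarray(concentration_at(params, doses, dose.start_time)))
    c2 = float(np.asarray(concentration_at(params, doses, dose.start_time + 2.0)))
    if residual_cv > 0:
        rng = np.random.default_rng(rng_seed)
        sigma = math.sqrt(math.log1p(residual_cv**2))
        eps = np.exp(sigma * rng.standard_normal(2))
        c0 *= float(eps[0])
        c2 *= float(eps[1])
    return c0, c2
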