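"""Dose-titration state machine for TDM-guided polymyxin B dosing.

Initial regimens by arm (HD: 150 mg load + 75 mg q12h; LD: 100 mg load +
50 mg q12h), ±25 mg maintenance adjustments driven by the limited-sampling
AUC estimate at the steady-state (7th-dose) occasion, rechecks four doses
after each adjustment, and stopping when the daily dose would leave the
closed 50-200 mg/day range. The loading dose is never adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .lss_auc import AUCEstimate, ConcentrationPair, estimate_auc
from .pk_model import DoseEvent, PKParameters, Regimen, sample_concentrations, true_auc_window
from .synthetic_cohort import VirtualPatient

__all__ = [
    "TitrationState",
    "ProtocolConfig",
    "TDMCourse",
    "SampleRecord",
    "StateError",
    "initial_regimen",
    "adjust_dose",
    "run_tdm_course",
    "DAILY_DOSE_BOUNDS",
    "DOSE_STEP_MG",
]

DAILY_DOSE_BOUNDS = (50.0, 200.0)  # closed interval, mg/day
DOSE_STEP_MG = 25.0
RECHECK_AFTER_DOSES = 4
DECISION_OCCASION = 7
INFO_OCCASION = 2

TERMINAL_STATUSES = frozenset(
    {"on_target", "stopped_dose_bounds", "stopped_max_adjustments", "off_study"}
)


class StateError(RuntimeError):
    """Raised when a terminal titration state is asked to transition."""


@dataclass(frozen=True)
class TitrationState:
    arm: str
    current_maintenance: float
    status: str = "titrating"
    adjustments_made: int = 0
    next_sampling_occasion: int | None = DECISION_OCCASION
    history: tuple[tuple[int, AUCEstimate, str], ...] = ()

    @property
    def daily_dose(self) -> float:
        return 2.0 * self.current_maintenance


@dataclass(frozen=True)
class ProtocolConfig:
    max_adjustments: int = 2
    residual_cv: float = 0.20
    dropout_hazard_per_day: float = 0.0
    infusion_duration: float = 1.0
    adjust_on_second_dose: bool = False

    def __post_init__(self) -> None:
        if self.max_adjustments < 0:
            raise ValueError("max_adjustments must be >= 0")
        if self.residual_cv < 0 or self.dropout_hazard_per_day < 0:
            raise ValueError("residual_cv and dropout hazard must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    occasion: int
    time_h: float
    c0h: float
    c2h: float


@dataclass(frozen=True)
class TDMCourse:
    """Full trajectory of one simulated TDM course."""

    arm: str
    final_state: TitrationState
    doses: tuple[DoseEvent, ...]
    samples: tuple[SampleRecord, ...]
    second_dose_estimate: AUCEstimate | None
    seventh_dose_estimate: AUCEstimate | None
    achieved_ssauc_dose7: float | None
    final_estimate: AUCEstimate | None

    @property
    def status(self) -> str:
        return self.final_state.status


def initial_regimen(arm: str, infusion_duration: float = 1.0) -> Regimen:
    """Per-protocol initial regimen for an arm."""
    if arm == "HD":
        return Regimen(150.0, 75.0, infusion_duration=infusion_duration)
    if arm == "LD":
        return Regimen(100.0, 50.0, infusion_duration=infusion_duration)
    raise ValueError(f"unknown arm {arm!r}; expected 'HD' or 'LD'")


def adjust_dose(state: TitrationState, estimate: AUCEstimate) -> TitrationState:
    """One protocol decision applied to a titrating state.

    Within-window: hold the dose, terminal ``on_target``. Below/above: step
    the maintenance dose ±25 mg and schedule a recheck four doses later,
    unless the new daily dose would leave the closed [50, 200] mg range, in
    which case the step is not applied and the course stops. An invalid
    (non-positive) estimate is treated as below-window.
    """
    if state.status != "titrating":
        raise StateError(f"cannot adjust a course in terminal status {state.status!r}")
    occ = estimate.occasion if estimate.occasion is not None else DECISION_OCCASION
    category = estimate.category if estimate.valid else "below"
    if category == "within":
        return replace(
            state,
            status="on_target",
            next_sampling_occasion=None,
            history=state.history + ((occ, estimate, "none"),),
        )
    step = DOSE_STEP_MG if category == "below" else -DOSE_STEP_MG
    proposed = state.current_maintenance + step
    lo, hi = DAILY_DOSE_BOUNDS
    if not lo <= 2.0 * proposed <= hi:
        return replace(
            state,
            status="stopped_dose_bounds",
            next_sampling_occasion=None,
            history=state.history + ((occ, estimate, "stop"),),
        )
    action = "+25" if step > 0 else "-25"
    return replace(
        state,
        current_maintenance=proposed,
        adjustments_made=state.adjustments_made + 1,
        next_sampling_occasion=occ + RECHECK_AFTER_DOSES,
        history=state.history + ((occ, estimate, action),),
    )


def run_tdm_course(
    patient: VirtualPatient,
    arm: str,
    config: ProtocolConfig = ProtocolConfig(),
    rng_seed=0,
) -> TDMCourse:
    """Simulate a whole TDM course for one patient (seed-deterministic).

    Samples at dose 2 (informational by default) and dose 7 (decision point),
    then applies adjust/recheck cycles until a terminal status, the
    adjustment cap, or a simulated off-study event. Each applied adjustment
    takes effect from the next scheduled dose; doses already administered
    keep their historical amounts. The true (noise-free, model-based) ssAUC
    over the 24 h after the 7th dose start is recorded alongside the
    estimates.
    """
    regimen = initial_regimen(arm, config.infusion_duration)
    rng = np.random.default_rng(rng_seed)
    params: PKParameters = patient.pk
    committed: dict[int, float] = {}  # dose index -> administered maintenance amount
    state = TitrationState(arm=arm, current_maintenance=regimen.maintenance_dose)
    samples: list[SampleRecord] = []
    second_est: AUCEstimate | None = None
    seventh_est: AUCEstimate | None = None
    achieved: float | None = None
    last_event_time = 0.0

    def doses_through(occ: int) -> tuple[DoseEvent, ...]:
        # enough trailing doses to cover a 24-h AUC window after the occasion dose
        n = occ + 3
        return tuple(
            DoseEvent(
                (k - 1) * 12.0,
                regimen.loading_dose if k == 1 else committed.get(k, state.current_maintenance),
                config.infusion_duration,
            )
            for k in range(1, n + 1)
        )

    def dropped_out(now_h: float) -> bool:
        if config.dropout_hazard_per_day <= 0:
            return False
        dt_days = (now_h - last_event_time) / 24.0
        p = 1.0 - math.exp(-config.dropout_hazard_per_day * dt_days)
        return bool(rng.uniform() < p)

    def take_sample(occ: int) -> AUCEstimate:
        doses = doses_through(occ)
        c0, c2 = sample_concentrations(params, doses, occ, config.residual_cv, rng)
        samples.append(SampleRecord(occ, doses[occ - 1].start_time, c0, c2))
        return estimate_auc(ConcentrationPair(c0, c2, occasion=occ))

    def apply_decision(est: AUCEstimate) -> None:
        nonlocal state
        occ = est.occasion if est.occasion is not None else DECISION_OCCASION
        new_state = adjust_dose(state, est)
        if new_state.current_maintenance != state.current_maintenance:
            # freeze the amounts already administered at the old maintenance
            for k in range(2, occ + 1):
                committed.setdefault(k, state.current_maintenance)
        state = new_state

    # --- dose 2: informational sample ---
    t2 = 12.0
    if dropped_out(t2):
        state = replace(state, status="off_study", next_sampling_occasion=None)
    else:
        last_event_time = t2
        second_est = take_sample(INFO_OCCASION)
        if config.adjust_on_second_dose:
            apply_decision(second_est)

    # --- decision loop from dose 7 ---
    while state.status == "titrating":
        occ = state.next_sampling_occasion or DECISION_OCCASION
        t_occ = (occ - 1) * 12.0
        if dropped_out(t_occ):
            state = replace(state, status="off_study", next_sampling_occasion=None)
            break
        last_event_time = t_occ
        est = take_sample(occ)
        if occ == DECISION_OCCASION:
            seventh_est = est
            achieved = true_auc_window(params, doses_through(occ), t_occ, t_occ + 24.0)
        category = est.category if est.valid else "below"
        if category != "within" and state.adjustments_made >= config.max_adjustments:
            state = replace(
                state,
                status="stopped_max_adjustments",
                next_sampling_occasion=None,
                history=state.history + ((occ, est, "stop"),),
            )
            break
        apply_decision(est)

    final_est = state.history[-1][1] if state.history else (seventh_est or second_est)
    max_occ = max([s.occasion for s in samples] + [DECISION_OCCASION])
    return TDMCourse(
        arm=arm,
        final_state=state,
        doses=doses_through(max_occ),
        samples=tuple(samples),
        second_dose_estimate=second_est,
        seventh_dose_estimate=seventh_est,
        achieved_ssauc_dose7=achieved,
        final_estimate=final_est,
    )
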