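"""Deterministic outcome classifiers: composite day-14 clinical response and
KDIGO acute-kidney-injury staging from a serum-creatinine series.

Creatinine is handled in µmol/L throughout the package (26.5 µmol/L = 0.3
mg/dL, 353.6 µmol/L = 4.0 mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["ClinicalCourse", "sofa_improved", "classify_response", "kdigo_stage"]

KDIGO_STAGE1_ABS_RISE_UMOL_L = 26.5
KDIGO_STAGE3_ABS_PEAK_UMOL_L = 353.6
STAGE1_RISE_WINDOW_DAYS = 2.0  # 48 h


@dataclass(frozen=True)
class ClinicalCourse:
    """Day-14 clinical state of one (simulated) patient.

    Fields guarded by an "applicable" flag (shock, pneumonia, bacteremia) may
    be ``None`` when the corresponding syndrome is absent.
    """

    alive_day14: bool
    sofa_baseline: int
    sofa_day14: int | None
    shock_at_baseline: bool = False
    map_day14: float | None = None
    on_vasopressor_day14: bool | None = None
    has_pneumonia: bool = False
    pf_baseline: float | None = None
    pf_day14: float | None = None
    has_bacteremia: bool = False
    blood_culture_day14_positive: bool | None = None
    scr_series: tuple[tuple[float, float], ...] = ()
    on_rrt: bool = False


def sofa_improved(baseline: int, day14: int) -> bool:
    """True if the SOFA criterion of the composite response is met.

    Baseline >= 3 requires at least 30% improvement (inclusive at exactly
    30%); baseline < 3 requires the score not to worsen.
    """
    if baseline < 0 or day14 < 0:
        raise ValueError("SOFA scores must be >= 0")
    if baseline >= 3:
        return (baseline - day14) / baseline >= 0.30
    return day14 <= baseline


def classify_response(course: ClinicalCourse, require_all: bool = True) -> bool:
    """Composite day-14 clinical response.

    Survival to day 14 and the SOFA criterion are always required; the
    hemodynamic, oxygenation and blood-culture criteria apply only when the
    corresponding syndrome is present at baseline (vacuously true otherwise).
    ``require_all=False`` is a clearly non-protocol sensitivity variant that
    accepts any single applicable criterion besides survival.
    """
    if not course.alive_day14:
        return False
    if course.sofa_day14 is None:
        raise ValueError("sofa_day14 is required for a surviving patient")
    checks = [sofa_improved(course.sofa_baseline, course.sofa_day14)]
    if course.shock_at_baseline:
        if course.map_day14 is None or course.on_vasopressor_day14 is None:
            raise ValueError("shock at baseline requires map_day14 and on_vasopressor_day14")
        checks.append(course.map_day14 > 65.0 and not course.on_vasopressor_day14)
    if course.has_pneumonia:
        if course.pf_baseline is None or course.pf_day14 is None:
            raise ValueError("pneumonia requires pf_baseline and pf_day14")
        checks.append(course.pf_day14 >= course.pf_baseline)
    if course.has_bacteremia:
        if course.blood_culture_day14_positive is None:
            raise ValueError("bacteremia requires blood_culture_day14_positive")
        checks.append(not course.blood_culture_day14_positive)
    return all(checks) if require_all else any(checks)


def kdigo_stage(scr_series: Sequence[tuple[float, float]], on_rrt: bool = False) -> int:
    """KDIGO stage 0-3 from a (day, creatinine µmol/L) series.

    Stage from the peak/baseline ratio, the 48-h absolute-rise criterion for
    stage 1, the absolute-peak criterion for stage 3, and renal replacement
    therapy (always stage 3). Urine-output criteria are not evaluated.
    """
    if not scr_series:
        raise ValueError("scr_series must be non-empty")
    series = sorted((float(d), float(v)) for d, v in scr_series)
    if series[0][0] != 0.0:
        raise ValueError("scr_series must contain a baseline value at day 0")
    baseline = series[0][1]
    if baseline <= 0:
        raise ValueError("baseline creatinine must be > 0")
    if on_rrt:
        return 3
    peak = max(v for _, v in series)
    ratio = peak / baseline
    rise_48h = 0.0
    for i, (di, vi) in enumerate(series):
        for dj, vj in series[i + 1:]:
            if dj - di <= STAGE1_RISE_WINDOW_DAYS:
                rise_48h = max(rise_48h, vj - vi)
    if ratio >= 3.0 or peak >= KDIGO_STAGE3_ABS_PEAK_UMOL_L:
        return 3
    if ratio >= 2.0:
        return 2
    if ratio >= 1.5 or rise_48h >= KDIGO_STAGE1_ABS_RISE_UMOL_L:
        return 1
    return 0
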