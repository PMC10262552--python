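"""Limited-sampling estimator of steady-state AUC from a (C0h, C2h) pair.

The estimator is a published linear equation on the trough and 2-h samples,
doubled to cover 24 h:

    ssAUC_0-24 = 2 * (-0.673 + 6.084 * C0h + 6.230 * C2h)

The 50-100 mg·h/L therapeutic window is closed on both ends; window
classification is isolated in :func:`classify_auc`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LSSCoefficients",
    "ConcentrationPair",
    "AUCEstimate",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_WINDOW",
    "estimate_auc",
    "classify_auc",
    "auc_to_css_avg",
    "compute_fauc_mic",
]

DEFAULT_WINDOW: tuple[float, float] = (50.0, 100.0)


@dataclass(frozen=True)
class LSSCoefficients:
    intercept: float = -0.673
    weight_c0: float = 6.084
    weight_c2: float = 6.230
    half_day_multiplier: float = 2.0


DEFAULT_COEFFICIENTS = LSSCoefficients()


@dataclass(frozen=True)
class ConcentrationPair:
    """Trough and 2-h concentrations (mg/L) for one sampling occasion."""

    c0h: float
    c2h: float
    occasion: int | None = None

    def __post_init__(self) -> None:
        if self.c0h < 0 or self.c2h < 0:
            raise ValueError(f"concentrations must be >= 0, got ({self.c0h}, {self.c2h})")


@dataclass(frozen=True)
class AUCEstimate:
    value: float
    category: str
    occasion: int | None = None
    valid: bool = True


def classify_auc(value: float, window: tuple[float, float] = DEFAULT_WINDOW) -> str:
    """'below' / 'within' / 'above' the therapeutic window (bounds inclusive)."""
    lo, hi = window
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"


def estimate_auc(
    pair: ConcentrationPair,
    coeffs: LSSCoefficients = DEFAULT_COEFFICIENTS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> AUCEstimate:
    """Apply the limited-sampling equation to one concentration pair.

    A non-positive estimate (possible at very low concentrations because of
    the negative intercept) is flagged ``valid=False`` rather than raised;
    downstream treats it as below-window.
    """
    value = coeffs.half_day_multiplier * (
        coeffs.intercept + coeffs.weight_c0 * pair.c0h + coeffs.weight_c2 * pair.c2h
    )
    return AUCEstimate(
        value=value,
        category=classify_auc(value, window),
        occasion=pair.occasion,
        valid=value > 0,
    )


def auc_to_css_avg(value: float) -> float:
    """Average steady-state concentration (mg/L) implied by a 24-h AUC."""
    if value < 0:
        raise ValueError("AUC must be >= 0")
    return value / 24.0


def compute_fauc_mic(auc: float, unbound_fraction: float, mic: float) -> float:
    """Unbound AUC to MIC ratio, the efficacy-driving PK/PD index.

    ``unbound_fraction`` has no default on purpose: it must be supplied.
    """
    if mic <= 0:
        raise ValueError(f"mic must be > 0, got {mic}")
    if not 0.0 <= unbound_fraction <= 1.0:
        raise ValueError("unbound_fraction must be within [0, 1]")
    return auc * unbound_fraction / mic
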