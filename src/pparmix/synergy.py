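"""Mixture synergy scoring.

Two null expectations for the activation of a fatty-acid mixture are
computed from its components' single-FA activations:

* weighted average — components compete for the ligand-binding pocket, so
  each contributes in proportion to its molarity:
  E_w = Σ(FA_x · µM_x) / Σ(µM_x);
* additive — components contribute independently: E_a = Σ FA_x,

where FA_x is the activation (fold-change) of component x measured alone
at its peak dose and µM_x its molarity in the mixture. The %Δ statistic is
the percentage increase of the measured mixture activation over an
expectation; a mixture is called synergistic when measured activation
strictly exceeds the additive expectation. Model adequacy across a set of
mixtures is summarized by the least-squares slope of measured on expected
activation with the intercept fixed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import FattyAcidProfile
from .mixtures import MixtureDesign, round_half_up

__all__ = [
    "ComponentActivation",
    "SynergyResult",
    "OriginFit",
    "expected_weighted",
    "expected_additive",
    "percent_delta",
    "classify_synergy",
    "fit_origin_slope",
    "synergy_table",
    "synergy_frame",
]


@dataclass(frozen=True)
class ComponentActivation:
    """One mixture component: its solo activation (fold-change at its
    reference dose) and its molarity in the mixture (µM)."""

    fa: str
    activation: float
    molarity: float

    def __post_init__(self) -> None:
        if self.activation < 0:
            raise ValueError(f"{self.fa}: activation must be >= 0")
        if self.molarity <= 0:
            raise ValueError(f"{self.fa}: molarity must be > 0")


@dataclass(frozen=True)
class SynergyResult:
    label: str
    measured: float
    expected_weighted: float
    expected_additive: float
    pct_delta_weighted: float
    pct_delta_additive: float
    ratio_weighted: float
    ratio_additive: float
    synergistic: bool


@dataclass(frozen=True)
class OriginFit:
    """Slope of the through-origin regression of actual on expected."""

    slope: float
    n_points: int


def expected_weighted(components: list[ComponentActivation]) -> float:
    """Molarity-weighted mean of component activations (competition model)."""
    if not components:
        raise ValueError("need at least one component")
    total = sum(c.molarity for c in components)
    if total <= 0:
        raise ValueError("total molarity must be positive")
    return sum(c.activation * c.molarity for c in components) / total


def expected_additive(components: list[ComponentActivation]) -> float:
    """Sum of component activations (independent-contribution model)."""
    if not components:
        raise ValueError("need at least one component")
    return float(sum(c.activation for c in components))


def percent_delta(measured: float, expected: float) -> float:
    """Percentage increase of measured over expected activation (unrounded;
    round half-up only for display)."""
    if expected <= 0:
        raise ValueError(f"expected activation must be > 0, got {expected}")
    return 100.0 * (measured - expected) / expected


def classify_synergy(measured: float, expected_additive: float) -> bool:
    """True iff the mixture beats the sum of its parts (strict)."""
    if expected_additive <= 0:
        raise ValueError(
            f"expected activation must be > 0, got {expected_additive}"
        )
    return measured / expected_additive > 1.0


def fit_origin_slope(expected, actual) -> OriginFit:
    """Least-squares slope a of actual = a * expected + 0."""
    e = np.asarray(expected, dtype=float)
    a = np.asarray(actual, dtype=float)
    if e.shape != a.shape or e.ndim != 1 or len(e) < 2:
        raise ValueError("expected and actual must be equal-length vectors (n >= 2)")
    denom = float(np.dot(e, e))
    if denom <= 0:
        raise ValueError("degenerate fit: all expected values are zero")
    return OriginFit(slope=float(np.dot(e, a) / denom), n_points=len(e))


def synergy_table(
    designs: list[MixtureDesign],
    profiles: dict[str, FattyAcidProfile],
    measured: dict[str, float],
) -> list[SynergyResult]:
    """Score every designed mixture against both expectation models.

    FA_x is each component's single-FA activation at its peak dose
    (profiles); µM_x its in-mixture dose (designs); measured values are
    mean mixture fold-changes keyed by mixture label.
    """
    results = []
    for design in designs:
        missing = [fa for fa in design.fas if fa not in profiles]
        if missing:
            raise KeyError(f"{design.label}: no profile for {missing}")
        if design.label not in measured:
            raise KeyError(f"no measurement for mixture {design.label}")
        comps = [
            ComponentActivation(fa, profiles[fa].peak_fold, dose)
            for fa, dose in design.components
        ]
        ew = expected_weighted(comps)
        ea = expected_additive(comps)
        m = float(measured[design.label])
        results.append(
            SynergyResult(
                label=design.label,
                measured=m,
                expected_weighted=ew,
                expected_additive=ea,
                pct_delta_weighted=percent_delta(m, ew),
                pct_delta_additive=percent_delta(m, ea),
                ratio_weighted=m / ew,
                ratio_additive=m / ea,
                synergistic=classify_synergy(m, ea),
            )
        )
    return results


def synergy_frame(results: list[SynergyResult]) -> pd.DataFrame:
    """Table-style frame; %Δ columns rounded half-up for display, raw values
    kept alongside."""
    rows = [
        {
            "label": r.label,
            "measured": r.measured,
            "expected_weighted": r.expected_weighted,
            "pct_delta_weighted": round_half_up(r.pct_delta_weighted),
            "expected_additive": r.expected_additive,
            "pct_delta_additive": round_half_up(r.pct_delta_additive),
            "pct_delta_weighted_raw": r.pct_delta_weighted,
            "pct_delta_additive_raw": r.pct_delta_additive,
            "ratio_weighted": r.ratio_weighted,
            "ratio_additive": r.ratio_additive,
            "synergistic": r.synergistic,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
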