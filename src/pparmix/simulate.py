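"""Synthetic dual-luciferase plate generator.

Emulates a 384-well transactivation experiment: a treatment-responsive
firefly luciferase reporter and a constitutive Renilla control are read
for every well. Ground truth is a per-fatty-acid polynomial fold-response
over dose (quadratic at most, intercept fixed at 1 = vehicle level),
a shared viability decline above a dose threshold that multiplies *both*
reporters, and independent multiplicative lognormal well noise. Mixture
wells respond under a declared truth model: the molarity-weighted mean of
the component responses, their plain sum, or the sum inflated by a synergy
multiplier kappa.

All randomness flows through an explicit integer seed; the same
(design, truth, seed) triple always reproduces the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .mixtures import MixtureDesign, fa_sort_key

__all__ = [
    "TruthModel",
    "PlateDesign",
    "make_dose_series",
    "true_fold",
    "true_mixture_fold",
    "simulate_plate",
    "write_plate_csv",
    "read_plate_csv",
    "default_truth",
    "default_panel",
    "single_label",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = [
    "plate_id",
    "well_id",
    "treatment",
    "components",
    "replicate",
    "firefly",
    "renilla",
]

_FOLD_FLOOR = 1e-6
MIXTURE_MODES = ("weighted", "additive", "synergy")


@dataclass(frozen=True)
class TruthModel:
    """Ground truth for the simulator.

    fa_params maps FA name -> (b0, b1, b2): fold = b0 + b1*d + b2*d^2 with
    d in µM and b0 = 1 enforced (vehicle fold is 1 by definition).
    viability_onset/viability_rate define the shared cytotoxic decline
    exp(-rate * (total_dose - onset)) applied to both reporters above the
    onset. noise_cv is the coefficient of variation of the multiplicative
    lognormal well noise, drawn independently for the two reporters.
    """

    fa_params: dict[str, tuple[float, float, float]]
    viability_onset: float = 125.0
    viability_rate: float = 0.004
    mixture_mode: str = "weighted"
    kappa: float = 1.0
    noise_cv: float = 0.10
    base_firefly: float = 50_000.0
    base_renilla: float = 25_000.0

    def __post_init__(self) -> None:
        for fa, coefs in self.fa_params.items():
            if len(coefs) != 3:
                raise InvalidDesignError(f"{fa}: need (b0, b1, b2), got {coefs}")
            if coefs[0] != 1.0:
                raise InvalidDesignError(
                    f"{fa}: intercept b0 must be 1 (fold at dose 0), got {coefs[0]}"
                )
        if self.mixture_mode not in MIXTURE_MODES:
            raise InvalidDesignError(
                f"mixture_mode must be one of {MIXTURE_MODES}, got {self.mixture_mode!r}"
            )
        if self.kappa < 0:
            raise InvalidDesignError(f"kappa must be >= 0, got {self.kappa}")
        if self.noise_cv < 0:
            raise InvalidDesignError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.viability_rate < 0 or self.viability_onset < 0:
            raise InvalidDesignError("viability parameters must be non-negative")

    def viability(self, total_dose: float) -> float:
        """Fraction of surviving signal at a given total FA load (µM)."""
        if total_dose <= self.viability_onset:
            return 1.0
        return math.exp(-self.viability_rate * (total_dose - self.viability_onset))


@dataclass(frozen=True)
class PlateDesign:
    """Layout of one simulated plate.

    fa_series maps FA name -> max dose µM; each such FA gets an
    ``n_dose_points``-point linear dose series from 0. ``singles`` are extra
    one-FA treatments at a fixed dose (e.g. each FA at its peak dose on a
    mixtures plate); ``mixtures`` are dosed :class:`MixtureDesign` objects.
    Every (treatment, replicate) cell is one well; vehicle wells carry the
    solvent only.
    """

    fa_series: dict[str, float] = field(default_factory=dict)
    n_dose_points: int = 10
    singles: tuple[tuple[str, float], ...] = ()
    mixtures: tuple[MixtureDesign, ...] = ()
    n_replicates: int = 4
    n_vehicle_per_replicate: int = 8
    plate_id: str = "P1"

    def __post_init__(self) -> None:
        if self.fa_series and self.n_dose_points < 2:
            raise InvalidDesignError("n_dose_points must be >= 2")
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be >= 1")
        if self.n_vehicle_per_replicate < 1:
            raise InvalidDesignError("need at least one vehicle well per replicate")
        for fa, mx in self.fa_series.items():
            if mx <= 0:
                raise InvalidDesignError(f"{fa}: max dose must be positive, got {mx}")


def make_dose_series(max_dose: float, n_points: int) -> np.ndarray:
    """Evenly spaced doses from 0 to ``max_dose`` µM inclusive.

    Mirrors a digital dispenser's linear curve with 0 as the minimum and
    the per-FA maximum (1% of stock concentration) as the top point.
    """
    if max_dose <= 0:
        raise InvalidDesignError(f"max_dose must be positive, got {max_dose}")
    if n_points < 2:
        raise InvalidDesignError(f"n_points must be >= 2, got {n_points}")
    return np.linspace(0.0, float(max_dose), int(n_points))


def true_fold(fa: str, dose: float, truth: TruthModel) -> float:
    """Ground-truth fold-change of one FA at one dose (floored at >0)."""
    if dose < 0:
        raise InvalidDesignError(f"dose must be >= 0, got {dose}")
    b0, b1, b2 = truth.fa_params[fa]
    return max(b0 + b1 * dose + b2 * dose * dose, _FOLD_FLOOR)


def true_mixture_fold(
    components: list[tuple[str, float]], truth: TruthModel
) -> float:
    """Ground-truth fold of a mixture under the declared truth model.

    weighted: molarity-weighted mean of the component folds at their
    in-mixture doses; additive: their sum; synergy: kappa times the sum.
    """
    if not components:
        raise InvalidDesignError("mixture must have at least one component")
    folds = np.array([true_fold(fa, d, truth) for fa, d in components])
    doses = np.array([d for _, d in components], dtype=float)
    if truth.mixture_mode == "weighted":
        if doses.sum() <= 0:
            raise InvalidDesignError("weighted mixture needs positive total molarity")
        return float(np.dot(folds, doses) / doses.sum())
    total = float(folds.sum())
    if truth.mixture_mode == "synergy":
        total *= truth.kappa
    return total


def single_label(fa: str, dose: float) -> str:
    return f"{fa}@{dose:g}"


def _treatments(design: PlateDesign, truth: TruthModel):
    """Deterministic treatment list: (label, components, true_fold)."""
    out: list[tuple[str, tuple[tuple[str, float], ...], float]] = []
    out.append(("vehicle", (), 1.0))
    for fa in sorted(design.fa_series, key=fa_sort_key):
        for dose in make_dose_series(design.fa_series[fa], design.n_dose_points):
            d = float(dose)
            out.append((single_label(fa, d), ((fa, d),), true_fold(fa, d, truth)))
    for fa, dose in design.singles:
        out.append(
            (single_label(fa, dose), ((fa, float(dose)),), true_fold(fa, dose, truth))
        )
    for mix in design.mixtures:
        comps = tuple(mix.components)
        out.append((mix.label, comps, true_mixture_fold(list(comps), truth)))
    return out


def simulate_plate(
    design: PlateDesign, truth: TruthModel, seed: int
) -> pd.DataFrame:
    """Simulate raw firefly/Renilla readings for every well of one plate.

    firefly = base_firefly * fold * viability(total dose) * noise and
    renilla = base_renilla * viability(total dose) * noise, with two
    independent lognormal mean-1 noise draws per well. Fully determined
    by (design, truth, seed).
    """
    rng = np.random.default_rng(int(seed))
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
    mu = -0.5 * sigma * sigma

    rows = []
    well = 0
    for label, comps, fold in _treatments(design, truth):
        total_dose = sum(d for _, d in comps)
        viab = truth.viability(total_dose)
        # repr round-trips floats exactly; the dose read back must equal the
        # dose the response was generated at
        comp_str = ";".join(f"{fa}:{d!r}" for fa, d in comps)
        n_wells = design.n_vehicle_per_replicate if label == "vehicle" else 1
        for rep in range(1, design.n_replicates + 1):
            for _ in range(n_wells):
                well += 1
                noise_f, noise_r = rng.lognormal(mu, sigma, size=2)
                rows.append(
                    (
                        design.plate_id,
                        f"W{well:03d}",
                        label,
                        comp_str,
                        rep,
                        truth.base_firefly * fold * viab * noise_f,
                        truth.base_renilla * viab * noise_r,
                    )
                )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def write_plate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"components": str}, keep_default_na=False)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidDesignError(f"plate CSV missing columns: {sorted(missing)}")
    return df


def parse_components(comp_str: str) -> tuple[tuple[str, float], ...]:
    """Parse the semicolon-joined "FA:dose" column (FA names may contain ':')."""
    if not comp_str or (isinstance(comp_str, float) and math.isnan(comp_str)):
        return ()
    out = []
    for item in str(comp_str).split(";"):
        fa, dose = item.rsplit(":", 1)
        out.append((fa, float(dose)))
    return tuple(out)


def _quadratic_with_vertex(vertex: float, peak_fold: float):
    """Coefficients (1, b1, b2) of a quadratic through (0, 1) peaking at
    (vertex, peak_fold)."""
    b1 = 2.0 * (peak_fold - 1.0) / vertex
    b2 = -(peak_fold - 1.0) / (vertex * vertex)
    return (1.0, b1, b2)


def default_truth(**overrides) -> TruthModel:
    """Truth emulating the six strongest PPAR-activating FAs of the study:
    C12:0 rising linearly to ~4.3-fold at 500 µM; the others quadratic with
    peaks of 2.5-3.2-fold at 158-190 µM."""
    params = {
        "C12:0": (1.0, 3.3 / 500.0, 0.0),
        "C16:0": _quadratic_with_vertex(158.0, 3.2),
        "C16:1": _quadratic_with_vertex(158.0, 2.6),
        "C18:0": _quadratic_with_vertex(190.0, 3.1),
        "C18:1": _quadratic_with_vertex(158.0, 2.5),
        "C20:0 BCFA": _quadratic_with_vertex(158.0, 2.8),
    }
    kwargs = dict(fa_params=params)
    kwargs.update(overrides)
    return TruthModel(**kwargs)


def default_panel() -> dict[str, float]:
    """Per-FA max tested dose (µM): 500 for the linear responder, twice the
    vertex for quadratic responders so the truth stays positive over the
    tested range."""
    return {
        "C12:0": 500.0,
        "C16:0": 316.0,
        "C16:1": 316.0,
        "C18:0": 380.0,
        "C18:1": 316.0,
        "C20:0 BCFA": 316.0,
    }
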