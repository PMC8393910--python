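"""Reusable simulation studies over the full pipeline.

Each study regenerates synthetic plates under a known truth, runs the
relevant pipeline stages, and reports a recovery or error rate. They are
the package's own evidence that the estimators behave: peak-dose recovery
and power, type-I control of the dose and pairwise tests, synergy-flag
rates around the additive boundary, and exact slope recovery of the
expectation models on noise-free data.

Study sizes (seeds per study, panel sizes) are chosen to give stable rates
at desk scale; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import normalize, synergy
from .dose_response import (
    fit_polynomial,
    fit_profile,
    peak_dose,
    profiles_from_normalized,
    single_fa_data,
)
from .mixtures import assign_doses, enumerate_mixtures
from .simulate import (
    PlateDesign,
    TruthModel,
    default_panel,
    default_truth,
    simulate_plate,
    single_label,
)
from .stats import dose_effect_test, pairwise_compare

__all__ = [
    "child_seeds",
    "peak_recovery_study",
    "type1_dose_study",
    "dose_power_study",
    "pairwise_type1_study",
    "synergy_detection_study",
    "slope_recovery_study",
]

_QUAD_FA = "C16:0"


def child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2**31) derived from one master seed."""
    return np.random.default_rng(int(seed)).integers(0, 2**31 - 1, size=n)


def _quad_truth(vertex: float, peak_fold: float, noise_cv: float) -> TruthModel:
    b1 = 2.0 * (peak_fold - 1.0) / vertex
    b2 = -(peak_fold - 1.0) / vertex**2
    return TruthModel(fa_params={_QUAD_FA: (1.0, b1, b2)}, noise_cv=noise_cv)


def peak_recovery_study(
    seed: int,
    n_seeds: int = 200,
    vertex: float = 158.0,
    peak_fold: float = 3.2,
    noise_cv: float = 0.10,
    n_replicates: int = 4,
    n_points: int = 10,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Recover the peak dose of a quadratic truth from noisy plates.

    Returns the median relative peak-dose error and the fraction of seeds
    in which the quadratic term is significant at ``alpha``.
    """
    truth = _quad_truth(vertex, peak_fold, noise_cv)
    design = PlateDesign(
        fa_series={_QUAD_FA: 2.0 * vertex},
        n_dose_points=n_points,
        n_replicates=n_replicates,
    )
    errors, hits = [], 0
    for s in child_seeds(seed, n_seeds):
        wells = simulate_plate(design, truth, int(s))
        norm = normalize.fold_changes(wells)
        doses, folds, reps = single_fa_data(norm, _QUAD_FA)
        fit = fit_polynomial(doses, folds, reps, degree=2, fa=_QUAD_FA)
        if fit.term_p_values["dose^2"] < alpha:
            hits += 1
        pk, _ = peak_dose(fit, (doses.min(), doses.max()))
        errors.append(abs(pk - vertex) / vertex)
    return {
        "median_rel_peak_error": float(np.median(errors)),
        "quad_term_significant_rate": hits / n_seeds,
        "n_seeds": n_seeds,
    }


def type1_dose_study(
    seed: int,
    n_seeds: int = 500,
    noise_cv: float = 0.10,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate of the dose main-effect F-test under a flat truth."""
    truth = TruthModel(fa_params={_QUAD_FA: (1.0, 0.0, 0.0)}, noise_cv=noise_cv)
    design = PlateDesign(fa_series={_QUAD_FA: 316.0}, n_dose_points=10)
    rejections = 0
    for s in child_seeds(seed, n_seeds):
        wells = simulate_plate(design, truth, int(s))
        norm = normalize.fold_changes(wells)
        doses, folds, reps = single_fa_data(norm, _QUAD_FA)
        if dose_effect_test(doses, folds, reps) < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_seeds, "n_seeds": n_seeds}


def dose_power_study(
    seed: int,
    n_seeds: int = 200,
    noise_cv: float = 0.10,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Power of the dose F-test under a strong linear truth (4-fold at the
    top dose)."""
    truth = TruthModel(
        fa_params={_QUAD_FA: (1.0, 3.0 / 500.0, 0.0)}, noise_cv=noise_cv
    )
    design = PlateDesign(fa_series={_QUAD_FA: 500.0}, n_dose_points=10)
    rejections = 0
    for s in child_seeds(seed, n_seeds):
        wells = simulate_plate(design, truth, int(s))
        norm = normalize.fold_changes(wells)
        doses, folds, reps = single_fa_data(norm, _QUAD_FA)
        if dose_effect_test(doses, folds, reps) < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_seeds, "n_seeds": n_seeds}


def pairwise_type1_study(
    seed: int,
    n_seeds: int = 500,
    noise_cv: float = 0.10,
    alpha: float = 0.05,
) -> dict[str, float]:
    """False-positive rate of the pairwise comparison on two identically
    distributed treatment groups (flat truth, two doses)."""
    truth = TruthModel(fa_params={_QUAD_FA: (1.0, 0.0, 0.0)}, noise_cv=noise_cv)
    design = PlateDesign(singles=((_QUAD_FA, 100.0), (_QUAD_FA, 50.0)))
    labels = [single_label(_QUAD_FA, 100.0), single_label(_QUAD_FA, 50.0)]
    flags = 0
    for s in child_seeds(seed, n_seeds):
        wells = simulate_plate(design, truth, int(s))
        norm = normalize.fold_changes(wells)
        groups = {
            lb: norm.loc[norm["treatment"] == lb, "fold_change"].to_numpy()
            for lb in labels
        }
        res = pairwise_compare(groups, alpha=alpha)
        if any(r.significant for r in res):
            flags += 1
    return {"flag_rate": flags / n_seeds, "n_seeds": n_seeds}


def synergy_detection_study(
    seed: int,
    kappa: float,
    n_seeds: int = 200,
    noise_cv: float = 0.10,
) -> dict[str, float]:
    """Flag rate of classify_synergy for an injected pair mixture.

    Truth: a linear and a quadratic activator (the study's two strongest),
    combined at their true peak doses under the synergy truth model with
    multiplier kappa. Each seed runs the full pipeline: simulate, fit both
    single-FA profiles, sum their estimated peak activations, and compare
    with the measured mixture fold.
    """
    params = {
        "C12:0": (1.0, 3.3 / 500.0, 0.0),
        "C16:0": (1.0, 2 * 2.2 / 158.0, -2.2 / 158.0**2),
    }
    truth = TruthModel(
        fa_params=params, mixture_mode="synergy", kappa=kappa, noise_cv=noise_cv
    )
    [mix] = enumerate_mixtures(["C12:0", "C16:0"], k=2)
    mix = assign_doses(mix, {"C12:0": 500.0, "C16:0": 158.0}, scale=1.0)
    design = PlateDesign(
        fa_series={"C12:0": 500.0, "C16:0": 316.0},
        n_dose_points=10,
        mixtures=(mix,),
    )
    flagged = 0
    for s in child_seeds(seed, n_seeds):
        wells = simulate_plate(design, truth, int(s))
        norm = normalize.fold_changes(wells)
        profiles = {
            fa: fit_profile(norm, fa) for fa in ("C12:0", "C16:0")
        }
        measured = float(
            norm.loc[norm["treatment"] == mix.label, "fold_change"].mean()
        )
        expected = sum(p.peak_fold for p in profiles.values())
        if synergy.classify_synergy(measured, expected):
            flagged += 1
    return {"flag_rate": flagged / n_seeds, "n_seeds": n_seeds}


def slope_recovery_study(
    mixture_mode: str,
    noise_cv: float = 0.0,
    kappa: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Origin-constrained slopes of measured on expected activation for the
    full six-FA panel pipeline under a declared truth model.

    With noise off, the slope of the model matching the truth is exactly 1
    for pair mixtures (component reference doses coincide with in-mixture
    doses); triples probe the dose-inconsistency of scoring scaled-dose
    mixtures with peak-dose activations.
    """
    truth = default_truth(mixture_mode=mixture_mode, kappa=kappa, noise_cv=noise_cv)
    panel = default_panel()
    fas = sorted(panel)

    series_design = PlateDesign(
        fa_series=panel, n_dose_points=10, plate_id="P1"
    )
    norm1 = normalize.fold_changes(simulate_plate(series_design, truth, seed))
    profiles = profiles_from_normalized(norm1, fas=fas)
    peaks = {fa: profiles[fa].peak_dose for fa in fas}

    pairs = [assign_doses(m, peaks, 1.0) for m in enumerate_mixtures(fas, 2)]
    triples = [assign_doses(m, peaks, 1.0 / 3.0) for m in enumerate_mixtures(fas, 3)]
    singles = tuple((fa, peaks[fa]) for fa in fas)
    mix_design = PlateDesign(
        singles=singles, mixtures=tuple(pairs + triples), plate_id="P2"
    )
    norm2 = normalize.fold_changes(simulate_plate(mix_design, truth, seed + 1))

    out: dict[str, float] = {}
    for name, designs in (("pairs", pairs), ("triples", triples)):
        measured = {
            m.label: float(
                norm2.loc[norm2["treatment"] == m.label, "fold_change"].mean()
            )
            for m in designs
        }
        results = synergy.synergy_table(designs, profiles, measured)
        exp_w = [r.expected_weighted for r in results]
        exp_a = [r.expected_additive for r in results]
        act = [r.measured for r in results]
        out[f"weighted_slope_{name}"] = synergy.fit_origin_slope(exp_w, act).slope
        out[f"additive_slope_{name}"] = synergy.fit_origin_slope(exp_a, act).slope
        out[f"n_synergistic_{name}"] = sum(r.synergistic for r in results)
    return out
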