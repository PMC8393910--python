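"""Polynomial dose-response fitting with replicate blocking.

Each fatty acid's fold-change is regressed on dose powers (degree 1-3)
with the replicate entering as a sum-to-zero block term, so dose
coefficients are unaffected by replicate-level offsets. The selected model
is the highest degree whose top-order term is significant; the dose of
peak activation is the maximizer of the selected polynomial over the
tested range (analytic for degree <= 2, 1-µM grid for cubics).

Adjusted R² is reported for the dose-only curve after removing block
means, i.e. it describes the curve fit rather than the block model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError
from .mixtures import round_half_up
from .simulate import parse_components

__all__ = [
    "DoseResponseFit",
    "FattyAcidProfile",
    "fit_polynomial",
    "select_model",
    "peak_dose",
    "predict",
    "fit_profile",
    "profiles_from_normalized",
    "single_fa_data",
]


@dataclass(frozen=True)
class DoseResponseFit:
    """One polynomial fit of fold-change on dose for a single FA."""

    fa: str
    degree: int
    coefficients: tuple[float, ...]  # b0..b_degree, fold per µM^k
    term_p_values: dict[str, float]  # "dose^k" -> p
    adjusted_r2: float
    selected: bool = False

    @property
    def top_term_p(self) -> float:
        return self.term_p_values[f"dose^{self.degree}"]


@dataclass(frozen=True)
class FattyAcidProfile:
    """Per-FA summary used downstream: the dose (integer µM, dispenser
    resolution) and predicted fold at peak activation."""

    fa: str
    peak_dose: float
    peak_fold: float
    selected_fit: DoseResponseFit
    significant: bool


def _block_matrix(replicates: np.ndarray) -> np.ndarray:
    """Sum-to-zero block encoding; empty for a single replicate level."""
    levels = np.unique(replicates)
    if len(levels) < 2:
        return np.empty((len(replicates), 0))
    cols = []
    ref = levels[0]
    for lv in levels[1:]:
        col = (replicates == lv).astype(float) - (replicates == ref).astype(float)
        cols.append(col)
    return np.column_stack(cols)


def fit_polynomial(
    doses,
    folds,
    replicates,
    degree: int,
    fa: str = "",
) -> DoseResponseFit:
    """OLS fit of fold on dose powers plus replicate block terms.

    Doses are internally rescaled to [0, 1] for conditioning; reported
    coefficients are on the raw µM scale. Per-term p-values come from the
    blocked model; adjusted R² from the block-corrected dose-only curve.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(folds, dtype=float)
    reps = np.asarray(replicates)
    if degree not in (1, 2, 3):
        raise FitError(f"degree must be 1, 2 or 3, got {degree}")
    n_distinct = len(np.unique(d))
    if n_distinct < degree + 2:
        raise FitError(
            f"need >= {degree + 2} distinct doses for degree {degree}, "
            f"got {n_distinct}"
        )
    if len(np.unique(reps)) < 2:
        raise FitError("need >= 2 replicates")

    scale = d.max() if d.max() > 0 else 1.0
    z = d / scale
    powers = np.column_stack([z**k for k in range(1, degree + 1)])
    X = np.column_stack(
        [np.ones(len(z)), powers, _block_matrix(reps)]
    )
    res = sm.OLS(y, X).fit()

    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = np.asarray(res.pvalues)
    term_p = {}
    for k in range(1, degree + 1):
        p = pvals[k]
        term_p[f"dose^{k}"] = 1.0 if np.isnan(p) else float(p)
    coefs = tuple(
        float(res.params[k] / scale**k) for k in range(0, degree + 1)
    )
    if not all(np.isfinite(coefs)):
        raise FitError(f"non-finite coefficients for {fa or 'FA'}")

    # curve-fit R²: remove replicate means, refit the dose-only polynomial
    grand = y.mean()
    y_adj = y.copy()
    for lv in np.unique(reps):
        m = reps == lv
        y_adj[m] = y[m] - y[m].mean() + grand
    Xd = np.column_stack([np.ones(len(z)), powers])
    beta, *_ = np.linalg.lstsq(Xd, y_adj, rcond=None)
    resid = y_adj - Xd @ beta
    sst = float(((y_adj - y_adj.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    n, p = len(y_adj), degree
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    return DoseResponseFit(
        fa=fa,
        degree=degree,
        coefficients=coefs,
        term_p_values=term_p,
        adjusted_r2=float(adj_r2),
    )


_PERFECT_R2 = 1.0 - 1e-9


def select_model(fits: list[DoseResponseFit], alpha: float = 0.05) -> DoseResponseFit:
    """Highest-degree fit whose top-order term has p < alpha; otherwise the
    degree-1 fit, left unselected (no supported dose trend).

    Parsimony tie-break: when a lower-degree model already fits to machine
    precision (adjusted R² at 1), higher-order terms only chase rounding
    noise and their t-statistics are meaningless, so the lowest perfectly
    fitting significant model wins.
    """
    by_degree = {f.degree: f for f in fits}
    for deg in sorted(by_degree):
        f = by_degree[deg]
        if f.adjusted_r2 >= _PERFECT_R2 and f.top_term_p < alpha:
            return dataclasses.replace(f, selected=True)
    for deg in sorted(by_degree, reverse=True):
        f = by_degree[deg]
        if f.top_term_p < alpha:
            return dataclasses.replace(f, selected=True)
    return dataclasses.replace(by_degree[min(by_degree)], selected=False)


def predict(fit: DoseResponseFit, dose) -> np.ndarray | float:
    d = np.asarray(dose, dtype=float)
    out = np.zeros_like(d)
    for k, b in enumerate(fit.coefficients):
        out = out + b * d**k
    return out if out.ndim else float(out)


def peak_dose(
    fit: DoseResponseFit, dose_range: tuple[float, float]
) -> tuple[float, float]:
    """Maximizer of the fitted polynomial over the closed tested range.

    Degree <= 2: closed form over boundary and stationary points; degree 3:
    dense 1-µM grid. Returns (dose, predicted fold)."""
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise FitError(f"invalid dose range {dose_range}")
    if not all(np.isfinite(fit.coefficients)):
        raise FitError("non-finite coefficients")

    if fit.degree <= 2:
        candidates = [lo, hi]
        if fit.degree == 2 and fit.coefficients[2] != 0:
            vertex = -fit.coefficients[1] / (2.0 * fit.coefficients[2])
            if lo < vertex < hi:
                candidates.append(vertex)
        vals = [predict(fit, c) for c in candidates]
        i = int(np.argmax(vals))
        return float(candidates[i]), float(vals[i])

    grid = np.unique(np.concatenate([np.arange(lo, hi, 1.0), [hi]]))
    vals = predict(fit, grid)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


def single_fa_data(normalized: pd.DataFrame, fa: str):
    """Extract (doses, folds, replicates) for wells treated with ``fa`` alone."""
    doses, folds, reps = [], [], []
    for _, row in normalized.iterrows():
        comps = parse_components(row["components"])
        if len(comps) == 1 and comps[0][0] == fa:
            doses.append(comps[0][1])
            folds.append(row["fold_change"])
            reps.append(row["replicate"])
    return np.asarray(doses), np.asarray(folds), np.asarray(reps)


def fit_profile(
    normalized: pd.DataFrame,
    fa: str,
    degrees: tuple[int, ...] = (1, 2, 3),
    alpha: float = 0.05,
) -> FattyAcidProfile:
    """Fit the feasible polynomial degrees for one FA, select, and locate
    the peak. The design peak dose is rounded to the nearest integer µM and
    the peak fold evaluated at that rounded dose."""
    doses, folds, reps = single_fa_data(normalized, fa)
    if len(doses) == 0:
        raise FitError(f"no single-FA wells for {fa}")
    n_distinct = len(np.unique(doses))
    feasible = [g for g in degrees if n_distinct >= g + 2]
    if not feasible:
        raise FitError(f"{fa}: only {n_distinct} distinct doses, cannot fit")
    fits = [fit_polynomial(doses, folds, reps, g, fa=fa) for g in feasible]
    chosen = select_model(fits, alpha=alpha)
    lo, hi = float(doses.min()), float(doses.max())
    pk_dose, _ = peak_dose(chosen, (lo, hi))
    design_dose = float(round_half_up(pk_dose))
    design_dose = min(max(design_dose, lo), hi)
    return FattyAcidProfile(
        fa=fa,
        peak_dose=design_dose,
        peak_fold=float(predict(chosen, design_dose)),
        selected_fit=chosen,
        significant=chosen.selected,
    )


def profiles_from_normalized(
    normalized: pd.DataFrame,
    fas: list[str] | None = None,
    alpha: float = 0.05,
    min_distinct_doses: int = 3,
) -> dict[str, FattyAcidProfile]:
    """Profiles for every FA with a dose series in the normalized table."""
    if fas is None:
        seen: dict[str, set] = {}
        for comp_str in normalized["components"].unique():
            comps = parse_components(comp_str)
            if len(comps) == 1:
                seen.setdefault(comps[0][0], set()).add(comps[0][1])
        fas = sorted(
            fa for fa, ds in seen.items() if len(ds) >= min_distinct_doses
        )
    return {fa: fit_profile(normalized, fa, alpha=alpha) for fa in fas}
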