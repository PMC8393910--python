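"""Group-comparison statistics for the reporter assay.

Reproduces the testing structure of a blocked plate experiment: an F-test
of the dose main effect with replicate as block, all-pairwise treatment
comparisons (Tukey HSD by default) summarized as a compact letter display,
and per-FA grids testing each mixture against the single FA it contains,
each FA getting its own model.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, FitError
from .mixtures import MixtureDesign

__all__ = [
    "ComparisonResult",
    "dose_effect_test",
    "pairwise_compare",
    "letter_display",
    "mixture_vs_component_grid",
]


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    estimate: float  # mean(b) - mean(a)
    p_value: float
    significant: bool


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rank = np.linalg.matrix_rank(X)
    return float((resid**2).sum()), rank


def dose_effect_test(doses, folds, replicates) -> float:
    """p-value of the dose main effect (categorical) in a replicate-blocked
    linear model, by extra-sum-of-squares F-test."""
    d = np.asarray(doses)
    y = np.asarray(folds, dtype=float)
    r = np.asarray(replicates)
    dose_levels = np.unique(d)
    rep_levels = np.unique(r)
    if len(dose_levels) < 2:
        raise FitError("need >= 2 distinct doses")
    if len(rep_levels) < 2:
        raise FitError("need >= 2 replicates")

    n = len(y)
    blocks = np.column_stack([(r == lv).astype(float) for lv in rep_levels[1:]])
    reduced = np.column_stack([np.ones(n), blocks])
    dose_dummies = np.column_stack(
        [(d == lv).astype(float) for lv in dose_levels[1:]]
    )
    full = np.column_stack([reduced, dose_dummies])

    sse_r, rank_r = _sse(reduced, y)
    sse_f, rank_f = _sse(full, y)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 < 1 or df2 < 1:
        raise FitError("degenerate design for dose F-test")
    sst = float(((y - y.mean()) ** 2).sum())
    if sse_r <= 1e-12 * max(sst, 1.0):
        # the blocked null already fits to machine precision: no dose effect
        return 1.0
    if sse_f <= 0:  # dose explains the remaining variation exactly
        return 0.0
    F = ((sse_r - sse_f) / df1) / (sse_f / df2)
    return float(sps.f.sf(F, df1, df2))


def pairwise_compare(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjust: str = "tukey",
) -> list[ComparisonResult]:
    """All unordered pairwise comparisons of group means.

    ``adjust``: "tukey" (HSD, default), "bonferroni", or "none"
    (unadjusted Welch t-tests).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [np.asarray(groups[lb], dtype=float) for lb in labels]
    for lb, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lb!r} has < 2 replicates")

    results = []
    if adjust == "tukey":
        with np.errstate(divide="ignore", invalid="ignore"):
            hsd = sps.tukey_hsd(*samples)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = float(hsd.pvalue[i, j])
                if np.isnan(p):  # zero within-group variance, equal means
                    p = 1.0 if samples[i].mean() == samples[j].mean() else 0.0
                results.append(
                    ComparisonResult(
                        labels[i],
                        labels[j],
                        float(samples[j].mean() - samples[i].mean()),
                        p,
                        p < alpha,
                    )
                )
        return results

    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    n_tests = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(sps.ttest_ind(samples[i], samples[j], equal_var=False).pvalue)
            if adjust == "bonferroni":
                p = min(1.0, p * n_tests)
            results.append(
                ComparisonResult(
                    labels[i],
                    labels[j],
                    float(samples[j].mean() - samples[i].mean()),
                    p,
                    p < alpha,
                )
            )
    return results


def letter_display(results: list[ComparisonResult]) -> dict[str, tuple[str, ...]]:
    """Compact letter display by insert-and-absorb.

    Maps each treatment to its tuple of letters; two treatments share no
    letter exactly when their pairwise comparison is significant. Requires
    results covering every unordered pair.
    """
    order: list[str] = []
    for r in results:
        for g in (r.group_a, r.group_b):
            if g not in order:
                order.append(g)
    pairs = {frozenset((r.group_a, r.group_b)) for r in results}
    expected = {
        frozenset((a, b))
        for i, a in enumerate(order)
        for b in order[i + 1 :]
    }
    if pairs != expected:
        raise ValueError("results must cover all unordered pairs exactly once")

    sets: list[set[str]] = [set(order)]
    for r in results:
        if not r.significant:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if r.group_a in s and r.group_b in s:
                new_sets.append(s - {r.group_a})
                new_sets.append(s - {r.group_b})
            else:
                new_sets.append(s)
        # absorb: drop empties, duplicates and strict subsets
        final: list[set[str]] = []
        for s in new_sets:
            if not s or s in final:
                continue
            if any(s < t for t in new_sets):
                continue
            final.append(s)
        sets = final

    idx = {t: i for i, t in enumerate(order)}
    sets.sort(key=lambda s: min(idx[t] for t in s))
    letters: dict[str, list[str]] = {t: [] for t in order}
    for letter, s in zip(_letter_sequence(), sets):
        for t in s:
            letters[t].append(letter)
    return {t: tuple(sorted(ls)) for t, ls in letters.items()}


def _letter_sequence():
    """a..z, then aa, ab, ... — plates can carry more than 26 groups."""
    for ch in string.ascii_lowercase:
        yield ch
    for ch1 in string.ascii_lowercase:
        for ch2 in string.ascii_lowercase:
            yield ch1 + ch2


def mixture_vs_component_grid(
    mixtures: list[MixtureDesign],
    component_labels: dict[str, str],
    measurements: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Per-FA significance grid: mixture vs the single FA it contains.

    For each FA a separate model holds the single-FA treatment and every
    mixture containing that FA; cells are True when the mixture differs
    from the component at ``alpha``. Rows: FA; columns: mixture labels;
    cells for mixtures not containing the FA are NA.
    """
    mix_labels = [m.label for m in mixtures]
    grid = pd.DataFrame(
        pd.NA, index=list(component_labels), columns=mix_labels, dtype=object
    )
    for fa, fa_label in component_labels.items():
        containing = [m for m in mixtures if fa in m.fas]
        if not containing:
            continue
        if fa_label not in measurements:
            raise ConfigError(f"no single-FA measurement for {fa} ({fa_label})")
        groups = {fa_label: measurements[fa_label]}
        for m in containing:
            if m.label not in measurements:
                raise ConfigError(f"no measurement for mixture {m.label}")
            groups[m.label] = measurements[m.label]
        comps = pairwise_compare(groups, alpha=alpha, adjust=adjust)
        for r in comps:
            pair = {r.group_a, r.group_b}
            if fa_label in pair:
                other = (pair - {fa_label}).pop()
                if other in grid.columns:
                    grid.loc[fa, other] = bool(r.significant)
    return grid
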