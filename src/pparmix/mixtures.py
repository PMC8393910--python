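"""Combinatorial mixture design.

Enumerates all k-component combinations of a fatty-acid panel and assigns
per-component doses from single-FA peak doses: pair mixtures at the full
peak dose, triple mixtures at one third of it (to limit total lipid load),
both overridable. Doses are rounded half-up to the nearest integer µM,
which is the resolution a digital dispenser is programmed at.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

from .errors import ConfigError, InvalidDesignError

__all__ = [
    "MixtureDesign",
    "enumerate_mixtures",
    "assign_doses",
    "fa_sort_key",
    "mixture_label",
    "round_half_up",
]

_FA_RE = re.compile(r"C(\d+)(?::(\d+))?")


def fa_sort_key(name: str) -> tuple[int, int, int, str]:
    """Canonical ordering key: carbon number, unsaturation, branching.

    Understands names like ``C12:0``, ``C16:1`` and ``C20:0 BCFA``;
    anything unparsable sorts last, alphabetically.
    """
    m = _FA_RE.match(name.strip())
    if m is None:
        return (10**6, 0, 0, name)
    carbons = int(m.group(1))
    unsat = int(m.group(2)) if m.group(2) else 0
    branched = 1 if "BCFA" in name.upper() else 0
    return (carbons, unsat, branched, name)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (dispenser rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mixture_label(names: list[str]) -> str:
    return "+".join(sorted(names, key=fa_sort_key))


@dataclass(frozen=True)
class MixtureDesign:
    """A k-component fatty-acid combination with assigned doses (µM).

    ``components`` is kept in canonical order (carbon number, then
    unsaturation) so the label is independent of panel order.
    """

    components: tuple[tuple[str, float], ...]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        names = [fa for fa, _ in self.components]
        if len(set(names)) != len(names):
            raise InvalidDesignError(f"duplicate component in mixture: {names}")
        ordered = tuple(sorted(self.components, key=lambda c: fa_sort_key(c[0])))
        object.__setattr__(self, "components", ordered)
        object.__setattr__(self, "label", mixture_label(names))

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def fas(self) -> tuple[str, ...]:
        return tuple(fa for fa, _ in self.components)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.components)

    @property
    def total_dose(self) -> float:
        return float(sum(self.doses))


def enumerate_mixtures(panel: list[str], k: int) -> list[MixtureDesign]:
    """All C(n, k) unordered k-combinations of ``panel``, doses unset (0).

    Doses are assigned afterwards by :func:`assign_doses`.
    """
    if len(set(panel)) != len(panel):
        raise InvalidDesignError("panel names must be distinct")
    if not 2 <= k <= len(panel):
        raise InvalidDesignError(f"k={k} out of range for panel of {len(panel)}")
    ordered = sorted(panel, key=fa_sort_key)
    return [
        MixtureDesign(tuple((fa, 0.0) for fa in combo))
        for combo in itertools.combinations(ordered, k)
    ]


def assign_doses(
    mixture: MixtureDesign,
    peak_doses: dict[str, float],
    scale: float,
) -> MixtureDesign:
    """Set each component dose to ``round_half_up(peak_dose * scale)`` µM."""
    if scale <= 0:
        raise InvalidDesignError(f"scale must be positive, got {scale}")
    missing = [fa for fa in mixture.fas if fa not in peak_doses]
    if missing:
        raise ConfigError(f"no peak dose for component(s): {missing}")
    comps = tuple(
        (fa, float(round_half_up(peak_doses[fa] * scale))) for fa in mixture.fas
    )
    return MixtureDesign(comps)
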