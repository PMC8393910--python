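"""Dual-reporter normalization.

Activation is quantified as the firefly/Renilla ratio, which cancels
well-to-well transfection efficiency and shared viability loss, and is then
expressed as fold-change versus the mean ratio of the vehicle wells of the
same plate. Renilla relative to the vehicle mean doubles as a cytotoxicity
proxy; wells below a viability threshold are flagged but retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateWellError, MissingControlError

__all__ = ["well_ratio", "fold_changes", "flag_viability", "VEHICLE_LABEL"]

logger = logging.getLogger(__name__)

VEHICLE_LABEL = "vehicle"


def well_ratio(firefly: float, renilla: float) -> float:
    """firefly / renilla for a single well; the unit of activation."""
    if renilla <= 0:
        raise DegenerateWellError(
            f"control reporter signal must be positive, got renilla={renilla}"
        )
    return float(firefly) / float(renilla)


def fold_changes(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize a table of raw wells to per-plate fold-changes.

    Per plate: the vehicle mean ratio (arithmetic mean over vehicle wells)
    is the fold-change denominator, and the vehicle mean Renilla the
    viability denominator. Wells with renilla <= 0 are dropped with a log
    entry. Plates without vehicle wells raise :class:`MissingControlError`.

    Returns a copy with ``ratio``, ``fold_change`` and ``viability_fraction``
    columns appended.
    """
    bad = wells["renilla"] <= 0
    if bad.any():
        for _, row in wells[bad].iterrows():
            logger.warning(
                "excluding degenerate well %s/%s (renilla=%g)",
                row["plate_id"],
                row["well_id"],
                row["renilla"],
            )
    out = wells.loc[~bad].copy()
    out["ratio"] = out["firefly"] / out["renilla"]

    parts = []
    for plate, grp in out.groupby("plate_id", sort=False):
        veh = grp[grp["treatment"] == VEHICLE_LABEL]
        if len(veh) < 2:
            raise MissingControlError(
                f"plate {plate!r}: need >= 2 vehicle wells, found {len(veh)}"
            )
        g = grp.copy()
        g["fold_change"] = g["ratio"] / veh["ratio"].mean()
        g["viability_fraction"] = g["renilla"] / veh["renilla"].mean()
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def flag_viability(wells: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Set ``viability_flag`` where the Renilla-derived viability fraction
    falls below ``threshold``. Flagged wells stay in the table."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    out = wells.copy()
    out["viability_flag"] = np.asarray(out["viability_fraction"]) < threshold
    return out
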