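"""End-to-end orchestration from a single YAML config.

A run is either a simulation (the config declares the truth model and
plate design) or an analysis of an existing long-format plate CSV. The
analysis executes normalization -> dose-response profiling -> mixture
scoring -> group statistics and writes plain-CSV outputs plus a text
summary. All thresholds (alpha, viability cutoff, mixture dose scales)
live in the config.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import normalize
from .dose_response import FattyAcidProfile, fit_profile
from .errors import ConfigError
from .mixtures import MixtureDesign, assign_doses, enumerate_mixtures, fa_sort_key
from .simulate import (
    PlateDesign,
    TruthModel,
    parse_components,
    simulate_plate,
    true_fold,
    write_plate_csv,
    read_plate_csv,
)
from .stats import letter_display, mixture_vs_component_grid, pairwise_compare
from .synergy import fit_origin_slope, synergy_frame, synergy_table

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SimulationBlock",
    "load_config",
    "default_run_config",
    "run_simulate",
    "run_analyze",
]


class FaTruth(BaseModel):
    """Per-FA truth: fold = 1 + b1*d + b2*d^2 over the tested 0..max_dose µM."""

    max_dose: float = Field(gt=0)
    b1: float = 0.0
    b2: float = 0.0


class SimulationBlock(BaseModel):
    panel: dict[str, FaTruth]
    n_dose_points: int = Field(default=10, ge=2)
    n_replicates: int = Field(default=4, ge=1)
    n_vehicle_per_replicate: int = Field(default=8, ge=1)
    noise_cv: float = Field(default=0.10, ge=0)
    base_firefly: float = Field(default=50_000.0, gt=0)
    base_renilla: float = Field(default=25_000.0, gt=0)
    viability_onset: float = Field(default=125.0, ge=0)
    viability_rate: float = Field(default=0.004, ge=0)
    mixture_mode: Literal["weighted", "additive", "synergy"] = "weighted"
    kappa: float = Field(default=1.0, ge=0)
    include_pairs: bool = True
    include_triples: bool = True


class RunConfig(BaseModel):
    input: Optional[str] = None
    simulation: Optional[SimulationBlock] = None
    out_dir: str = "results"
    seed: int = 1
    alpha: float = Field(default=0.05, gt=0, lt=1)
    viability_threshold: float = Field(default=0.7, gt=0, lt=1)
    exclude_toxic: bool = False
    pair_scale: float = Field(default=1.0, gt=0)
    triple_scale: float = Field(default=1.0 / 3.0, gt=0)

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.input is None) == (self.simulation is None):
            raise ValueError("exactly one of 'input' and 'simulation' must be set")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid config: " + "; ".join(lines)) from err


def default_run_config(
    out_dir: str = "results",
    seed: int = 1,
    noise_cv: float = 0.10,
    mixture_mode: str = "weighted",
    kappa: float = 1.0,
) -> RunConfig:
    """Study configuration for the six-FA panel: the default truth model,
    10-point series, 4 replicates, pairs at peak doses and triples at one
    third."""
    from .simulate import default_panel, default_truth

    truth = default_truth()
    panel = default_panel()
    sim = SimulationBlock(
        panel={
            fa: FaTruth(
                max_dose=panel[fa],
                b1=truth.fa_params[fa][1],
                b2=truth.fa_params[fa][2],
            )
            for fa in panel
        },
        noise_cv=noise_cv,
        mixture_mode=mixture_mode,
        kappa=kappa,
    )
    return RunConfig(simulation=sim, out_dir=out_dir, seed=seed)


def _truth_peak_doses(truth: TruthModel, panel: dict[str, float]) -> dict[str, float]:
    """Analytic peak dose of each truth polynomial over its tested range."""
    peaks = {}
    for fa, max_dose in panel.items():
        _, b1, b2 = truth.fa_params[fa]
        candidates = [0.0, max_dose]
        if b2 != 0:
            vertex = -b1 / (2 * b2)
            if 0 < vertex < max_dose:
                candidates.append(vertex)
        peaks[fa] = max(candidates, key=lambda d: true_fold(fa, d, truth))
    return peaks


def run_simulate(config: RunConfig, seed: int | None = None) -> Path:
    """Generate the study dataset: a dose-series plate (P1) and a mixtures
    plate (P2: each FA at its truth peak dose, plus all pair and triple
    combinations at the configured scales). Writes plate_data.csv."""
    if config.simulation is None:
        raise ConfigError("simulation: block required for simulate")
    sim = config.simulation
    seed = config.seed if seed is None else int(seed)
    truth = TruthModel(
        fa_params={fa: (1.0, t.b1, t.b2) for fa, t in sim.panel.items()},
        viability_onset=sim.viability_onset,
        viability_rate=sim.viability_rate,
        mixture_mode=sim.mixture_mode,
        kappa=sim.kappa,
        noise_cv=sim.noise_cv,
        base_firefly=sim.base_firefly,
        base_renilla=sim.base_renilla,
    )
    panel = {fa: t.max_dose for fa, t in sim.panel.items()}
    fas = sorted(panel, key=fa_sort_key)

    series = PlateDesign(
        fa_series=panel,
        n_dose_points=sim.n_dose_points,
        n_replicates=sim.n_replicates,
        n_vehicle_per_replicate=sim.n_vehicle_per_replicate,
        plate_id="P1",
    )
    frames = [simulate_plate(series, truth, seed)]

    peaks = _truth_peak_doses(truth, panel)
    mixtures: list[MixtureDesign] = []
    if sim.include_pairs and len(fas) >= 2:
        mixtures += [
            assign_doses(m, peaks, config.pair_scale)
            for m in enumerate_mixtures(fas, 2)
        ]
    if sim.include_triples and len(fas) >= 3:
        mixtures += [
            assign_doses(m, peaks, config.triple_scale)
            for m in enumerate_mixtures(fas, 3)
        ]
    if mixtures or len(fas) > 0:
        mix_plate = PlateDesign(
            singles=tuple((fa, float(round(peaks[fa]))) for fa in fas),
            mixtures=tuple(mixtures),
            n_replicates=sim.n_replicates,
            n_vehicle_per_replicate=sim.n_vehicle_per_replicate,
            plate_id="P2",
        )
        frames.append(simulate_plate(mix_plate, truth, seed + 1))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "plate_data.csv"
    df = pd.concat(frames, ignore_index=True)
    write_plate_csv(df, path)
    cfg_hash = hashlib.sha256(
        config.model_dump_json().encode()
    ).hexdigest()[:12]
    logger.info(
        "simulated %d wells -> %s (config %s, seed %d)", len(df), path, cfg_hash, seed
    )
    return path


def _series_plates(norm: pd.DataFrame, fa: str, min_doses: int = 4) -> pd.DataFrame:
    """Rows from plates where ``fa`` has a dose series (>= min_doses distinct
    single-FA doses); keeps curve fitting within one plate's normalization."""
    keep = []
    for plate, grp in norm.groupby("plate_id", sort=False):
        doses = set()
        for comp_str in grp["components"].unique():
            comps = parse_components(comp_str)
            if len(comps) == 1 and comps[0][0] == fa:
                doses.add(comps[0][1])
        if len(doses) >= min_doses:
            keep.append(grp)
    if not keep:
        return norm.iloc[0:0]
    return pd.concat(keep, ignore_index=True)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_analyze(config: RunConfig, input_path=None) -> dict[str, Path]:
    """Run the full analysis on a plate CSV and write all output tables.

    Stages: normalization and viability flagging; per-FA dose-response
    profiles; mixture scoring against both expectation models with
    through-origin slopes per mixture size; all-pairwise comparisons with
    letters and the per-FA mixture-vs-component grid.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if input_path is None:
        if config.input is None:
            raise ConfigError("input: plate CSV path required for analyze")
        input_path = config.input
    wells = read_plate_csv(input_path)
    logger.info("read %d wells from %s", len(wells), input_path)

    norm = normalize.flag_viability(
        normalize.fold_changes(wells), config.viability_threshold
    )
    logger.info(
        "normalized %d wells (%d excluded, %d viability-flagged)",
        len(norm),
        len(wells) - len(norm),
        int(norm["viability_flag"].sum()),
    )
    outputs = {"normalized": _write(norm, out_dir / "normalized.csv")}

    # --- dose-response profiles ---------------------------------------
    fas = sorted(
        {
            comps[0][0]
            for comp_str in norm["components"].unique()
            for comps in [parse_components(comp_str)]
            if len(comps) == 1
        },
        key=fa_sort_key,
    )
    profiles: dict[str, FattyAcidProfile] = {}
    for fa in fas:
        data = _series_plates(norm, fa)
        if data.empty:
            continue
        if config.exclude_toxic:
            data = data[~data["viability_flag"]]
        profiles[fa] = fit_profile(data, fa, alpha=config.alpha)
    prof_rows = []
    for fa, p in profiles.items():
        f = p.selected_fit
        coefs = list(f.coefficients) + [np.nan] * (4 - len(f.coefficients))
        prof_rows.append(
            {
                "fa": fa,
                "degree": f.degree,
                "b0": coefs[0],
                "b1": coefs[1],
                "b2": coefs[2],
                "b3": coefs[3],
                "top_term_p": f.top_term_p,
                "adjusted_r2": f.adjusted_r2,
                "peak_dose": p.peak_dose,
                "peak_fold": p.peak_fold,
                "significant": p.significant,
            }
        )
    outputs["profiles"] = _write(pd.DataFrame(prof_rows), out_dir / "profiles.csv")
    logger.info("fitted %d dose-response profiles", len(profiles))

    # --- mixtures present in the data ---------------------------------
    designs: dict[str, MixtureDesign] = {}
    for comp_str in norm["components"].unique():
        comps = parse_components(comp_str)
        if len(comps) >= 2:
            d = MixtureDesign(comps)
            designs[d.label] = d
    design_list = sorted(designs.values(), key=lambda m: (m.k, m.label))
    measured = {
        m.label: float(norm.loc[norm["treatment"] == m.label, "fold_change"].mean())
        for m in design_list
    }

    synergy_rows, slope_rows = [], []
    scorable = [
        m for m in design_list if all(fa in profiles for fa in m.fas)
    ]
    if scorable:
        results = synergy_table(scorable, profiles, measured)
        synergy_rows = synergy_frame(results)
        for k in sorted({m.k for m in scorable}):
            sub = [r for r, m in zip(results, scorable) if m.k == k]
            if len(sub) >= 2:
                for model in ("weighted", "additive"):
                    exp = [getattr(r, f"expected_{model}") for r in sub]
                    act = [r.measured for r in sub]
                    fit = fit_origin_slope(exp, act)
                    slope_rows.append(
                        {
                            "k": k,
                            "model": model,
                            "slope": fit.slope,
                            "n_points": fit.n_points,
                        }
                    )
    outputs["synergy"] = _write(
        pd.DataFrame(synergy_rows), out_dir / "synergy.csv"
    )
    outputs["slopes"] = _write(pd.DataFrame(slope_rows), out_dir / "slopes.csv")

    # --- group comparisons on the mixtures plate ----------------------
    comp_rows, letter_rows, grid = [], [], pd.DataFrame()
    mix_plates = {
        norm.loc[norm["treatment"] == m.label, "plate_id"].iloc[0]
        for m in design_list
        if (norm["treatment"] == m.label).any()
    }
    if mix_plates:
        plate_df = norm[norm["plate_id"].isin(mix_plates)]
        groups = {
            t: g["fold_change"].to_numpy()
            for t, g in plate_df.groupby("treatment", sort=True)
            if t != normalize.VEHICLE_LABEL and len(g) >= 2
        }
        if len(groups) >= 2:
            comps = pairwise_compare(groups, alpha=config.alpha)
            comp_rows = [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "estimate": c.estimate,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in comps
            ]
            letters = letter_display(comps)
            letter_rows = [
                {"treatment": t, "letters": "".join(ls)}
                for t, ls in sorted(letters.items())
            ]
        # per-FA grids need each component measured singly on the plate
        component_labels = {}
        for t in plate_df["treatment"].unique():
            comps_t = parse_components(
                plate_df.loc[plate_df["treatment"] == t, "components"].iloc[0]
            )
            if len(comps_t) == 1:
                component_labels[comps_t[0][0]] = t
        relevant = {
            fa: lb
            for fa, lb in component_labels.items()
            if any(fa in m.fas for m in design_list)
        }
        if relevant:
            grid = mixture_vs_component_grid(
                design_list, relevant, groups, alpha=config.alpha
            )
    outputs["comparisons"] = _write(
        pd.DataFrame(comp_rows), out_dir / "comparisons.csv"
    )
    outputs["letters"] = _write(pd.DataFrame(letter_rows), out_dir / "letters.csv")
    grid_out = grid.map(lambda v: "" if v is pd.NA else int(v)) if not grid.empty else grid
    grid_out.to_csv(out_dir / "mixture_vs_component_grid.csv")
    outputs["grid"] = out_dir / "mixture_vs_component_grid.csv"

    # --- summary -------------------------------------------------------
    n_syn = (
        int(synergy_rows["synergistic"].sum()) if len(synergy_rows) else 0
    )
    summary = [
        f"wells read: {len(wells)}",
        f"wells normalized: {len(norm)} (excluded: {len(wells) - len(norm)})",
        f"viability-flagged wells: {int(norm['viability_flag'].sum())}",
        f"dose-response profiles: {len(profiles)}",
        f"mixtures scored: {len(scorable)} of {len(design_list)}",
        f"synergistic mixtures (measured > additive expectation): {n_syn}",
    ]
    for row in slope_rows:
        summary.append(
            f"origin slope, k={row['k']} {row['model']} model: {row['slope']:.3f}"
        )
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    outputs["summary"] = out_dir / "summary.txt"
    logger.info("analysis complete: %s", ", ".join(str(p) for p in outputs.values()))
    return outputs
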