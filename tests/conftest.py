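import numpy as np
import pandas as pd
import pytest

from pparmix.simulate import PlateDesign, TruthModel, default_truth, simulate_plate


@pytest.fixture
def noise_free_truth() -> TruthModel:
    """Six-FA truth with noise off: downstream values are closed-form."""
    return default_truth(noise_cv=0.0)


@pytest.fixture
def quad_truth() -> TruthModel:
    """Single quadratic activator peaking at 250 µM (3.5-fold)."""
    return TruthModel(fa_params={"C16:0": (1.0, 0.02, -4e-5)}, noise_cv=0.0)


@pytest.fixture
def small_series_design() -> PlateDesign:
    return PlateDesign(fa_series={"C16:0": 500.0}, n_dose_points=10)


def make_wells(rows: list[dict]) -> pd.DataFrame:
    """Hand-built well table with defaults filled in."""
    defaults = {
        "plate_id": "P1",
        "well_id": "",
        "treatment": "vehicle",
        "components": "",
        "replicate": 1,
        "firefly": 100.0,
        "renilla": 100.0,
    }
    out = []
    for i, row in enumerate(rows, 1):
        r = dict(defaults, **row)
        r["well_id"] = r["well_id"] or f"W{i:03d}"
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def normalized_quad(quad_truth, small_series_design):
    """Noise-free normalized plate for the quadratic activator."""
    from pparmix.normalize import fold_changes

    wells = simulate_plate(small_series_design, quad_truth, seed=1)
    return fold_changes(wells)
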