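import numpy as np
import pandas as pd
import pytest

from pheretima_risk.datamodel import MEASURED_METALS, ConsumptionRecords
from pheretima_risk.synthetic import default_consumption_models, default_metal_models

#: Published per-metal mean concentrations, mg/kg (calibration anchors).
METAL_MEANS = {
    "As": 13.51, "Cd": 2.52, "Cr": 31.85, "Cu": 17.23,
    "Hg": 1.58, "Mn": 83.45, "Ni": 8.05, "Pb": 9.33,
}


@pytest.fixture(scope="session")
def metal_models():
    return default_metal_models()


@pytest.fixture(scope="session")
def consumption_models():
    return default_consumption_models()


@pytest.fixture()
def small_records():
    frame = pd.DataFrame(
        {
            "annual_consumption": [100.0, 200.0, 300.0, 400.0, 500.0],
            "exposure_frequency": [10.0, 20.0, 30.0, 40.0, 50.0],
            "daily_intake": [8.0, 9.0, 10.0, 11.0, 12.0],
        }
    )
    return ConsumptionRecords(frame=frame)


@pytest.fixture()
def concentration_csv(tmp_path):
    """Three fully-detected samples written as a CSV fixture."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(3):
        row = {"sample_id": f"S{i + 1}", "origin": "Anhui"}
        for m in MEASURED_METALS:
            row[m] = round(float(rng.uniform(0.5, 40.0)), 4)
        rows.append(row)
    path = tmp_path / "conc.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
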