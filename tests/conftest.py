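import numpy as np
import pandas as pd
import pytest

from cqmark import SimulationConfig, AssaySpec, simulate_cohort


def make_cq_frame(rows):
    """rows: (sample, assay, plate, replicate, cq) tuples; cq None = undetermined."""
    return pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "plate_id", "replicate", "cq"]
    ).astype({"cq": float})


@pytest.fixture
def toy_assays():
    from cqmark.plate_model import validate_assays

    return validate_assays(
        pd.DataFrame(
            {
                "assay_id": ["A", "B", "C", "D", "mir23a", "mir451a", "cal"],
                "roles": [
                    "target",
                    "target",
                    "target",
                    "target",
                    "target;hemolysis_stable",
                    "target;hemolysis_erythrocyte",
                    "interplate_calibrator",
                ],
            }
        )
    )


@pytest.fixture
def noiseless_config():
    """All SDs zero, no plate offsets: fully deterministic Cq values."""
    return SimulationConfig(
        seed=0,
        n_control=4,
        n_case=4,
        assays=[
            AssaySpec("T1", 30.0, group_effect=1.0),
            AssaySpec("T2", 28.0),
            AssaySpec("R1", 25.0, roles=frozenset({"target", "reference_candidate"})),
            AssaySpec("R2", 26.0, roles=frozenset({"target", "reference_candidate"})),
            AssaySpec("H1", 24.0, roles=frozenset({"target", "hemolysis_stable"})),
            AssaySpec("H2", 19.0, erythrocyte_coeff=2.0,
                      roles=frozenset({"target", "hemolysis_erythrocyte"})),
            AssaySpec("CAL", 19.0, roles=frozenset({"interplate_calibrator"})),
        ],
        sigma_tech=0.0,
        sigma_sample=0.0,
        plate_offsets=[0.0, 0.0],
        hemolysis_scale=0.0,
        absorbance_coeffs=(0.05, 0.15, 0.0),
    )


@pytest.fixture
def default_cohort():
    """One default-parameter cohort, session-cached per test module."""
    return simulate_cohort(SimulationConfig(seed=11))
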