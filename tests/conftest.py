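import numpy as np
import pandas as pd
import pytest

from sbrt_tcp import CohortSpec, generate_cohort, load_params, simulate_outcomes


@pytest.fixture(scope="session")
def params():
    """Shipped default model-parameter config."""
    return load_params()


@pytest.fixture(scope="session")
def cohort(params):
    """A small complete synthetic cohort with both outcome horizons filled."""
    spec = CohortSpec(n_patients=120, seed=42)
    coh = generate_cohort(spec)
    return simulate_outcomes(coh, "klement", params, horizons=(2, 3), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_patients(n, rng, bed_lo=60.0, bed_hi=160.0):
    """Random patient table spanning the clinically relevant covariate range."""
    bed_dmax = rng.uniform(bed_lo, bed_hi, n)
    bed_pd = bed_dmax * rng.uniform(0.75, 1.0, n)
    return pd.DataFrame(
        {
            "patient_id": [f"R{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(40, 90, n),
            "clinical_stage": rng.choice(["I", "II", "III", "IV"], n),
            "primary_or_metastatic": rng.choice(["primary", "metastatic"], n),
            "location": rng.choice(["peripheral", "central"], n),
            "diameter_cm": rng.uniform(0.8, 8.0, n),
            "n_fractions": rng.integers(1, 11, n),
            "dose_per_fraction_gy": rng.uniform(6, 26, n),
            "bed_pd_gy": bed_pd,
            "bed_dmax_gy": bed_dmax,
            "treatment_duration_days": rng.integers(1, 22, n),
            "chemo_prior": rng.integers(0, 2, n),
            "lc_2yr": pd.array([pd.NA] * n, dtype="Int64"),
            "lc_3yr": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
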