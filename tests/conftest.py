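import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import seropanel as sp

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phase2_cohort():
    """Broad-array synthetic cohort (126 AAV + 168 HC × 151 antigens)."""
    config = sp.phase_config("phase2", seed=1)
    matrix, samples, antigens, truth = sp.generate_cohort(config)
    return {
        "config": config,
        "matrix": matrix,
        "samples": samples,
        "metadata": sp.samples_to_frame(samples),
        "antigens": antigens,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def phase3_large_effect():
    """Kinesin-array-shaped cohort with a strongly separated planted effect."""
    config = dataclasses.replace(
        sp.phase_config("phase3", seed=1),
        positive_effect_log_mean=float(np.log(150)),
        positive_effect_log_sd=0.3,
    )
    matrix, samples, antigens, truth = sp.generate_cohort(config)
    calls = sp.call_reactivity(matrix, sp.CutoffSpec(n_factor=20.0))
    return {
        "config": config,
        "matrix": matrix,
        "metadata": sp.samples_to_frame(samples),
        "truth": truth,
        "calls": calls,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_samples=20, n_antigens=30) -> sp.IntensityMatrix:
    values = np.exp(rng.normal(6.0, 0.6, size=(n_samples, n_antigens)))
    return sp.IntensityMatrix(
        pd.DataFrame(
            values,
            index=[f"S{i:03d}" for i in range(n_samples)],
            columns=[f"A{j:03d}" for j in range(n_antigens)],
        )
    )
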