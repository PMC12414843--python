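import numpy as np
import pytest

from tmtdea import (
    assign_batches,
    generate_cohort,
    generate_proteome,
    quantify_batches,
)


@pytest.fixture(scope="session")
def cohort60():
    """The study design: 60 samples, exact subtype counts, 12 six-plex batches."""
    samples = generate_cohort(60, exact_counts=True, seed=7)
    design, placed = assign_batches(samples, plex=6, seed=7)
    return design, placed


@pytest.fixture(scope="session")
def small_study(cohort60):
    """300-protein simulated study with batch effects and noise."""
    design, cohort = cohort60
    tables, truth = generate_proteome(
        design, cohort, n_proteins=300, n_de=20, batch_sd=0.5, sigma=0.5, seed=11
    )
    return design, cohort, tables, truth


@pytest.fixture(scope="session")
def small_matrix(small_study):
    """Complete ratio matrix of the small study (no missingness injected)."""
    _, cohort, tables, _ = small_study
    return quantify_batches(tables, cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values):
    """Proteins x samples RatioMatrix from an array, batches of five samples."""
    import pandas as pd

    values = np.asarray(values, float)
    samples = [f"S{i}" for i in range(values.shape[1])]
    data = pd.DataFrame(values, columns=samples,
                        index=[f"P{i}" for i in range(values.shape[0])])
    batches = pd.Series({s: 1 + i // 5 for i, s in enumerate(samples)})
    from tmtdea.quant import RatioMatrix

    return RatioMatrix(data=data, batches=batches)
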