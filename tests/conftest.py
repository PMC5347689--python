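import numpy as np
import pandas as pd
import pytest

from e2fscore import (
    CohortSpec,
    ExpressionMatrix,
    PairedTissueSpec,
    concordance_screen_targets,
    generate_cohort,
    generate_paired_set,
)


@pytest.fixture(scope="session")
def small_cohort():
    """50-patient FF cohort with a moderate latent hazard effect."""
    return generate_cohort(CohortSpec(n_patients=50, latent_hazard_coef=0.6, seed=11))


@pytest.fixture(scope="session")
def screen_paired_set():
    """106-gene paired FF/FFPE set built for the concordance screen:
    74 well-concordant genes and 32 poorly concordant ones."""
    return generate_paired_set(
        PairedTissueSpec(
            n_patients=36,
            n_genes=106,
            target_correlations=concordance_screen_targets(106, 32),
            seed=20,
        )
    )


@pytest.fixture
def tiny_matrix():
    """4-gene, 5-sample log-scale matrix with non-trivial structure."""
    rng = np.random.default_rng(3)
    vals = rng.normal(8, 2, (4, 5))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"G{i}" for i in range(4)], columns=[f"S{j}" for j in range(5)])
    )


def make_clinical(times, events, sample_prefix="P", **extra):
    """Minimal clinical table from parallel time/event arrays."""
    n = len(times)
    base = {
        "sample_id": [f"{sample_prefix}{i}" for i in range(n)],
        "cohort": "TEST",
        "platform": "FF",
        "stage": "I",
        "arm": "none",
        "os_months": list(times),
        "os_event": list(events),
        "pfs_months": list(times),
        "pfs_event": list(events),
    }
    base.update(extra)
    return pd.DataFrame(base)
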