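import numpy as np
import pytest

from rootvol import load_cohort


@pytest.fixture(scope="session")
def cohort():
    """The bundled 27-molar reference cohort."""
    return load_cohort()


@pytest.fixture(scope="session")
def records(cohort):
    return cohort.to_case_records()


@pytest.fixture(scope="session")
def applied_constant(cohort):
    """The single constant behind the cohort's published per-case volume column."""
    q = cohort.df["applied_volume_pr_mm3"].to_numpy() / cohort.df[
        "pr_surface_mm2"
    ].to_numpy()
    return float(np.median(q))
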