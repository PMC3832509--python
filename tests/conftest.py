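import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tnbcprofiler as tp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-sample, 400-probe cohort with detection data and slides of 8."""
    return tp.simulate_cohort(n_samples=24, n_probes=400, slide_size=8, seed=11)


@pytest.fixture()
def annotation_fixture():
    """Five samples: one Hispanic, one metastasis, one duplicated patient."""
    return tp.validate_annotation(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4", "s5"],
        "patient_id": ["p1", "p2", "p3", "p4", "p1"],
        "ethnicity": ["AA", "EA", "Hispanic", "AA", "AA"],
        "stage": ["1", "2", "3", "unknown", "2"],
        "nodal": ["pos", "neg", "neg", "pos", "unknown"],
        "age": [50, 61, 47, 55, 50],
        "tissue_site": ["primary", "primary", "primary", "other", "primary"],
    }))


def make_matrix(values, probes=None, samples=None, genes=None, **kw):
    """Shorthand to build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=probes, columns=samples)
    symbols = None
    if genes is not None:
        symbols = pd.Series(genes, index=probes, dtype="string")
    return tp.ExpressionMatrix(values=frame, gene_symbols=symbols, **kw)
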