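import numpy as np
import pytest

from metaboqc.core_matrix import FeatureRecord, PeakMatrix, SampleRecord, SampleType


def build_matrix(rows, feature_ids=None, corrected=False, dilutions=None):
    """Compact matrix builder for tests.

    ``rows`` is a list of ``(sample_type, values)`` or
    ``(sample_type, values, batch)`` tuples; injection order is the row
    position (1-based).  ``dilutions`` maps row index -> dilution factor.
    """
    samples = []
    values = []
    for i, row in enumerate(rows):
        stype, vals, *rest = row
        batch = rest[0] if rest else 1
        dil = (dilutions or {}).get(i)
        samples.append(
            SampleRecord(
                sample_id=f"s{i + 1:03d}",
                sample_type=SampleType(stype),
                injection_order=i + 1,
                batch=batch,
                dilution_factor=dil,
            )
        )
        values.append(vals)
    n_feat = len(values[0])
    fids = feature_ids or [f"F{j + 1}" for j in range(n_feat)]
    features = [FeatureRecord(feature_id=f) for f in fids]
    return PeakMatrix(samples, features, np.array(values, dtype=float), corrected=corrected)


@pytest.fixture
def matrix_builder():
    return build_matrix


@pytest.fixture(scope="session")
def drifted_study():
    """Single-batch study with mixed drift shapes and 12 pooled QCs."""
    from metaboqc.simulate import simulate_study

    return simulate_study(
        45,
        30,
        1,
        drift_spec={"linear": 0.3, "monotone_nonlinear": 0.3, "nonmonotone_smooth": 0.4},
        sigma_technical=0.05,
        seed=2024,
    )


@pytest.fixture(scope="session")
def quiet_study():
    """Drift-free low-noise study used for identity-regime checks."""
    from metaboqc.simulate import simulate_study

    return simulate_study(30, 20, 1, drift_spec="none", sigma_technical=0.02, seed=99)
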