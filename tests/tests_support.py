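"""Small programmatic fixtures shared across test modules."""

import numpy as np

from metaboqc.core_matrix import FeatureRecord, PeakMatrix, SampleRecord, SampleType


def tiny_matrix(feature_ids):
    """Minimal valid matrix (one QC + one biological row) used when only
    the feature axis matters."""
    samples = [
        SampleRecord("qc1", SampleType.POOLED_QC, 1, 1),
        SampleRecord("bio1", SampleType.BIOLOGICAL, 2, 1),
    ]
    features = [FeatureRecord(feature_id=f) for f in feature_ids]
    values = np.ones((2, len(feature_ids)))
    return PeakMatrix(samples, features, values)


def blank_fixture(contributions_pct, bio_median=1000.0):
    """Matrix whose per-feature blank contribution (% of the biological
    median) equals ``contributions_pct`` exactly: three biological rows
    share the median and one process blank carries the scaled signal."""
    n = len(contributions_pct)
    blank_row = [bio_median * c / 100.0 for c in contributions_pct]
    rows = [
        ("process_blank", blank_row),
        ("biological", [bio_median * 0.9] * n),
        ("biological", [bio_median] * n),
        ("biological", [bio_median * 1.1] * n),
    ]
    samples = []
    values = []
    for i, (stype, vals) in enumerate(rows):
        samples.append(
            SampleRecord(f"s{i + 1}", SampleType(stype), i + 1, 1)
        )
        values.append(vals)
    features = [FeatureRecord(feature_id=f"F{j + 1}") for j in range(n)]
    return PeakMatrix(samples, features, np.array(values))
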