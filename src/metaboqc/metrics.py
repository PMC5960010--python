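"""Per-feature precision metrics and threshold-based data cleaning.

The four per-feature statistics computed from pooled-QC injections:

* ``RSD  = 100 * s_qc / mean_qc`` — relative standard deviation,
  sample (n-1) SD;
* ``RSD* = 100 * 1.4826 * MAD_qc / median_qc`` — robust alternative
  (1.4826 = 1/Phi^-1(0.75) rescales the MAD to a Gaussian SD);
* ``D-ratio  = 100 * s_qc / s_sample`` — QC dispersion relative to the
  biological-sample dispersion (0% = perfect measurement, 100% = pure
  technical noise); robust variant uses raw MADs, where the 1.4826
  factor cancels;
* detection rate — percentage of expected pooled-QC injections in
  which the feature was detected (present and > 0).

Cleaning retains a feature only if detection rate > 70%, RSD < 20%
(strict profile; 30% lenient) and D-ratio < 50%, all strict
inequalities; a statistic that cannot be computed fails its criterion.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_matrix import PeakMatrix, SampleType

__all__ = [
    "MAD_TO_SD",
    "QCFeatureStats",
    "CleaningCriteria",
    "CRITERIA_PROFILES",
    "rsd",
    "robust_rsd",
    "d_ratio",
    "detection_rate",
    "compute_feature_stats",
    "clean",
    "dilution_linearity",
]

#: Consistency factor rescaling the MAD to the SD of a Gaussian:
#: 1 / Phi^-1(3/4) = 1.4826 (to 4 d.p.).
MAD_TO_SD: float = 1.0 / sps.norm.ppf(0.75)


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) over pooled-QC measurements.

    Missing values are excluded.  Returns ``NaN`` when fewer than two
    values remain or the mean is zero (undefined, not zero).
    """
    v = _finite(values)
    if v.size < 2:
        return math.nan
    mean = v.mean()
    if mean == 0:
        return math.nan
    return 100.0 * v.std(ddof=1) / mean


def robust_rsd(values: Sequence[float]) -> float:
    """Robust RSD (%): 100 * 1.4826 * MAD / median."""
    v = _finite(values)
    if v.size < 2:
        return math.nan
    med = np.median(v)
    if med == 0:
        return math.nan
    mad = np.median(np.abs(v - med))
    return 100.0 * MAD_TO_SD * mad / med


def d_ratio(
    qc_values: Sequence[float],
    sample_values: Sequence[float],
    robust: bool = False,
) -> float:
    """Dispersion ratio (%): QC spread over biological-sample spread.

    ``sample_values`` must come from biological samples only.  The
    robust variant divides raw MADs (the Gaussian consistency factor
    cancels).  Undefined (``NaN``) when either vector has fewer than two
    values or the biological dispersion is zero.
    """
    q = _finite(qc_values)
    s = _finite(sample_values)
    if q.size < 2 or s.size < 2:
        return math.nan
    if robust:
        num = np.median(np.abs(q - np.median(q)))
        den = np.median(np.abs(s - np.median(s)))
    else:
        num = q.std(ddof=1)
        den = s.std(ddof=1)
    if den == 0:
        return math.nan
    return 100.0 * num / den


def detection_rate(
    qc_values: Sequence[float], *, noise_floor: float = 0.0
) -> float:
    """Percentage of expected QC injections where the feature was
    detected (non-missing and above ``noise_floor``, default 0)."""
    v = np.asarray(qc_values, dtype=float)
    if v.size == 0:
        raise ValueError("at least one expected QC injection is required")
    detected = np.isfinite(v) & (v > noise_floor)
    return 100.0 * detected.sum() / v.size


@dataclasses.dataclass
class QCFeatureStats:
    """Per-feature QC statistics; undefined values are ``NaN``."""

    feature_id: str
    mean_qc: float = math.nan
    sd_qc: float = math.nan
    median_qc: float = math.nan
    mad_qc: float = math.nan
    rsd: float = math.nan
    robust_rsd: float = math.nan
    sd_sample: float = math.nan
    mad_sample: float = math.nan
    d_ratio: float = math.nan
    robust_d_ratio: float = math.nan
    detection_rate: float = 0.0
    n_qc_detected: int = 0
    n_qc_expected: int = 0
    flags: set[str] = dataclasses.field(default_factory=set)


def stats_to_frame(stats: Sequence[QCFeatureStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        d = dataclasses.asdict(s)
        d["flags"] = ";".join(sorted(s.flags))
        rows.append(d)
    return pd.DataFrame(rows).set_index("feature_id")


def compute_feature_stats(
    matrix: PeakMatrix,
    transform: Literal["none", "log10"] = "none",
    *,
    noise_floor: float = 0.0,
    log_offset: float = 1.0,
) -> list[QCFeatureStats]:
    """Compute :class:`QCFeatureStats` for every feature.

    Pooled-QC rows feed the numerators (RSD, QC dispersion); biological
    rows feed the D-ratio denominator.  Conditioning rows must already
    be removed.  Under ``transform="log10"`` all statistics are computed
    on ``log10(x + log_offset)`` and flagged accordingly (RSDs on the
    log scale are not percentages of raw signal).
    """
    if matrix.type_mask({SampleType.CONDITIONING_QC}).any():
        raise ValueError("remove conditioning injections before computing QC stats")
    qc_mask = matrix.type_mask({SampleType.POOLED_QC})
    bio_mask = matrix.type_mask({SampleType.BIOLOGICAL})
    if qc_mask.sum() < 2:
        raise ValueError(
            "at least two pooled-QC injections are required: without pooled "
            "QCs the quality of a measurement cannot be calculated"
        )
    if bio_mask.sum() < 2:
        raise ValueError("at least two biological samples are required")

    data = matrix.intensities
    if transform == "log10":
        with np.errstate(invalid="ignore"):
            data = np.log10(data + log_offset)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    out: list[QCFeatureStats] = []
    for j, f in enumerate(matrix.features):
        raw_qc = matrix.intensities[qc_mask, j]
        qc = _finite(data[qc_mask, j])
        bio = _finite(data[bio_mask, j])
        s = QCFeatureStats(feature_id=f.feature_id)
        s.n_qc_expected = int(qc_mask.sum())
        s.detection_rate = detection_rate(raw_qc, noise_floor=noise_floor)
        s.n_qc_detected = int(round(s.detection_rate / 100 * s.n_qc_expected))
        if transform == "log10":
            s.flags.add("log10_scale")
        if qc.size >= 2:
            s.mean_qc = float(qc.mean())
            s.sd_qc = float(qc.std(ddof=1))
            s.median_qc = float(np.median(qc))
            s.mad_qc = float(np.median(np.abs(qc - np.median(qc))))
            s.rsd = rsd(qc)
            s.robust_rsd = robust_rsd(qc)
            if math.isnan(s.rsd):
                s.flags.add("rsd_undefined")
        else:
            s.flags.add("insufficient_qc")
        if bio.size >= 2:
            s.sd_sample = float(bio.std(ddof=1))
            s.mad_sample = float(np.median(np.abs(bio - np.median(bio))))
        if qc.size >= 2 and bio.size >= 2:
            s.d_ratio = d_ratio(qc, bio, robust=False)
            s.robust_d_ratio = d_ratio(qc, bio, robust=True)
            if math.isnan(s.d_ratio):
                s.flags.add("no_biological_variance")
        out.append(s)
    return out


@dataclasses.dataclass(frozen=True)
class CleaningCriteria:
    """Thresholds for feature retention, all applied strictly:
    retain iff detection_rate > min_detection_rate AND rsd < max_rsd
    AND d_ratio < max_d_ratio."""

    min_detection_rate: float = 70.0
    max_rsd: float = 20.0
    max_d_ratio: float = 50.0
    use_robust: bool = False

    def __post_init__(self) -> None:
        for name in ("min_detection_rate", "max_rsd", "max_d_ratio"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100], got {v}")


CRITERIA_PROFILES: dict[str, CleaningCriteria] = {
    "strict": CleaningCriteria(max_rsd=20.0),
    "lenient": CleaningCriteria(max_rsd=30.0),
}


def clean(
    matrix: PeakMatrix,
    stats: Sequence[QCFeatureStats],
    criteria: CleaningCriteria | str = "strict",
) -> tuple[PeakMatrix, pd.DataFrame]:
    """Remove features failing the acceptance criteria.

    Returns the cleaned matrix and a per-feature report with the
    criterion values, pass/fail per criterion, and the thresholds used
    (the criteria applied in a study should always be reported).  An
    undefined statistic fails its criterion.
    """
    if isinstance(criteria, str):
        criteria = CRITERIA_PROFILES[criteria]
    by_id = {s.feature_id: s for s in stats}
    missing = [f.feature_id for f in matrix.features if f.feature_id not in by_id]
    if missing:
        raise ValueError(f"stats missing for features: {missing[:5]}")

    rows = []
    keep: list[str] = []
    for f in matrix.features:
        s = by_id[f.feature_id]
        use_rsd = s.robust_rsd if criteria.use_robust else s.rsd
        use_d = s.robust_d_ratio if criteria.use_robust else s.d_ratio
        pass_dr = s.detection_rate > criteria.min_detection_rate
        pass_rsd = (not math.isnan(use_rsd)) and use_rsd < criteria.max_rsd
        pass_d = (not math.isnan(use_d)) and use_d < criteria.max_d_ratio
        retained = pass_dr and pass_rsd and pass_d
        if retained:
            keep.append(f.feature_id)
        rows.append(
            {
                "feature_id": f.feature_id,
                "detection_rate": s.detection_rate,
                "rsd": use_rsd,
                "d_ratio": use_d,
                "pass_detection_rate": pass_dr,
                "pass_rsd": pass_rsd,
                "pass_d_ratio": pass_d,
                "retained": retained,
            }
        )
    report = pd.DataFrame(rows).set_index("feature_id")
    report.attrs["criteria"] = dataclasses.asdict(criteria)
    return matrix.select_features(keep), report


def dilution_linearity(
    matrix: PeakMatrix,
    method: Literal["pearson", "spearman"] = "pearson",
    min_correlation: float = 0.0,
) -> pd.DataFrame:
    """Correlate response with dilution factor across dilution-QC rows.

    Features whose correlation is ``<= min_correlation`` (or undefined)
    are flagged ``nonlinear_dilution`` in the matrix's feature metadata;
    they are flagged rather than removed, because filtering on dilution
    behaviour biases the retained features toward linear responders.
    """
    mask = matrix.type_mask({SampleType.DILUTION_QC})
    factors = np.array(
        [s.dilution_factor for s in matrix.samples if s.sample_type is SampleType.DILUTION_QC],
        dtype=float,
    )
    if len(np.unique(factors)) < 3:
        raise ValueError("need >= 3 dilution-QC rows with distinct dilution factors")
    corr_fn = sps.pearsonr if method == "pearson" else sps.spearmanr

    rows = []
    for j, f in enumerate(matrix.features):
        y = matrix.intensities[mask, j]
        ok = np.isfinite(y)
        flagged = False
        r = math.nan
        if ok.sum() >= 3 and np.ptp(y[ok]) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(corr_fn(factors[ok], y[ok]).statistic)
        if math.isnan(r) or r <= min_correlation:
            flagged = True
            f.flags.add("nonlinear_dilution")
        rows.append({"feature_id": f.feature_id, "correlation": r, "flagged": flagged})
    return pd.DataFrame(rows).set_index("feature_id")
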