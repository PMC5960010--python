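"""System-suitability assessment and per-sample internal-standard monitoring.

Before any biological sample is injected, a small mixture of authentic
standards is analysed and compared against predefined acceptance
criteria: mass error within 5 ppm of theoretical, retention-time error
below 2% of expected, peak area within 10% of expected, and a
symmetrical peak with no splitting.  If any analyte fails, corrective
maintenance is indicated before the run proceeds.  No community-agreed
criteria exist, so every tolerance is configurable per standard.

Separately, process internal standards spiked into every test sample
allow per-injection monitoring during the run; a breach of the area
tolerance from some injection onward warns of systematic failure.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_matrix import PeakMatrix

__all__ = [
    "ReferenceStandard",
    "ObservedStandard",
    "AnalyteResult",
    "SuitabilityReport",
    "ppm_error",
    "assess_suitability",
    "read_standards_table",
    "monitor_internal_standards",
]


@dataclasses.dataclass(frozen=True)
class ReferenceStandard:
    name: str
    theoretical_mz: float
    expected_rt: float
    expected_area: float
    ppm_max: float = 5.0
    rt_error_max: float = 2.0      # percent of expected RT
    area_error_max: float = 10.0   # percent of expected area
    tailing_min: float = 0.8
    tailing_max: float = 1.5

    def __post_init__(self) -> None:
        if min(self.ppm_max, self.rt_error_max, self.area_error_max) <= 0:
            raise ValueError(f"{self.name}: all tolerances must be > 0")


@dataclasses.dataclass(frozen=True)
class ObservedStandard:
    name: str
    observed_mz: float
    observed_rt: float
    observed_area: float
    peak_split: bool = False
    tailing_factor: float | None = None


@dataclasses.dataclass
class AnalyteResult:
    name: str
    observed: bool
    ppm_error: float = np.nan
    rt_error_pct: float = np.nan
    area_error_pct: float = np.nan
    pass_mz: bool = False
    pass_rt: bool = False
    pass_area: bool = False
    pass_shape: bool = False

    @property
    def passed(self) -> bool:
        return self.observed and self.pass_mz and self.pass_rt and self.pass_area and self.pass_shape


@dataclasses.dataclass
class SuitabilityReport:
    analytes: list[AnalyteResult]

    @property
    def passed(self) -> bool:
        return all(a.passed for a in self.analytes)

    @property
    def recommendation(self) -> str:
        if self.passed:
            return "system suitable: proceed with sample analysis"
        failed = [a.name for a in self.analytes if not a.passed]
        return (
            f"system NOT suitable (failed: {', '.join(failed)}); perform "
            f"corrective maintenance of the analytical platform and reanalyse "
            f"the suitability solution"
        )

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "recommendation": self.recommendation,
            "analytes": [dataclasses.asdict(a) | {"passed": a.passed} for a in self.analytes],
        }

    def to_text(self) -> str:
        lines = [f"System suitability: {'PASS' if self.passed else 'FAIL'}"]
        for a in self.analytes:
            if not a.observed:
                lines.append(f"  {a.name}: NOT OBSERVED -> fail")
                continue
            lines.append(
                f"  {a.name}: {'pass' if a.passed else 'FAIL'} "
                f"(mz {a.ppm_error:.2f} ppm, rt {a.rt_error_pct:.2f}%, "
                f"area {a.area_error_pct:+.1f}%, shape "
                f"{'ok' if a.pass_shape else 'bad'})"
            )
        lines.append(self.recommendation)
        return "\n".join(lines)


def ppm_error(theoretical_mz: float, observed_mz: float) -> float:
    """Absolute mass error in parts per million."""
    if theoretical_mz <= 0 or observed_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * abs(observed_mz - theoretical_mz) / theoretical_mz


def assess_suitability(
    standards: Sequence[ReferenceStandard],
    observed: Sequence[ObservedStandard],
) -> SuitabilityReport:
    """Compare observed suitability analytes to their acceptance criteria.

    A standard with no matching observation fails; the overall run
    passes only if every analyte passes every criterion.
    """
    names = [o.name for o in observed]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate observation names: {dup}")
    by_name = {o.name: o for o in observed}

    results: list[AnalyteResult] = []
    for std in standards:
        obs = by_name.get(std.name)
        if obs is None:
            results.append(AnalyteResult(name=std.name, observed=False))
            continue
        ppm = ppm_error(std.theoretical_mz, obs.observed_mz)
        rt_err = 100.0 * abs(obs.observed_rt - std.expected_rt) / std.expected_rt
        area_err = 100.0 * (obs.observed_area - std.expected_area) / std.expected_area
        shape_ok = not obs.peak_split
        if obs.tailing_factor is not None:
            shape_ok = shape_ok and (std.tailing_min <= obs.tailing_factor <= std.tailing_max)
        results.append(
            AnalyteResult(
                name=std.name,
                observed=True,
                ppm_error=ppm,
                rt_error_pct=rt_err,
                area_error_pct=area_err,
                pass_mz=ppm <= std.ppm_max,
                pass_rt=rt_err < std.rt_error_max,
                pass_area=abs(area_err) <= std.area_error_max,
                pass_shape=shape_ok,
            )
        )
    return SuitabilityReport(analytes=results)


def read_standards_table(path: str | Path) -> list[ReferenceStandard]:
    """Read a TSV of reference standards with optional per-row tolerance
    overrides (columns ppm_max, rt_error_max, area_error_max)."""
    tab = pd.read_csv(path, sep="\t")
    out = []
    for _, row in tab.iterrows():
        kwargs = {}
        for col in ("ppm_max", "rt_error_max", "area_error_max", "tailing_min", "tailing_max"):
            if col in tab.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        out.append(
            ReferenceStandard(
                name=str(row["name"]),
                theoretical_mz=float(row["theoretical_mz"]),
                expected_rt=float(row["expected_rt"]),
                expected_area=float(row["expected_area"]),
                **kwargs,
            )
        )
    return out


def monitor_internal_standards(
    matrix: PeakMatrix,
    standard_features: Sequence[str],
    expected: dict[str, float] | None = None,
    tolerance: float = 20.0,
) -> pd.DataFrame:
    """Track per-injection deviation of process internal standards.

    For every injection and every internal-standard feature, reports the
    deviation (%) of the observed area from its expected value (default:
    the feature's own median across the run) and flags breaches outside
    ``tolerance``.  A run of flags from some injection onward warns of
    systematic failure mid-run.
    """
    for fid in standard_features:
        matrix.feature_index(fid)  # raises KeyError for unknown ids
    rows = []
    for fid in standard_features:
        y = matrix.feature_values(fid)
        exp = (expected or {}).get(fid)
        if exp is None:
            exp = float(np.nanmedian(y))
        for s, value in zip(matrix.samples, y):
            dev = np.nan if not np.isfinite(value) else 100.0 * (value - exp) / exp
            rows.append(
                {
                    "injection_order": s.injection_order,
                    "sample_id": s.sample_id,
                    "sample_type": s.sample_type.value,
                    "feature_id": fid,
                    "expected": exp,
                    "observed": value,
                    "deviation_pct": dev,
                    "breach": bool(np.isfinite(dev) and abs(dev) > tolerance)
                    or not np.isfinite(value),
                }
            )
    return pd.DataFrame(rows)
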