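"""Whole-matrix PCA diagnostics and the summary QC report.

A quick visual check of data quality: project the cleaned matrix onto
its first two principal components and compare how tightly the pooled
QCs cluster relative to the biological cloud.  Tight QC clustering
(regardless of where the cluster sits — a constant offset reflects
pipetting, not dispersion) indicates low technical variance.  The
``qc_dispersion_ratio`` quantifies that visual impression as the ratio
of within-group score dispersions in the PC1-PC2 plane, on the same
scale as the D-ratio (smaller is better, with 0.5 as the advisory
threshold).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_matrix import BLANK_TYPES, PeakMatrix, SampleType

__all__ = ["PcaResult", "pca_check", "qc_dispersion_ratio", "build_report"]

Scaling = Literal["centre_only", "unit_variance", "pareto"]
Imputation = Literal["feature_median", "half_minimum"]


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame               # index sample_id, columns PC1.., plus sample_type
    explained_variance: np.ndarray     # fraction per component, non-increasing
    scaling_used: Scaling
    imputation_used: Imputation


def pca_check(
    matrix: PeakMatrix,
    scaling: Scaling = "unit_variance",
    imputation: Imputation = "feature_median",
    n_components: int = 2,
) -> PcaResult:
    """PCA scores of the (blank- and conditioning-free) matrix.

    Data are always mean-centred; ``unit_variance`` additionally divides
    by the feature SD and ``pareto`` by its square root.  Missing values
    are imputed per feature (median, or half the observed minimum)
    before projection, with the policy recorded in the result.
    """
    keep = ~matrix.type_mask(BLANK_TYPES | {SampleType.CONDITIONING_QC})
    sub = matrix.select_samples(keep)
    if sub.n_samples < 3 or sub.n_features < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 features after exclusion")
    X = sub.intensities.copy()
    all_missing = np.all(~np.isfinite(X), axis=0)
    if all_missing.any():
        bad = [sub.features[j].feature_id for j in np.where(all_missing)[0]]
        raise ValueError(
            f"features with no observed values: {bad[:5]}; clean the matrix first"
        )
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            fill = (
                np.nanmedian(col)
                if imputation == "feature_median"
                else np.nanmin(col) / 2.0
            )
            col[miss] = fill

    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        sd = np.sqrt(X.std(axis=0, ddof=1))
        X = X / np.where(sd > 0, sd, 1.0)
    elif scaling != "centre_only":
        raise ValueError(f"unknown scaling {scaling!r}")

    n_components = min(n_components, sub.n_samples - 1, sub.n_features)
    n_components = max(n_components, 2)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=pd.Index(sub.sample_ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    frame["sample_type"] = [s.sample_type.value for s in sub.samples]
    return PcaResult(
        scores=frame,
        explained_variance=pca.explained_variance_ratio_,
        scaling_used=scaling,
        imputation_used=imputation,
    )


def qc_dispersion_ratio(
    result: PcaResult,
    qc_type: str = SampleType.POOLED_QC.value,
    bio_type: str = SampleType.BIOLOGICAL.value,
    advisory_threshold: float = 0.5,
) -> tuple[float, str]:
    """QC-to-biological score dispersion ratio in the PC1-PC2 plane.

    Dispersion per group is the square root of the trace of the
    within-group covariance of (PC1, PC2) — rotation- and
    translation-invariant, so an offset QC cluster is not penalised.
    Returns ``(ratio, message)``; ``NaN`` for degenerate groups.
    """
    qc = result.scores.loc[result.scores["sample_type"] == qc_type, ["PC1", "PC2"]]
    bio = result.scores.loc[result.scores["sample_type"] == bio_type, ["PC1", "PC2"]]
    if len(qc) < 2 or len(bio) < 2:
        return float("nan"), "undefined: need >= 2 QC and >= 2 biological scores"
    disp_qc = float(np.sqrt(np.trace(np.cov(qc.to_numpy().T))))
    disp_bio = float(np.sqrt(np.trace(np.cov(bio.to_numpy().T))))
    if disp_bio == 0:
        return float("nan"), "undefined: degenerate biological score cloud"
    ratio = disp_qc / disp_bio
    if ratio < advisory_threshold:
        msg = f"pass: QC cluster is tight relative to biological spread ({ratio:.3f})"
    else:
        msg = (
            f"advise: QC dispersion is {ratio:.3f} of the biological spread "
            f"(threshold {advisory_threshold}); inspect drift correction and "
            f"per-feature RSDs"
        )
    return ratio, msg


def build_report(
    *,
    suitability: dict | None = None,
    blank_table: pd.DataFrame | None = None,
    correction: dict | None = None,
    stats_table: pd.DataFrame | None = None,
    cleaning: pd.DataFrame | None = None,
    pca_ratio: tuple[float, str] | None = None,
    runorder_results: list | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble the study-level QC report.

    Sections not produced by the pipeline run are marked absent rather
    than omitted, and every threshold actually used is embedded, so the
    report is publishable alongside the study as its QC record.
    """
    report: dict = {"sections": {}}

    def section(name: str, value) -> None:
        report["sections"][name] = value if value is not None else "absent"

    section("suitability", suitability)
    if blank_table is not None:
        removed = blank_table[blank_table["action"] == "removed"]
        flagged = blank_table[blank_table["action"] == "flagged"]
        section(
            "blanks",
            {
                "policy": blank_table.attrs.get("policy", {}),
                "n_features": int(len(blank_table)),
                "n_removed": int(len(removed)),
                "n_flagged": int(len(flagged)),
                "removed_features": removed.index.tolist(),
            },
        )
    else:
        section("blanks", None)
    section("correction", correction)
    if stats_table is not None:
        section(
            "metrics",
            {
                "n_features": int(len(stats_table)),
                "rsd_median": _q(stats_table, "rsd", 0.5),
                "rsd_q90": _q(stats_table, "rsd", 0.9),
                "d_ratio_median": _q(stats_table, "d_ratio", 0.5),
                "d_ratio_q90": _q(stats_table, "d_ratio", 0.9),
                "detection_rate_median": _q(stats_table, "detection_rate", 0.5),
            },
        )
    else:
        section("metrics", None)
    if cleaning is not None:
        section(
            "cleaning",
            {
                "criteria": cleaning.attrs.get("criteria", {}),
                "n_features": int(len(cleaning)),
                "n_retained": int(cleaning["retained"].sum()),
                "n_removed": int((~cleaning["retained"]).sum()),
            },
        )
    else:
        section("cleaning", None)
    if pca_ratio is not None:
        section("pca", {"qc_dispersion_ratio": pca_ratio[0], "message": pca_ratio[1]})
    else:
        section("pca", None)
    if runorder_results is not None:
        section(
            "runorder",
            {
                "passed": all(r.passed for r in runorder_results),
                "rules": [
                    {
                        "rule": r.rule,
                        "passed": r.passed,
                        "positions": list(r.positions),
                        "message": r.message,
                    }
                    for r in runorder_results
                ],
            },
        )
    else:
        section("runorder", None)
    section("config", config)
    return report


def _q(table: pd.DataFrame, column: str, q: float) -> float | None:
    if column not in table.columns:
        return None
    vals = table[column].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(np.quantile(vals, q)) if vals.size else None


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
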