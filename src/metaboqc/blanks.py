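"""Blank-based contaminant and carryover filtering.

Process (extraction) blanks are prepared with every reagent and step
but no biological material, so any signal they carry is contamination.
Three exclusion policies are supported:

* ``noise_multiple`` — remove features whose mean blank signal exceeds
  k x an expected background-noise level (default k = 10);
* ``percent_of_median`` — remove features whose mean blank signal
  exceeds a percentage (default 5%) of the median biological signal;
* ``flag_only`` — compute the contribution but only flag the feature
  as ``potentially_contaminated``.

Whichever policy is applied, the exclusion table records the criterion
and thresholds used, since these should always be reported alongside a
study.  Carryover is assessed separately from a blank injected after a
stretch of biological samples.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .core_matrix import PeakMatrix, SampleType

__all__ = ["BlankPolicy", "blank_contribution", "apply_blank_policy", "carryover_check"]


@dataclasses.dataclass(frozen=True)
class BlankPolicy:
    mode: Literal["noise_multiple", "percent_of_median", "flag_only"] = "percent_of_median"
    noise_multiple_k: float = 10.0
    percent_threshold: float = 5.0
    noise_floor: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("noise_multiple", "percent_of_median", "flag_only"):
            raise ValueError(f"unknown blank policy mode {self.mode!r}")
        if self.noise_multiple_k <= 0 or self.percent_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.mode == "noise_multiple" and self.noise_floor is None:
            raise ValueError(
                "noise_multiple mode needs an explicit noise_floor: there is "
                "no operational definition of expected background noise"
            )


def _blank_bio_aggregates(matrix: PeakMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(mean blank signal, median biological signal) per feature.

    Process blanks only (the pre-run system blank is a suitability
    artefact).  A missing blank value counts as 0 — absence of a peak in
    a blank is evidence of absence — while missing biological values are
    excluded from the median.
    """
    blank_mask = matrix.type_mask({SampleType.PROCESS_BLANK})
    bio_mask = matrix.type_mask({SampleType.BIOLOGICAL})
    if not blank_mask.any():
        raise ValueError(
            "no process-blank rows present; blank contributions cannot be "
            "computed in any mode (including flag_only)"
        )
    if not bio_mask.any():
        raise ValueError("no biological rows present")
    blank = np.nan_to_num(matrix.intensities[blank_mask, :], nan=0.0).mean(axis=0)
    bio = np.nanmedian(matrix.intensities[bio_mask, :], axis=0)
    return blank, bio


def blank_contribution(matrix: PeakMatrix, feature_id: str) -> float:
    """Mean process-blank signal as % of the median biological signal.

    Returns ``inf`` when the biological median is 0 but blank signal is
    present, and 0 when both are absent.
    """
    j = matrix.feature_index(feature_id)
    blank, bio = _blank_bio_aggregates(matrix)
    b, m = float(blank[j]), float(bio[j])
    if b == 0:
        return 0.0
    if not np.isfinite(m) or m == 0:
        return np.inf
    return 100.0 * b / m


def apply_blank_policy(
    matrix: PeakMatrix, policy: BlankPolicy | None = None
) -> tuple[PeakMatrix, pd.DataFrame]:
    """Apply a blank exclusion policy.

    Returns the (possibly feature-reduced) matrix and an exclusion table
    covering every input feature with the criterion value and the action
    taken.  Boundary values are retained: removal requires the criterion
    value to exceed the threshold strictly.
    """
    policy = policy or BlankPolicy()
    blank, bio = _blank_bio_aggregates(matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        contribution = np.where(
            blank == 0,
            0.0,
            np.where(np.nan_to_num(bio) == 0, np.inf, 100.0 * blank / bio),
        )

    rows = []
    keep: list[str] = []
    for j, f in enumerate(matrix.features):
        if policy.mode == "noise_multiple":
            value = float(blank[j])
            exceeded = value > policy.noise_multiple_k * float(policy.noise_floor)
            criterion = f"blank_mean > {policy.noise_multiple_k} * noise_floor"
        else:
            value = float(contribution[j])
            exceeded = value > policy.percent_threshold
            criterion = f"contribution_pct > {policy.percent_threshold}"
        if policy.mode == "flag_only":
            action = "flagged" if exceeded else "retained"
            if exceeded:
                f.flags.add("potentially_contaminated")
            keep.append(f.feature_id)
        else:
            action = "removed" if exceeded else "retained"
            if not exceeded:
                keep.append(f.feature_id)
        rows.append(
            {
                "feature_id": f.feature_id,
                "blank_mean": float(blank[j]),
                "biological_median": float(bio[j]),
                "contribution_pct": float(contribution[j]),
                "criterion": criterion,
                "action": action,
            }
        )
    table = pd.DataFrame(rows).set_index("feature_id")
    table.attrs["policy"] = dataclasses.asdict(policy)
    return matrix.select_features(keep), table


def carryover_check(
    matrix: PeakMatrix,
    post_run_blank: str,
    window: int = 5,
    percent_threshold: float = 5.0,
) -> pd.DataFrame:
    """Check a post-run blank for sample carryover.

    Each feature's signal in the named blank is expressed as a
    percentage of its mean over the ``window`` biological injections
    immediately preceding the blank; features strictly above
    ``percent_threshold`` are flagged ``carryover``.
    """
    try:
        idx = matrix.sample_ids.index(post_run_blank)
    except ValueError:
        raise KeyError(f"no sample named {post_run_blank!r}") from None
    bio_before = [
        i for i in range(idx)
        if matrix.samples[i].sample_type is SampleType.BIOLOGICAL
    ]
    if len(bio_before) < window:
        raise ValueError(
            f"blank {post_run_blank!r} is preceded by only {len(bio_before)} "
            f"biological injections (window={window})"
        )
    ref_rows = matrix.intensities[bio_before[-window:], :]
    ref_mean = np.nanmean(ref_rows, axis=0)
    blank_row = matrix.intensities[idx, :]

    rows = []
    for j, f in enumerate(matrix.features):
        b = blank_row[j]
        if not np.isfinite(b) or b == 0:
            pct = 0.0
        elif not np.isfinite(ref_mean[j]) or ref_mean[j] == 0:
            pct = np.inf
        else:
            pct = 100.0 * b / ref_mean[j]
        flagged = pct > percent_threshold
        if flagged:
            f.flags.add("carryover")
        rows.append(
            {
                "feature_id": f.feature_id,
                "blank_signal": float(b) if np.isfinite(b) else np.nan,
                "preceding_mean": float(ref_mean[j]),
                "carryover_pct": pct,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
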