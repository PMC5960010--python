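"""Pooled-QC-anchored signal-drift and batch correction.

The measurement model is additive: ``m_ij = mbar_i + f_i(t_j) + eps``,
with the same systematic error function ``f_i`` governing QC and test
samples.  Per feature and per batch, ``f_i`` is estimated by least
squares on the pooled-QC trajectory and subtracted from every sample,
re-adding the QC mean:

    z_ij = m_ij - fhat_i(t_j) + mean(QC_i)

Smoothing-parameter selection is the hazardous step: an unconstrained
smoother fits the random error as well as the drift and makes the
post-correction precision look unrealistically good.  The smoothing
value is therefore chosen by cross-validation on held-out QCs
(leave-one-out with the end QCs pinned, k-fold, or a random one-third
hold-out), minimising held-out RMSE with ties broken toward the
smoothest curve.

After within-batch correction, batches are aligned by subtracting each
batch's QC-mean offset from the grand mean of the batch QC means.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import make_smoothing_spline

from .core_matrix import BLANK_TYPES, PeakMatrix, SampleType
from .metrics import rsd

__all__ = [
    "DriftModel",
    "CorrectionConfig",
    "CorrectionReport",
    "ExtrapolationError",
    "fit_drift",
    "apply_correction",
    "correct_batches",
    "correct_matrix",
    "default_smoothing_grid",
]

Method = Literal["cubic_spline", "loess", "linear", "bracketed_linear"]
CvScheme = Literal["loo", "kfold", "holdout_third"]

#: Minimum pooled QCs for a nonlinear drift model.
MIN_QC_NONLINEAR = 8
#: Minimum pooled QCs for a linear drift model.
MIN_QC_LINEAR = 2

#: Sample types the fitted correction is applied to.  Blanks carry no
#: biological signal, conditioning data are discarded upstream, and the
#: suitability injections sit outside the QC-bracketed span.
CORRECTABLE_TYPES = frozenset(
    {
        SampleType.BIOLOGICAL,
        SampleType.POOLED_QC,
        SampleType.LTR,
        SampleType.SRM,
        SampleType.DILUTION_QC,
    }
)


class ExtrapolationError(ValueError):
    """A sample lies outside the QC-bracketed time span of its batch.

    Correction curves are interpolators; evaluating them beyond the
    first or last QC would extrapolate with unpredictable results,
    which usually signals missing end-of-batch QCs.
    """


@dataclasses.dataclass
class DriftModel:
    """Fitted systematic-error trajectory for one feature in one batch.

    ``curve`` predicts the QC trajectory ghat(t); the correction applied
    is ``z = y - ghat(t) + qc_mean``, so a flat trajectory yields the
    identity.
    """

    feature_id: str
    batch: int
    method: Method
    curve: Callable[[np.ndarray], np.ndarray]
    qc_mean: float
    t_span: tuple[float, float]
    smoothing: float
    cv_scheme: CvScheme
    cv_error: float
    n_qc_used: int
    fallback_applied: bool = False
    holdout_idx: tuple[int, ...] = ()
    cv_curve: tuple[tuple[float, float], ...] = ()  # (smoothing, cv RMSE) pairs

    def predict(self, t) -> np.ndarray:
        return np.asarray(self.curve(np.asarray(t, dtype=float)), dtype=float)


def default_smoothing_grid(method: Method, n_qc: int, grid_size: int = 21) -> np.ndarray:
    """Log-spaced smoothing grid from near-interpolation to near-linear.

    For the regularised cubic spline the grid is the roughness penalty
    ``lam`` on injection order rescaled to [0, 1]; for LOESS it is the
    local-window fraction.  Linear and bracketed-linear methods have no
    smoothing parameter.
    """
    if method == "cubic_spline":
        return np.logspace(-7, 2, grid_size)
    if method == "loess":
        lo = min(0.99, max(0.3, 3.0 / max(n_qc, 3)))
        return np.geomspace(lo, 1.0, grid_size)
    return np.array([0.0])


def _fit_one(
    method: Method,
    t: np.ndarray,
    y: np.ndarray,
    smoothing: float,
    t0: float,
    t1: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit one candidate curve; t is assumed strictly increasing."""
    if method == "cubic_spline":
        # rescale t to [0, 1] so lam has a data-independent meaning
        ts = (t - t0) / (t1 - t0)
        spline = make_smoothing_spline(ts, y, lam=float(smoothing))
        return lambda x: spline((np.asarray(x, dtype=float) - t0) / (t1 - t0))
    if method == "loess":
        frac = float(smoothing)

        def predict(x, _t=t, _y=y, _frac=frac):
            x = np.atleast_1d(np.asarray(x, dtype=float))
            out = sm.nonparametric.lowess(
                _y, _t, frac=_frac, xvals=x, return_sorted=False
            )
            return np.atleast_1d(out)

        return predict
    if method == "linear":
        slope, intercept = np.polyfit(t, y, 1)
        return lambda x: slope * np.asarray(x, dtype=float) + intercept
    if method == "bracketed_linear":
        return lambda x: np.interp(np.asarray(x, dtype=float), t, y)
    raise ValueError(f"unknown method {method!r}")


def _cv_folds(
    n: int, scheme: CvScheme, rng: np.random.Generator
) -> list[np.ndarray]:
    """Held-out index sets.  The first and last QC are never held out:
    they pin the curve ends and prevent extrapolation during CV."""
    interior = np.arange(1, n - 1)
    if scheme == "loo":
        return [np.array([i]) for i in interior]
    if scheme == "kfold":
        k = min(5, len(interior))
        shuffled = rng.permutation(interior)
        return [fold for fold in np.array_split(shuffled, k) if fold.size]
    if scheme == "holdout_third":
        n_hold = max(1, round(len(interior) / 3))
        return [np.sort(rng.choice(interior, size=n_hold, replace=False))]
    raise ValueError(f"unknown cv_scheme {scheme!r}")


def fit_drift(
    t_qc: Sequence[float],
    y_qc: Sequence[float],
    method: Method = "cubic_spline",
    cv_scheme: CvScheme = "loo",
    smoothing_grid: Sequence[float] | None = None,
    *,
    feature_id: str = "",
    batch: int = 1,
    seed: int = 0,
) -> DriftModel:
    """Fit a drift model to one pooled-QC trajectory.

    For every candidate smoothing value the curve is fitted to the
    training QCs and scored by RMSE on the held-out QCs; the value with
    the lowest cross-validated error wins, ties going to the largest
    (smoothest) candidate.  Under ``holdout_third`` the final curve is
    fitted on the training two-thirds only, keeping the hold-out blind
    for precision reporting.
    """
    t = np.asarray(t_qc, dtype=float)
    y = np.asarray(y_qc, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t_qc and y_qc must be equal-length 1-d vectors")
    if np.any(np.diff(t) <= 0):
        raise ValueError("injection orders must be strictly increasing")
    n = t.size
    min_n = MIN_QC_NONLINEAR if method in ("cubic_spline", "loess") else MIN_QC_LINEAR
    if n < min_n:
        raise ValueError(
            f"{method} needs at least {min_n} pooled QCs per batch, got {n}"
        )

    t0, t1 = float(t[0]), float(t[-1])
    rng = np.random.default_rng(seed)
    grid = (
        np.asarray(smoothing_grid, dtype=float)
        if smoothing_grid is not None
        else default_smoothing_grid(method, n)
    )

    folds = [f for f in _cv_folds(n, cv_scheme, rng) if f.size]
    cv_curve: list[tuple[float, float]] = []
    all_sq: list[np.ndarray] = []
    for s in grid:
        sq_errs: list[float] = []
        if folds:
            for hold in folds:
                train = np.setdiff1d(np.arange(n), hold)
                curve = _fit_one(method, t[train], y[train], s, t0, t1)
                pred = curve(t[hold])
                sq_errs.extend((np.asarray(pred) - y[hold]) ** 2)
        else:
            # too few points to hold any out (e.g. 2-point linear fit):
            # fall back to in-sample residuals
            curve = _fit_one(method, t, y, s, t0, t1)
            sq_errs.extend((np.asarray(curve(t)) - y) ** 2)
        sq = np.asarray(sq_errs, dtype=float)
        all_sq.append(sq)
        cv_curve.append((float(s), float(np.sqrt(sq.mean()))))
    # Minimise CV MSE with ties resolved toward the smoothest curve.
    # "Tie" is read statistically: candidates within one standard error
    # of the minimising candidate's CV estimate are indistinguishable,
    # and picking the smoothest of them guards against the smoother
    # chasing random error when noise dominates any real drift.
    mse = np.array([sq.mean() for sq in all_sq])
    if not np.isfinite(mse).any():
        raise ValueError(
            f"{method}: no smoothing candidate produced finite held-out "
            f"predictions (n={n} QCs)"
        )
    mse[~np.isfinite(mse)] = np.inf
    k = int(np.argmin(mse))
    n_sq = all_sq[k].size
    se = all_sq[k].std(ddof=1) / np.sqrt(n_sq) if n_sq > 1 else 0.0
    eligible = np.where(mse <= mse[k] + se)[0]
    best_idx = int(eligible[np.argmax(grid[eligible])])
    best_s, best_err = float(grid[best_idx]), float(cv_curve[best_idx][1])

    holdout: tuple[int, ...] = ()
    if cv_scheme == "holdout_third":
        holdout = tuple(int(i) for i in folds[0])
        train = np.setdiff1d(np.arange(n), folds[0])
        final_curve = _fit_one(method, t[train], y[train], best_s, t0, t1)
        n_used = train.size
    else:
        final_curve = _fit_one(method, t, y, best_s, t0, t1)
        n_used = n

    return DriftModel(
        feature_id=feature_id,
        batch=batch,
        method=method,
        curve=final_curve,
        qc_mean=float(y.mean()),
        t_span=(t0, t1),
        smoothing=best_s,
        cv_scheme=cv_scheme,
        cv_error=best_err,
        n_qc_used=n_used,
        holdout_idx=holdout,
        cv_curve=tuple(cv_curve),
    )


def apply_correction(
    t_all: Sequence[float],
    y_all: Sequence[float],
    model: DriftModel,
) -> np.ndarray:
    """Subtract the fitted trajectory, re-adding the QC mean.

    Missing values stay missing.  Negative corrected values are allowed
    (callers count and may clip them).  Times outside the model's QC
    span raise :class:`ExtrapolationError`.
    """
    t = np.asarray(t_all, dtype=float)
    y = np.asarray(y_all, dtype=float)
    lo, hi = model.t_span
    outside = (t < lo) | (t > hi)
    if outside.any():
        raise ExtrapolationError(
            f"injections at t={t[outside].astype(int).tolist()} lie outside "
            f"the QC span [{lo:g}, {hi:g}] of batch {model.batch}; check for "
            f"missing end-of-batch QCs"
        )
    z = y - model.predict(t) + model.qc_mean
    z[~np.isfinite(y)] = np.nan
    return z


def correct_batches(matrix: PeakMatrix) -> PeakMatrix:
    """Align batches to the grand mean of the per-batch QC means.

    Per feature: the batch mean is the mean of that batch's pooled-QC
    values, the grand mean is the mean of the batch means, and
    ``batch_mean - grand_mean`` is subtracted from every (non-blank)
    sample in the batch.  A feature with no QC values in some batch is
    flagged ``uncorrectable_batch`` and left unshifted there.
    """
    out = matrix.copy()
    out.corrected = True
    batches = out.batches
    unique_batches = sorted(set(batches))
    if len(unique_batches) < 2:
        return out
    qc_mask = out.type_mask({SampleType.POOLED_QC})
    blank_mask = out.type_mask(BLANK_TYPES)

    for j, feat in enumerate(out.features):
        means: dict[int, float] = {}
        for b in unique_batches:
            vals = out.intensities[qc_mask & (batches == b), j]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                means[b] = float(vals.mean())
        if len(means) < len(unique_batches):
            feat.flags.add("uncorrectable_batch")
            if not means:
                continue
        grand = float(np.mean(list(means.values())))
        for b, m in means.items():
            rows = (batches == b) & ~blank_mask
            out.intensities[rows, j] -= m - grand
    return out


@dataclasses.dataclass(frozen=True)
class CorrectionConfig:
    method: Method = "cubic_spline"
    cv_scheme: CvScheme = "loo"
    grid_size: int = 21
    smoothing_grid: tuple[float, ...] | None = None
    log10: bool = False
    log_offset: float = 1.0
    min_qc_nonlinear: int = MIN_QC_NONLINEAR
    clip_negative: bool = False
    align_batches: bool = True
    seed: int = 0


@dataclasses.dataclass
class CorrectionReport:
    models: pd.DataFrame            # per feature x batch model summaries
    feature_summary: pd.DataFrame   # pre/post QC RSD and D-ratio inputs
    skipped: dict[str, str]
    n_negative_post: int
    config: CorrectionConfig

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["smoothing_grid"] = (
            list(cfg["smoothing_grid"]) if cfg["smoothing_grid"] else None
        )
        return {
            "config": cfg,
            "n_negative_post": self.n_negative_post,
            "skipped": self.skipped,
            "median_rsd_pre": float(np.nanmedian(self.feature_summary["rsd_pre"])),
            "median_rsd_post": float(np.nanmedian(self.feature_summary["rsd_post"])),
            "n_fallback": int(self.models["fallback_applied"].sum()),
        }


def correct_matrix(
    matrix: PeakMatrix,
    config: CorrectionConfig | None = None,
) -> tuple[PeakMatrix, CorrectionReport]:
    """Drift-correct every feature in every batch, then align batches.

    Per feature and batch, the pooled-QC trajectory is fitted with the
    configured method; features with too few QCs for a nonlinear method
    fall back to linear, then to no correction, with
    ``fallback_applied`` recorded.  The correction is applied to
    biological, pooled-QC, reference and dilution rows; blanks are left
    untouched.  The report carries pre/post QC RSDs so the gain (or
    lack of it) is visible per feature.
    """
    config = config or CorrectionConfig()
    if matrix.type_mask({SampleType.CONDITIONING_QC}).any():
        raise ValueError("remove conditioning injections before drift correction")
    qc_mask = matrix.type_mask({SampleType.POOLED_QC})
    if not qc_mask.any():
        raise ValueError("no pooled QCs: QC-free drift correction is not supported")

    out = matrix.copy()
    out.corrected = True
    t_all = out.injection_order.astype(float)
    batches = out.batches
    apply_mask = np.array(
        [s.sample_type in CORRECTABLE_TYPES for s in out.samples], dtype=bool
    )

    data = out.intensities
    if config.log10:
        with np.errstate(invalid="ignore"):
            work = np.log10(data + config.log_offset)
    else:
        work = data.copy()

    model_rows: list[dict] = []
    skipped: dict[str, str] = {}
    pre_rsd = np.full(out.n_features, np.nan)
    post_rsd = np.full(out.n_features, np.nan)

    for j, feat in enumerate(out.features):
        pre_rsd[j] = rsd(data[qc_mask, j])
        for b in sorted(set(batches)):
            in_batch = batches == b
            qc_rows = qc_mask & in_batch
            t_qc = t_all[qc_rows]
            y_qc = work[qc_rows, j]
            ok = np.isfinite(y_qc)
            t_fit, y_fit = t_qc[ok], y_qc[ok]

            method: Method | None = config.method
            fallback = False
            if method in ("cubic_spline", "loess") and t_fit.size < config.min_qc_nonlinear:
                method, fallback = "linear", True
            if method in ("linear", "bracketed_linear") and t_fit.size < MIN_QC_LINEAR:
                method, fallback = None, True

            if method is None:
                skipped[feat.feature_id] = (
                    f"batch {b}: only {t_fit.size} usable QC values"
                )
                feat.flags.add("uncorrected")
                continue

            model = fit_drift(
                t_fit,
                y_fit,
                method=method,
                cv_scheme=config.cv_scheme if method not in ("linear", "bracketed_linear") else "loo",
                smoothing_grid=config.smoothing_grid,
                feature_id=feat.feature_id,
                batch=b,
                seed=config.seed + b,
            )
            model_rows.append(
                {
                    "feature_id": feat.feature_id,
                    "batch": b,
                    "method": method,
                    "smoothing": model.smoothing,
                    "cv_error": model.cv_error,
                    "n_qc_used": model.n_qc_used,
                    "fallback_applied": fallback,
                }
            )

            rows = apply_mask & in_batch
            lo, hi = model.t_span
            # a missing end-QC value narrows the usable span for this
            # feature; rather than extrapolate the curve, evaluate it at
            # the nearest span end (constant extrapolation) and flag
            out_of_span = rows & ((t_all < lo) | (t_all > hi))
            if np.any(out_of_span & np.isfinite(work[:, j])):
                feat.flags.add("edge_clamped")
            t_eval = np.clip(t_all[rows], lo, hi)
            z = apply_correction(t_eval, work[rows, j], model)
            if config.log10:
                data[rows, j] = np.power(10.0, z) - config.log_offset
            else:
                data[rows, j] = z
        post_rsd[j] = rsd(data[qc_mask, j])

    n_negative = int(np.nansum(data[apply_mask, :] < 0))
    if config.clip_negative:
        data[apply_mask, :] = np.clip(data[apply_mask, :], 0.0, None)

    if config.align_batches and len(set(batches)) > 1:
        out = correct_batches(out)
        data = out.intensities
        for j in range(out.n_features):
            post_rsd[j] = rsd(data[out.type_mask({SampleType.POOLED_QC}), j])

    feature_summary = pd.DataFrame(
        {
            "feature_id": out.feature_ids,
            "rsd_pre": pre_rsd,
            "rsd_post": post_rsd,
        }
    ).set_index("feature_id")
    models = pd.DataFrame(
        model_rows,
        columns=[
            "feature_id", "batch", "method", "smoothing",
            "cv_error", "n_qc_used", "fallback_applied",
        ],
    )
    report = CorrectionReport(
        models=models,
        feature_summary=feature_summary,
        skipped=skipped,
        n_negative_post=n_negative,
        config=config,
    )
    return out, report
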