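"""Synthetic multi-batch study generator with retained ground truth.

Every downstream stage of the package is testable against simulated
data built on the additive measurement model

    m_ij = mbar_i + f_i(t_j) + batch_offset + eps,

where ``mbar_i`` is the true mean response of feature *i*, ``f_i`` a
smooth drift function of injection order, and ``eps`` Gaussian noise
whose variance is purely technical for QC-derived injections and
technical + biological for biological samples.  The generator emulates
the qualitative drift catalogue seen on real platforms — no drift,
linear increase/decrease, exponential (monotone nonlinear) change, and
smooth non-monotone wander — plus between-batch step offsets, random
missingness, and low-level blank contamination for a subset of
features.

It does not model chromatographic peak shapes, m/z-domain effects, or
ionisation suppression; see the methods note for what that implies.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core_matrix import (
    BLANK_TYPES,
    FeatureRecord,
    PeakMatrix,
    SampleRecord,
    SampleType,
)
from .runorder import RunOrder, RunOrderSpec, design_study

__all__ = [
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_study",
    "truth_rsd",
    "DRIFT_SHAPES",
]

DRIFT_SHAPES = ("none", "linear", "monotone_nonlinear", "nonmonotone_smooth")

#: Injections drawing from the pooled-QC material (technical error only).
_QC_POOL_TYPES = {
    SampleType.POOLED_QC,
    SampleType.CONDITIONING_QC,
    SampleType.DILUTION_QC,
}


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth retained alongside a simulated matrix."""

    mean_response: np.ndarray            # mbar_i, per feature
    drift_shape: list[str]               # per feature
    drift_values: np.ndarray             # f_i(t) on the injection grid
    injection_grid: np.ndarray           # the t values drift_values refers to
    sigma_technical: np.ndarray          # absolute units, per feature
    sigma_biological: np.ndarray         # absolute units, per feature
    batch_offsets: np.ndarray            # (n_batches, n_features) additive shifts
    contaminated_features: list[str]     # features with nonzero blank signal
    blank_levels: np.ndarray             # per feature, absolute blank signal
    missing_rate: float
    n_clipped_negative: int
    seed: int

    def drift_function(self, feature_index: int) -> Callable[[np.ndarray], np.ndarray]:
        """f_i as a callable over injection order (linear interpolation
        between the simulated grid points, which cover every injection)."""
        grid = self.injection_grid
        vals = self.drift_values[:, feature_index]
        return lambda t: np.interp(np.asarray(t, dtype=float), grid, vals)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "missing_rate": self.missing_rate,
            "n_clipped_negative": self.n_clipped_negative,
            "injection_grid": self.injection_grid.tolist(),
            "mean_response": self.mean_response.tolist(),
            "drift_shape": self.drift_shape,
            "drift_values": self.drift_values.tolist(),
            "sigma_technical": self.sigma_technical.tolist(),
            "sigma_biological": self.sigma_biological.tolist(),
            "batch_offsets": self.batch_offsets.tolist(),
            "contaminated_features": self.contaminated_features,
            "blank_levels": self.blank_levels.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


@dataclasses.dataclass
class SimulatedStudy:
    matrix: PeakMatrix
    truth: SimulationTruth


def truth_rsd(truth: SimulationTruth, feature_index: int) -> float:
    """Asymptotic QC RSD (%) a drift-free measurement should recover:
    100 * sigma_technical / mean_response."""
    mbar = truth.mean_response[feature_index]
    if mbar == 0:
        raise ValueError("mean response is zero; RSD undefined")
    return 100.0 * truth.sigma_technical[feature_index] / mbar


def simulate_study(
    n_biological: int,
    n_features: int,
    n_batches: int = 1,
    *,
    run_order_spec: RunOrderSpec | None = None,
    drift_spec: str | Sequence[str] | dict[str, float] = "none",
    drift_amplitude: float = 0.2,
    sigma_technical: float | Sequence[float] = 0.05,
    sigma_biological: float | Sequence[float] = 0.25,
    batch_shift_sd: float = 0.1,
    missing_rate: float = 0.0,
    blank_leakage: float = 0.0,
    blank_level_range: tuple[float, float] = (0.01, 0.12),
    lognormal_noise: bool = False,
    seed: int,
) -> SimulatedStudy:
    """Simulate a multi-batch untargeted study with known ground truth.

    Parameters
    ----------
    drift_spec
        Either one shape name from :data:`DRIFT_SHAPES` applied to all
        features, an explicit per-feature sequence, or a dict of mixture
        weights (e.g. ``{"linear": 0.5, "nonmonotone_smooth": 0.5}``).
    drift_amplitude
        Peak drift excursion as a fraction of the feature mean over the
        run (default 0.2; drawn per feature in [amplitude/2, amplitude]).
    sigma_technical, sigma_biological
        Relative standard deviations (fractions of the feature mean),
        scalar or per feature.  QC-derived rows draw only technical
        noise; biological rows draw sqrt(tech^2 + bio^2).
    batch_shift_sd
        SD of per-batch per-feature additive offsets, as a fraction of
        the feature mean.
    blank_leakage
        Fraction of features that show a genuine signal in process
        blanks; their blank level is drawn from ``blank_level_range``
        (fractions of the feature mean).
    lognormal_noise
        If True, noise is multiplicative log-normal with matched CV,
        for stress-testing the robust statistics.
    seed
        Mandatory; identical seeds give bitwise-identical studies.
    """
    if n_biological < 1 or n_features < 1 or n_batches < 1:
        raise ValueError("all counts must be positive")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    order = design_study(n_biological, n_batches, run_order_spec, seed=seed)
    n_inj = len(order.entries)
    t_grid = np.arange(1, n_inj + 1, dtype=float)

    feature_ids = [f"F{j + 1:04d}" for j in range(n_features)]
    # mean responses span ~3 orders of magnitude, as peak areas do
    mean_response = 10.0 ** rng.uniform(3.0, 6.0, n_features)
    shapes = _resolve_shapes(drift_spec, n_features, rng)
    sig_tech = np.broadcast_to(np.asarray(sigma_technical, dtype=float), (n_features,)).copy()
    sig_bio = np.broadcast_to(np.asarray(sigma_biological, dtype=float), (n_features,)).copy()
    sig_tech_abs = sig_tech * mean_response
    sig_bio_abs = sig_bio * mean_response

    drift_values = np.zeros((n_inj, n_features))
    for j, shape in enumerate(shapes):
        amp = rng.uniform(drift_amplitude / 2, drift_amplitude) * mean_response[j]
        drift_values[:, j] = _drift_curve(shape, t_grid, amp, rng)

    batch_offsets = rng.normal(0.0, batch_shift_sd, (n_batches, n_features)) * mean_response

    n_contam = int(round(blank_leakage * n_features))
    contam_idx = rng.choice(n_features, size=n_contam, replace=False) if n_contam else np.array([], dtype=int)
    blank_levels = np.zeros(n_features)
    if n_contam:
        blank_levels[contam_idx] = (
            rng.uniform(*blank_level_range, n_contam) * mean_response[contam_idx]
        )

    # per-biological-sample true deviations (shared across injections of
    # the same sample id, though each id is injected once here)
    bio_ids = sorted({e.sample_id for e in order.entries
                      if e.sample_type is SampleType.BIOLOGICAL})
    bio_offset = {
        sid: rng.normal(0.0, 1.0, n_features) for sid in bio_ids
    }

    samples: list[SampleRecord] = []
    values = np.zeros((n_inj, n_features))
    for i, e in enumerate(order.entries):
        t = float(e.position)
        base = mean_response + drift_values[i, :] + batch_offsets[e.batch - 1, :]
        if e.sample_type in BLANK_TYPES:
            # blanks: contaminant signal (drift-free) plus tiny instrument noise
            level = blank_levels.copy()
            noise = rng.normal(0.0, 1.0, n_features) * (0.05 * blank_levels + 1.0)
            row = level + noise
        elif e.sample_type is SampleType.BIOLOGICAL:
            sd = np.sqrt(sig_tech_abs**2 + sig_bio_abs**2)
            if lognormal_noise:
                row = base * _lognormal_factor(rng, sd / mean_response, n_features)
            else:
                row = base + bio_offset[e.sample_id] * sig_bio_abs
                row += rng.normal(0.0, 1.0, n_features) * sig_tech_abs
        else:
            # pooled QC, conditioning, LTR/SRM, suitability: technical only
            if lognormal_noise:
                row = base * _lognormal_factor(rng, sig_tech, n_features)
            else:
                row = base + rng.normal(0.0, 1.0, n_features) * sig_tech_abs
            if e.sample_type is SampleType.CONDITIONING_QC:
                # early injections are noisier while the platform equilibrates
                row += rng.normal(0.0, 1.0, n_features) * sig_tech_abs
        values[i, :] = row
        samples.append(
            SampleRecord(
                sample_id=e.sample_id,
                sample_type=e.sample_type,
                injection_order=e.position,
                batch=e.batch,
                vial_id=e.vial_id,
            )
        )

    n_neg = int((values < 0).sum())
    if n_neg:
        frac = n_neg / values.size
        if frac > 0.5:
            warnings.warn(
                f"{100 * frac:.0f}% of simulated intensities were negative "
                f"and clipped; drift/noise magnitudes are implausible"
            )
        values = np.clip(values, 0.0, None)

    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    features = [
        FeatureRecord(
            feature_id=fid,
            mz=float(rng.uniform(70, 1000)),
            rt=float(rng.uniform(30, 900)),
        )
        for fid in feature_ids
    ]
    matrix = PeakMatrix(samples, features, values)
    truth = SimulationTruth(
        mean_response=mean_response,
        drift_shape=list(shapes),
        drift_values=drift_values,
        injection_grid=t_grid,
        sigma_technical=sig_tech_abs,
        sigma_biological=sig_bio_abs,
        batch_offsets=batch_offsets,
        contaminated_features=[feature_ids[k] for k in sorted(contam_idx)],
        blank_levels=blank_levels,
        missing_rate=missing_rate,
        n_clipped_negative=n_neg,
        seed=seed,
    )
    return SimulatedStudy(matrix=matrix, truth=truth)


def _resolve_shapes(
    drift_spec: str | Sequence[str] | dict[str, float],
    n_features: int,
    rng: np.random.Generator,
) -> list[str]:
    if isinstance(drift_spec, str):
        _check_shape(drift_spec)
        return [drift_spec] * n_features
    if isinstance(drift_spec, dict):
        names = list(drift_spec)
        for name in names:
            _check_shape(name)
        w = np.array([drift_spec[n] for n in names], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative and sum > 0")
        return list(rng.choice(names, size=n_features, p=w / w.sum()))
    shapes = list(drift_spec)
    if len(shapes) != n_features:
        raise ValueError("per-feature drift_spec length must equal n_features")
    for name in shapes:
        _check_shape(name)
    return shapes


def _check_shape(name: str) -> None:
    if name not in DRIFT_SHAPES:
        raise ValueError(f"unknown drift shape {name!r}; choose from {DRIFT_SHAPES}")


def _drift_curve(
    shape: str, t: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean drift curve over the run with peak excursion ~amplitude."""
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    x = (t - t[0]) / span
    if shape == "none":
        return np.zeros_like(t)
    if shape == "linear":
        sign = rng.choice([-1.0, 1.0])
        curve = sign * amplitude * x
    elif shape == "monotone_nonlinear":
        # exponential approach to an asymptote, direction random
        rate = rng.uniform(2.0, 6.0)
        sign = rng.choice([-1.0, 1.0])
        curve = sign * amplitude * (1.0 - np.exp(-rate * x))
    elif shape == "nonmonotone_smooth":
        # low-order random smooth wander: sum of 2-3 sine terms
        n_terms = rng.integers(2, 4)
        curve = np.zeros_like(t)
        for _ in range(n_terms):
            freq = rng.uniform(0.5, 2.0)
            phase = rng.uniform(0, 2 * np.pi)
            curve += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * x + phase)
        peak = np.max(np.abs(curve)) or 1.0
        curve = amplitude * curve / peak
    else:  # pragma: no cover - guarded upstream
        raise ValueError(shape)
    return curve - curve.mean()


def _lognormal_factor(
    rng: np.random.Generator, cv: np.ndarray | float, n: int
) -> np.ndarray:
    cv = np.broadcast_to(np.asarray(cv, dtype=float), (n,))
    sigma_log = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-(sigma_log**2) / 2, sigma_log, n)
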