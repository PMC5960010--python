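# Methods

## Measurement model

All computations assume the additive error model for the response of
feature *i* at injection *t_j*:

```
m_ij = m̄_i + f_i(t_j) + ε_i,     ε_i ~ N(0, σ²_i,total)
```

`f_i` is a smooth, feature-specific systematic error ("drift") in
injection order; `ε` collects the random error. For pooled-QC
injections the biological term vanishes, so
`σ²_qc ≈ σ²_technical`, while biological samples carry
`σ²_total = σ²_biological + σ²_technical` (variances add because the
two sources are independent). Injection order is the only time axis:
wall-clock timestamps are not modelled, and batches must be contiguous
in injection order because drift is fitted per batch.

Missing intensities are explicit (`NaN`; empty cell on disk) and
distinct from measured zeros. A feature not present in the pooled QC
has no computable quality: its statistics are reported as absent, never
as zero, and absent statistics fail their cleaning criterion.

## Precision metrics

- `RSD = 100·s/mean` with the sample (n−1) standard deviation.
- `RSD* = 100·(1.4826·MAD)/median`. The constant is `1/Φ⁻¹(3/4)`,
  which rescales the median absolute deviation to the standard
  deviation of a Gaussian; the package computes it from the normal
  quantile rather than hard-coding it. Note the asymmetry — Eq-style
  robust RSD divides by the median while the plain RSD divides by the
  mean — is intentional and preserved.
- `D-ratio = 100·s_qc/s_sample`, the QC dispersion as a fraction of the
  biological-sample dispersion. The denominator uses biological samples
  only (never QCs, blanks or reference samples). The robust variant
  divides raw MADs; the 1.4826 factor cancels and is therefore not
  applied.
- Detection rate counts QC values that are present and strictly greater
  than a noise floor (default 0).

Cleaning retains a feature iff detection rate > 70% AND RSD < 20%
(strict profile; 30% lenient) AND D-ratio < 50%. All inequalities are
strict, so a feature sitting exactly on a threshold is removed. On
harsh data (heavy drift, contamination, missingness) the combined
blank + cleaning filters can plausibly remove a large minority of
features; that is the intended behaviour, not a failure mode.

Statistics may be computed on `log10(x + offset)` (offset default 1)
when the error structure is multiplicative; results carry a
`log10_scale` flag because log-scale RSDs are not percentages of raw
signal. The pipeline computes statistics after drift correction and
cleans on those values (the pre-correction RSDs are retained in the
correction report for comparison).

## Drift correction

Per feature and per batch, the pooled-QC trajectory `(t_qc, y_qc)` is
fitted by least squares with one of:

- `cubic_spline` — regularised cubic smoothing spline
  (`scipy.interpolate.make_smoothing_spline`), roughness penalty `λ` on
  injection order rescaled to [0, 1] so the grid is data-independent;
- `loess` — local linear regression (statsmodels `lowess`), smoothing
  parameter = window fraction;
- `linear` — ordinary least squares line;
- `bracketed_linear` — piecewise-linear interpolation between
  consecutive QCs.

The corrected value re-adds the QC mean: `z = y − ĝ(t) + mean(y_qc)`,
where `ĝ` is the fitted QC trajectory, so within each batch the
per-feature QC mean is preserved exactly and biological samples are
shifted additively by the same curve as their QC neighbours.

### Smoothing selection

The smoothing grid holds 21 log-spaced values spanning
near-interpolation (`λ = 10⁻⁷`) to near-linear (`λ = 10²`); LOESS
fractions span `max(3/n, 0.3)` to 1. Each candidate is scored by
cross-validated RMSE on held-out QCs:

- `loo` (default): leave-one-out over the interior QCs; the first and
  last QC are never held out, because they pin the curve ends and
  holding them out would force extrapolation.
- `kfold`: 5-fold over the interior QCs.
- `holdout_third`: a random third of the interior QCs is blinded; the
  final curve is fitted on the training two-thirds only, so the
  hold-out can report an unbiased precision.

An unconstrained smoother fits the random error as well as the drift
and makes the post-correction precision look better than it is. The
selection therefore minimises CV MSE with **ties resolved toward the
smoothest curve, where "tie" is read statistically**: every candidate
within one standard error of the minimising candidate's CV estimate is
considered indistinguishable and the smoothest of them wins (the
familiar one-standard-error rule). With ~10 held-out points the raw CV
minimum lands on the most flexible grid point for a few percent of
pure-noise features; the 1-SE rule removes that failure mode (measured:
0/120 pure-noise features select the most flexible candidate) without
affecting drift recovery (100% of drifted features still improve).
Single noise realisations can still show their empirical CV minimum at
a grid extreme — the guard is about what gets *selected*, not about the
shape of every realised CV curve.

### Preconditions and fallbacks

Nonlinear methods need ≥ 8 pooled QCs per batch after dropping missing
values (linear needs ≥ 2); features below the minimum fall back
spline → linear → uncorrected, with `fallback_applied` recorded.
Evaluating a correction curve outside the span of the QCs it was
fitted to is extrapolation with unpredictable results, and the
low-level `apply_correction` refuses it, naming the offending
injections (the usual cause is a missing end-of-batch QC). Inside the
full-matrix driver a per-feature missing end-QC value would otherwise
abort an entire run, so there the curve is evaluated at the nearest
span end instead (constant extrapolation) and the feature is flagged
`edge_clamped`. Blanks are never corrected; LTR/SRM and dilution QCs
are corrected but never used for fitting, since they come from a
different pool than the study QCs. Negative corrected values are legal,
counted, and clipped only on request.

### Batch alignment

After within-batch correction, each feature's per-batch mean of pooled
QC values is computed, the grand mean is the mean of those batch means,
and `batch_mean − grand_mean` is subtracted from every non-blank sample
in the batch. QC-derived batch means are used (rather than all-sample
means) because pooled QCs are the only injections guaranteed identical
across batches. A feature with no QC values in some batch is flagged
`uncorrectable_batch` and left unshifted there. After alignment the
per-batch QC means agree to floating-point tolerance.

## Blank policy

The blank aggregate is the mean across process blanks with missing
treated as 0 (a missing blank peak is evidence of absence); the
biological aggregate is the median with missing excluded (robust to
skewed abundance distributions). Removal requires the criterion value
to exceed the threshold strictly, so a feature at exactly 5% of the
median is retained. Pre-run system blanks are suitability artefacts and
are excluded from contamination arithmetic. There is no operational
definition of the "expected background noise"; `noise_multiple` mode
therefore requires an explicit noise floor from the user.

## PCA diagnostic

Data are always mean-centred; unit-variance scaling is the default
(centre-only and Pareto available) since no community convention
exists. Missing values are imputed per feature (median by default, or
half-minimum) and the policy is recorded. Dispersion per group is
`sqrt(trace(cov(PC1, PC2)))` — rotation- and translation-invariant, so
a QC cluster offset from the origin (pipetting, weighing) is not
penalised; only its spread matters. The QC/biological dispersion ratio
is advisory with a default threshold of 0.5, chosen to mirror the
D-ratio default since both compare technical to biological spread.

## Run-order design

A designed batch is: system blank; suitability standard; 8 conditioning
QCs with a process blank midway (the blank is an additional injection,
not one of the 8); 2 lead pooled QCs; the randomised biological block
with a pooled QC every 5th sample (densified if needed so a batch never
has fewer than 5 pooled QCs) and 3 reference injections at even thirds;
2 trailing pooled QCs; a carryover process blank; a final suitability
standard. Randomisation permutes only biological samples — the QC/blank
scaffold is deterministic — and pooled-QC vials rotate with at most 3
injections per vial. The validator checks any sequence against the gap,
count, bracketing, blank-placement and re-conditioning rules and
reports each failure with positions.

## Simulator

`simulate_study` draws mean responses from `10^U(3,6)` (typical
peak-area magnitudes spanning three decades), drift curves per feature
from four shapes (none; linear ±; exponential approach to an asymptote;
smooth non-monotone wander built from 2–3 sine terms), with peak
excursion drawn in `[amplitude/2, amplitude]`·m̄ (default amplitude
0.2). Noise is Gaussian on the natural scale by default, with a
matched-CV log-normal switch for stress-testing the robust statistics;
σ parameters are supplied as CVs (defaults: technical 5%, biological
25%). Batch offsets are `N(0, 10%·m̄)`. Conditioning injections get
doubled technical noise to emulate an unequilibrated platform. A
configurable fraction of features leaks into process blanks at
1–12% of m̄. Negative simulated intensities are clipped to zero and
counted; missing cells are inserted uniformly. Seeds are mandatory and
identical seeds give bitwise-identical studies.

The simulator does **not** emulate chromatographic peak shapes,
m/z-domain effects, retention-time drift, ionisation
suppression/enhancement, or structured (non-uniform) missingness such
as censoring at the detection limit. Passing tests on simulated data
therefore demonstrate the statistical machinery — they do not guarantee
behaviour under matrix effects or intensity-dependent missingness,
which real studies have.

## Problem sizes and numerical conventions

Tests and the acceptance suite run on studies of roughly 30–60
biological samples, 10–60 features and 1–3 batches — about 12 pooled
QCs per batch, the scale at which a nonlinear correction is defensible
— chosen as representative desk-scale studies. Monte-Carlo checks of
the 1.4826 calibration use 10⁶ Gaussian draws. Exact identities (batch
QC-mean equality, D-ratio limit cases, linear-drift cancellation) are
asserted to 10⁻⁹ relative tolerance or better; statistical recoveries
use 3× their theoretical sampling error.

## Known limitations

- Correction is per batch; drift continuing smoothly across a batch
  boundary is modelled as two independent curves plus a step.
- The LOESS path predicts held-out points by statsmodels' interpolation
  and can be undefined for very small window fractions; such candidates
  are dropped from the CV comparison.
- Dilution-series linearity uses correlation only; it deliberately does
  not quantify sensitivity (slope) and flags rather than removes,
  because filtering on linearity biases the retained feature set.
- The QC report is JSON plus derived TSVs; no plotting is performed by
  the computation path (score/drift plots are optional extras).
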