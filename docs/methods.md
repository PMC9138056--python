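# Methods

## The problem

In a diet-switch experiment, consumers raised on one diet are moved to an
isotopically distinct diet and their tissue δ13C/δ15N values are tracked as
they relax toward equilibrium with the new food. Two quantities of applied
interest fall out of that relaxation: **turnover rates** (how fast tissue
isotopic composition is replaced, split into growth dilution and metabolic
replacement) and the **diet–tissue discrimination factor** Δδ (the offset
between equilibrated tissue and diet, needed to interpret field isotope
data). `isoturn` implements this analysis for the juvenile-seahorse design it
emulates — two diet groups switched from copepods to *Artemia* nauplii at 6
or 11 days after release (DAR), two replicate tanks per diet, pooled samples
at 6, 11, 18, 25, 32, 46 and 60 DAR — but the machinery is generic for any
single-switch, first-order design.

## Models

Both are first-order one-compartment descriptions of the same relaxation,
parameterized against different progress variables.

**Growth-based (model G).** δ = δ_eq + a·W_R^c, where W_R = W_t/W_i is the
fold-increase in dry weight since the switch, a = δ_i − δ_eq is the initial
offset, and c < 0 the metabolic decay constant. c = −1 is pure growth
dilution (new biomass simply dilutes old tissue); c < −1 means metabolism
also replaces existing tissue.

**Time-based (model D).** δ = δ_eq + a·e^{−(m+k)t}, with t days since the
switch, k = ln(W_R)/t the exponential growth rate computed from endpoint dry
weights and held fixed, and m ≥ 0 the fitted metabolic constant.

Under exactly exponential growth the two are the same curve with
c = −(m+k)/k, a fact the synthetic generator and several tests exploit.

Derived quantities, all closed-form:

- Turnover milestones: G_α = e^{ln(1−α/100)/c} (fold biomass) and
  D_α = |ln(1−α/100)|/(m+k) (days), at α = 50 and 95 by default
  (configurable). The printed form of D_α lacks the absolute value and would
  be negative; the implementation takes the magnitude, which reproduces every
  reported positive day count. D_95/D_50 ≡ ln 0.05/ln 0.5 ≈ 4.32 — tissue is
  effectively at equilibrium after four to five half-lives.
- Partition: P_g = 2(G_50 − 1)/G_50, P_m = (2 − G_50)/G_50. For G_50 > 2 the
  raw P_m is negative; it is clipped to 0 and P_g set to 1 − P_m so the
  fractions always close to 1. The clip encodes "no metabolic contribution",
  matching how such cells are reported in practice.
- Discrimination: Δδ = δ_eq − δ_diet, with cross-model mean ± sd when both
  model fits are available.

## Fitting

`scipy.optimize.least_squares` (trust-region reflective) with analytic
Jacobians; a Levenberg–Marquardt retry only if the bounded solver fails, and
the result always carries an honest `converged` flag. Starting values come
from the monotone shape of a relaxation curve: δ_eq ← last observation,
a ← first − last, c ← −1, m ← 10⁻⁴. Bounds c ∈ [−10, −0.01], m ∈ [0, 1]/day:
a non-negative m and a negative c are the only biologically identified
regions for a system approaching equilibrium. Standard errors are
√diag(s²(JᵀJ)⁻¹) with s² = SS_res/(n−3); `se_from="replicates"` instead uses
the between-replicate spread of per-replicate fits (the provenance of
reported SEs in such studies is often ambiguous; the pooled covariance is
the default). Confidence intervals are t-based with n−3 degrees of freedom.
Fits use replicate-mean series per diet (one parameter set per diet), with
per-replicate fitting available; the k entering model D is the mean of
per-replicate endpoint rates.

Degenerate inputs: a flat δ series yields a ≈ 0 with c (or m) unidentifiable
and is flagged, not raised; fewer than four distinct abscissae is an error.

## Preprocessing

- **Lipid normalization.** Lipids are ¹³C-depleted; tissue with C:N > 3.56
  (strict inequality) is treated as lipid-rich and its δ values multiplied by
  a taxon- and isotope-specific conversion factor (seahorse 0.903/1.019,
  *Artemia* 0.922/1.059, copepod 0.940/1.370 for δ13C/δ15N). **Convention
  flag:** the source factors are bare dimensionless scalars with no stated
  equation; this package applies them multiplicatively (`f · δ_raw`), the
  only reading consistent with dimensionless scalars. If an additive-offset
  or mass-balance convention is ever established, supply custom factors or a
  custom normalizer — the pipeline takes the normalization as a pluggable
  step. Correction is applied only to rows the C:N proxy flags.
- **Weight ratios and growth rates.** W_R is relative to the observed
  switch-day weight (no imputation if it is absent); k uses endpoint weights
  only, exactly as defined, with an OLS-on-log-weights alternative offered
  but never the default.
- **Scale conversion.** Comparing G_α (fold) with D_α (days) needs the
  batch's weight-vs-time relationship. Default: monotone piecewise-linear
  interpolation of ln(weight) against day through the replicate-mean weights;
  a closed-form pure-exponential option (days = ln fold / k) is provided and
  used in tests. The exact transformation behind published cross-scale
  columns in the reference study is unstated and does not reproduce from
  either interpolant (e.g. ln(1.6)/0.0620 = 7.6 d where 8.4 d is printed), so
  those columns are excluded from validation; each model's native-scale
  columns reproduce to one decimal, apart from a few last-digit
  inconsistencies documented in the tests.

## Synthetic experiments

The generator (`paper_default_config`, `simulate_experiment`) emulates the
study conditions: switch days {6, 11}, sampling days {6, 11, 18, 25, 32, 46,
60}, two tanks per diet with four pooled individuals per sample, initial dry
weights 0.80/2.20 mg, endpoint growth rates 0.0620/0.0694 day⁻¹, equilibrium
values and metabolic constants from the time-based model estimates, and
Gaussian analytical noise σ = 0.15‰ (the reported 1-sigma precision of the
measuring laboratory). Switch-day tissue values are set to the copepod
baseline plus the diet's discrimination factor — tissue assumed at
equilibrium with the pre-switch diet — which reproduces the reported ~2.7‰
δ15N rise over the first five post-switch days in the later-switch group.
Weights are exponential with multiplicative lognormal tank-level variation
(`weight_cv`, default 0.15, the typical between-tank CV of the reported mean
dry weights). δ noise is i.i.d. (one pooled sample per tank per day — no
autocorrelation). Rows whose C:N flags lipid-rich tissue are emitted as raw
measurements (model value divided by the taxon factor) so the preprocessing
stage inverts them exactly; `raw_measurements=False` skips this. Randomness
derives from one root seed with per-replicate child streams, so adding a
replicate never perturbs existing ones.

**What the generator does not emulate — and what passing tests therefore do
not show.** Real series carry biological scatter well beyond analytical
noise: the reference fits report R² ≈ 0.78–0.96, whereas σ = 0.15‰ against a
3–7‰ relaxation signal yields R² ≈ 0.998. Recovery and CI-coverage results
on synthetic data certify the estimation machinery, not robustness to
unmodelled biological variation, early-mortality selection, non-exponential
growth (a logistic option exists for robustness exercises), or diet isotope
drift. Weight noise also makes the growth model's regressor noisy
(errors-in-variables), which neither this fitting nor the original analysis
models; the CI-calibration check is therefore run with weight noise off.

## Numerical and design choices

- D_α uses the magnitude of the log term (sign fix above).
- P_m clipping to [0, 1] with renormalization.
- α levels default to (50, 95); any pair in (0, 100) is accepted.
- Display rounding is one decimal for the headline columns and applies only
  at serialization/printing; all stored values are full precision.
- Isotope plausibility windows (δ13C ∈ [−60, 10], δ15N ∈ [−20, 40]) warn but
  never reject.
- Out of scope by design: mass-spectrometry calibration and the δ-from-ion
  ratio computation (inputs are already δ values), survival/growth hypothesis
  testing, Bayesian or multi-compartment models, and model selection (both
  models are reported side by side; neither is "chosen").

## Known limitations

- The multiplicative lipid-normalization convention is an interpretation
  (flagged above).
- Cross-scale turnover conversion depends on the interpolant once growth is
  not exactly exponential; extrapolation beyond the observed day range is
  flagged but linear in log-weight.
- SEs for m truths at the m = 0 boundary are anti-conservative (the estimate
  piles on the bound); the median-near-zero behaviour is tested instead.
- Three published derived cells differ in the last digit from the values
  their own printed inputs imply, and one published G_95/Δδ pair is
  internally inconsistent with its printed c and δ_eq; the package documents
  and excludes these rather than matching them.
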