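# Methods

## Scope and model

`raymix` analyses growth-inhibition assays of binary chemical mixtures laid
out as fixed-ratio *rays*. The response is the inhibition rate

    E = (I0 − Ii) / I0,

with `I0` the pooled mean OD680 of the blank controls and `Ii` the OD680 of
a treatment well. Inhibition vs concentration is modelled by one of two
2-parameter sigmoids of `x = log10(c)`:

    Logit:    E = 1 / (1 + exp(−α − β·x))
    Weibull:  E = 1 − exp(−exp(α + β·x))

with slope `β > 0`. Both are fitted per treatment series by nonlinear least
squares on the per-concentration mean effects, and the better of the two is
selected by adjusted R² (ties broken by RMSE, then by the declared model
order, Logit first). The fit statistics are

    R²_adj = 1 − [(n−1)·SS_res] / [(n−m)·SS_tot],     RMSE = √(SS_res / n),

where `n` is the number of concentration points and `m = 2` the number of
parameters; note the RMSE divisor is `n`, not `n − m` — this is the form
conventionally printed in mixture-toxicity tables and both statistics are
reproduced exactly as defined (the plain R² is stored alongside for
transparency). Designs must supply at least five observations per parameter
(`n ≥ 10`); the default ladder has 12 points.

### Parameter conventions

Published parameter tables in this literature use two incompatible
conventions. Single-compound tables usually print the *mirrored* location,
for which the half-effect concentration is `10^(+α/β)` with `c` in µg/L;
mixture tables often print the location of the verbatim model above with
`c` in g/L, for which `EC50 = 10^(−α/β)`. `FittedCRC` therefore carries an
explicit `conc_scale ∈ {ugL, gL}` and an `alpha_sign ∈ {+1 verbatim, −1
mirrored}`; `ecx()` inverts either convention in closed form, and the
report layer emits single rows in the mirrored µg/L style and mixture rows
in the verbatim g/L style, each row tagged with its convention. Internally
everything is fitted verbatim on µg/L; `with_conc_scale()` shifts the
location by `β·log10(10⁶)` when converting, leaving the curve as a function
of concentration unchanged.

## Experimental design

A series spans the window between the maximum-effect concentration `C_H`
(≈98% inhibition) and the minimum-effect concentration `C_L` (≤1%) with a
geometric ladder `C_k = C_H·F^(k−1)`, `F = (C_L/C_H)^(1/(n−1))`, so points
are equidistant on the log axis. Mixture rays follow the direct
equipartition (EquRay) construction: ray k of n combines k toxic units of
component A with `n+1−k` of B (one toxic unit = that component's EC50),
giving mass fractions `p_A(k) = k·EC50_A / (k·EC50_A + (n+1−k)·EC50_B)`.
Rays are indexed by increasing `p_A`. Fractions are mass-concentration
fractions; they are dimensionless and invariant to a common rescaling of
the two EC50s, so the concentration unit cannot leak into the design. An
extra ray at any stated environmental mass ratio (e.g. 1:10) can be added.

## EC50, NOEC/LOEC, confidence intervals

* **ECx** — closed-form inversion of the fitted sigmoid, with a round-trip
  guarantee (`effect_at(ecx(x)) = x` to 1e−9).
* **NOEC/LOEC** — the assay itself defines "observed effect" only loosely,
  so two procedures are exposed. Default: a one-sided Dunnett many-to-one
  comparison of replicate effects against the control replicates at
  α = 0.05 (LOEC = lowest significant concentration, NOEC = next one
  down). Fallback: a threshold rule calling any mean effect above 1%
  "observed", mirroring the `C_L` design criterion. The Dunnett p-values
  involve a randomized evaluation of the multivariate-t distribution; the
  generator is pinned so repeated runs agree bit-for-bit. Sentinels: NOEC
  is NaN when even the lowest concentration shows an effect (below tested
  range); LOEC is NaN when nothing does (NOEC = highest tested).
* **FCI** (function-based interval) — pointwise delta-method band around
  the fitted curve using the Gauss–Newton covariance `σ²(JᵀJ)⁻¹` and a
  t-quantile on `n − m` degrees of freedom.
* **OCI** (observation-based interval) — per tested concentration,
  `mean ± t_{reps−1, 0.975}·SE` of the replicate mean. This is the
  simplest interval consistent with the name; it is an isolated function
  and can be swapped out.

## Mixture reference models and classification

* **Concentration addition** (Loewe):
  `EC_x,mix = [Σ p_i / EC_x,i]⁻¹`. Reading the CA curve on the effect axis
  requires inverting this relation in `x`; `ca_ecx` is strictly increasing
  in `x`, so a bracketed root search (Brent, tolerance 1e−10 on `x`)
  is used.
* **Independent action** (Bliss):
  `E(c) = 1 − Π(1 − f_i(p_i·c))` with `f_i` the component's best-fit curve
  at its partial concentration.

At each tested concentration the reference prediction is compared with the
95% OCI of the observed mean: inside → additive; prediction below the
interval (observed toxicity stronger) → synergistic; above → antagonistic.
This is the toxicological effect-axis orientation — equivalent to the
observed ECx lying below the CA-predicted ECx — and a configuration switch
(`orientation="concentration_axis"`) flips the non-additive labels for
users who state the rule on the dose axis. The ray-level verdict is the
majority label among points whose fitted effect lies in [0.2, 0.8], the
window where a sigmoid actually discriminates between the hypotheses; ties
resolve conservatively to additive. A secondary summary reports the
majority label in fixed low (<10³ µg/L), medium (10³–2·10⁴) and high
(>2·10⁴) total-concentration bands (edges configurable).

Sham combinations (a compound mixed with itself) recover the single
compound's curve exactly under CA — this is asserted to machine precision.
The 2-parameter sigmoid families are not closed under IA composition, so
the IA sham deviation is reported but not asserted to vanish.

## Synthetic data generator

The generator emulates the assay's statistical structure: a 12-point
geometric ladder per series, 3 replicates, 3 blank controls, one 96 h
OD680 endpoint. The instrument model is

    control OD   ~ N(control_od, σ_od) truncated at 0
    treatment OD = control_od·(1 − E_true(c)) + background + N(0, σ_od),

i.e. noise lives on the absorbance scale by default (an effect-scale noise
channel exists for statistical checks that require iid effect residuals).
Defaults: `control_od = 0.70`, `σ_od = 0.02` — chosen once so that fitted
RMSEs land in the low-0.02 range typical of published fits of this assay.
Design windows default to the concentrations at which the truth reaches 1%
and 98% inhibition, the same criterion a range-finding experiment applies.

Mixture truths are generated from the reference models themselves
(`CA_truth` by numerically inverting the CA combination, `IA_truth` by
Bliss composition). A dose-modification factor κ evaluates the truth at
`κ·c_total`: κ > 1 yields data stronger than CA predicts (synergism-like),
κ < 1 weaker. κ is a harness device for exercising the classifier, not a
toxicokinetic claim. All randomness flows through one seeded NumPy PCG64
generator, so scenarios are bit-reproducible across platforms.

What the generator does **not** emulate: time-resolved growth, hormesis
(non-monotone low-dose stimulation beyond symmetric noise),
concentration-dependent variance, plate-position effects, or chemical
speciation. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data features.

## Numerical choices

* Fits: `scipy.optimize.least_squares` with tolerances 1e−14, multi-start
  (a linearised logit/cloglog regression seed on effects clipped to
  [1e−4, 1−1e−4], plus a coarse slope grid β ∈ {0.5, 1, 2, 4, 8} centred
  at the median log-concentration); best converged objective wins; slope
  bounded below by 1e−12.
* Effects are not truncated to [0, 1] before fitting — noise can push them
  outside and truncation would bias the curve; negative means only warn.
* Degenerate inputs (constant effects, fewer than 10 distinct
  concentrations, zero observed variance) raise typed errors rather than
  returning nonsense.
* The geometric ladder pins its endpoints to `C_H`/`C_L` exactly to
  suppress accumulated floating-point drift.
* Singular covariances degrade gracefully: the fit is kept, the FCI
  collapses with a warning.

## Problem sizes used in the test-suite simulations

Simulation-based checks use the study design (12 points × 3 replicates):
200 refits for Wald-interval and band-coverage checks, 100 seeded runs
each for the additive-truth and dose-modifier classification checks, and
30 refits per noise level for the noise-monotonicity check. These sizes
give Monte-Carlo error comfortably inside the asserted margins.

## Known limitations

* Only binary mixtures and 2-parameter monotone sigmoids; no hormesis or
  4-parameter families, no ≥3-component designs.
* The OCI is a per-point t-interval; it does not account for multiplicity
  across the 12 points of a ray.
* CA/IA predictions use the plug-in best-fit component curves; component
  parameter uncertainty is not propagated into the prediction lines.
* NOEC/LOEC by Dunnett assumes approximately normal, homoscedastic
  replicate effects.
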