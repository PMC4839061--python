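# Methods

## Scope and data model

`tensiofit` analyses equilibrium surface tension γᵉ versus bulk surfactant
concentration C. A `TensionDataset` stores C in mol/m³ (numerically mmol/L),
γᵉ in mN/m, the absolute temperature T and the solvent tension γ₀; rows are
sorted by concentration on construction and validated (positive values,
γᵉ ≤ γ₀ within a 3 % measurement tolerance that reflects typical
tensiometric run-to-run reproducibility). Concentration units are always
declared by the user at I/O time — never inferred — and the reported unit of
the equilibrium constant K follows the declared unit. R and N_A are fixed
CODATA values.

## Adsorption models

All tension equations work in mN/m; RTΓ∞ (N/m) is scaled by 10³ where it
meets a tension.

**Gibbs.** Γ∞ = −s/(nRT) from the OLS slope s of γᵉ on lnC over premicellar
points. The prefactor n (≥ 1) captures dissociation/counter-ion effects; at
high counter-ion excess n ≈ 1, which is the default.

**Langmuir–Szyszkowski.** γᵉ = γ₀ − RTΓ∞ ln(1 + KC), fitted over (Γ∞, K).
Its coverage is θ = KC/(1+KC), which also supplies the per-point coverage
reported with the fit.

**Frumkin.** γᵉ = γ₀ + (RTΓ∞/2)(2ln(1−θ) + βθ²) coupled with
C = θe^(−βθ)/(K(1−θ)). The isotherm is strictly increasing in θ only when
1/θ + 1/(1−θ) − β > 0 for all θ, i.e. β < 4; β is therefore box-constrained
to (−10, 4) and parameter construction rejects β ≥ 4 outright. The inner
inverse C → θ is solved on ln C(θ), which is monotone under that bound, by
Brent's method on θ ∈ (0, 1−10⁻¹²) at ~10⁻¹⁵ relative tolerance; round trips
reproduce C to better than 10⁻⁸ relative everywhere we test.

**Two-region (anchored) variants.** When the premicellar γᵉ–lnC curve has
two slopes, only the upper branch (region 2) is fitted, re-based at the
region-1/region-2 intersection (C₁₂, γ₁₂):

- anchored Frumkin: γ₂ᵉ = γ₁₂ + (RTΓ∞/2)(2ln((Γ∞−Γᵉ)/(Γ∞−Γ₁₂)) +
  β(θ² − θ₁₂²)) and C₂ = C₁₂ + (1/K)(h(θ) − h(θ₁₂)) with
  h(θ) = θe^(−βθ)/(1−θ);
- anchored Langmuir–Szyszkowski: γ₂ᵉ = γ₁₂ − RTΓ∞ ln((1+KC)/(1+KC₁₂)).

Both reduce exactly to the plain equations when the anchor lies on the plain
curve. The anchor coverage Γ₁₂ is not observable from the tension curve and
is fitted as a bounded free parameter (0 < Γ₁₂ < Γ∞, parametrised by a
logistic transform); C₁₂ and γ₁₂ come from segmentation (or the user) and
are held fixed.

## Fitting

The objective is the unweighted sum of squared tension residuals in mN/m,
the convention in this field's regressions; weighted schemes are out of
scope. Positivity of Γ∞ and K is enforced by optimising their logarithms.
Optimisation uses trust-region-reflective least squares with
ftol = xtol = gtol = 10⁻¹⁴ and at most 500 function evaluations per start,
from a fixed multi-start grid: Γ∞ ∈ {0.5, 1, 2, 4} µmol/m², K chosen so the
Langmuir form passes through the mid-curve point at each trial Γ∞,
β ∈ {−2, 0, 2}, and θ₁₂ ∈ {0.3, 0.6} for the anchored Frumkin fit. The start
with the lowest final objective wins; near-ties go to the smallest |β|.
Everything is deterministic: the same data always yield the same fit. An
inner-solve failure at a trial point penalises that trial rather than
aborting; a fit whose curve is essentially flat across the data span is
flagged as non-converged (non-adsorbing input).

On noiseless self-generated data all four nonlinear fitters recover their
generating parameters to ≈10⁻¹¹ relative (the acceptance script recomputes
this). Under 1 % multiplicative noise the information content of a 15-point
curve limits what any estimator can do: a Cramér–Rao calculation at the
package's own operating points shows median |β̂ − β| of ≈0.4 for a
strongly-adsorbing anionic-like truth (Γ∞ = 3.67 µmol/m², β = −0.8) but
≈0.6 for the nonionic-like truth (Γ∞ = 2.84 µmol/m², β = −2.1), and Γ∞
errors of a few percent for both — the measured medians sit at those levels,
and we verified the fitter's objective never exceeds the objective at the
truth, so the scatter is statistical, not algorithmic. For a
weakly-adsorbing truth (RTΓ∞ ≈ 2.9 mN/m, as for large lipopeptides) the
bound is far looser (~18 % median on Γ∞ even for the plain model), which is
why recovery tolerances in the tests differ by parameter set.

## Error metrics

Seven residual metrics are computed with r = γ_exp − γ_cal: RMSE =
√(Σr²/(n−2)); SSE = Σr²; CFEF = Σr²/γ_exp; MPSD = Σ(r/γ_exp)²; ARE =
Σ|r/γ_exp|; EABS = Σ|r|; APE = 100·ARE/n. ARE and MPSD are deliberately
sums rather than means, and RMSE always divides by n−2 regardless of the
model's parameter count, so that the numbers are directly comparable across
models and with published tabulations that use these exact definitions.

## Segmentation

The two premicellar regions and the post-CMC plateau are located in
(lnC, γ) space. The region-1/region-2 anchor is the knot of a continuous
segmented ("hinge") regression γ = γ* + m₁min(x−k,0) + m₂max(x−k,0) +
a·max(x−k,0)², found in two deterministic stages: a global scan that
minimises the plain-hinge residual within every admissible inter-point
interval (≥3 points per side), then a refinement of the three leading
candidates with the quadratic term, the knot confined to one median
point-spacing of each; the curvature-aware residual adjudicates among them,
since the plain model is misspecified on a curved branch and its near-tied
candidates are best separated by the richer model.
The quadratic term matters: an adsorption-isotherm branch is visibly curved
in lnC, and fitting two independent straight lines and intersecting them —
the obvious alternative — mislocates the anchor by ~10–20 % even on
noiseless curves, because the region-2 line is dragged by curvature. The
hinge-with-curvature estimator is unbiased to ~2 % noiseless and reaches a
~20 % median error at 1 % tension noise, close to the two-line-intersection
information limit for these curves.

Collinear input (no two-slope structure) is detected by comparing the hinge
slopes and by checking whether a single line already achieves the hinge's
residual; it yields a degenerate single-segment split with no anchor.
Three-segment fits enumerate every admissible plateau start, give the
plateau its own line (its slope magnitude must be the smallest of the
three), and put the CMC where the region-2 branch meets the plateau line.
The automatic mode of the CLI additionally requires a candidate plateau to
be at least 4× flatter than both premicellar slopes before accepting a
three-segment interpretation, to avoid hallucinating plateaus on purely
premicellar curves. Manual breakpoints override everything.

## Synthetic data

The generator emulates a pendant-bubble dilution series: fractional
coverages θ on a log-spaced grid (default [0.2, 0.97], 15 points) are mapped
through the chosen forward model to (C, γᵉ); optional post-CMC points extend
the curve at constant tension. Noise is multiplicative Gaussian on γ with
coefficient of variation `noise_cv` (default 1 %, capped at 3 % to match the
instrument-reproducibility bound) and truncated at ±3σ, so generated
tensions never exceed γ₀(1 + 3·noise_cv). Defaults are γ₀ = 72.0 mN/m
(water-like solvent at 25 °C) and T = 298.15 K.

Two-slope curves graft a log-linear region-1 branch through the anchor with
slope a configurable multiple (default 2) of the region-2 tangent slope
there, spanning up to one decade below C₁₂ (clipped so γ ≤ γ₀). The dilute
branch is not modelled physically — depletion of the solute from the bulk
has no accepted closed form and only region 2 is ever fitted — the graft
exists to exercise segmentation. A slope multiple of 1 degenerates the curve
to a single log-linear branch. The canonical lipopeptide-like condition used
in tests and the acceptance script is Γ∞ = 1.16 µmol/m², β = 2.8, θ₁₂ = 0.6
with K = 30 m³/mol, C₁₂ = 0.01 mol/m³ and γ₁₂ = 45 mN/m, which places the
CMC near 7×10⁻⁵ M with a plateau near 39 mN/m — the right order of magnitude
for a lipopeptide in buffer.

What passing tests on these curves do **not** show about real data: the
generator has no depletion physics, no systematic drifts or surface-ageing
kinetics, no replicate structure (noise is i.i.d. across concentrations),
and its premicellar branch follows the fitted model family exactly, so
model-misspecification error is absent by construction.

## Known limitations

- K cannot be validated externally; it is only exercised through round
  trips and self-consistent recovery.
- β at 1 % noise on 15 points is identified only to a few tenths at best
  (see the information-limit discussion above); treat small |β| as "no
  resolvable interaction" rather than a measured repulsion/attraction.
- No uncertainty quantification beyond the residual metrics (no bootstrap
  or profile intervals), and no electrical double-layer, mixed-surfactant or
  dynamic-adsorption models.
- Area rounding for reports keeps one decimal only when the first decimal
  digit is 5 (e.g. 61.5 Å²); all other values round to the nearest integer.
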