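# tensiofit

Adsorption-isotherm regression of equilibrium surface-tension data for
surfactants (including biosurfactants such as lipopeptides) self-assembling
at the liquid–air interface.

Pendant-bubble tensiometry of a dilution series yields equilibrium surface
tensions γᵉ at bulk concentrations C. From such a γᵉ–C curve, `tensiofit`
estimates the maximum adsorption density Γ∞ (mol/m²), the adsorption
equilibrium constant K and the lateral interaction parameter β between the
adsorbed molecules, and converts Γ∞ to the interfacial area per molecule
A = 10²⁰/(Γ∞·N_A) in Å².

## Models

With R the gas constant, T the absolute temperature, γ₀ the solvent tension
and θ = Γᵉ/Γ∞ the fractional surface coverage:

* **Gibbs adsorption equation** — `(∂γᵉ/∂lnC)_T = −nRTΓ∞`: Γ∞ from the
  premicellar γᵉ–lnC slope, with the prefactor n ≈ 1 for nonionic
  surfactants and for ionic ones at high counter-ion excess.
* **Langmuir–Szyszkowski** — `γᵉ = γ₀ − RTΓ∞ ln(1 + KC)`: no lateral
  interactions.
* **Frumkin** — the coupled equation of state and isotherm
  `γᵉ = γ₀ + (RTΓ∞/2)(2ln(1−θ) + βθ²)`,
  `C = θ e^(−βθ) / (K(1−θ))`,
  where β > 0 means net attraction between adsorbed molecules and β < 0 net
  repulsion. Fitting requires inverting the isotherm for θ at every trial
  parameter vector; the inverse is well defined for β < 4.
* **Two-region (anchored) variants** — very surface-active solutes can show
  two distinct slopes in the premicellar γᵉ–lnC curve (the dilute branch is
  distorted by depletion of the solute from the bulk). Both the Frumkin and
  Langmuir–Szyszkowski forms are re-based at the region-1/region-2
  intersection (C₁₂, γ₁₂) so that only the reliable upper branch constrains
  the fit; the coverage at the intersection is estimated as a bounded free
  parameter.

Fits are scored by seven residual metrics (RMSE, SSE, CFEF, MPSD, ARE, EABS,
APE), a `segmentation` module locates the two premicellar regions and the
CMC from the data, and a `synthetic` module generates curves with known
ground truth (multiplicative tension noise bounded by the ≤3 % run-to-run
reproducibility typical of the instrument).

## Worked example

```python
import numpy as np
from tensiofit import (IsothermParams, SyntheticSpec, generate, fit_frumkin)

# an anionic-surfactant-like truth: Gamma_inf = 3.67 umol/m2, mild repulsion
truth = IsothermParams(gamma_inf=3.67e-6, K=3.0, beta=-0.8)
spec = SyntheticSpec("frumkin", truth, noise_cv=0.01, n_points=15,
                     coverage_range=(0.3, 0.97), seed=7)
dataset, _ = generate(spec)

result = fit_frumkin(dataset)
print(result.summary())
```

prints

```
=================================================
Model:                frumkin
No. observations:     15
Converged:            True
Gamma_inf (umol/m2):  3.745
Area per molecule:    44.34 A^2
K (m3/mol):           3.143
beta (-):             -1.034
Lateral interaction:  repulsive
RMSE / SSE:           0.4057 mN/m / 2.14 (mN/m)^2
=================================================
```

At 1 % tension noise the saturation density is recovered within ~2 %
(3.745 vs 3.67 µmol/m², i.e. 44.3 vs 45.2 Å² per molecule), the equilibrium
constant within ~5 %, and the interaction parameter to a few tenths — β is
the softest parameter of the Frumkin model at realistic noise. The RMSE of
0.41 mN/m matches the injected noise level (≈1 % of ~50–70 mN/m).
`result.plot()` draws the measured points and the fitted curve;
`result.errors` carries all seven metrics.

The same workflow runs from the shell:

```bash
tensiofit simulate --spec recipe.json --seed 7 --out curve.csv
tensiofit fit --input curve.csv --conc-unit mmol/L --temp 298.15 \
    --gamma0 72.0 --models gibbs,langmuir,frumkin --segment auto --out results/
tensiofit segment --input curve.csv --out split.json
```

`tensiofit fit` writes `results.json` (machine-readable parameters, areas,
error metrics, anchor/CMC) and `report.txt` (aligned parameter and
error-analysis tables).

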