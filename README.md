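# aralogic

Tools for inferring in-vivo transcription-factor activity from
repression-based synthetic reporters and for learning how promoters of the
*E. coli* arabinose regulon (P_araBAD, P_araC, P_araE, P_araFGH) integrate
their two transcriptional inputs, AraC–arabinose and CRP–cAMP.

The package is aimed at systems/synthetic biologists working with
plate-reader luciferase data: it covers the whole chain from raw
OD600/luminescence time series to fitted input-integration rules and
predicted induction kinetics during diauxic shift, plus a seeded synthetic
generator so the entire analysis is testable without wet-lab data.

## The model

A repression reporter is a constitutive σ70 promoter with the factor's
operator immediately downstream; its expression at factor activity *A\** is

    S = α_rep / (1 + A*) + T

with activation span α_rep and basal level *T*. Inverting this curve (and
clamping negative solutions to zero) turns measured expression into the
dimensionless activities *A\** (AraC–arabinose) and *C\** (CRP–cAMP), while a
bare constitutive reporter measures the polymerase signal σ.

Steady-state promoter expression *B* is modelled additively over the bound
states — AraC alone, CRP alone, both:

    B = σ (α A* + β C* + γ A* C*) + T_B

fitted by nonlinear least squares. Coefficients insignificant at p = 0.05
are dropped and the reduced model refit; the two fits are compared by
residual standard error and AIC. For all four promoters the CRP-alone term
β is the one that drops, leaving AND-like logic (γ) with an AraC-alone
component (α). Dynamics during diauxic shift follow

    dB/dt = σ(t) (α A*(t) + γ A*(t) C*(t)) + T_B − μ B

where μ is first-order loss: dilution ln 2/τ for long-lived products, plus
a degradation constant (0.0833 min⁻¹) for the short-lived AraC.

## Worked example

Simulate a 96-well arabinose × cAMP gradient from the P_araBAD coefficient
set with 5 % multiplicative noise, fit the full three-term model, and reduce
it:

```python
import numpy as np
from aralogic import (GradientDesign, REFERENCE_COEFFICIENTS,
                      simulate_gradient_expression, reduce_and_compare)

rng = np.random.default_rng(1)
data = simulate_gradient_expression(
    GradientDesign(), REFERENCE_COEFFICIENTS["araBAD"],
    noise_sigma=0.05, rng=rng,
)
comp = reduce_and_compare(data)
sel = comp.reduced if comp.selected == "reduced" else comp.full
print("dropped:", list(comp.dropped), "| selected:", comp.selected)
print(f"alpha = {sel.coefficients.alpha:.3f}  (p = {sel.p_values['alpha']:.2e})")
print(f"gamma = {sel.coefficients.gamma:.3f}  (p = {sel.p_values['gamma']:.2e})")
print(f"AIC full = {comp.full.aic:.2f}  reduced = {comp.reduced.aic:.2f}")
```

prints

```
dropped: ['beta'] | selected: reduced
alpha = 2.706  (p = 2.05e-31)
gamma = 4.230  (p = 1.33e-77)
AIC full = -179.84  reduced = -181.50
```

The data were generated without a CRP-alone contribution, and the fit agrees:
β is statistically indistinguishable from zero and removing it improves the
AIC, while α and γ land close to the generating values (2.535 and 4.347).
The same machinery is available sklearn-style via
`PromoterIntegrationModel(...).fit(X, y)` with `X = (A*, C*, σ)` columns,
and the full pipeline (simulate → activities → fit → reduce → predict the
diauxic shift → score) runs with `aralogic run-all --seed 1 --outdir results`.

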