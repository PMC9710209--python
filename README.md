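# oligoflux

Analysis pipeline for antibody screening against α-synuclein aggregation:
thioflavin-T (ThT) kinetic-trace fitting, the analytical **oligomer flux**
framework, saturation-binding (K_D) estimation, single-molecule pull-down
(SiMPull) spot counting, and super-resolved aggregate morphometrics — plus
synthetic-data generators so every stage can be exercised and validated
without instrument raw data.

It is aimed at protein-aggregation labs screening inhibitors (e.g. designed
single-domain antibodies, DesAbs) for their effect on secondary nucleation,
and at single-molecule imaging groups quantifying aggregate load and shape
in biofluids.

## The model

Seeded aggregation is treated in the linear polymerisation picture
`dM/dt = 2k₊P·m` (M: normalized fibril mass, m = 1 − M: monomer fraction,
P: fibril number). High-seed traces isolate elongation: the slope of the
first six points is the effective elongation rate r₊ ∝ 2k₊P(0)m(0),
interpreted relative to the antibody-free control. Low-seed traces, where
secondary nucleation dominates, are fitted with a generalized logistic

    M(t) = 1 − [1 + (c/a)·e^{κt}]^{−1/c},   c fixed at 0.3,

with κ the effective growth rate (elongation × secondary nucleation) and
λ = κ√(2/a) the primary-nucleation combination. The net flux toward
oligomeric species is φ(t) = dP/dt with P = M′/(r₊m); substituting the
logistic gives closed forms for the bell-shaped profile and its summaries
(u = (c/a)e^{κt}):

    φ(t) = κ²u / (r₊c(1+u)²),   φ_Area = κa / (r₊c(a+c)),
    φ_Time = ln(a/c)/κ,          φ_Peak = κ² / (4r₊c).

φ_Peak, φ_Area and φ_Time — each reported relative to the control mean —
summarize how strongly, how much and how late a condition generates
oligomers; an effective inhibitor lowers the first two and delays the third.
Binding titrations are fitted with the saturation equation
`Y = B_Max·x/(K_D + x)`; TIRF stacks are frame-averaged and spots counted as
robust local maxima; localization tables are clustered into aggregates whose
length, area, eccentricity and circularity are measured. See
`docs/methods.md` for assumptions, estimator choices and limitations.

## Worked example

Simulate a control and an inhibited low-seed experiment, fit the logistic,
and compare oligomer fluxes; then fit a binding titration:

```python
import numpy as np
from oligoflux import (
    KineticGroundTruth, gen_tht_traces, fit_logistic, compute_flux,
    normalize_metrics, gen_binding_curve, zero_floor, fit_saturation,
)
from oligoflux.synthetic import default_time_grid

t = default_time_grid(2000.0, 2.0)  # minutes
control = gen_tht_traces(KineticGroundTruth(a=50, kappa=0.020, seed=1), t)
treated = gen_tht_traces(KineticGroundTruth(a=50, kappa=0.012, seed=2), t)

fit_ctrl, fit_trt = fit_logistic(control), fit_logistic(treated)
print(f"control: kappa = {fit_ctrl.kappa:.4f} /min, t_half = {fit_ctrl.t_half:.0f} min")
print(f"treated: kappa = {fit_trt.kappa:.4f} /min, t_half = {fit_trt.t_half:.0f} min")

r_plus = 0.002  # effective elongation rate from the high-seed assay
profiles = {"control": [compute_flux(fit_ctrl, r_plus)],
            "DesAb": [compute_flux(fit_trt, r_plus)]}
rel = normalize_metrics(profiles)["DesAb"]
print(f"DesAb vs control: phi_peak_rel = {rel.phi_peak_rel[0]:.2f}, "
      f"phi_area_rel = {rel.phi_area_rel[0]:.2f}, phi_time_rel = {rel.phi_time_rel[0]:.2f}")

curve = zero_floor(gen_binding_curve(kd=1.2, bmax=10.0, top_conc=100.0,
                                     noise_sd=0.1, seed=3))
bf = fit_saturation(curve)
print(f"K_D = {bf.kd:.2f} uM, B_Max = {bf.bmax:.2f}, R^2 = {bf.r_squared:.3f}")
```

Output:

```
control: kappa = 0.0201 /min, t_half = 183 min
treated: kappa = 0.0120 /min, t_half = 304 min
DesAb vs control: phi_peak_rel = 0.36, phi_area_rel = 0.60, phi_time_rel = 1.67
K_D = 1.25 uM, B_Max = 9.84, R^2 = 0.998
```

The fits recover the generating parameters (κ = 0.020 and 0.012 /min; K_D =
1.2 μM within the noise), and the inhibited condition shows the signature of
reduced secondary nucleation: a lower, smaller and later oligomer flux
(φ_peak 0.36×, φ_area 0.60×, φ_time 1.67× the control).

A CLI wraps the same stages (`oligoflux simulate | fit-kinetics | flux |
fit-binding | bli-correct | count-spots | shapes | compare`), each accepting
`--config`, `--seed` and `--out-dir` and writing CSV outputs plus a run log.

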