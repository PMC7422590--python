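# egpest

Tracer-free estimation of liver endogenous-glucose-production (EGP)
parameters from diurnal plasma glucose, insulin and insulin-secretion-rate
(ISR) curves.

## The problem

EGP — the release of glucose into blood, chiefly by the liver — is
suppressed after a meal and recovers over ~4 hours. Measuring it directly
requires triple-tracer isotope experiments that are too expensive for
large studies. `egpest` implements a procedure that estimates the
parameters of a standard liver EGP subsystem **without tracer data**, using
only quantities measurable in an ordinary three-meal protocol: plasma
glucose G (mg/dl), plasma insulin I (pmol/l) and the insulin secretion rate
ISR (pmol/kg/min), sampled on minutes-since-meal grids for breakfast, lunch
and dinner, plus one basal EGP value per meal.

## The model

EGP is affine in three liver inputs,

```
EGP(t) = kp1 − kp2·Gp(t) − kp3·Id(t) − kp4*·Ipo(t)
```

where `Gp = G·Vg` is the plasma glucose mass (mg/kg), `Id` is plasma
insulin passed through a two-compartment first-order chain with rate `ki`
(delayed insulin action), `Ipo = ISR/γ` is portal insulin (pmol/kg), and
`kp4* = A·kp4` during breakfast only (`A` captures the morning shift in
insulin sensitivity). `Vg`, `ki`, `γ` are fixed constants chosen from the
fasting glucose (healthy / type-2-diabetic reference values with linear
interpolation between 99 and 126 mg/dl). Per segment, `kp1` is anchored so
that `EGP(0)` equals the measured basal EGP:

```
kp1 = EGP_b + kp2·Gp_b + kp3·Id_b + kp4*·Ipo_b
```

**Tracer-free route.** For each meal, form the coefficients
`C23 = kp2·Gp_b − kp3·Id_b`, `C24 = kp2·Gp_b − kp4*·Ipo_b`,
`C34 = C24 − C23` from the basal anchors. The working assumption is that
these do not vary across the three meals of one day; the estimator
minimises

```
obj(θ) = sqrt( Σ_{meal pairs} (ΔC23 + ΔC24 + ΔC34)² )  =  2·sqrt( Σ ΔC24² )
```

over bounds `kp2 ∈ [0.0009, 0.02]`, `kp3 ∈ [0.001, 0.05]`,
`kp4 ∈ [0.01, 0.09]`, `A ∈ [0.8, 1.4]` with 150-start bounded least
squares. The reduction to C24 differences means the objective identifies
**only the ratio kp2/kp4 and A**; kp3 and the common scale of
(kp2, kp3, kp4) are structurally undetermined and are reported as found —
the profile-likelihood module quantifies exactly this.

**Direct (reference) route.** When measured EGP curves exist, the same
machinery minimises the root total squared misfit
`V = sqrt(ΣΣ (EGP_calc − EGP_exp)²)`, recovering all four parameters when
the input deviations are linearly independent.

**Identifiability.** Profile likelihood on the weighted misfit
`χ² = ΣΣ ((y_exp − y_calc)/σ)²` with `σ = 0.10·y + 0.05·max(y)`:
each parameter is stepped away from the optimum (multiplicative 2% steps)
while the others are re-fitted, until the χ² increase crosses
`Δα = Q_χ²(0.68, df)` (≈ 0.9889 for df = 1). Finite interval on both sides →
identifiable; open on one side → practically non-identifiable; flat → 
structurally non-identifiable.

## Worked example

The built-in generator produces three-meal datasets on the standard
0–240 min grid with known truth. In consistency mode the meal-invariance
assumption holds exactly, so the tracer-free estimate can be checked
against the generating parameters (here kp2/kp4 = 0.05556, A = 0.90):

```python
from egpest import GeneratorConfig, LiverEGPModel, generate_dataset

synth = generate_dataset(GeneratorConfig(consistency_mode=True, seed=11))
model = LiverEGPModel(synth.dataset)   # constants picked from fasting glucose
res = model.fit(seed=11)               # tracer-free, 150 multistarts
print(res.summary())
```

```
Tracer-free liver EGP parameter estimation
==========================================================
n starts                           150   converged 131
seed                                11
objective (mg/kg/min)            4.320e-11
----------------------------------------------------------
parameter         estimate  identified?
kp2              0.0020719  ratio kp2/kp4 only
kp3               0.049999  no (structural)
kp4               0.037294  ratio kp2/kp4 only
A                      0.9  yes
kp2/kp4           0.055556  yes
==========================================================
```

The objective reaches ~1e-11 (the invariance assumption is satisfiable),
`A` and the ratio match the truth to ~1e-12, while the individual kp2/kp3/
kp4 values are one arbitrary point of the zero-objective continuum — read
them together with `model.profile()` / `summary_table`, which classifies
kp3 as structurally non-identifiable from tracer-free data. With measured
EGP curves, `model.fit_direct(seed=7)` pins all four parameters
(cost ~2e-13 and exact recovery on noise-free synthetic data).

The same workflow is available from the shell:

```
egpest simulate --consistency --seed 11 --out-dir run/
egpest estimate run/dataset.csv --seed 11 --out-dir run/
egpest directfit run/dataset.csv --seed 11 --out-dir run/
egpest profile run/dataset.csv --seed 11 --out-dir run/
```

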