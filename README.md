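# deepcompartment

Constrained deep compartment models for population pharmacokinetics.

Clinicians dosing factor VIII (FVIII) concentrate in haemophilia A face a
familiar problem: weight-based dosing leaves large between-patient spread in
achieved drug levels, and classical population-PK covariate modelling — the
tool for individualizing doses — is slow, expert-driven work.  A *deep
compartment model* (DCM) replaces the hand-built covariate model with a
neural network while keeping the mechanistic core: the network maps patient
covariates $x^{(i)}$ to the PK parameters
$\zeta^{(i)} = (CL, V_1, Q, V_2) = \phi(x^{(i)}; w)$ of a two-compartment
system

$$\dot A_1 = \mathrm{In}(t) + k_{21}A_2 - (k_{10}+k_{12})A_1,\qquad
\dot A_2 = k_{12}A_1 - k_{21}A_2,$$

with $k_{10}=CL/V_1$, $k_{12}=Q/V_1$, $k_{21}=Q/V_2$, doses applied as
events, and weights fitted by minimizing
$\sum_i\sum_k\bigl(y^{(i)}_k - C(t^{(i)}_k;\zeta^{(i)})\bigr)^2$.

Unconstrained networks fitted to sparse data (three samples per patient)
routinely learn absurd concentration–time curves between the observations.
This package implements the DCM together with three architectural
constraints that restore robustness — physiological **bounds** on the
parameters, **global** population-level scalars for the unidentifiable
distribution parameters Q and V2, and an interpretable **multi-branch
product network** in which each covariate subset feeds its own sub-model
and the factors multiply, as in classical covariate models — plus a
synthetic-study generator and the Monte Carlo cross-validation harness used
to measure robustness (median true-curve RMSE, and the *divergence rate*:
the share of trained replicates whose test RMSE exceeds 150 % of the
median).

It is written for pharmacometricians and ML-for-PK researchers who want a
small, fully reproducible NumPy implementation to experiment with hybrid
model constraints.

## Worked example

```python
import deepcompartment as dc
from deepcompartment.evaluate import global_spec, monte_carlo_cv, naive_spec

# a virtual haemophilia-A study: 120 subjects, 50 IU/kg bolus,
# samples near 4/24/48 h, additive noise sigma = 5 IU/dL
study = dc.simulate_population(dc.PopulationConfig(n=120, seed=42))
dataset = study.to_dataset(["weight", "height", "age"])

fit = dc.train(dataset.subset(range(60)),
               global_spec(("weight", "height", "age")),
               dc.TrainingProtocol(epochs=500, seed=0))
print(f"final training loss: {fit.history[-1]:.1f} (IU/dL)^2")

z = fit.predict_parameters(dataset.subset([60]))[0]
print(f"predicted CL={z[0]:.3f} L/h, V1={z[1]:.2f} L, "
      f"Q={z[2]:.3f} L/h, V2={z[3]:.2f} L")
```

prints

```
final training loss: 21059.7 (IU/dL)^2
predicted CL=0.172 L/h, V1=3.99 L, Q=0.250 L/h, V2=0.83 L
```

The loss of ≈ 21 000 over 180 observations corresponds to a residual of
≈ 11 IU/dL per sample — the additive noise (5 IU/dL) plus the
inter-individual variability that covariates cannot explain.  The held-out
subject (118 kg, 23 y) gets a clearance of 0.172 L/h and a central volume
of 4.0 L; the Q and V2 values are the shared global estimates.

The robustness contrast that motivates the constraints:

```python
res = monte_carlo_cv(
    study,
    {"naive": naive_spec(("weight", "height", "age")),
     "global": global_spec(("weight", "height", "age"))},
    sizes=(20,), n_splits=5, n_reps=2, seed=1,
)
print(res.aggregates[["architecture", "median_rmse", "divergence_pct"]]
      .round(2).to_string(index=False))
```

```
architecture  median_rmse  divergence_pct
       naive        11.56            30.0
      global        10.70            10.0
```

Both models reach similar *typical* accuracy, but with only 20 training
subjects 30 % of naive replicates diverge (test RMSE > 1.5× the median,
driven by collapsed central-volume estimates that predict absurd peaks for
extrapolated subjects) against 10 % for the global-parameter model.

## Command line

```bash
dcm simulate --n 300 --seed 1 --out runs/study
dcm fit      --data runs/study/study.csv --arch causal --out runs/fit
dcm crossval --data runs/study/study.csv --arch naive --arch global \
             --sizes 20,120 --splits 10 --reps 3 --out runs/cv
dcm effects  --checkpoint runs/fit/checkpoint.json --out runs/fx --plot
dcm predict  --checkpoint runs/fit/checkpoint.json \
             --data runs/study/study.csv --out runs/pred.csv
```

Every command is byte-reproducible under a fixed `--seed` and writes a
`run.json` log with the configuration hash.  Event tables are CSV with
NONMEM-like columns (`ID, TIME, DV, AMT[, RATE|DUR]`, covariates).

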