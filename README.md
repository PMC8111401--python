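# radpk

Population pharmacokinetics of lisinopril in irradiated vs. non-irradiated
rats: a tested, reusable implementation of the analysis pipeline behind a
radiation-countermeasure PK study.

ACE inhibitors such as lisinopril are leading candidates for mitigating the
delayed organ injuries caused by high-dose radiation exposure. Licensing
them for that indication requires knowing whether irradiation itself
changes the drug's kinetics. The study this package reimplements compared
single-dose lisinopril disposition in female WAG/RijCmcr rats 35 days after
partial-body irradiation against non-irradiated siblings, using sparse
plasma sampling (1–4 draws per animal), single 24-h cumulative urine
collections, and both oral (gavage) and IV dosing. `radpk` is for
pharmacometricians and biostatisticians who want to reproduce, stress-test
or extend that analysis.

## What it implements

**Structural model.** A linear two-compartment model with a gut depot and a
urine output:

    dY_depot/dt  = -ka Y_depot
    dY_plasma/dt = +F ka Y_depot - Cl C2 - Q C2 + Q Y_peri/V3
    dY_peri/dt   = +Q C2 - Q Y_peri/V3
    dY_urine/dt  = +Cl C2,          C2 = Y_plasma / V2

solved exactly (matrix exponential / closed-form exponentials; no ODE
stepping). Secondary quantities: micro-constants, disposition eigenvalues,
terminal half-life ln2/β, AUC(0,∞) = F·D/Cl.

**Mixed-effects estimation** (`radpk.fit`): radiation enters as
multiplicative group ratios on ka, Cl, Q and F; animals carry log-normal
random effects on V2 and V3; residual error is additive per observed
compartment (plasma concentration, cumulative urine amount). The marginal
likelihood uses a vectorised Laplace approximation; inference is maximum
likelihood with Wald intervals and per-ratio tests, plus a likelihood-ratio
test against the nested one-compartment model.

**Non-compartmental analysis** (`radpk.auc_ratio`, `radpk.bootstrap_t_ci`):
dose-normalised trapezoidal AUC(0–tlast) over per-time-point arithmetic
means with bootstrap-t intervals, resampling animals within time-point
batches (serial-sampling design), and the irradiated/control AUC ratio.

**Synthetic studies** (`radpk.simulate_study`): the original 219-animal
design (radiation × route × dose cells, scheduled sampling menus, urine
collections) with the stated stochastic structure, so the whole pipeline is
testable without the undeposited animal data.

## Worked example

```python
import radpk

# reference typical values (control rats) and radiation effect ratios
print(f"control t1/2    = {radpk.terminal_half_life(radpk.CONTROL_PARAMS):.1f} h")
irr = radpk.apply_radiation(radpk.CONTROL_PARAMS, radpk.RADIATION_RATIOS)
print(f"irradiated t1/2 = {radpk.terminal_half_life(irr):.1f} h")
print(f"irradiated F    = {irr.F:.3f}")

# simulate a compact two-group study and refit it
cfg = radpk.default_config(seed=1, design=radpk.reduced_design())
records = radpk.simulate_study(cfg)
result = radpk.fit(records, config=radpk.FitConfig(seed=1))
for name in ("ka", "F", "Cl", "Q", "V2", "V3", "r_ka", "r_Cl", "r_Q", "r_F"):
    lo, hi = result.ci[name]
    p = result.pvalues.get(name)
    tail = f"  p = {p:.2g}" if p is not None else ""
    print(f"{name:5s} {result.estimates[name]:8.4f}  [{lo:.4f}, {hi:.4f}]{tail}")

ratio = radpk.auc_ratio(records, B=1999, seed=1)
print(f"AUC(0-24h) ratio irradiated/control = {ratio.ratio:.2f} "
      f"[{ratio.ci_low:.2f}, {ratio.ci_high:.2f}], p = {ratio.p_value:.3g}")
```

prints

```
control t1/2    = 65.3 h
irradiated t1/2 = 83.5 h
irradiated F    = 0.255
ka      0.2858  [0.2621, 0.3116]
F       0.1750  [0.1548, 0.1973]
Cl      0.0090  [0.0079, 0.0103]
Q       0.0116  [0.0094, 0.0144]
V2      0.0081  [0.0072, 0.0091]
V3      0.5482  [0.3839, 0.7829]
r_ka    0.7908  [0.7236, 0.8643]  p = 2.3e-07
r_Cl    0.9489  [0.8080, 1.1144]  p = 0.52
r_Q     0.7312  [0.5823, 0.9181]  p = 0.007
r_F     1.5412  [1.3622, 1.7437]  p = 6.6e-12
AUC(0-24h) ratio irradiated/control = 1.72 [1.60, 1.88], p = 0.0005
```

Reading the output: the slow disposition eigenvalue of the reference
parameters gives a 65 h terminal half-life in controls and 83 h once the
radiation ratios (notably the 0.615 drop in inter-compartmental clearance)
are applied — lisinopril lingers because it re-enters plasma slowly from
the large peripheral (tissue-bound) pool. The refit of a simulated 38-animal
study recovers the generating values (ka 0.279, F 0.192, Cl 0.009,
Q 0.014, V2 0.008, V3 0.513) within its confidence intervals, and both the
bioavailability ratio (r_F, truth 1.326) and the distribution-clearance
ratio (r_Q, truth 0.615) are detected as significant, while renal clearance
(r_Cl, truth 0.943) rightly is not. The model-free AUC contrast agrees:
irradiated animals carry substantially more circulating drug over the first
24 h per µg dosed.

## Command line

```sh
radpk simulate --seed 1 -o study.csv        # synthetic study, full design
radpk validate study.csv                    # schema check with row diagnostics
radpk fit study.csv --params-out params.csv --report-out report.json
radpk nca study.csv --tlast 24 --boot 2000 --seed 1 -o nca.csv
```

Datasets are CSV with columns `ID,GROUP,ROUTE,DOSE_UG,TIME,CMT,DV,EFF`
(`CMT` ∈ {plasma, urine}; `DV` raw measured value; `EFF` extraction
efficiency, divided out before analysis).

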