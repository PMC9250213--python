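# csfclear

Population pharmacokinetics of cerebrospinal-fluid-to-blood tracer
clearance.

After a lumbar intrathecal injection, the MRI contrast agent gadobutrol
leaves the CSF along extra-vascular routes and appears in venous blood over
the next one to two days. Because the tracer cannot cross the blood–brain
barrier, its appearance in blood is a direct readout of CSF-to-blood
clearance — relevant for characterizing CSF disorders (hydrocephalus,
intracranial hyper-/hypotension, cysts) and for dosing intrathecal drugs.
This package estimates that clearance from sparse venous concentration–time
profiles and compares it across diagnosis groups. It is written for
pharmacometricians and quantitative neuroscientists who want the full
estimation chain — simulation, fitting, individual prediction, group
statistics — as inspectable, testable Python.

## The model

A depot (CSF) compartment drains into a central (blood) compartment with
first-order rate `Ka` after a lag `Tlag`; blood exchanges with a peripheral
tissue compartment (`Kcp`, `Kpc`) and eliminates with rate `Ke`:

    dAd/dt = −Ka·Ad                      (t > Tlag; Ad(0) = dose)
    dAc/dt =  Ka·Ad − (Ke+Kcp)·Ac + Kpc·Ap
    dAp/dt =  Kcp·Ac − Kpc·Ap            C(t) = Ac/V

Profiles are closed-form (partial fractions over the three exponentials; no
step-size error). `T1/2,abs = ln2/Ka` is the absorption half-life — the
surrogate for CSF-to-blood clearance. The population distribution of
`(Ka, Tlag, V, Ke, Kcp, Kpc)` is estimated nonparametrically as weighted
support points maximizing the mixture likelihood (adaptive-grid NPML with a
monotone EM inner solver and per-subject likelihood-peak seeding), and each
subject gets a Bayesian posterior over the support. Derived metrics
(`T1/2,abs`, `Tmax`, `Cmax`, `Tlag`, `AUC0-∞`, dose-normalized forms) come
from 1-minute prediction grids to 72 h at the posterior-mean parameters.
Because the study's patient-level data is available only on request, a
calibrated synthetic cohort generator (161 subjects, 8 diagnosis groups,
0.10/0.25/0.50 mmol dose arms) stands in for it; see `docs/methods.md` for
the model, calibration and its limits.

## Worked example

Simulate a reference cohort, fit the population model, and derive each
subject's clearance metrics:

```python
import dataclasses
from csfclear import (AssayErrorModel, FitConfig, default_study_config,
                      simulate_cohort, fit, posterior_individual, derive_all)

cfg = default_study_config(seed=7)            # the full 161-subject design
ref = next(g for g in cfg.groups if g.name == "REF")
ref = dataclasses.replace(ref, n_subjects=28,
                          dose_allocation={0.10: 0, 0.25: 0, 0.50: 28})
cfg = dataclasses.replace(cfg, groups=(ref,))

subjects, truth = simulate_cohort(cfg)
model = fit(subjects, cfg.noise, FitConfig(structure="two_compartment", seed=7))
for s in subjects[:3]:
    post = posterior_individual(s, model, cfg.noise)
    m = derive_all(post, s.dose)
    print(f"{s.id}: T1/2,abs {m.t_half_abs:.2f} h  Tmax {m.t_max:.1f} h  "
          f"Cmax {m.c_max_dn:.2f} uM  AUC {m.auc_dn:.1f} uM*h")
```

```
REF-001: T1/2,abs 5.85 h  Tmax 6.0 h  Cmax 0.56 uM  AUC 11.5 uM*h
REF-002: T1/2,abs 1.92 h  Tmax 4.6 h  Cmax 0.94 uM  AUC 15.0 uM*h
REF-003: T1/2,abs 1.78 h  Tmax 3.5 h  Cmax 0.98 uM  AUC 14.5 uM*h
```

Each line is one subject's posterior estimate: the absorption half-life
(time for half the tracer to clear from CSF to blood), the time and height
of the blood peak (dose-normalized to the 0.50 mmol arm), and total
systemic exposure. The threefold spread in half-life across three subjects
is the point — inter-individual variability in CSF clearance is large even
within a reference group.

The full study pipeline is laid out as numbered drivers:

```bash
python analysis/01_simulate_cohort.py      # 161 subjects, 8 groups, 3 arms
python analysis/02_blood_plasma_ratio.py   # regression through the origin
python analysis/03_fit_population_model.py # split, select 1- vs 2-cpt, refit
python analysis/04_derive_pk_metrics.py    # posterior metrics + group table
python analysis/05_group_statistics.py     # contrasts, ANOVA, correlations
```

On the default synthetic cohort this chain prints, among other things, a
plasma/whole-blood slope of 1.792 (truth 1.795, adjusted R² 0.999 at
n = 204), selects the two-compartment structure (development RMSE% 12.5 vs
13.1 for one compartment), and recovers the built-in group structure: the
intracranial-hypertension group peaks earlier with higher exposure than the
reference cohort, the normal-pressure-hydrocephalus group shows greater
dose-normalized exposure, and across dose arms only the dose-normalized
AUC differs significantly — the same dose-linearity picture the design
encodes. Small summary tables land in `results/`; bulky per-sample
intermediates go to `scratch/`.

A thin `csfclear` CLI (`simulate`, `fit`, `metrics`, `report`) wraps the
same functions for shell use.

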