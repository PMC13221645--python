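# frapdyn

Quantitative tools for two complementary views of nuclear-protein dynamics:

* **FRAP binding kinetics** — normalize fluorescence-recovery-after-
  photobleaching intensity traces and fit the Sprague two-state binding
  model to estimate how much of a protein population is freely mobile,
  transiently bound, weakly bound, or stably trapped on chromatin (the
  immobile fraction).  The motivating application is topoisomerase 1:
  drug-stabilized Top1–DNA cleavage complexes show up in FRAP as a growing
  immobile fraction.
* **Elastic-network / ensemble dynamics** — anisotropic network model (ANM)
  normal modes from Cα coordinates and per-residue RMSF profiles from
  superposed conformational ensembles, the standard protocol for asking
  which region of a protein (e.g. a flexible linker domain) carries the
  dominant collective motion.

A synthetic-data module generates every input the pipeline consumes —
noisy FRAP cohorts with known ground truth, toy two-domain/linker
structures, and synthetic ensembles — so the whole analysis is testable
end to end without microscopy or MD data.

## The model

Normalized recovery curves are fitted with the two-state binding model

```
frap(t) = (F_eq + C1_eq) [ e^{-x} (I0(x) + I1(x)) ] + C2_eq (1 - e^{-k2_off t}),
          x = tau1_eff / (2 t)
```

where `F_eq`, `C1_eq`, `C2_eq` are the equilibrium fractions of the free
and the two bound states, `tau1_eff` is the effective recovery time of the
diffusion-coupled population, `k2_off` the dissociation rate of the weakly
bound state, and `I0`, `I1` are modified Bessel functions of the first
kind.  The plateau `F_eq + C1_eq + C2_eq` is the mobile fraction; its
deficit from 1 is the immobile fraction.  Curves are normalized full-scale,
`F_norm(t) = (F(t) - F0) / (F_prebleach - F0)`, after frame-wise background
correction; the percent-of-prebleach form
`ROI(t) = (I_t - I_bg)/(I_o - I_bg) x 100` is also provided.

The ANM connects Cα atoms within 15 Å by uniform springs; the lowest
non-trivial eigenmode ("Mode 1") gives per-residue mobility amplitudes
(unscaled eigenvector norms).  Ensembles are superposed onto their first
frame with a proper Kabsch rotation before computing per-residue RMSF.

## Worked example

```python
import numpy as np
import frapdyn as fd

truth = fd.TwoStateParams(f_eq=0.49, c1_eq=0.0, c2_eq=0.21,
                          tau1_eff=2.0, k2_off=0.05)   # immobile 0.30
trace = fd.simulate_frap_trace(truth, noise=fd.NoiseModel(sigma_add=0.02, seed=3))
curve = fd.normalize_full_scale(trace)
fit = fd.fit_two_state(curve)
rep = fd.summarize_fractions(fit)
print(f"mobile {rep['mobile_pct']:.1f}%  immobile {rep['immobile_pct']:.1f}%  "
      f"tau1_eff {rep['tau1_eff_s']:.2f} s  k2_off {rep['k2_off_per_s']:.3f} /s")
```

prints (seed 3):

```
mobile 70.6%  immobile 29.4%  tau1_eff 2.34 s  k2_off 0.044 /s
```

i.e. the fit recovers the generating truth (70% mobile, 30% immobile,
tau ~2 s, k2_off ~0.05/s) from a single noisy cell.  The same estimator is
available as a scikit-learn regressor (`fd.TwoStateFrapModel`) with
`fit(t, y)` / `predict(t)` and fitted attributes `params_`, `result_`.

On the structural side:

```python
s = fd.make_toy_structure("two_domain_linker", 40)   # chains A / L / B
anm = fd.AnisotropicNetworkModel(cutoff=15.0, n_modes=10).fit(s)
mob = anm.mobility(mode_index=1)
chains = np.array([r[0] for r in s.residue_ids])
ratio = np.median(mob.values[chains == "L"]) / np.median(mob.values[chains != "L"])
print(f"zero modes: {anm.n_zero_modes_}, linker/domain Mode-1 ratio: {ratio:.1f}")
```

```
zero modes: 6, linker/domain Mode-1 ratio: 2.6
```

— the flexible linker joining two compact domains carries the dominant
low-frequency motion, mirroring the behaviour expected of a linker "brake"
region in a two-domain enzyme.

Everything is scriptable from the shell too:

```bash
frapdyn simulate --truths truths.csv --out cohort/ --seed 1
frapdyn fit --input cohort/traces.csv --out results/ --seed 1
frapdyn make-fixture --kind two_domain_linker --n 40 --out toy.pdb
frapdyn enm-modes --pdb toy.pdb --cutoff 15 --n-modes 10 --mode 1 --out mobility.csv
frapdyn enm-rmsf --traj ensemble.pdb --selection ca --out rmsf.csv
```

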