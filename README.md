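# liverkin

Kinetic estimation for **short-term dynamic liver FDG-PET**.

Fully dynamic liver PET takes an hour per patient; a short-term
protocol — 5 minutes of dynamic frames (12 x 5 s, 4 x 60 s) plus one
1-minute static sample at 60 minutes post-injection — captures almost
the same kinetic information.  `liverkin` implements the estimation
chain for that protocol:

* the **dual-input two-tissue compartment model** for liver tissue,
  with input `C_B(t) = HPI * A(t) + (1-HPI) * V(t)` mixing the aortic
  and portal-vein curves by the hepatic perfusion index (HPI), tissue
  response `C_T = (1-Vb) * h (*) C_B + Vb * C_B`, and bi-exponential
  impulse response `h` with macro rates from [K1, k2, k3, k4];
* the **maximum-slope perfusion method** with gamma-variate
  recirculation correction: HAP = S_ART/A_ART x 6000,
  HVP = S_PV/A_PV x 6000 (mL/100 mL/min), TLP = HAP + HVP,
  HPI = HAP/TLP and time-to-peak, with the splenic peak separating the
  arterial from the portal-venous phase;
* the **combined model** — the maximum-slope HPI held fixed inside the
  compartment fit, reducing the estimation to [K1, k2, k3, k4, Vb] and
  stabilising it;
* weighted nonlinear least-squares fitting with seeded multi-start,
  goodness of fit R = 1 - sqrt(sum(y-yhat)^2/sum y^2);
* a **synthetic cohort simulator** (input functions, four-ROI subject
  TACs on both protocols, two-group truth distributions) so that every
  estimator is testable by parameter recovery without clinical data;
* the study's **statistics**: Pearson correlation with Fisher-z CI,
  Passing-Bablok regression, ROC/AUC via the Mann-Whitney identity,
  and group summary tables.

Intended users: researchers in PET pharmacokinetics and medical image
analysis who want a tested, scriptable reference implementation of
short-protocol liver kinetics.  Inputs are region-of-interest TAC
tables (delimited text); image reconstruction, ROI delineation and
DICOM handling are out of scope.

## Worked example

Simulate one HCC-like subject on the short-term protocol, estimate its
perfusion by the maximum slope method, then fit the combined model:

```python
import liverkin as lk

truth = lk.KineticParams(k1=1.52, k2=1.84, k3=0.046, k4=0.021,
                         hpi=0.764, vb=0.052)
ifp = lk.InputFunctionParams()
subj = lk.simulate_subject(truth, ifp, lk.make_schedule("short_term"),
                           noise_cv=0.02, seed=1)

perf = lk.perfusion_params(subj.tissue, subj.aorta,
                           subj.portal_vein, subj.spleen)
print(f"HAP {perf.hap:.1f}  HVP {perf.hvp:.1f}  TLP {perf.tlp:.1f} "
      f"mL/100mL/min   HPI {perf.hpi:.3f}   TTP {perf.ttp_s:.1f} s")

A = lk.simulate_arterial_input(ifp)
V = lk.simulate_portal_input(A, ifp.tau_pv_s)
fit = lk.fit_combined(subj.tissue, A, V, hpi_fixed=truth.hpi,
                      opts=lk.FitOptions(n_starts=4, seed=1))
p = fit.params
print(f"K1 {p.k1:.3f}  k2 {p.k2:.3f}  k3 {p.k3:.4f}  k4 {p.k4:.4f} "
      f"Vb {p.vb:.4f}   R {fit.r_gof:.4f}")
```

prints

```
HAP 101.3  HVP 55.6  TLP 156.9 mL/100mL/min   HPI 0.645   TTP 29.5 s
K1 1.546  k2 1.879  k3 0.0475  k4 0.0218 Vb 0.0494   R 0.9935
```

The perfusion line: this lesion's supply is arterial-dominated (HPI
0.65 by the maximum-slope index; the lesion peaks ~30 s after the
aorta).
The fit line: at 2% frame noise the combined model recovers the
generating rate constants to within a few percent, with a near-perfect
goodness of fit.

Longer narrative scripts live in `examples/` (one per capability:
simulation, maximum slope, fitting, protocol comparison, statistics).

A thin CLI wraps the same functions:

```sh
liverkin simulate --protocol short_term --n 5 --noise-cv 0.05 --seed 1 --out sim/
liverkin maxslope --tacs sim/hcc_000.csv --out perf.csv
liverkin fit --tacs sim/hcc_000.csv --model combined --hpi-from-maxslope --out fit.csv
liverkin recover --config examples/recover_config.yaml
```

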