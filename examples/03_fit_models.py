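"""Fit the six-parameter and combined models to one noisy subject.

The combined model fixes HPI from the maximum-slope method, leaving
five free parameters; on noisy short-protocol data this removes the
flat HPI-Vb trade-off that destabilises the six-parameter fit.
"""

import liverkin as lk
from liverkin.experiment import fit_subject, maxslope_hpi

truth = lk.KineticParams(1.52, 1.84, 0.046, 0.021, hpi=0.764, vb=0.052)
subj = lk.simulate_subject(
    truth, lk.InputFunctionParams(), lk.make_schedule("short_term"),
    noise_cv=0.05, seed=11,
)

opts = lk.FitOptions(n_starts=6, seed=0)
hpi_ms = maxslope_hpi(subj)
f3 = fit_subject(subj, "three_compartment", opts)
fc = fit_subject(subj, "combined", opts, hpi_fixed=hpi_ms)

print(f"maximum-slope HPI (fixed in the combined fit): {hpi_ms:.3f}")
print(f"{'':>18} {'K1':>7} {'k2':>7} {'k3':>8} {'k4':>8} {'HPI':>7} "
      f"{'Vb':>8} {'R':>7}")
print(f"{'truth':>18} {truth.k1:7.3f} {truth.k2:7.3f} {truth.k3:8.4f} "
      f"{truth.k4:8.4f} {truth.hpi:7.3f} {truth.vb:8.4f} {'':>7}")
for name, fit in (("three-compartment", f3), ("combined", fc)):
    p = fit.params
    print(f"{name:>18} {p.k1:7.3f} {p.k2:7.3f} {p.k3:8.4f} {p.k4:8.4f} "
          f"{p.hpi:7.3f} {p.vb:8.4f} {fit.r_gof:7.4f}")

print(
    "\nBoth models fit the curve comparably well (R close to 1), yet on\n"
    "this noise draw the six-parameter fit slid along the flat HPI-Vb\n"
    "valley (HPI near 0, Vb inflated) while the combined fit, anchored by\n"
    "the measured HPI, keeps k3 and Vb near the generating values; run\n"
    "with different seeds to see the replicate spread."
)
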