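"""Maximum-slope perfusion with gamma-variate recirculation correction.

Simulates an arterially-fed (HCC-like) and a portally-fed (liver-like)
subject, estimates HAP/HVP/TLP/HPI/TTP for each, and shows the pattern
the method is used for: lesions have higher arterial perfusion and an
earlier time-to-peak than background liver.
"""

import liverkin as lk

ifp = lk.InputFunctionParams()
sched = lk.make_schedule("short_term")

cases = {
    "HCC-like  ": lk.KineticParams(1.52, 1.84, 0.046, 0.021, hpi=0.764, vb=0.052),
    "liver-like": lk.KineticParams(1.00, 1.01, 0.005, 0.023, hpi=0.428, vb=0.010),
}

print(f"{'case':>10} {'HAP':>7} {'HVP':>7} {'TLP':>7} {'HPI':>6} {'TTP_s':>6}")
for name, truth in cases.items():
    subj = lk.simulate_subject(truth, ifp, sched, noise_cv=0.02, seed=3)
    perf = lk.perfusion_params(subj.tissue, subj.aorta,
                               subj.portal_vein, subj.spleen)
    print(f"{name:>10} {perf.hap:7.1f} {perf.hvp:7.1f} {perf.tlp:7.1f} "
          f"{perf.hpi:6.3f} {perf.ttp_s:6.1f}")

print(
    "\nHAP/HVP/TLP are in mL/100 mL/min. The arterially-fed case shows a\n"
    "higher HPI and peaks sooner after the aorta (smaller TTP); TLP is\n"
    "exactly HAP + HVP by construction. The maximum-slope HPI is a biased\n"
    "but stable index: FDG trapped after the splenic peak inflates the\n"
    "apparent portal slope, pulling HPI toward 0.5 (see docs/methods.md)."
)
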