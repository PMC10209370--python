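"""Simulate one subject's four-ROI TAC set on the short-term protocol.

Builds an HCC-like truth, simulates tissue/aorta/portal-vein/spleen
time-activity curves with 5% frame noise, and prints the frame table.
The aortic curve peaks near 30 s; the portal curve is its dispersed,
delayed echo; the tissue curve mixes both supplies and keeps rising as
FDG is trapped.
"""

import numpy as np

import liverkin as lk

truth = lk.KineticParams(k1=1.52, k2=1.84, k3=0.046, k4=0.021,
                         hpi=0.764, vb=0.052)
subj = lk.simulate_subject(
    truth, lk.InputFunctionParams(), lk.make_schedule("short_term"),
    noise_cv=0.05, seed=7,
)

sched = subj.tissue.schedule
print(f"{'start_s':>8} {'dur_s':>6} {'tissue':>8} {'aorta':>8} "
      f"{'portal':>8} {'spleen':>8}")
for i in range(sched.n_frames):
    print(f"{sched.start_s[i]:8.0f} {sched.duration_s[i]:6.0f} "
          f"{subj.tissue.values[i]:8.3f} {subj.aorta.values[i]:8.3f} "
          f"{subj.portal_vein.values[i]:8.3f} {subj.spleen.values[i]:8.3f}")

print("\nAortic peak frame value:", np.round(subj.aorta.values.max(), 2),
      "- the true continuous peak (35.2) is averaged down by the 5 s frame.")
print("Tissue keeps rising through the static 60-min frame:",
      np.round(subj.tissue.values[-1], 2))
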