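"""The two per-scale studies behind the design: artifact sensitivity and
awake/anesthesia discrimination.

Small, fast versions: 3 cases and a coarse SNR grid for the EOG study,
6 subject pairs for the stage study.
"""

import numpy as np

from doamon import (SNRGrid, eog_sensitivity_study, generate_eog,
                    generate_synthetic_eeg, stage_discrimination_study)

cases = [generate_synthetic_eeg(60, 125, "preoperation", seed=100 + i)
         for i in range(3)]
eog = generate_eog(60, 125, seed=99)
sens = eog_sensitivity_study(cases, eog, SNRGrid(10, -20, -3),
                             scales=(1, 2, 5, 10, 14, 20))
print("EOG sensitivity (CV% of entropy across artifact levels):")
for s, m, sd in zip(sens.scales, sens.cv_mean, sens.cv_sd):
    print(f"  scale {s:2d}: {m:5.1f} +- {sd:4.1f} %")
print("  -> scale 1 (plain SampEn) is the most artifact-sensitive scale.")
print()

s1 = [generate_synthetic_eeg(30, 125, "preoperation", seed=i) for i in range(6)]
s3 = [generate_synthetic_eeg(30, 125, "maintenance", seed=i) for i in range(6)]
disc = stage_discrimination_study(s1, s3, scales=(1, 2, 5, 10, 20))
print("Awake vs anesthesia (paired t-test per scale):")
for s, m1, m3, p in zip(disc.scales, disc.mean_stage1, disc.mean_stage3,
                        disc.p_value):
    mark = "*" if p < 0.05 else " "
    print(f"  scale {s:2d}: awake {m1:5.2f}  anesthesia {m3:5.2f}  "
          f"p={p:.2e} {mark}")
print("  -> awake EEG is more complex at scale 1; at large scales the")
print("     slow-wave signal can even exceed it, so scales complement each")
print("     other - the reason for fusing all 20.")
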