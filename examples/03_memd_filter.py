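"""Denoise EOG-corrupted EEG with the noise-assisted MEMD IMF2+IMF3 filter.

Decomposes a corrupted record, shows the exact reconstruction property,
and compares the sub-4 Hz (artifact band) power fraction before and after
filtering.
"""

import numpy as np
from scipy.signal import periodogram

from doamon import (MEMDConfig, eeg_filter, generate_eog,
                    generate_synthetic_eeg, mix_at_snr)


def sub4(x, fs=125.0):
    f, p = periodogram(x, fs)
    return p[f < 4].sum() / p.sum()


eeg = generate_synthetic_eeg(30, 125, "preoperation", seed=3)
eog = generate_eog(30, 125, seed=4)
corrupted = mix_at_snr(eeg, eog, snr_db=-5.0)

filtered, imfset = eeg_filter(corrupted, MEMDConfig(seed=5),
                              imf_selection=(2, 3), return_imfs=True)

recon_err = np.linalg.norm(imfset.reconstruct_all() - corrupted.samples) \
    / np.linalg.norm(corrupted.samples)
print(f"decomposition: {imfset.n_imfs} IMFs + residue, "
      f"reconstruction error {recon_err:.2e}")
print(f"sub-4 Hz power fraction: corrupted {sub4(corrupted.samples):.3f} "
      f"-> filtered {sub4(filtered.samples):.3f}")
print(f"SD: corrupted {corrupted.samples.std():.1f} uV "
      f"-> filtered {filtered.samples.std():.1f} uV")
print()
print("Blink energy lives in the slow IMFs; keeping only IMF2+IMF3 strips")
print("it while retaining the mid-frequency EEG the entropy analysis needs.")
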