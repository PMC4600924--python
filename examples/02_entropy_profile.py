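"""Multiscale entropy of Gaussian white noise vs. the analytic curve.

For i.i.d. Gaussian noise with tolerance fixed at 0.2x the scale-1 SD,
MSE(tau) = -ln erf(0.1*sqrt(tau)); the measured profile should track it
and decrease with scale.
"""

import math

from doamon import generate_white_noise, mse_profile

x = generate_white_noise(30000, sigma=1.0, seed=1).samples
scales = (1, 2, 5, 10, 20)
profile = mse_profile(x, scales)

print("scale   measured   analytic")
for tau, got in zip(scales, profile):
    expected = -math.log(math.erf(0.1 * math.sqrt(tau)))
    print(f"{tau:5d}   {got:8.4f}   {expected:8.4f}")
print()
print("Entropy falls with scale because coarse-graining shrinks the")
print("variance of white noise while the tolerance stays fixed — the")
print("calibration that anchors the entropy implementation.")
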