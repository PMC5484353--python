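"""Selectivity of the DANTE saturation train.

Integrates the full Bloch equations through the pulsed train (100 us on,
230 us off) to its periodic steady state: how completely the on-resonance
peak is destroyed, and how much of a peak 289 Hz away survives, as a
function of the saturation field amplitude and of the off-resonance T2.
"""

import numpy as np

from boast31p import DantePulseTrain, dante_saturation_profile

train = DantePulseTrain()  # 100 us pulses, 230 us gaps
gb1 = np.array([10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
prof = dante_saturation_profile(train, gb1)
print("gammaB1 (Hz)   on-res residual   Q at 289 Hz")
for row in prof:
    print(f"   {row.gamma_b1_hz:6.0f}        {row.residual_mz:8.4f}        {row.q:6.3f}")
# residual << 1 means the saturated peak is fully destroyed; Q near 1 means
# the neighbouring peak 289 Hz away is spared.  Both hold simultaneously
# only over a limited amplitude window: strong trains power-broaden the
# saturation band onto the neighbour.

print("\nsensitivity of Q (at 200 Hz amplitude) to the spared peak's T2:")
for t2 in (0.02, 0.05, 0.1, 0.2, 0.3):
    p = dante_saturation_profile(train, [200.0], t2_off=t2)
    print(f"  T2 = {t2:4.2f} s -> Q = {p.q[0]:.3f}")
# longer T2 narrows the spillover, improving Q at a fixed offset.
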