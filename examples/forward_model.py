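"""Two-pool exchange forward physics: apparent relaxation under saturation.

Builds the myocardial PCr/gamma-ATP system, computes the apparent (T1', M0')
of PCr under continuous gamma-ATP saturation, verifies the rate-equation
round trip, and shows the minimum-TR rule for the saturation duty cycle.
"""

from boast31p import (
    PoolSystem,
    SequenceParams,
    minimum_tr,
    saturated_pool_steady_state,
    steady_state_signal,
)

pools = PoolSystem()  # [PCr]:[ATP]=1.5, T1*=6.0/2.0 s, kf=0.32 1/s
t1_prime, m0_prime = saturated_pool_steady_state(pools)
print(f"apparent T1' = {t1_prime:.4f} s, M0' = {m0_prime:.4f} (M0 = {pools.m0_pcr})")

kf = (1.0 / t1_prime) * (1.0 - m0_prime / pools.m0_pcr)
print(f"rate-equation round trip: kf = {kf:.4f} 1/s (truth {pools.kf})")
# saturation shortens PCr's apparent T1 from 6.0 to ~2.05 s and removes
# ~66% of its equilibrium magnetization; inverting the rate equation
# recovers the exchange rate exactly.

for flip in (16.0, 64.0):
    seq = SequenceParams(tr=0.4, flip=flip, saturation="gamma_atp", sat_fraction=1.0)
    pcr, _ = steady_state_signal(pools, seq)
    print(f"saturated steady-state PCr signal at {flip:>4.0f} deg: {pcr:.4f}")

tr_min = minimum_tr(dead_time=0.090, required_sat_fraction=0.76)
print(f"minimum TR for 90 ms dead time at 76% saturation duty: {tr_min*1e3:.0f} ms")
# 375 ms is the shortest repetition time keeping the gamma-ATP pool in a
# saturated steady state given the readout/excitation overhead.
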