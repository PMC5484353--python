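"""Monte-Carlo protocol design: where should the two flip angles sit?

Sweeps the flip-angle pair (beta = 4 alpha) at TR = 0.4 s with amplitude
noise calibrated to a PCr SNR of 13, and reports bias, precision and the
minimum-MSE protocol.
"""

import numpy as np

from boast31p import DesignGrid, PoolSystem, find_optimum, reference_noise_sd, sensitivity_analysis, sweep

pools = PoolSystem()
sigma = reference_noise_sd(pools)
print(f"amplitude noise SD at the SNR-13 calibration: {sigma:.4f}")

grid = DesignGrid(alphas=np.arange(4.0, 45.0, 1.0), trs=np.array([0.4]),
                  m_values=(4,), n_draws=20_000, seed=0)
res = sweep(grid, pools, noise_sd=sigma)
alpha, beta, tr = find_optimum(res, m=4, tr=0.4)
row = res[res.alpha == alpha].iloc[0]
print(f"optimum: alpha = {alpha:.0f} deg, beta = {beta:.0f} deg at TR = {tr} s")
print(f"  bias = {row.bias_pct:+.1f}% of kf, SD = {row.sd_pct:.1f}%")
# the minimum-MSE pair sits near (16, 64) degrees; away from it the kf
# estimate rapidly loses accuracy (small flips) or gains bias (large flips).

sens = sensitivity_analysis(pools, perturbations=(-0.25, 0.25), n_draws=10_000, seed=1)
print("\nrobustness to the assumed tissue parameters (+/-25%):")
for _, r in sens.iterrows():
    print(f"  {r.parameter:>14s} {r.perturbation:+.2f}: "
          f"bias change {r.delta_bias_pts:+.1f} pts, SD change {r.delta_sd_rel*100:+.0f}%")
# the chosen working point barely moves when the assumed concentrations or
# exchange rate are wrong by a quarter.
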