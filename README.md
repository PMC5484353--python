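# boast31p

Tools for measuring the creatine-kinase (CK) forward rate constant in vivo
by phosphorus-31 magnetic resonance spectroscopy, using the four-angle
saturation-transfer method with Bloch-Siegert flip-angle calibration.

## The problem

Phosphocreatine (PCr) and the terminal phosphate of ATP exchange through
creatine kinase. Selectively saturating the gamma-ATP resonance drains PCr
magnetization at a rate set by the pseudo first-order forward constant
`kf`: the PCr pool then relaxes with an apparent time constant

    1/T1' = 1/T1*_PCr + kf

toward a reduced equilibrium `M0' = M0 * (1/T1*_PCr) / (1/T1')`, so

    kf = (1/T1') * (1 - M0'/M0).

T1' and M0' (and their unsaturated counterparts T1, M0) are obtained from
two dual-angle steady-state measurements: PCr amplitudes `M(alpha)`,
`M(beta)` acquired with a spoiled pulse train at two flip angles obey

    M(theta) = sin(theta) M0 (1 - E) / (1 - cos(theta) E),   E = e^(-TR/T1),

which inverts in closed form for (T1, M0) from the amplitude ratio. With a
surface transmit coil the flip angles vary across the heart, so they are
calibrated per voxel from a Bloch-Siegert B1+ map (the phase difference of
two off-resonance Fermi-pulse acquisitions is `2 K_BS (gamma B1)^2`).
Combining `kf` with the PCr/ATP amplitude ratio and a literature ATP
concentration gives the CK flux `kf x [PCr]` in mmol kg^-1 s^-1.

The package implements, as importable modules:

- `exchange_model` — two-pool longitudinal Bloch-McConnell propagation
  under pulsed excitation and selective saturation (exact piecewise matrix
  exponentials), DANTE saturation-train Bloch simulation, Bloch-Siegert
  phase of a Fermi pulse, and the minimum-TR rule;
- `fast_estimator` — the four-angle inversion with first-order and
  Monte-Carlo uncertainties, Q-factor spillover correction, multiparametric
  Bloch-McConnell least squares, concentration/flux conversion, weighted
  literature means, B1-error propagation and phase-pair B1/flip maps;
- `spectral_fitting` — time-domain prior-knowledge (AMARES-style)
  Lorentzian-multiplet fitting with Cramer-Rao lower bounds and
  matched-filter SNR;
- `protocol_optimizer` — Monte-Carlo bias/precision/MSE maps over flip
  angles and TR, optimum finding, acceptable-region widths, L-curves and
  sensitivity analysis;
- `csi_psf` — chemical-shift-imaging point-spread-function analysis of
  B1-map resolution and its effect on `kf`;
- `synthetic_data` — seeded scenario generator (cardiac, calf, phantom)
  producing every input the pipeline consumes, plus the transcribed
  literature tables.

A thin CLI (`boast simulate|b1map|fit-spectra|estimate-kf|optimize-protocol|psf-analysis`)
wraps the same functions; `examples/` holds one narrative script per
capability.

## Worked example

```bash
python examples/forward_model.py
```

prints

```
apparent T1' = 2.0548 s, M0' = 0.5137 (M0 = 1.5)
rate-equation round trip: kf = 0.3200 1/s (truth 0.32)
saturated steady-state PCr signal at   16 deg: 0.1200
saturated steady-state PCr signal at   64 deg: 0.1278
minimum TR for 90 ms dead time at 76% saturation duty: 375 ms
```

Continuous gamma-ATP saturation shortens the PCr apparent T1 from 6.0 s to
2.05 s and removes two thirds of its equilibrium magnetization; plugging
(T1', M0', M0) into the rate equation returns the exchange rate exactly,
and the timing rule gives the shortest repetition time (375 ms) that keeps
the saturated steady state valid. `examples/estimate_kf_pipeline.py` runs
the full synthetic acquisition through both estimators and the flux
conversion, and `examples/literature_flux.py` reproduces the pooled
literature numbers ([ATP] 5.82 +/- 0.40, [PCr] 9.58 +/- 0.44 mmol/kg,
normal-cohort kf 0.33 1/s).

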