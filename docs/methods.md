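# Methods

## Exchange model

Longitudinal magnetization of the PCr/gamma-ATP pair evolves as
`dMz/dt = A Mz + b` with

    A = [ -1/T1*_PCr - kf        kr              ]        b = [ M0_PCr / T1*_PCr  ]
        [  kf                   -1/T1*_gATP - kr ]            [ M0_ATP / T1*_gATP ]

and the reverse rate fixed by detailed balance, `kr = kf M0_PCr / M0_ATP`
(never an independent input). Pulsed sequences are propagated exactly:
instantaneous rotations (`Mz -> Mz cos(theta)`, ideal spoiling assumed — the
readout is a spoiled FID, so no transverse coherence survives a TR), free
segments via the matrix exponential of `A`, and saturated segments with the
gamma-ATP row clamped to zero, which reduces PCr to a scalar
relaxation-plus-leak equation. The steady state is the fixed point of the
per-TR affine map, solved directly; iterative propagation with a
successive-change tolerance of 1e-12 is available and agrees with the fixed
point to better than 1e-9 relative (property-tested over 1000 random
parameter draws). Under full-duty saturation the fixed point coincides with
the closed-form apparent pair `T1' = 1/(1/T1*_PCr + kf)`,
`M0' = M0 (T1'/T1*_PCr)`.

Default tissue parameters are the myocardial values used throughout:
`[PCr]:[ATP] = 1.5`, `T1*_PCr = 6.0 s`, `T1*_gATP = 2.0 s`, `kf = 0.32 1/s`.
The 2.4 ppm PCr-to-gamma-ATP separation together with its 289 Hz value
fixes the assumed 31P frequency at 120.42 MHz. Angles are degrees at every
interface and radians internally.

## DANTE saturation

The saturation train (defaults: 100 us pulses, 230 us gaps, constant
amplitude) is integrated with the full three-component Bloch equations,
again by exact per-segment matrix exponentials; the periodic steady state
is the affine fixed point of the one-period map, cross-checked against
brute-force ODE integration. Two relaxation pairs matter: the saturated
peak (defaults T1 = 2.0 s, T2 = 0.03 s, gamma-ATP-like) for the
on-resonance residual, and the spared peak (defaults T1 = 6.0 s,
T2 = 0.1 s, PCr-like) for the preserved fraction Q at the 289 Hz offset.
T2 values are configurable; `examples/dante_profile.py` reports the
sensitivity of Q to T2 over 0.02-0.3 s.

A structural finding worth stating plainly: on-resonance saturation and
289-Hz sparing cannot both hold across a 16-fold amplitude range. The
duty-cycle-averaged field (0.303 x the pulse amplitude) power-broadens the
saturation band; in the CW-equivalent steady state
`Mz/M0 = (1 + (2 pi f T2)^2) / (1 + (2 pi f T2)^2 + w_eff^2 T1 T2)`,
keeping Q >= 0.95 at 289 Hz with an 800 Hz train amplitude would require a
physically impossible T2 for the spared peak. The simulated Q therefore
falls from 0.99 at 10 Hz through 0.86 at 50 Hz to 0.02 at 800 Hz, while
the on-resonance residual stays below 0.1 for everything above ~6 Hz.
Trains intended to spare a neighbour a few hundred Hz away must keep their
amplitude within roughly a five-fold window.

## Bloch-Siegert phase and B1 maps

The phase imparted to on-resonance spins by an off-resonance Fermi pulse
(`gB1(t) = peak / (1 + exp((|t|-T0)/a))`, truncated to width TP; defaults
TP = 3.5 ms, T0 = 0.875 ms, a = 0.224 ms, +/-2000 Hz offset) is computed by
adaptive quadrature of `pi gB1(t)^2 / f_offset`, valid for
`|offset| >= 4 x peak` (enforced); it agrees with the exact adiabatic
phase integral to under 2% at that bound and is antisymmetric in the
offset sign. Half the phase difference of the +/-offset acquisitions
divided by the unit-amplitude phase constant gives `gB1^2`; voxels with a
negative phase difference are masked. Flip-angle maps scale linearly with
B1, anchored so a chosen target voxel receives the nominal flip; the
beta-scan voltage is the alpha-scan voltage times m = beta/alpha, so every
voxel's two flips share one spatial scale factor.

## Four-angle estimation

T1 (or T1') comes from the closed-form inversion of the dual-angle
amplitude ratio, M0 (or M0') from either of two algebraically equivalent
closed forms, both evaluated and asserted to agree to 1e-10 relative.
Log arguments outside (0, 1) — which genuine noise produces — yield NaN,
never exceptions; `estimate_all` marks such voxels unusable with the
offending quantity named, and cohort code is expected to keep them visible.
When the optional unsaturated scan is present, the spillover factor
Q = M(ctrl)/M(unsat) at the shared beta flip is measured and, by default,
divides the control-scan M0 before the rate equation; without it Q is 1.
Uncertainties are propagated two ways and both reported: a first-order
delta method (central-difference Jacobian against the amplitude SDs) and
seeded Monte-Carlo resampling (default 10,000 draws; invalid draws
counted).

The multiparametric fit minimises the SD-weighted squared residuals of all
available amplitudes against the exact two-pool forward model:
PCr from the four (or five) scans, and gamma-/alpha-ATP from every scan in
which they are unsaturated (the unsaturated scan and both control scans —
mirrored control irradiation does not touch the ATP resonances).
Alpha-ATP is modelled as a non-exchanging pool sharing M0_ATP; when it is
observed at only one flip angle its T1 is not identifiable and is held at
2.0 s. Optimisation is bounded trust-region least squares with four
multistarts; parameter SDs are Gauss-Newton, from the weighted Jacobian at
the optimum. On noiseless data generated by the same forward model the fit
is a zero-residual fixed point recovering every parameter.

`propagate_b1_error` isolates the effect of flip-angle miscalibration by
generating signals from the apparent single-pool forms (so the inversion is
exact at zero error) and inverting with flips scaled by (1 + epsilon); the
bias is markedly asymmetric (+24% of kf at epsilon = +10%, -21% at -10%).

## Spectral model and CRLBs

FIDs are sums of Lorentzians `a e^{i phi0} e^{(2 pi i f - pi lw) t}` with
multiplet prior knowledge: gamma- and alpha-ATP doublets (1:1) and the
beta-ATP triplet (1:2:1), all with a 16 Hz scalar coupling (a configurable
default — the couplings are conventional values, not fitted), shared
linewidths within a multiplet, one global zero-order phase, first-order
phase fixed by the acquisition delay. The muscle prior set has 10 lines
(ATP multiplets, PCr, PDE, Pi), the cardiac set 11 (PDE and two
2,3-DPG lines; DPG/PDE/Pi relative amplitudes in the generator are typical
31P values, not measurements). Fitting is bounded time-domain least
squares on stacked real/imaginary residuals; amplitude CRLBs are
`sqrt(diag(F^-1))` with `F = J^T J / sd^2` over all free parameters, and
Monte-Carlo fit SDs attain the bound within 20% at moderate SNR.
The FID-tail noise estimator assumes the tail is noise-dominated, which
holds at the SNRs the generator targets but not for nearly noiseless
synthetic FIDs; tests that need exact noise levels pass them explicitly.
Matched-filter SNR multiplies the FID by the normalized Lorentzian decay
and reads the spectral peak against the filtered noise SD.

## Protocol optimisation

At each design point the four noiseless PCr amplitudes come from the full
two-pool propagation (so the inversion's exchange-model mismatch — about
+5% in kf at the working point — is part of the measured bias), Gaussian
amplitude noise is added, and every draw is inverted. The noise SD is
calibrated so the beta-flip control scan at TR = 0.4 s has PCr amplitude
SNR 13, and scales with `sqrt(TR/0.4)` — the fixed-total-scan-time
convention (shorter TR buys more averages); `constant` and `linear`
alternatives are selectable. Bias and SD are percent of the true kf over
the finite draws, MSE = bias^2 + SD^2; invalid draws are counted and
reported, and the kf draw distribution is heavy-tailed enough at low SNR
that moments should be read with its valid-fraction alongside.

The MSE surface near its minimum is flat (neighbouring 1-degree grid
points differ by ~1.6%), so optimum-finding runs use 200,000 draws per
point, enough to keep Monte-Carlo error below one grid step; the sweep
seeds each grid point independently from its coordinates, making results
independent of evaluation order. At the SNR-13 calibration the optimum is
alpha = 17 +/- 1 degrees, beta = 4 alpha, at the shortest admissible TR.
Sensitivity analysis perturbs kf directly and the concentration ratio
through the ATP pool (holding the PCr amplitude, hence the noise
calibration, fixed): +/-25% perturbations move the bias by under 1
percentage point and the SD by under 11%.

## CSI point-spread-function analysis

The PSF is the inverse transform of the (optionally Hamming-weighted)
finite k-space window, normalized to unit area, symmetric about the voxel
centre; voxel centres sit at `fov (i + 0.5)/n - fov/2`. Low-resolution
maps interpolate by k-space zero padding (exact for band-limited
profiles). The resolution-error simulation evaluates apparent-model FAST
signals at every high-resolution position with the flips the local B1
delivers, sums them per voxel under the PSF and a receive weighting
approximated by the normalized B1 profile, and inverts each voxel with the
B1 the same PSF would have measured there. Using the apparent single-pool
forward model makes a uniform field give exactly zero error, so the
reported error isolates resolution effects. The default synthetic coil is
a 50 mm radius loop 160 mm from the object centre (on-axis Biot-Savart
field), giving a ~17x B1 range across a 160 mm object — comparable to a
surface coil over the septum. Coarse matrices leave most voxels with
|kf error| > 20%; the fraction falls monotonically with matrix size, and
voxels on steeper field gradients err more.

## Synthetic scenarios

`cardiac_config` encodes the study conditions: the myocardial pools above,
nominal flips (16, 64) degrees at the target voxel, TR = 0.4 s with a
0.775 saturation duty cycle (90 ms dead time), spillover Q = 0.95
(applied multiplicatively to control-scan PCr), 11-peak priors, 512-point
6 kHz FIDs, and complex noise calibrated to matched-filter PCr SNR 13 at
the target beta-control scan. `calf_config` uses kf = 0.28 1/s,
PCr:ATP = 4 (typical resting skeletal muscle), SNR 22, Q = 0.97;
`phantom_config` is a single pool with kf = 0. Amplitude records carry
SDs equal to the PCr amplitude CRLB at the calibrated noise; the
`forward_model` switch selects the apparent single-pool forms (default;
exact under the four-angle inversion, so round-trip tests are exact) or
the full two-pool propagation (used when exercising the multiparametric
fit and model-bias studies). Every dataset stores the noiseless truth, and
identical config + seed reproduces bitwise-identical outputs.

What the generator does not emulate: spatial k-space encoding of the
spectroscopy scans themselves (voxels are simulated independently;
PSF mixing is the separate `csi_psf` analysis), B0 inhomogeneity beyond a
static linewidth, motion, and blood 2,3-DPG/NADH contamination of the ATP
amplitudes. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to those effects.

## Known limitations

- The control scan is modelled as leaving both pools untouched apart from
  the multiplicative Q on PCr; actual off-resonance irradiation effects on
  gamma-ATP are not simulated.
- kf moments at low SNR depend on tail handling because the estimator has
  poles; reported optima at strongly degraded SNR are convention-dependent.
- The DANTE amplitude window quantified above limits simultaneous
  saturation and sparing; the packaged defaults reflect the literature
  timing, not an amplitude optimisation.
- Absolute concentrations rest on a literature [ATP]; no phantom
  referencing is implemented.
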