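# Methods

This note documents the models, numerical choices and known limits of
`eddycalc`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Proton-budget model of calcification

The package treats the benthic proton flux as the sum of two ecosystem
terms: a metabolic term (photosynthesis and respiration exchange DIC,
and the carbonate system re-equilibrates, consuming or releasing
protons) and a calcification term (precipitating CaCO₃ removes one DIC
and two alkalinity, releasing protons; dissolution reverses the sign).
Both terms are linear in the underlying carbon rates, with coefficients
given by equilibrium proton yields of the carbonate system:

- `dh_ddic` — change in total [H⁺] per unit DIC added at constant
  alkalinity. Defined per DIC *added*, so it is a positive number; the
  metabolic proton-flux term carries an explicit minus sign
  (photosynthesis takes DIC up). This sign convention makes the G_net
  inversion an exact algebraic inverse of the forward relations, which
  the suite verifies to 1e-10 relative.
- `dh_ddic2alk` — change in total [H⁺] per mole of CaCO₃ precipitated
  (ΔDIC = −1, ΔAₜ = −2 µmol kg⁻¹). Also positive.

Both are central finite differences with a 1 µmol kg⁻¹ DIC step (2 for
alkalinity), the natural unit perturbation of the problem; step-halving
convergence (relative change < 1e-4 between steps 1 and 0.5) is enforced
by test. Assumptions inherited by any user of the method: carbonate
equilibrium is reached between the organism and the measurement volume
(minutes of transit against tens of seconds of CO₂ equilibration in
warm water), alkalinity is constant over a deployment, and
calcification is the dominant nonmetabolic proton source — anaerobic
proton sources (denitrification, DNRA, sulfate reduction) are *not*
modelled and environments where they matter need an independent
constraint.

## Carbonate solver

Total pH scale throughout; conversions to the free scale are internal
(bisulfate association). Constants: Lueker et al. (2000) K1/K2 (valid
T 0–40 °C, S 19–43; inputs outside this raise), Dickson (1990) KSO₄ and
KB, Perez & Fraga (1987) KF, Millero (1995, as tabulated on the total
scale) KW, Lee et al. (2010) total boron. Pressure is accepted but the
constants are evaluated at one atmosphere: at the <15 m depths this
package targets, pressure corrections are far below the alkalinity and
pH accuracy terms. Nutrient (phosphate/silicate) alkalinity is excluded;
at oligotrophic nutrient levels its contribution is well below the
1e-3 µmol kg⁻¹ closure tolerance, and the speciation routine is the
single extension point if that changes.

Solving TA + pH is closed-form through carbonate alkalinity; TA + DIC
uses a bracketed Brent root on pH ∈ [2, 12] (the TA residual is monotone
in pH), absolute tolerance 1e-10. Density is the one-atmosphere EOS-80
(Millero & Poisson) fit, used only for µmol kg⁻¹ ↔ mmol m⁻³ conversion.

With no CO2SYS-family package available at build time, correctness is
anchored two ways: the constants reproduce published check values at
S = 35, 25 °C (pK1 5.8472, pK2 8.9660, ln KB −19.7964, ln KW −30.434)
to the printed precision, and the TA+pH→DIC inversion matches an
independently coded explicit-speciation root solve to well within 0.2%
over the deployment-condition grid.

## Flux processing chain

Defaults follow common aquatic eddy-covariance practice and are all
`RunConfig` keys:

- **Downsampling** of 16 Hz velocities onto the 5 Hz scalar grid by
  block means assigned by time (the 16:5 ratio is not integer; blocks
  hold 3–4 samples). A block under 50% valid becomes a gap.
- **Planar fit** over the whole deployment, from 5-min mean-flow
  vectors (300 s segments; windows would work but give few vectors on
  short records). Requires mean flows spanning ≥2 directions, else a
  degenerate-geometry error — a single-direction record cannot
  constrain the tilt plane. The fitted w-offset is removed before
  rotation. One rotation per deployment, recorded in the run log.
- **Reynolds decomposition** with a 500 s centered running mean that
  shrinks symmetrically at record edges; the first and last 250 s are
  excluded from flux windows to avoid edge bias.
- **Lag alignment** of each scalar to w at the peak absolute
  cross-correlation within ±2 s, at sample resolution (0.2 s), ties
  toward smaller |lag|. Windows whose peak |r| falls below 0.05 are
  flagged `low_correlation`.
- **Windows** of 29 min on a 30-min grid (the remaining minute is the
  pump-reversal blank of the pH intake). Fluxes are means of w′c′ over
  valid samples, converted to mmol m⁻² d⁻¹ via density; windows under
  50% valid are invalidated. Positive flux = efflux from the bed.
- **QC**: cumulative-flux linearity (R² ≥ 0.8 against time and no 5%
  span of samples carrying >50% of the net change; windows whose total
  covariance is within 3 robust standard errors of zero are reported
  `low_flux`, not nonlinear), a `low_turbulence` flag below 2 cm s⁻¹
  mean speed, and an optional 6-MAD/10 s despike filter (on by
  default). Because the running median of a locally monotone signal is
  the center sample, the local MAD is floored with a first-difference
  noise scale; without that floor the filter flags smooth signals.
- **Cospectra** are single-segment boxcar cross-spectral densities, so
  the Parseval identity (integral = covariance) holds by construction
  and is tested at 1%. The high-frequency loss estimator scales test
  and reference ogives to agree at the frequency below which the lowest
  quartile of the reference flux accumulates — low enough that neither
  sensor attenuates — then reports the relative shortfall at Nyquist.
  Scaling at a fixed bin-count quartile instead biases the estimate
  low whenever attenuation reaches into mid frequencies.
- **Storage flux** (Δconcentration/Δt × layer height) is computed only
  when enabled; proton storage is never corrected, since vent CO₂
  contamination makes an ecosystem storage split ill-defined.

## Calcification aggregation

Per-window carbonate states use the window-mean pH (from the
running-mean [H⁺]) with the deployment's fixed alkalinity, temperature
and salinity. Q defaults to (n+2)/n at an ecosystem C:N of 22.2
(`cn_ratio`), with an alternative metabolism-fraction-weighted
arithmetic mixing of component C:N ratios (epiphytes 13.7 at 1/3,
seagrass 26.8 at 2/3 → 22.43); the mixing rule for autotroph C:N is not
uniquely defined, which is why the direct override is the default. The
same Q serves light and dark. Light/dark classification uses window-mean
PAR against a 1 µmol photons m⁻² s⁻¹ threshold.

Vent flagging is explicit and configurable: a window is `vent_affected`
when |proton flux in CO₂ equivalents| exceeds 3× the larger of |O₂
flux| and a 50 mmol m⁻² d⁻¹ floor, or when the mean flow direction
falls in a configured exclusion sector. Flagged windows stay in the
output but are excluded from ecosystem aggregation. Daily standard
errors are quadrature sums of the light and dark standard errors of the
mean.

## Sensitivity analysis

`gnet_error_curve` generates true fluxes from prescribed (P_net, G_net)
at the true state and Q, then inverts with a biased state (pH ± δ or
Aₜ ± δ) or biased Q. By default only the inversion inputs are biased —
this isolates the error entering through the assumed proton-yield
ratios. `bias_measured_flux=True` additionally scales the measured
proton flux by 10^(−δpH), which is the physically complete model of a
single biased pH sensor (the same offset that shifts the assumed state
also scales the inferred [H⁺] fluctuations); the two effects partially
cancel, so the complete model gives substantially smaller errors. The
error decomposes into a constant bias floor plus a term ∝ 1/(G_net/
P_net): exactly 1/r for Q biases, approximately so for pH/alkalinity
biases below r ≈ 0.5. P_net is fixed at 100 mmol m⁻² d⁻¹ for numerical
conditioning; errors are relative, so the scale cancels.

## Synthetic deployments

The generator's defaults are the study conditions the package targets:
~5 cm s⁻¹ mean flows (slowly modulated ±40% in speed and ±60° in
direction so the tilt plane is identifiable), w′ of 1 cm s⁻¹, O₂ fluxes
of ~109 mmol m⁻² d⁻¹ in the light and −54.5 in the dark (P_net 100/−50
through Q = 1.09), G_net 30 (light) / −15 (dark) mmol CaCO₃ m⁻² d⁻¹,
background pH 8.04 at Aₜ 2650 µmol kg⁻¹, 25 °C, S 38, 12 h light from
06:00. Turbulence is band-limited Gaussian noise with a low-frequency
plateau rolling into a −5/3 power law at 0.05 Hz; the scalar is built
as α(t)·w′ plus independent shaped noise, with α set per 30-min block
so the ensemble covariance equals the forward-model flux. Vent events
add DIC at constant alkalinity (pure CO₂ intrusion; 65 µmol kg⁻¹
produces the ~0.1-unit pH drop scale) plus a configurable vent proton
efflux. Artifacts applied after the truth record is fixed: frame tilt
rotation, first-order low-pass with a stated t₉₀, pure delay, white
noise, Poisson spikes, and a 1-min pump blank per 30-min block.

What the generator does *not* emulate — real turbulence intermittency
and anisotropy, wave pumping, thermal stratification, sensor drift,
canopy transit-time smearing — bounds what passing recovery tests show:
they validate the processing algebra and its statistical behaviour
under realistic signal-to-noise, not robustness to every field
pathology. Recovery tests use 20+ windows (a 25 h deployment runs in
seconds), chosen so turbulent sampling error, not runtime, sets the
test tolerances.

## Known limitations

- Ecosystem NEC/NEM values from field campaigns are not reproducible
  here without the archived raw data; the package validates against
  synthetic truth and desk-scale published numbers instead.
- The error-amplification figures quoted for a 0.04 pH bias in the
  source literature correspond to an unstated baseline and procedure;
  this package's procedure (bias the inversion only) gives a larger
  amplification at the same nominal point, and its physically complete
  variant (`bias_measured_flux=True`) a smaller one. Both are reported
  by the sensitivity module; neither was tuned to match the quoted
  figure.
- No pressure corrections to equilibrium constants, no nutrient
  alkalinity, no air–sea exchange, no saturation-state (Ω) computation.
- Gap handling is linear interpolation for spectral estimates and
  exclusion for covariances; no gap-filling of long outages.
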