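# eddycalc

Benthic ecosystem calcification from paired pH and O₂ aquatic eddy
covariance.

In benthic ecosystems, photosynthesis is a proton sink while
calcification is a proton source. Where calcification is the dominant
nonmetabolic proton source, net ecosystem calcification (G_net) can be
isolated as the residual between the measured benthic proton flux and
the proton flux predicted from O₂-derived metabolism. `eddycalc`
implements that inversion end to end for users of aquatic
eddy-covariance instruments over calcifying benthic communities
(coralline-algae epiphytes in seagrass meadows, coral reefs, carbonate
sands): the turbulence flux-processing chain, the carbonate-system
proton-yield ratios, daily calcification and metabolism aggregation
with propagated errors, a measurement-error sensitivity analysis, and a
ground-truthed deployment simulator so every stage is testable without
field data.

## The method

Aquatic eddy covariance measures a benthic solute flux as the mean
product of the fluctuating vertical velocity and solute concentration,
`flux = mean(w'c')`, over ~29-min windows. With O₂ and total-scale pH
measured in the same sampling volume, the proton budget reads

    fluxH_ecosystem = −fluxH_Pnet + fluxH_Gnet
    fluxH_Pnet      = (O₂flux / Q) · dH⁺/dDIC
    fluxH_Gnet      = G_net · dH⁺/d(DIC 2Aₜ)

where Q = (n+2)/n is the community photosynthetic quotient (n = molar
C:N of the organic matter fixed and respired), and the two dimensionless
ratios are equilibrium proton yields of the carbonate system, evaluated
by numerical perturbation at the in-situ state (per unit DIC added at
constant alkalinity, and per mole CaCO₃ precipitated, i.e. ΔDIC = −1,
ΔAₜ = −2 µmol kg⁻¹). Solving for calcification:

    G_net = [fluxH_ecosystem + (O₂flux / Q) · dH⁺/dDIC] / [dH⁺/d(DIC 2Aₜ)]

Daily net ecosystem calcification is the hour-weighted mean of light and
dark G_net, `NEC = G_light·h_light/24 + G_dark·h_dark/24`, with standard
errors propagated in quadrature. O₂-based metabolism (R, GPP, NEM)
comes from the same flux windows.

The carbonate system is solved on the total pH scale with the Lueker
et al. (2000) carbonic-acid constants, Dickson (1990) bisulfate and
borate, Perez & Fraga (1987) fluoride, and the Lee et al. (2010)
boron-to-salinity ratio.

## Worked example

`examples/daily_calcification.py` simulates a 25-hour deployment with
prescribed calcification of 30 mmol CaCO₃ m⁻² d⁻¹ in the light and −15
in the dark (net dissolution), passes the pH, O₂ and velocity channels
through the full processing chain, and recovers the daily budget:

```
planar-fit tilt: 0.23 deg (scenario applied 0)
G_net light:   28.7 +/- 1.5 (truth 30.0), n = 24
G_net dark:   -14.7 +/- 0.8 (truth -15.0), n = 24
daily NEC:      7.0 +/- 1.7 mmol CaCO3 m-2 d-1 (truth 7.5)
O2 metabolism: R -52, GPP 78, NEM 27 mmol O2 m-2 d-1
```

The light and dark G_net means and the daily NEC recover the simulated
truth within their propagated standard errors; the small shortfall
(~3–5%) is the expected high-frequency loss of the block-mean
resampling and running-mean decomposition. The other examples print the
carbonate proton-yield ratios (`carbonate_proton_yields.py`), the
flux-estimator sampling behaviour (`flux_from_synthetic_turbulence.py`),
and the error-amplification table (`error_amplification.py`), each with
a line explaining its numbers.

A thin CLI drives the same pipeline from the shell:

```sh
eddycalc simulate --seed 1 --outdir sim
eddycalc process  --indir sim  --outdir proc
eddycalc calcify  --indir proc --outdir calc
eddycalc sensitivity --parameter pH --magnitude 0.04 --out curve.csv
```

Every run writes its effective configuration and a QC summary beside
its outputs.

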