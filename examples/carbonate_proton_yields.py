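"""Solve the carbonate system at deployment conditions and print the
proton-yield ratios that link proton fluxes to carbon fluxes.

The two ratios are the heart of the method: dH+/dDIC converts metabolic
DIC uptake into the proton flux it implies, and dH+/d(DIC 2At) converts
a residual proton flux into CaCO3 precipitated.
"""

from eddycalc import carbonate as cb

state = cb.solve_state(2650.0, 25.0, 38.0, pH=8.04)
print(f"background state: pH {state.pH:.3f}, DIC {state.dic:.1f} umol/kg, "
      f"density {state.density:.2f} kg/m3")

d1 = cb.dh_ddic(state)
d2 = cb.dh_ddic2alk(state)
print(f"dH+/dDIC        = {d1:.3e} mol H+ per mol DIC added")
print(f"dH+/d(DIC 2At)  = {d2:.3e} mol H+ per mol CaCO3 precipitated")

low = cb.solve_state(2650.0, 25.0, 38.0, pH=7.94)
print(f"a 0.1-unit pH drop at constant alkalinity corresponds to "
      f"{low.dic - state.dic:.1f} umol/kg of added DIC (vent CO2 scale)")

flux_h = 3.0e-6  # mol H+ m-2 d-1, a typical ecosystem-scale proton flux
co2eq = cb.proton_flux_to_co2_equivalents(flux_h, state)
print(f"a proton flux of {flux_h:.1e} mol m-2 d-1 is {co2eq:.0f} "
      "mmol CO2-equivalents m-2 d-1")
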