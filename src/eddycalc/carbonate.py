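"""Seawater CO2-system speciation on the total pH scale.

Solves the carbonate system from total alkalinity plus either pH or DIC,
using the dissociation-constant set conventional for open-ocean work:
Lueker et al. (2000) refit of Mehrbach for carbonic acid, Dickson (1990)
for bisulfate and boric acid, Perez & Fraga (1987) for hydrogen fluoride,
Millero (1995) for water, and the Lee et al. (2010) boron-to-salinity
ratio.  All pH values are on the total hydrogen-ion scale and all
concentrations are per kilogram of seawater.

The module also provides the two finite-difference proton-yield ratios
that connect eddy-covariance proton fluxes to carbon fluxes:

``dh_ddic``
    equilibrium change in total [H+] per unit DIC added at constant
    alkalinity (mol H+ per mol DIC), the buffer response to respiration
    or CO2 intrusion;
``dh_ddic2alk``
    equilibrium change in total [H+] per mole of CaCO3 precipitated,
    i.e. for the stoichiometric perturbation dDIC = -1, dTA = -2
    umol kg-1 (mol H+ per mol CaCO3).

Both are positive numbers for natural seawater.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "ConstantsSet",
    "SeawaterState",
    "compute_constants",
    "solve_state",
    "dh_ddic",
    "dh_ddic2alk",
    "proton_flux_to_co2_equivalents",
    "seawater_density",
]

# Lueker et al. (2000) fit validity
_T_RANGE = (0.0, 40.0)
_S_RANGE = (19.0, 43.0)


class CarbonateRangeError(ValueError):
    """Input outside the validity range of the constant parameterizations."""


class CarbonateSolverError(RuntimeError):
    """The pH root solve failed or produced inconsistent speciation."""


@dataclass(frozen=True)
class ConstantsSet:
    """Stoichiometric dissociation constants at fixed T, S, P.

    Equilibrium constants are in mol kg-sw-1 on the total pH scale,
    except ``kso4`` (free scale, as published).  Totals are umol kg-1.
    """

    temperature: float
    salinity: float
    pressure: float
    k1: float
    k2: float
    kb: float
    kw: float
    kso4: float
    kf: float
    total_boron: float
    total_sulfate: float
    total_fluoride: float


def compute_constants(temperature: float, salinity: float, pressure: float = 0.0) -> ConstantsSet:
    """Dissociation constants and totals for the deployment constant set.

    Parameters
    ----------
    temperature : float
        In-situ temperature, degrees C.  Valid 0-40.
    salinity : float
        Practical salinity.  Valid 19-43 (Lueker fit range).
    pressure : float
        Gauge pressure in dbar; must be >= 0.  Constants are evaluated at
        one atmosphere: over the <15 m deployment depths the pressure
        corrections to the constants are far below the other error terms.
    """
    if not _T_RANGE[0] <= temperature <= _T_RANGE[1]:
        raise CarbonateRangeError(
            f"temperature {temperature} C outside Lueker validity {_T_RANGE}"
        )
    if not _S_RANGE[0] <= salinity <= _S_RANGE[1]:
        raise CarbonateRangeError(
            f"salinity {salinity} outside Lueker validity {_S_RANGE}"
        )
    if pressure < 0:
        raise CarbonateRangeError(f"pressure {pressure} dbar must be >= 0")

    t_k = temperature + 273.15
    ln_t = math.log(t_k)
    s = salinity
    sqrt_s = math.sqrt(s)

    # Carbonic acid, Lueker et al. (2000), total scale, mol/kg-sw
    pk1 = 3633.86 / t_k - 61.2172 + 9.6777 * ln_t - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / t_k + 25.929 - 3.16967 * ln_t - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Boric acid, Dickson (1990b), total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s) / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_t
        + 0.053105 * sqrt_s * t_k
    )
    kb = math.exp(ln_kb)

    # Water, Millero (1995) fit as tabulated on the total scale
    ln_kw = (
        148.9652
        - 13847.26 / t_k
        - 23.6521 * ln_t
        + (118.67 / t_k - 5.977 + 1.0495 * ln_t) * sqrt_s
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    # Bisulfate, Dickson (1990a), free scale, mol/kg-sw
    ion_s = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ks = (
        -4276.1 / t_k
        + 141.328
        - 23.093 * ln_t
        + (-13856.0 / t_k + 324.57 - 47.986 * ln_t) * math.sqrt(ion_s)
        + (35474.0 / t_k - 771.54 + 114.723 * ln_t) * ion_s
        - 2698.0 / t_k * ion_s ** 1.5
        + 1776.0 / t_k * ion_s * ion_s
        + math.log(1.0 - 0.001005 * s)
    )
    kso4 = math.exp(ln_ks)

    # Hydrogen fluoride, Perez & Fraga (1987), total scale
    kf = math.exp(874.0 / t_k - 9.68 + 0.111 * sqrt_s)

    # Totals (umol/kg): boron from Lee et al. (2010); sulfate and fluoride
    # from chlorinity proportionality
    total_boron = 0.0004326 * s / 35.0 * 1e6
    total_sulfate = (0.14 / 96.062) * (s / 1.80655) * 1e6
    total_fluoride = (0.000067 / 18.998) * (s / 1.80655) * 1e6

    return ConstantsSet(
        temperature=temperature,
        salinity=salinity,
        pressure=pressure,
        k1=k1,
        k2=k2,
        kb=kb,
        kw=kw,
        kso4=kso4,
        kf=kf,
        total_boron=total_boron,
        total_sulfate=total_sulfate,
        total_fluoride=total_fluoride,
    )


@dataclass(frozen=True)
class SeawaterState:
    """One water parcel's solved carbonate system.

    Concentrations in umol kg-1 except ``pH`` (total scale) and
    ``density`` (kg m-3).  Constructed via :func:`solve_state`.
    """

    temperature: float
    salinity: float
    pressure: float
    total_alkalinity: float
    pH: float
    dic: float
    density: float
    co2: float
    hco3: float
    co3: float
    boh4: float
    oh: float
    h_free: float
    hso4: float
    hf: float
    constants: ConstantsSet = field(repr=False)

    def alkalinity_residual(self) -> float:
        """Reconstructed alkalinity minus nominal, umol kg-1 (closure check)."""
        recon = (
            self.hco3 + 2.0 * self.co3 + self.boh4 + self.oh
            - self.h_free - self.hso4 - self.hf
        )
        return recon - self.total_alkalinity

    def to_record(self) -> str:
        """Flat one-line-per-field text serialization."""
        fields = (
            "temperature", "salinity", "pressure", "total_alkalinity",
            "pH", "dic", "density", "co2", "hco3", "co3", "boh4", "oh",
            "h_free", "hso4", "hf",
        )
        return "\n".join(f"{name} = {getattr(self, name):.10g}" for name in fields)


def _speciation(alkalinity: float, ph: float, k: ConstantsSet) -> dict:
    """Species concentrations (umol/kg) at given TA and total-scale pH.

    DIC is derived from the carbonate alkalinity left after the minor
    acid-base contributions are removed.
    """
    h_t = 10.0 ** (-ph)  # mol/kg, total scale
    ts = k.total_sulfate * 1e-6
    tf = k.total_fluoride * 1e-6
    tb = k.total_boron * 1e-6

    h_free = h_t / (1.0 + ts / k.kso4)
    oh = k.kw / h_t
    boh4 = tb * k.kb / (k.kb + h_t)
    hso4 = ts / (1.0 + k.kso4 / h_free)
    hf = tf / (1.0 + k.kf / h_t)

    # carbonate alkalinity (mol/kg)
    ca = alkalinity * 1e-6 - boh4 - oh + h_free + hso4 + hf
    denom = k.k1 * h_t + 2.0 * k.k1 * k.k2
    dic = ca * (h_t * h_t + k.k1 * h_t + k.k1 * k.k2) / denom
    co2 = dic * h_t * h_t / (h_t * h_t + k.k1 * h_t + k.k1 * k.k2)
    hco3 = dic * k.k1 * h_t / (h_t * h_t + k.k1 * h_t + k.k1 * k.k2)
    co3 = dic * k.k1 * k.k2 / (h_t * h_t + k.k1 * h_t + k.k1 * k.k2)

    return {
        "dic": dic * 1e6,
        "co2": co2 * 1e6,
        "hco3": hco3 * 1e6,
        "co3": co3 * 1e6,
        "boh4": boh4 * 1e6,
        "oh": oh * 1e6,
        "h_free": h_free * 1e6,
        "hso4": hso4 * 1e6,
        "hf": hf * 1e6,
    }


def _ph_from_dic(alkalinity: float, dic: float, k: ConstantsSet) -> float:
    """Bracketed root solve for total-scale pH given TA and DIC."""

    def residual(ph: float) -> float:
        return _speciation(alkalinity, ph, k)["dic"] - dic

    lo, hi = 2.0, 12.0
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise CarbonateSolverError(
            f"no pH root bracketed in [2, 12] for TA={alkalinity}, DIC={dic}"
        )
    # residual is monotone decreasing in pH at fixed TA
    return brentq(residual, lo, hi, xtol=1e-10)


def solve_state(
    alkalinity: float,
    temperature: float,
    salinity: float,
    pressure: float = 0.0,
    *,
    pH: float | None = None,
    dic: float | None = None,
) -> SeawaterState:
    """Solve the full carbonate system from TA plus exactly one of pH, DIC.

    Parameters
    ----------
    alkalinity : float
        Total alkalinity, umol kg-1, in (0, 10000].
    pH, dic : float
        Exactly one must be given; pH on the total scale in [2, 12],
        DIC in umol kg-1.

    Returns
    -------
    SeawaterState
        With both pH and DIC set and the full speciation.
    """
    if (pH is None) == (dic is None):
        raise ValueError("exactly one of pH and dic must be given")
    if not 0.0 < alkalinity <= 10000.0:
        raise CarbonateRangeError(f"alkalinity {alkalinity} outside (0, 10000] umol/kg")
    if pH is not None and not 2.0 <= pH <= 12.0:
        raise CarbonateRangeError(f"pH {pH} outside [2, 12]")

    k = compute_constants(temperature, salinity, pressure)
    if pH is None:
        pH = _ph_from_dic(alkalinity, dic, k)
    spec = _speciation(alkalinity, pH, k)
    if dic is None:
        dic = spec["dic"]
    if min(spec["co2"], spec["hco3"], spec["co3"]) < 0:
        raise CarbonateSolverError(
            f"negative carbonate species at TA={alkalinity}, pH={pH}"
        )
    return SeawaterState(
        temperature=temperature,
        salinity=salinity,
        pressure=pressure,
        total_alkalinity=alkalinity,
        pH=pH,
        dic=dic,
        density=seawater_density(temperature, salinity, pressure),
        co2=spec["co2"],
        hco3=spec["hco3"],
        co3=spec["co3"],
        boh4=spec["boh4"],
        oh=spec["oh"],
        h_free=spec["h_free"],
        hso4=spec["hso4"],
        hf=spec["hf"],
        constants=k,
    )


def _h_total_umol(state_like_ta: float, dic: float, k: ConstantsSet) -> float:
    """Total [H+] (umol/kg) at equilibrium for given TA and DIC."""
    ph = _ph_from_dic(state_like_ta, dic, k)
    return 10.0 ** (-ph) * 1e6


def dh_ddic(state: SeawaterState, step: float = 1.0) -> float:
    """Proton yield per unit DIC added at constant alkalinity.

    Central finite difference with the stated DIC perturbation step
    (umol kg-1).  Dimensionless (mol H+ per mol DIC), positive.
    """
    k = state.constants
    h_plus = _h_total_umol(state.total_alkalinity, state.dic + step, k)
    h_minus = _h_total_umol(state.total_alkalinity, state.dic - step, k)
    return (h_plus - h_minus) / (2.0 * step)


def dh_ddic2alk(state: SeawaterState, step: float = 1.0) -> float:
    """Proton yield per mole of CaCO3 precipitated.

    Precipitating ``step`` umol kg-1 of CaCO3 removes ``step`` DIC and
    ``2 * step`` alkalinity.  Central difference between the
    precipitation and dissolution perturbations; dimensionless
    (mol H+ per mol CaCO3), positive.
    """
    k = state.constants
    h_precip = _h_total_umol(
        state.total_alkalinity - 2.0 * step, state.dic - step, k
    )
    h_dissol = _h_total_umol(
        state.total_alkalinity + 2.0 * step, state.dic + step, k
    )
    return (h_precip - h_dissol) / (2.0 * step)


def proton_flux_to_co2_equivalents(h_flux: float, state: SeawaterState) -> float:
    """Express a proton flux in CO2 equivalents.

    Parameters
    ----------
    h_flux : float
        Proton flux, mol H+ m-2 d-1.

    Returns
    -------
    float
        Flux in mmol CO2-equivalents m-2 d-1: ``h_flux * dDIC/dH+``,
        the DIC change that would produce the observed proton flux
        through carbonate-system equilibration.
    """
    ratio = dh_ddic(state)
    if ratio == 0.0:
        raise CarbonateSolverError("degenerate buffer: dh_ddic is zero")
    return h_flux / ratio * 1e3


def seawater_density(temperature: float, salinity: float, pressure: float = 0.0) -> float:
    """One-atmosphere seawater density (kg m-3), EOS-80.

    Millero & Poisson (1981) fit; the dbar-level pressure dependence is
    irrelevant for the shallow deployments this package targets and is
    not applied.
    """
    if not -2.0 <= temperature <= 40.0 or not 0.0 <= salinity <= 43.0:
        raise CarbonateRangeError(
            f"T={temperature}, S={salinity} outside EOS-80 fit range"
        )
    t = temperature
    s = salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t ** 2
        + 1.001685e-4 * t ** 3
        - 1.120083e-6 * t ** 4
        + 6.536332e-9 * t ** 5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t ** 2
        - 8.2467e-7 * t ** 3
        + 5.3875e-9 * t ** 4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t ** 2
    c = 4.8314e-4
    return rho_w + a * s + b * s ** 1.5 + c * s ** 2


def perturbed(state: SeawaterState, *, d_dic: float = 0.0, d_alk: float = 0.0) -> SeawaterState:
    """Re-equilibrated state after adding DIC and/or alkalinity (umol/kg)."""
    return solve_state(
        state.total_alkalinity + d_alk,
        state.temperature,
        state.salinity,
        state.pressure,
        dic=state.dic + d_dic,
    )


def with_ph_offset(state: SeawaterState, delta_ph: float) -> SeawaterState:
    """State re-solved with a biased pH at the same alkalinity (sensor-error model)."""
    return solve_state(
        state.total_alkalinity,
        state.temperature,
        state.salinity,
        state.pressure,
        pH=state.pH + delta_ph,
    )
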