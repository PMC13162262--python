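"""Error propagation for the dual-tracer calcification inversion.

The calcification signal is a small residual between two larger proton
terms, so measurement biases in pH, alkalinity, or the photosynthetic
quotient Q inflate the relative error of G_net roughly as 1/(G_net /
P_net).  This module quantifies that amplification by a forward /
perturbed-inverse experiment: true fluxes are generated from prescribed
(P_net, G_net) at the true carbonate state and quotient, then inverted
with a state (or quotient) carrying the prescribed bias.

By default only the inversion state is biased while the flux inputs are
the true ones, which isolates the error contributed through the assumed
proton-yield ratios.  For a pH bias, ``bias_measured_flux=True``
additionally scales the measured proton flux by 10**(-dpH) -- a biased
pH sensor multiplies the inferred [H+] fluctuations by that factor --
which partially cancels the ratio errors and is the physically complete
single-sensor bias model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calcify import gnet
from .carbonate import (
    SeawaterState,
    dh_ddic,
    dh_ddic2alk,
    solve_state,
)

__all__ = ["PerturbationSpec", "ErrorCurve", "forward_fluxes", "gnet_error_curve"]

_PARAMETERS = ("pH", "alkalinity", "Q")


@dataclass(frozen=True)
class PerturbationSpec:
    """One measurement-error scenario.

    ``magnitude`` is in pH units for pH, umol kg-1 for alkalinity, and a
    relative fraction for Q (0.10 = a 10% overestimate).
    """

    parameter: str
    magnitude: float
    baseline_state: SeawaterState
    q_true: float

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise ValueError(f"parameter must be one of {_PARAMETERS}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.q_true <= 0:
            raise ValueError("q_true must be positive")


@dataclass
class ErrorCurve:
    """Relative G_net error versus the true G_net/P_net ratio."""

    ratios: np.ndarray
    relative_error: np.ndarray  # fraction of true G_net, signed
    spec: PerturbationSpec = field(repr=False, default=None)  # type: ignore[assignment]


def forward_fluxes(state: SeawaterState, p_net: float, g_net: float, q: float):
    """Fluxes implied by prescribed net photosynthesis and calcification.

    Parameters
    ----------
    p_net, g_net : float
        mmol C m-2 d-1 and mmol CaCO3 m-2 d-1.

    Returns
    -------
    (flux_o2, flux_h) : mmol O2 m-2 d-1 and mol H+ m-2 d-1.
    """
    if q <= 0:
        raise ValueError("photosynthetic quotient must be positive")
    flux_o2 = p_net * q
    flux_h = (-p_net * dh_ddic(state) + g_net * dh_ddic2alk(state)) * 1e-3
    return flux_o2, flux_h


def _perturbed_inputs(spec: PerturbationSpec):
    """(state, q, h_flux_scale) seen by the biased analyst."""
    st, q = spec.baseline_state, spec.q_true
    if spec.parameter == "pH":
        biased = solve_state(
            st.total_alkalinity, st.temperature, st.salinity, st.pressure,
            pH=st.pH + spec.magnitude,
        )
        return biased, q, 10.0 ** (-spec.magnitude)
    if spec.parameter == "alkalinity":
        biased = solve_state(
            st.total_alkalinity + spec.magnitude,
            st.temperature, st.salinity, st.pressure, pH=st.pH,
        )
        return biased, q, 1.0
    return st, q * (1.0 + spec.magnitude), 1.0


def gnet_error_curve(
    spec: PerturbationSpec,
    ratio_grid,
    p_net: float = 100.0,
    bias_measured_flux: bool = False,
) -> ErrorCurve:
    """Relative G_net error across a grid of true G_net/P_net ratios.

    For each ratio r, true fluxes are generated with ``p_net`` (the
    absolute scale is immaterial; errors are relative) and g_net =
    r * p_net at the true state and Q, then inverted with the biased
    inputs of ``spec``.  Ratios of zero are dropped with a warning (the
    relative error is undefined there).
    """
    ratios = np.asarray(ratio_grid, dtype=float)
    if np.any(ratios == 0.0):
        warnings.warn("ratio 0 excluded: relative G_net error undefined", stacklevel=2)
        ratios = ratios[ratios != 0.0]
    state_hat, q_hat, h_scale = _perturbed_inputs(spec)
    if not bias_measured_flux:
        h_scale = 1.0
    errors = np.empty_like(ratios)
    for i, r in enumerate(ratios):
        g_true = r * p_net
        flux_o2, flux_h = forward_fluxes(spec.baseline_state, p_net, g_true, spec.q_true)
        g_hat = gnet(flux_h * h_scale, flux_o2, q_hat, state_hat)
        errors[i] = (g_hat - g_true) / g_true
    return ErrorCurve(ratios=ratios, relative_error=errors, spec=spec)
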