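"""End-to-end processing: raw channels -> flux windows -> calcification.

Glue over :mod:`eddycalc.eddy`, :mod:`eddycalc.carbonate` and
:mod:`eddycalc.calcify`; all tunables come from a :class:`RunConfig`
(:mod:`eddycalc.config`).
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import calcify as cf
from .carbonate import dh_ddic, seawater_density, solve_state
from .config import RunConfig
from .eddy import (
    ChannelSeries,
    FluxWindow,
    VelocityRecord,
    compute_flux,
    cumulative_flux_qc,
    despike,
    downsample,
    lag_align,
    planar_fit,
    reynolds_decompose,
    storage_flux,
)

__all__ = ["process_windows", "calcify_windows", "windows_to_frame"]


def windows_to_frame(windows: list[FluxWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        d = asdict(w)
        d["qc_flags"] = ";".join(sorted(w.qc_flags))
        rows.append(d)
    return pd.DataFrame(rows)


def _window_grid(n: int, rate: float, config: RunConfig, start_time: float):
    """Yield (i0, i1, t0, t1) for each eligible averaging window."""
    block = config.block_min * 60.0
    window = config.window_min * 60.0
    edge = config.edge_exclusion_s
    total_s = n / rate
    b = 0
    while (b + 1) * block <= total_s + 1e-9:
        t0 = b * block
        t1 = t0 + window
        b += 1
        if t0 < edge or t1 > total_s - edge:
            continue
        yield int(round(t0 * rate)), int(round(t1 * rate)), start_time + t0, start_time + t1


def process_windows(
    velocity: VelocityRecord,
    scalars: dict[str, ChannelSeries],
    config: RunConfig | None = None,
):
    """Quality-controlled covariance fluxes for each scalar channel.

    Velocities are block-averaged to the scalar rate, tilt-corrected
    with a whole-deployment planar fit, and Reynolds-decomposed together
    with each scalar (centered running mean); each 29-min window is then
    lag-aligned and its flux, linearity QC and flow statistics computed.

    Returns
    -------
    (windows, fit) : dict of scalar name -> list[FluxWindow], PlanarFit
    """
    config = config or RunConfig()
    rate = config.target_rate_hz
    u5 = downsample(velocity.u, rate)
    v5 = downsample(velocity.v, rate)
    w5 = downsample(velocity.w, rate)
    n = min(len(u5), len(v5), len(w5), *(len(s) for s in scalars.values()))
    density = seawater_density(config.temperature, config.salinity)

    grid = list(_window_grid(n, rate, config, velocity.u.start_time))
    if not grid:
        raise ValueError("record too short for any averaging window")

    # tilt plane from 5-min segment means over the whole deployment
    seg = int(round(config.planar_fit_segment_s * rate))
    n_seg = n // seg
    means = np.array(
        [
            [
                np.nanmean(u5.values[i * seg : (i + 1) * seg]),
                np.nanmean(v5.values[i * seg : (i + 1) * seg]),
                np.nanmean(w5.values[i * seg : (i + 1) * seg]),
            ]
            for i in range(n_seg)
        ]
    )
    fit = planar_fit(means)
    ur, vr, wr = fit.apply(u5.values[:n], v5.values[:n], w5.values[:n])

    _, w_prime = reynolds_decompose(wr, rate, config.running_mean_s)

    out: dict[str, list[FluxWindow]] = {}
    for name, chan in scalars.items():
        raw_gaps = chan.gaps[:n]
        vals = chan.masked()[:n]
        if config.despike_enabled:
            vals = despike(vals, rate, config.despike_n_mad, config.despike_window_s)
        cmean, c_prime = reynolds_decompose(vals, rate, config.running_mean_s)
        windows: list[FluxWindow] = []
        for i0, i1, t0, t1 in grid:
            wp = w_prime[i0:i1]
            cp = c_prime[i0:i1]
            shifted, lag_s, lag_flags = lag_align(
                wp, cp, rate, config.max_lag_s, config.low_corr_threshold
            )
            flags = set(lag_flags)
            if raw_gaps[i0:i1].any():
                flags.add("pump_reversal_masked")
            um, vm = np.nanmean(ur[i0:i1]), np.nanmean(vr[i0:i1])
            speed_cm = 100.0 * math.hypot(um, vm)
            if speed_cm < config.low_speed_cm_s:
                flags.add("low_turbulence")
            qc = cumulative_flux_qc(
                wp,
                shifted,
                config.qc_r2_threshold,
                config.qc_burst_sample_fraction,
                config.qc_burst_change_fraction,
            )
            if not qc["linear"]:
                flags.add("nonlinear_cumulative")
            win = compute_flux(
                wp,
                shifted,
                None,
                density,
                start=t0,
                end=t1,
                applied_lag=lag_s,
                min_valid_fraction=config.min_valid_fraction,
                extra_flags=flags,
            )
            win.mean_speed = speed_cm
            win.mean_direction = math.degrees(math.atan2(um, vm)) % 360.0
            win.mean_scalar = float(np.nanmean(cmean[i0:i1]))
            windows.append(win)
        out[name] = windows
    return out, fit


def calcify_windows(
    h_windows: list[FluxWindow],
    o2_windows: list[FluxWindow],
    light_flags,
    config: RunConfig | None = None,
):
    """Pair proton and O2 flux windows and invert for G_net.

    ``h_windows`` must be fluxes of total [H+] carried in umol kg-1
    (i.e. the flux values are mmol "H+" m-2 d-1); ``light_flags`` is a
    boolean per window.  The per-window carbonate state uses the
    window-mean pH (from the running-mean [H+]) and the deployment's
    fixed alkalinity, temperature and salinity.
    """
    config = config or RunConfig()
    if not (len(h_windows) == len(o2_windows) == len(light_flags)):
        raise ValueError("window lists must be aligned")
    q = config.effective_q()
    density = seawater_density(config.temperature, config.salinity)
    storage = np.zeros(len(o2_windows))
    if config.storage_correction and len(o2_windows) > 1:
        # rate of change of the O2 inventory below the sensor, from the
        # centered difference of neighbouring window means
        means = np.array([w.mean_scalar for w in o2_windows])
        mids = np.array([(w.start + w.end) / 2.0 for w in o2_windows])
        for i in range(len(o2_windows)):
            j0, j1 = max(0, i - 1), min(len(o2_windows) - 1, i + 1)
            dt = mids[j1] - mids[j0]
            if dt > 0 and np.isfinite(means[j0]) and np.isfinite(means[j1]):
                storage[i] = storage_flux(
                    means[j0], means[j1], dt, config.storage_layer_m, density
                )
    out: list[cf.CalcificationWindow] = []
    for (hw, ow, light), stor in zip(
        zip(h_windows, o2_windows, light_flags), storage
    ):
        if abs(hw.start - ow.start) > 1e-6:
            raise ValueError("proton and O2 windows are not aligned in time")
        flags = set(hw.qc_flags) | set(ow.qc_flags)
        if not np.isfinite(hw.flux) or not np.isfinite(ow.flux):
            flags.add("invalid")
        mean_h_umol = hw.mean_scalar
        if not np.isfinite(mean_h_umol) or mean_h_umol <= 0:
            flags.add("invalid")
            state = None
        else:
            ph_mean = -math.log10(mean_h_umol * 1e-6)
            state = solve_state(
                config.alkalinity, config.temperature, config.salinity, pH=ph_mean
            )
        o2_flux = ow.flux - stor  # storage subtracts from the benthic efflux
        if state is not None and "invalid" not in flags:
            flux_h = hw.flux * 1e-3  # mmol -> mol H+ m-2 d-1
            g = cf.gnet(flux_h, o2_flux, q, state)
            co2eq = flux_h * 1e3 / dh_ddic(state)
        else:
            flux_h, g, co2eq = np.nan, np.nan, np.nan
        out.append(
            cf.CalcificationWindow(
                start=hw.start,
                end=hw.end,
                flux_h=flux_h,
                flux_h_co2_equiv=co2eq,
                flux_o2=o2_flux,
                q=q,
                gnet=g,
                light=bool(light),
                mean_direction=hw.mean_direction,
                qc_flags=frozenset(flags),
            )
        )
    return cf.vent_flag(
        out,
        config.vent_ratio_threshold,
        config.vent_direction_sectors,
        config.vent_o2_floor,
    )
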