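"""Aquatic eddy-covariance flux processing.

Turns raw velocity and scalar time series into quality-controlled
29-minute benthic fluxes: block-mean downsampling to the scalar rate,
planar-fit tilt rotation, Reynolds decomposition with a 500 s running
mean, cross-correlation lag alignment (+/-2 s), covariance fluxes with
pump-reversal masking, cumulative-flux linearity QC, and cospectral
diagnostics (ogives, high-frequency loss).

Scalars are expected in umol kg-1 (protons may be carried in umol kg-1
after :func:`ph_to_proton` / 1e3); fluxes come out in mmol m-2 d-1 with
positive = efflux from the bed into the water column (w positive up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ChannelSeries",
    "VelocityRecord",
    "FluxWindow",
    "Cospectrum",
    "PlanarFit",
    "downsample",
    "planar_fit",
    "reynolds_decompose",
    "lag_align",
    "compute_flux",
    "cumulative_flux_qc",
    "cospectrum",
    "estimate_highfreq_loss",
    "storage_flux",
    "ph_to_proton",
    "calibrate_isfet",
    "despike",
]

SECONDS_PER_DAY = 86400.0


class InsufficientDataError(ValueError):
    """Series too short for the requested operation."""


class DegenerateGeometryError(ValueError):
    """Planar fit cannot be determined from the supplied mean flows."""


class CalibrationError(ValueError):
    """Reference point unusable for single-point calibration."""


@dataclass
class ChannelSeries:
    """One uniformly sampled sensor channel.

    ``start_time`` is seconds since an arbitrary epoch shared by all
    channels of a deployment; sample i is at ``start_time + i / rate``.
    Invalid samples are marked both by NaN in ``values`` and True in
    ``gaps``.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    units: str = ""
    gaps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gaps is None:
            self.gaps = ~np.isfinite(self.values)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)
            if self.gaps.shape != self.values.shape:
                raise ValueError("gap mask length must match values")
            self.gaps = self.gaps | ~np.isfinite(self.values)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[self.gaps] = np.nan
        return out


@dataclass
class VelocityRecord:
    """Three-component velocity on a common timebase (m s-1).

    Heading convention: u east, v north before rotation; reported flow
    direction is degrees clockwise from north.
    """

    u: ChannelSeries
    v: ChannelSeries
    w: ChannelSeries

    def __post_init__(self) -> None:
        for c in (self.v, self.w):
            if (
                len(c) != len(self.u)
                or c.rate != self.u.rate
                or c.start_time != self.u.start_time
            ):
                raise ValueError("u, v, w must share start_time, rate and length")


@dataclass
class FluxWindow:
    """One 29-min averaging interval's flux and QC state."""

    start: float
    end: float
    flux: float  # mmol m-2 d-1 (units of c assumed umol/kg)
    mean_speed: float = np.nan  # cm s-1
    mean_direction: float = np.nan  # degrees clockwise from north
    applied_lag: float = 0.0  # s
    qc_flags: frozenset = frozenset()
    n_samples: int = 0
    mean_scalar: float = np.nan  # window-mean scalar, input units

    @property
    def valid(self) -> bool:
        return np.isfinite(self.flux) and not self.qc_flags & {
            "invalid",
            "nonlinear_cumulative",
        }


@dataclass
class Cospectrum:
    """Cross-spectral density of w' and c' with its normalized ogive."""

    frequencies: np.ndarray
    co_density: np.ndarray  # flux units per Hz
    ogive: np.ndarray  # cumulative flux fraction from lowest frequency
    total: float  # covariance (integral of co_density)


def downsample(series: ChannelSeries, target_rate: float = 5.0) -> ChannelSeries:
    """Block-mean resample onto a lower-rate grid.

    Each output sample is the mean of the valid input samples falling in
    its time block; a block with fewer than half its samples valid
    becomes a gap.  Non-integer rate ratios (16 -> 5 Hz) are handled by
    assigning input samples to blocks by time.
    """
    if target_rate > series.rate:
        raise ValueError("target rate must not exceed input rate")
    n = len(series)
    if n == 0:
        return ChannelSeries(np.empty(0), target_rate, series.start_time, series.units)
    idx = np.floor(np.arange(n) / series.rate * target_rate).astype(np.int64)
    n_out = int(idx[-1]) + 1
    vals = series.masked()
    good = np.isfinite(vals)
    sums = np.bincount(idx[good], weights=vals[good], minlength=n_out)
    counts = np.bincount(idx[good], minlength=n_out)
    totals = np.bincount(idx, minlength=n_out)
    out = np.full(n_out, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    gap = counts < 0.5 * totals
    out[gap] = np.nan
    return ChannelSeries(out, target_rate, series.start_time, series.units, gap)


@dataclass
class PlanarFit:
    """Tilt rotation fitted to the deployment's mean-flow plane.

    Rows of ``rotation`` are the new (streamwise-x, cross-y, vertical-z)
    unit vectors in instrument coordinates; ``w_offset`` is the fitted
    vertical-velocity bias removed before rotation.
    """

    rotation: np.ndarray  # (3, 3), orthonormal
    w_offset: float
    tilt_deg: float

    def apply(self, u: np.ndarray, v: np.ndarray, w: np.ndarray):
        vel = np.vstack([u, v, np.asarray(w) - self.w_offset])
        out = self.rotation @ vel
        return out[0], out[1], out[2]


def planar_fit(mean_velocities: np.ndarray) -> PlanarFit:
    """Fit the mean-flow plane of Wilczak-style tilt correction.

    Parameters
    ----------
    mean_velocities : (n, 3) array
        Window-mean (u, v, w) vectors, n >= 6, spanning at least two
        distinct horizontal directions.
    """
    m = np.asarray(mean_velocities, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] < 6:
        raise InsufficientDataError("need >= 6 mean-velocity vectors of shape (n, 3)")
    design = np.column_stack([np.ones(len(m)), m[:, 0], m[:, 1]])
    # guard collinear flows: horizontal directions must span the plane
    sv = np.linalg.svd(m[:, :2] - m[:, :2].mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-8 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("mean flows are collinear; tilt plane undetermined")
    coef, *_ = np.linalg.lstsq(design, m[:, 2], rcond=None)
    b0, b1, b2 = coef
    norm = math.sqrt(1.0 + b1 * b1 + b2 * b2)
    k = np.array([-b1, -b2, 1.0]) / norm  # unit normal of the mean-flow plane
    # streamwise axis: instrument x projected into the plane
    i = np.array([1.0, 0.0, 0.0])
    i = i - np.dot(i, k) * k
    i /= np.linalg.norm(i)
    j = np.cross(k, i)
    rot = np.vstack([i, j, k])
    tilt = math.degrees(math.acos(min(1.0, k[2])))
    return PlanarFit(rotation=rot, w_offset=float(b0), tilt_deg=tilt)


def reynolds_decompose(values: np.ndarray, rate: float, window_s: float = 500.0):
    """Split a series into running mean and fluctuation.

    Centered running mean of ``window_s`` seconds; the averaging window
    shrinks symmetrically at the record edges.  NaN samples are ignored
    in the mean and stay NaN in the fluctuation.

    Returns
    -------
    (mean, fluctuation) : ndarray pair
    """
    x = np.asarray(values, dtype=float)
    win = int(round(window_s * rate))
    if win % 2 == 0:
        win += 1
    if len(x) < win:
        raise InsufficientDataError(
            f"series of {len(x)} samples shorter than {win}-sample running mean"
        )
    mean = (
        pd.Series(x).rolling(window=win, center=True, min_periods=1).mean().to_numpy()
    )
    return mean, x - mean


def lag_align(
    w_prime: np.ndarray,
    c_prime: np.ndarray,
    rate: float,
    max_lag_s: float = 2.0,
    low_corr_threshold: float = 0.05,
):
    """Align a scalar to vertical velocity at their peak cross-correlation.

    Searches integer-sample lags within +/- ``max_lag_s``; positive lag
    means the scalar lags (is delayed relative to) the velocity.  Ties
    are broken toward the smaller absolute lag.

    Returns
    -------
    (shifted_c_prime, lag_s, flags) where ``flags`` may contain
    ``low_correlation`` or ``undefined_correlation``.
    """
    w = np.asarray(w_prime, dtype=float)
    c = np.asarray(c_prime, dtype=float)
    if len(w) != len(c):
        raise ValueError("series must have equal length")
    max_lag = int(round(max_lag_s * rate))
    flags: set[str] = set()

    def corr_at(lag: int) -> float:
        if lag >= 0:
            a, b = w[: len(w) - lag], c[lag:]
        else:
            a, b = w[-lag:], c[: len(c) + lag]
        good = np.isfinite(a) & np.isfinite(b)
        if good.sum() < 3:
            return 0.0
        a, b = a[good], b[good]
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            return np.nan
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    best_lag, best_r = 0, np.nan
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        r = corr_at(lag)
        if np.isnan(r):
            continue
        if np.isnan(best_r) or abs(r) > abs(best_r):
            best_lag, best_r = lag, r
    if np.isnan(best_r):
        flags.add("undefined_correlation")
        best_lag, best_r = 0, 0.0
    elif abs(best_r) < low_corr_threshold:
        flags.add("low_correlation")

    shifted = np.full_like(c, np.nan)
    if best_lag >= 0:
        shifted[: len(c) - best_lag] = c[best_lag:]
    else:
        shifted[-best_lag:] = c[: len(c) + best_lag]
    return shifted, best_lag / rate, flags


def compute_flux(
    w_prime: np.ndarray,
    c_prime: np.ndarray,
    pump_mask: np.ndarray | None,
    density: float,
    *,
    start: float = 0.0,
    end: float = np.nan,
    applied_lag: float = 0.0,
    min_valid_fraction: float = 0.5,
    extra_flags: set | frozenset = frozenset(),
) -> FluxWindow:
    """Covariance flux over one averaging window.

    flux = mean(w'c') over unmasked samples, converted from
    (m s-1)(umol kg-1) to mmol m-2 d-1 via seawater density and the
    86400 s day.  Positive flux is efflux from the bed (w positive up).
    Windows with fewer than ``min_valid_fraction`` valid samples are
    invalidated.
    """
    w = np.asarray(w_prime, dtype=float)
    c = np.asarray(c_prime, dtype=float)
    prod = w * c
    valid = np.isfinite(prod)
    if pump_mask is not None:
        valid &= ~np.asarray(pump_mask, dtype=bool)
    flags = set(extra_flags)
    n_valid = int(valid.sum())
    if n_valid < min_valid_fraction * len(prod):
        flags.add("invalid")
        flux = np.nan
    else:
        cov = float(np.mean(prod[valid]))  # (m/s)(umol/kg)
        flux = cov * density * SECONDS_PER_DAY / 1000.0
    cvals = c[np.isfinite(c)]
    return FluxWindow(
        start=start,
        end=end,
        flux=flux,
        applied_lag=applied_lag,
        qc_flags=frozenset(flags),
        n_samples=n_valid,
        mean_scalar=float(cvals.mean()) if cvals.size else np.nan,
    )


def cumulative_flux_qc(
    w_prime: np.ndarray,
    c_prime: np.ndarray,
    r2_threshold: float = 0.8,
    burst_sample_fraction: float = 0.05,
    burst_change_fraction: float = 0.5,
) -> dict:
    """Linearity diagnostics of the cumulative flux contribution.

    The cumulative sum of w'c' should grow linearly in time for a
    stationary flux; a poor linear fit (R^2 below threshold) or a burst
    (more than half the cumulative change carried by <5% of samples)
    flags the window.  Windows with negligible net covariance are
    reported ``low_flux`` rather than nonlinear.
    """
    prod = np.asarray(w_prime, dtype=float) * np.asarray(c_prime, dtype=float)
    prod = np.where(np.isfinite(prod), prod, 0.0)
    cum = np.cumsum(prod)
    t = np.arange(len(cum), dtype=float)
    res = stats.linregress(t, cum)
    r2 = float(res.rvalue**2)
    # a net covariance indistinguishable from zero (under 3 standard errors
    # of the random-walk total) cannot violate linearity
    total = abs(cum[-1])
    # robust scale so a burst does not inflate its own null band
    sigma = 1.4826 * float(np.median(np.abs(prod - np.median(prod))))
    scatter = sigma * math.sqrt(len(prod))
    low_flux = total < 3.0 * max(scatter, 1e-300)
    # burst: any contiguous 5% of samples carrying > 50% of the net change
    k = max(1, int(burst_sample_fraction * len(prod)))
    chunk = np.abs(cum[k:] - cum[:-k]) if len(cum) > k else np.array([total])
    burst = bool(total > 0 and chunk.max() > burst_change_fraction * total)
    nonlinear = (r2 < r2_threshold or burst) and not low_flux
    return {
        "linear": not nonlinear,
        "r2": r2,
        "burst": bool(burst),
        "low_flux": bool(low_flux),
    }


def _interp_gaps(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if bad.all():
        raise InsufficientDataError("all samples invalid")
    if bad.any():
        idx = np.arange(len(x))
        x = x.copy()
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def cospectrum(w_prime: np.ndarray, c_prime: np.ndarray, rate: float) -> Cospectrum:
    """Cospectrum (real cross-spectral density) of w' and c'.

    Single-segment boxcar estimate so the integral over frequency equals
    the window covariance (Parseval).  Gaps are linearly interpolated.
    """
    w = _interp_gaps(w_prime)
    c = _interp_gaps(c_prime)
    if len(w) < 1024:
        raise InsufficientDataError("cospectrum needs >= 1024 samples")
    f, pxy = signal.csd(
        w, c, fs=rate, window="boxcar", nperseg=len(w), detrend="constant"
    )
    co = pxy.real
    df = f[1] - f[0]
    total = float(np.sum(co) * df)
    cum = np.cumsum(co) * df
    ogive = cum / total if total != 0.0 else np.full_like(cum, np.nan)
    return Cospectrum(frequencies=f, co_density=co, ogive=ogive, total=total)


def estimate_highfreq_loss(
    cospectrum_test: Cospectrum, cospectrum_reference: Cospectrum
) -> float:
    """Fraction of flux lost at high frequency by the slower sensor.

    Both unnormalized ogives are scaled to agree at the frequency below
    which the lowest quartile of the reference flux accumulates --
    frequencies low enough that neither sensor attenuates -- and the
    loss is the shortfall of the test ogive at the Nyquist frequency
    relative to the reference.  Negative values (test richer in high
    frequencies) are allowed; the result is clipped to [-0.5, 1].  NaN
    is returned when the low-frequency flux is too small to define the
    scaling.
    """
    df_r = cospectrum_reference.frequencies[1] - cospectrum_reference.frequencies[0]
    df_t = cospectrum_test.frequencies[1] - cospectrum_test.frequencies[0]
    o_ref = np.cumsum(cospectrum_reference.co_density) * df_r
    o_test = np.cumsum(cospectrum_test.co_density) * df_t
    frac = o_ref / o_ref[-1] if o_ref[-1] != 0.0 else np.full_like(o_ref, np.nan)
    above = np.nonzero(frac >= 0.25)[0]
    q = int(above[0]) if above.size else 0
    ref_q, test_q = o_ref[q], o_test[min(q, len(o_test) - 1)]
    if abs(o_ref[-1]) < 1e-300 or abs(ref_q) < 1e-6 * abs(o_ref[-1]) or test_q == 0.0:
        return float("nan")
    loss = 1.0 - (o_test[-1] / test_q) / (o_ref[-1] / ref_q)
    return float(np.clip(loss, -0.5, 1.0))


def storage_flux(
    c_start: float,
    c_end: float,
    dt_s: float,
    layer_height_m: float,
    density: float,
) -> float:
    """Rate of change of solute inventory below the sensor, mmol m-2 d-1.

    Positive when concentration rises; subtract from the measured
    turbulent flux to recover the benthic exchange.  ``c`` in umol kg-1.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    return (c_end - c_start) / dt_s * layer_height_m * density * SECONDS_PER_DAY / 1000.0


def ph_to_proton(ph: np.ndarray) -> np.ndarray:
    """Total-scale pH to total [H+] in nmol kg-1, elementwise."""
    p = np.asarray(ph, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 2.0 or finite.max() > 12.0):
        raise ValueError("pH outside [2, 12]")
    return 10.0 ** (-p) * 1e9


def calibrate_isfet(
    mv: np.ndarray,
    times: np.ndarray,
    reference_time: float,
    reference_ph: float,
    gain_mv_per_ph: float = 590.0,
) -> np.ndarray:
    """Single-point calibration of the raw ISFET signal to total-scale pH.

    pH(t) = pH_ref + (mV(t) - mV(t_ref)) / gain, with the amplified
    ISFET response of ``gain_mv_per_ph`` (default 590 mV per pH unit).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(mv, dtype=float)
    if not t[0] <= reference_time <= t[-1]:
        raise CalibrationError("reference time outside the series span")
    good = np.isfinite(v)
    mv_ref = float(np.interp(reference_time, t[good], v[good]))
    return reference_ph + (v - mv_ref) / gain_mv_per_ph


def despike(
    values: np.ndarray,
    rate: float,
    n_mad: float = 6.0,
    window_s: float = 10.0,
) -> np.ndarray:
    """Median/MAD spike filter; spikes are replaced by NaN.

    A sample deviating from the running median by more than ``n_mad``
    running MADs (within a ``window_s`` window) is treated as a spike.
    """
    x = np.asarray(values, dtype=float)
    win = max(3, int(round(window_s * rate)) | 1)
    s = pd.Series(x)
    med = s.rolling(win, center=True, min_periods=1).median()
    mad = (s - med).abs().rolling(win, center=True, min_periods=1).median()
    # the running median of a locally monotone signal is the center sample,
    # so the local MAD can collapse to zero; floor it with the Gaussian-MAD
    # noise scale estimated from first differences
    diffs = np.abs(np.diff(x[np.isfinite(x)]))
    sigma = np.median(diffs) / 0.9539 if diffs.size else 0.0
    dev = (s - med).abs().to_numpy()
    thresh = n_mad * np.maximum(mad.to_numpy(), max(0.6745 * sigma, 1e-12))
    out = x.copy()
    out[dev > thresh] = np.nan
    return out
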