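"""Delimited-text readers and writers for channels, windows and results.

CSV dialect: comma separator, "." decimal, ISO-8601 UTC timestamps,
mandatory header row; missing values are accepted as "NA" (or empty) on
read and written as "" on write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eddy import ChannelSeries, VelocityRecord

__all__ = [
    "write_channel_csv",
    "read_channel_csv",
    "read_channels",
    "write_windows_csv",
    "read_windows_csv",
]

NA_VALUES = ("NA", "")


class ChannelFormatError(ValueError):
    """Malformed channel file (timestamps, rate, or overlap problems)."""


def _to_epoch_s(ts: pd.Series) -> np.ndarray:
    dt = pd.to_datetime(ts, utc=True, format="ISO8601")
    return dt.astype("int64").to_numpy() / 1e9


def write_channel_csv(path, series: ChannelSeries, name: str = "value") -> None:
    t = pd.to_datetime(series.times(), unit="s", utc=True)
    df = pd.DataFrame(
        {
            "timestamp": t.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            name: series.masked(),
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_channel_csv(path, column: str | None = None) -> ChannelSeries:
    """Read one uniformly sampled channel; infers and validates the rate."""
    df = pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=True)
    if "timestamp" not in df.columns:
        raise ChannelFormatError(f"{path}: missing 'timestamp' column")
    if column is None:
        value_cols = [c for c in df.columns if c != "timestamp"]
        if len(value_cols) != 1:
            raise ChannelFormatError(
                f"{path}: specify which of {value_cols} to read"
            )
        column = value_cols[0]
    t = _to_epoch_s(df["timestamp"])
    dt = np.diff(t)
    dup = np.where(dt <= 0)[0]
    if dup.size:
        raise ChannelFormatError(
            f"{path}: non-monotone or duplicated timestamp at line {dup[0] + 3}"
        )
    step = np.median(dt)
    if np.any(np.abs(dt - step) > 0.01 * step):
        raise ChannelFormatError(f"{path}: sampling interval varies by more than 1%")
    return ChannelSeries(
        df[column].to_numpy(dtype=float),
        rate=1.0 / step,
        start_time=float(t[0]),
        units="",
    )


def read_channels(config) -> dict:
    """Read all configured channels and trim them to their common overlap.

    ``config.channel_paths`` holds (role, path) pairs with roles from
    {u, v, w, o2, ph, ph_mv, par}.  Rates may differ between channels;
    all are aligned to the common start time (within one sample of the
    fastest channel).
    """
    channels: dict[str, ChannelSeries] = {}
    for role, path in config.channel_paths:
        channels[role] = read_channel_csv(path)
    if not channels:
        raise ChannelFormatError("no channel paths configured")
    t0 = max(c.start_time for c in channels.values())
    t1 = min(c.start_time + len(c) / c.rate for c in channels.values())
    if t1 <= t0:
        raise ChannelFormatError("channel files do not overlap in time")
    out = {}
    for role, c in channels.items():
        i0 = int(round((t0 - c.start_time) * c.rate))
        i1 = int(round((t1 - c.start_time) * c.rate))
        out[role] = ChannelSeries(
            c.values[i0:i1], c.rate, start_time=t0, units=c.units, gaps=c.gaps[i0:i1]
        )
    return out


def velocity_from_channels(channels: dict) -> VelocityRecord:
    try:
        return VelocityRecord(u=channels["u"], v=channels["v"], w=channels["w"])
    except KeyError as err:
        raise ChannelFormatError(f"missing velocity channel: {err}") from err


def write_windows_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, na_rep="")


def read_windows_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=True)


def write_run_log(path, lines) -> None:
    Path(path).write_text("\n".join(str(x) for x in lines) + "\n")
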