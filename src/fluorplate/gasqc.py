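"""Chamber gas-log quality control: stability and switching performance.

The imaging chamber holds leaf sections under a controlled O2/CO2
atmosphere; sensors log concentrations (typically every 15 s).  Two
questions matter for a screen: how stable is each gas around its mean
during a measurement window, and how quickly does the chamber settle
after a supply switch (e.g. ambient air to a 2% O2 pre-mix).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GasLog",
    "GasStabilityReport",
    "SwitchResult",
    "stability_report",
    "switch_time",
    "GAS_LOG_COLUMNS",
]

GAS_LOG_COLUMNS = ["time_s", "o2_mmol_mol", "co2_umol_mol", "pressure_kpa"]
_CHANNELS = {"o2": "o2_mmol_mol", "co2": "co2_umol_mol", "pressure": "pressure_kpa"}


@dataclass
class GasLog:
    """Sensor time series: O2 (mmol mol⁻¹), CO2 (µmol mol⁻¹), pressure (kPa)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(GAS_LOG_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"gas log missing columns {sorted(missing)}")
        t = self.data["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("gas log time must be strictly increasing")
        for col in GAS_LOG_COLUMNS[1:]:
            if np.any(self.data[col].to_numpy() < 0):
                raise ValueError(f"gas log column {col} has negative values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_interval_s(self) -> float:
        return float(np.median(np.diff(self.data["time_s"])))

    def window(self, start_s: float | None = None, end_s: float | None = None) -> "GasLog":
        t = self.data["time_s"]
        mask = pd.Series(True, index=self.data.index)
        if start_s is not None:
            mask &= t >= start_s
        if end_s is not None:
            mask &= t <= end_s
        return GasLog(self.data[mask].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.data[GAS_LOG_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GasLog":
        return cls(pd.read_csv(path))


@dataclass
class GasStabilityReport:
    """Per-channel mean and maximum absolute percent deviation from it."""

    per_gas: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.per_gas, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = []
        for gas, stats in sorted(self.per_gas.items()):
            lines.append(
                f"{gas}: mean {stats['mean']:.3f}, "
                f"max |dev| {stats['max_abs_pct_dev']:.2f}% of mean"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class SwitchResult:
    """Outcome of a gas-switch timing measurement."""

    channel: str
    target: float
    tolerance_fraction: float
    achieved: bool
    elapsed_s: float  # NaN when not achieved

    def __str__(self) -> str:
        if not self.achieved:
            return f"{self.channel} -> {self.target}: not achieved"
        return f"{self.channel} -> {self.target}: in band after {self.elapsed_s:.0f} s"


def stability_report(
    log: GasLog,
    window: tuple[float | None, float | None] | None = None,
    reference: str = "mean",
    setpoints: dict[str, float] | None = None,
) -> GasStabilityReport:
    """Stability of each gas channel over a time window.

    Deviation is the maximum of |x - ref| / ref * 100 where ``ref`` is the
    window mean (default) or, with ``reference="setpoint"``, a supplied
    per-channel setpoint.
    """
    if window is not None:
        log = log.window(*window)
    if len(log) < 2:
        raise ValueError("stability window must contain at least 2 samples")
    report = GasStabilityReport()
    for gas, col in _CHANNELS.items():
        x = log.data[col].to_numpy(dtype=float)
        mean = float(x.mean())
        if reference == "mean":
            ref = mean
        elif reference == "setpoint":
            if setpoints is None or gas not in setpoints:
                continue
            ref = float(setpoints[gas])
        else:
            raise ValueError(f"unknown reference {reference!r}")
        if ref == 0:
            raise ValueError(f"zero reference for channel {gas}")
        report.per_gas[gas] = {
            "mean": mean,
            "max_abs_pct_dev": float(np.max(np.abs(x - ref)) / ref * 100.0),
        }
    return report


def switch_time(
    log: GasLog,
    switch_time_s: float,
    target: float,
    channel: str = "o2",
    tolerance_fraction: float = 0.02,
    hold_window_s: float = 300.0,
) -> SwitchResult:
    """Time from a supply switch until the channel settles at the target.

    "Settled" means sustained in-band residence, not first crossing: the
    returned time is to the first sample after which every sample in the
    following ``hold_window_s`` (truncated at log end) stays within
    ``target * (1 ± tolerance_fraction)``.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    if tolerance_fraction <= 0:
        raise ValueError("tolerance_fraction must be > 0")
    col = _CHANNELS.get(channel)
    if col is None:
        raise ValueError(f"unknown channel {channel!r}; one of {sorted(_CHANNELS)}")
    t = log.data["time_s"].to_numpy(dtype=float)
    if not (t[0] <= switch_time_s <= t[-1]):
        raise ValueError(f"switch time {switch_time_s} outside log range")
    x = log.data[col].to_numpy(dtype=float)
    in_band = np.abs(x - target) <= tolerance_fraction * target
    candidates = np.nonzero((t >= switch_time_s) & in_band)[0]
    for i in candidates:
        window_end = t[i] + hold_window_s
        j = np.searchsorted(t, window_end, side="right")
        if in_band[i:j].all():
            return SwitchResult(channel, target, tolerance_fraction, True,
                                float(t[i] - switch_time_s))
    return SwitchResult(channel, target, tolerance_fraction, False, math.nan)
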