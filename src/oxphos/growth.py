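"""Tumor-volume arithmetic and treatment-response metrics for xenografts.

Caliper measurements give V = a * b^2 / 2 (a = major, b = minor diameter,
mm); per-mouse series are expressed as relative tumor volume RTV = Vn / V0,
and treatment response as change to baseline,
((treated RTV / mean control RTV) - 1) * 100, at the final common
measurement day.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid-approximation volume a * b^2 / 2 (mm^3); a is the major diameter."""
    if a <= 0 or b <= 0:
        raise ValueError("diameters must be positive")
    if b > a:
        warnings.warn("minor diameter exceeds major; swapping", stacklevel=2)
        a, b = b, a
    return a * b**2 / 2.0


def rtv(volumes: pd.Series | np.ndarray) -> pd.Series:
    """Relative tumor volume: each volume divided by the first (V0)."""
    v = pd.Series(volumes).astype(float)
    v0 = v.iloc[0]
    if v0 <= 0:
        raise ValueError("V0 must be positive")
    return v / v0


def change_to_baseline(treated_rtv, control_rtv_mean: float):
    """Per-mouse response percent: ((treated RTV / mean control RTV) - 1) * 100."""
    if control_rtv_mean <= 0:
        raise ValueError("control RTV mean must be positive")
    treated_rtv = np.asarray(treated_rtv, dtype=float)
    out = (treated_rtv / control_rtv_mean - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def waterfall_table(series: pd.DataFrame, final_day: int | None = None) -> pd.DataFrame:
    """Per-mouse change to baseline at the last common day of a volume table.

    ``series`` has columns mouse, arm ({control, treated}), day, volume_mm3.
    Baseline is the mean control RTV at that day.  Returns one row per
    treated mouse with its RTV and change percent.
    """
    required = {"mouse", "arm", "day", "volume_mm3"}
    if not required.issubset(series.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    rtvs = (
        series.sort_values("day")
        .groupby("mouse", sort=False)
        .apply(lambda g: g.assign(rtv=rtv(g["volume_mm3"].to_numpy()).to_numpy()), include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    if final_day is None:
        final_day = min(g["day"].max() for _, g in rtvs.groupby("mouse"))
    at_end = rtvs[rtvs["day"] == final_day]
    control_mean = at_end.loc[at_end["arm"] == "control", "rtv"].mean()
    treated = at_end[at_end["arm"] == "treated"].copy()
    treated["change_pct"] = change_to_baseline(treated["rtv"].to_numpy(), control_mean)
    return treated[["mouse", "day", "rtv", "change_pct"]].reset_index(drop=True)
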