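"""Location-standardized treatment comparisons and across-location tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import SampleFrame


@dataclass
class ComparisonResult:
    variable: str
    n_control: int
    n_treated: int
    statistic: float
    p: float
    direction: str  # 'increase' | 'decrease' | 'none'
    percent_change_by_location: pd.Series  # may contain NaN where control mean == 0


def zscore_by_location(frame: SampleFrame, variable: str) -> pd.Series:
    """Per location: subtract the pooled-arm mean and divide by the pooled-arm
    sd. Locations with zero within-location variance are excluded with a
    warning; missing values propagate."""
    v = frame.data[variable].astype(float)
    loc = frame.data["location"]
    out = pd.Series(np.nan, index=v.index, name=variable)
    for lv in loc.unique():
        mask = (loc == lv) & v.notna()
        if mask.sum() < 2:
            if mask.sum() == 1:
                warnings.warn(f"location {lv}: <2 values for '{variable}', excluded")
            continue
        sd = v[mask].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"location {lv}: zero variance for '{variable}', excluded")
            continue
        out[mask] = (v[mask] - v[mask].mean()) / sd
    return out


def _percent_change(values: pd.Series, frame: SampleFrame) -> pd.Series:
    loc = frame.data["location"]
    arm = frame.data["treatment"]
    rows = {}
    for lv in sorted(loc.unique()):
        c = values[(loc == lv) & (arm == "control")].dropna()
        t = values[(loc == lv) & (arm == "treated")].dropna()
        if len(c) == 0 or len(t) == 0 or c.mean() == 0:
            rows[lv] = np.nan
        else:
            rows[lv] = 100.0 * (t.mean() - c.mean()) / c.mean()
    return pd.Series(rows, name="percent_change")


def treated_vs_control(
    frame: SampleFrame, variable: str, standardize: bool = True
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum of treated vs control, optionally on
    location-standardized values, pooled across locations.

    Percent change per location is always computed on the raw scale.
    """
    raw = frame.data[variable].astype(float)
    values = zscore_by_location(frame, variable) if standardize else raw
    arm = frame.data["treatment"]
    c = values[(arm == "control")].dropna()
    t = values[(arm == "treated")].dropna()
    if len(c) == 0 or len(t) == 0:
        raise ValueError(f"'{variable}' entirely missing in one arm")
    stat, p = stats.mannwhitneyu(t, c, alternative="two-sided")
    diff = t.mean() - c.mean()
    direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
    return ComparisonResult(
        variable=variable,
        n_control=len(c),
        n_treated=len(t),
        statistic=float(stat),
        p=float(p),
        direction=direction,
        percent_change_by_location=_percent_change(raw, frame),
    )


def across_locations(frame: SampleFrame, variable: str) -> tuple[float, float]:
    """Kruskal-Wallis across locations (tie-corrected)."""
    v = frame.data[variable].astype(float)
    loc = frame.data["location"]
    groups = [v[(loc == lv)].dropna().to_numpy() for lv in sorted(loc.unique())]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 locations")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def net_change_comparison(
    values: pd.DataFrame, frame: SampleFrame, variable: str
) -> ComparisonResult:
    """Treated-vs-control Wilcoxon on per-plot net change value(T1) - value(T0),
    location-standardized.

    `values` must carry sample_id-indexed measurements in column `variable`;
    plots are matched on (location, treatment, replicate) parsed from the
    sample id stem (everything before the trailing timepoint token).
    Unmatched plots are dropped.
    """
    meta = frame.data
    v = values[variable]
    rows = []
    for sid in meta.index:
        tp = meta.loc[sid, "timepoint"]
        stem = sid[: -len(str(tp)) - 1] if sid.endswith(f"_{tp}") else sid
        rows.append((stem, tp, v.get(sid, np.nan)))
    wide = (
        pd.DataFrame(rows, columns=["plot", "timepoint", "value"])
        .pivot_table(index="plot", columns="timepoint", values="value", aggfunc="first")
    )
    if "T0" not in wide.columns or "T1" not in wide.columns:
        raise ValueError("need both T0 and T1 values")
    matched = wide.dropna(subset=["T0", "T1"])
    delta = (matched["T1"] - matched["T0"]).rename(variable)

    t1_ids = {
        (sid[: -3] if sid.endswith("_T1") else sid): sid
        for sid in meta.index[meta["timepoint"] == "T1"]
    }
    plot_ids = [t1_ids[p] for p in delta.index if p in t1_ids]
    delta.index = plot_ids
    sub = SampleFrame(meta.loc[plot_ids].copy())
    sub.data[f"delta_{variable}"] = delta
    arm = sub.data["treatment"]
    if delta.nunique() <= 1:
        # constant deltas carry no treatment information
        return ComparisonResult(
            variable=f"delta_{variable}",
            n_control=int((arm == "control").sum()),
            n_treated=int((arm == "treated").sum()),
            statistic=float("nan"),
            p=1.0,
            direction="none",
            percent_change_by_location=_percent_change(delta, sub),
        )
    return treated_vs_control(sub, f"delta_{variable}", standardize=True)
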