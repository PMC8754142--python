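"""Growth-curve analytics: OD conversion, lag estimators, relative biomass.

OD600 plate-reader readings are converted to cell counts with an empirical
cubic calibration (flow-cytometry counts vs. OD600)::

    biomass = -2e6*OD^3 + 3e7*OD^2 + 3e6*OD + 2.203e5   [cells per 200 ul well]

valid on OD in [0, 2], where the polynomial is strictly increasing.

Two lag-phase estimators are provided: the threshold rule (time for OD to
rise 0.01 above its initial value) and the maximum-growth-rate rule (time of
the maximal finite-difference derivative of biomass).  Relative-biomass
normalisations divide a culture's biomass either by the per-time mean of the
mixed-culture replicates, or by the matched culture starved in the simple
environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CONVERSION_COEFFS",
    "GrowthCurve",
    "od_to_biomass",
    "biomass_to_od",
    "lag_threshold",
    "lag_max_growth",
    "relative_biomass_vs_mixed",
    "relative_biomass_env",
]

#: Calibration cubic coefficients (c3, c2, c1, c0), cells per OD^k.
CONVERSION_COEFFS = (-2.0e6, 3.0e7, 3.0e6, 2.203e5)

OD_MIN, OD_MAX = 0.0, 2.0
#: Lag threshold: OD increase over the initial reading that ends the lag phase.
LAG_DELTA_OD = 0.01


@dataclass
class GrowthCurve:
    """One replicate's regrowth time series on a uniform time grid."""

    times: np.ndarray
    od: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same shape")
        if len(self.times) < 2:
            raise ValueError("a growth curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od readings must be finite")

    @property
    def biomass(self) -> np.ndarray:
        return od_to_biomass(self.od)


def od_to_biomass(od, on_range: str = "raise"):
    """Convert OD600 to cell number (per 200 µl well) via the calibration cubic.

    ``on_range`` controls handling of readings outside the calibrated
    [0, 2] interval: ``"raise"``, ``"warn"`` or ``"ignore"``.
    Accepts scalars or arrays.
    """
    arr = np.asarray(od, dtype=float)
    if np.any(arr < OD_MIN) or np.any(arr > OD_MAX):
        msg = f"OD outside calibration range [{OD_MIN}, {OD_MAX}]"
        if on_range == "raise":
            raise ValueError(msg)
        if on_range == "warn":
            warnings.warn(msg, stacklevel=2)
        elif on_range != "ignore":
            raise ValueError(f"unknown on_range policy: {on_range!r}")
    c3, c2, c1, c0 = CONVERSION_COEFFS
    out = ((c3 * arr + c2) * arr + c1) * arr + c0
    return float(out) if np.isscalar(od) else out


def biomass_to_od(cells: float) -> float:
    """Invert the calibration cubic on [0, 2] by bracketed root finding.

    ``cells`` must lie between the cubic's values at OD 0 and OD 2; the
    cubic is strictly increasing there, so the root is unique.
    """
    lo = od_to_biomass(OD_MIN)
    hi = od_to_biomass(OD_MAX)
    if not lo <= cells <= hi:
        raise ValueError(
            f"biomass {cells:.4g} outside invertible range [{lo:.4g}, {hi:.4g}]"
        )
    if cells == lo:
        return 0.0
    return brentq(lambda od: od_to_biomass(od) - cells, OD_MIN, OD_MAX,
                  xtol=1e-12, rtol=1e-15)


def lag_threshold(curve: GrowthCurve, delta_od: float = LAG_DELTA_OD) -> Optional[float]:
    """Lag length by the threshold rule.

    The smallest sampled time at which OD has risen by ``delta_od`` (default
    0.01) above the reading at the start of regrowth.  Returns ``None`` if
    the curve never crosses the threshold (the caller must not treat that as
    a numeric lag).
    """
    rise = curve.od - curve.od[0]
    hits = np.nonzero(rise >= delta_od)[0]
    if len(hits) == 0:
        return None
    return float(curve.times[hits[0]])


def lag_max_growth(curve: GrowthCurve, second_derivative: bool = False,
                   prefilter: bool = False) -> Optional[float]:
    """Lag length as the time of maximal growth rate.

    Converts OD to biomass and differentiates with centred finite
    differences on the raw grid.  The primary definition is the time of the
    maximal *first* derivative of biomass (the maximum growth rate);
    ``second_derivative=True`` selects the time of the maximal second
    derivative instead.  ``prefilter`` applies a 3-point running median
    before differencing, for noisy curves.  Ties break to the earliest time;
    a flat curve returns ``None``.
    """
    if len(curve.times) < 5:
        raise ValueError("lag_max_growth needs at least 5 points")
    biomass = curve.biomass
    if prefilter:
        padded = np.concatenate([biomass[:1], biomass, biomass[-1:]])
        biomass = np.median(
            np.column_stack([padded[:-2], padded[1:-1], padded[2:]]), axis=1
        )
    if np.allclose(biomass, biomass[0]):
        return None
    deriv = np.gradient(biomass, curve.times)
    if second_derivative:
        deriv = np.gradient(deriv, curve.times)
    # interior points only: one-sided boundary estimates are half-order
    interior = slice(1, len(deriv) - 1)
    idx = 1 + int(np.argmax(deriv[interior]))
    return float(curve.times[idx])


def _require_columns(df: pd.DataFrame, cols: tuple, where: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{where}: missing column(s) {missing}")


def relative_biomass_vs_mixed(df: pd.DataFrame,
                              biomass_col: str = "biomass") -> pd.DataFrame:
    """Relative biomass of each curve against the mixed-culture mean.

    ``df`` holds one environment and one week of long-format data with
    columns ``culture_type``, ``replicate``, ``time_h`` and ``biomass_col``.
    Every curve's biomass is divided by the mean biomass of the mixed
    replicates at the same time point, so the mixed cultures' relative
    biomass averages to exactly 1 at every time.
    """
    _require_columns(df, ("culture_type", "replicate", "time_h", biomass_col),
                     "relative_biomass_vs_mixed")
    for col in ("environment", "week"):
        if col in df.columns and df[col].nunique() > 1:
            raise ValueError(
                f"relative_biomass_vs_mixed expects a single {col}, "
                f"got {sorted(df[col].unique())}"
            )
    mixed = df[df["culture_type"] == "mixed"]
    if mixed.empty:
        raise ValueError("no mixed-culture reference replicates present")
    ref = mixed.groupby("time_h")[biomass_col].mean()
    times_needed = set(df["time_h"].unique())
    missing = times_needed - set(ref.index)
    if missing:
        raise ValueError(
            f"mixed reference missing at time point(s) {sorted(missing)[:5]}"
        )
    if np.any(ref.values == 0):
        raise ZeroDivisionError("mixed-culture mean biomass is zero at some time")
    out = df.copy()
    out["relative_biomass"] = out[biomass_col].values / ref.reindex(out["time_h"]).values
    return out


def relative_biomass_env(curves_complex: pd.DataFrame,
                         curves_simple: pd.DataFrame,
                         biomass_col: str = "biomass") -> pd.DataFrame:
    """Complex-vs-simple relative biomass per culture type and time point.

    For each (culture_type, week, time_h) the mean biomass of replicates
    starved in the complex environment is divided by the mean biomass of
    the same culture type starved in the simple environment.  The two
    frames must cover identical (culture_type, week, time_h) grids; no
    interpolation is attempted.
    """
    keys = ["culture_type", "week", "time_h"]
    for frame, name in ((curves_complex, "complex"), (curves_simple, "simple")):
        _require_columns(frame, (*keys, biomass_col), f"relative_biomass_env ({name})")
    mean_c = curves_complex.groupby(keys)[biomass_col].mean()
    mean_s = curves_simple.groupby(keys)[biomass_col].mean()
    if not mean_c.index.equals(mean_s.index):
        only_c = mean_c.index.difference(mean_s.index)
        only_s = mean_s.index.difference(mean_c.index)
        raise ValueError(
            "complex/simple grids do not align: "
            f"{len(only_c)} keys only in complex, {len(only_s)} only in simple"
        )
    if np.any(mean_s.values == 0):
        raise ZeroDivisionError("simple-environment mean biomass is zero at some point")
    out = (mean_c / mean_s).rename("relative_biomass").reset_index()
    return out
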