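"""Reconstructing fishing days from port entry/exit trip records.

For years without vessel geolocation, fishing days per trip are predicted
from at-sea days via zero-intercept linear regressions fitted separately by
fishing port and vessel size class (no at-sea days imply no fishing days, so
the intercept is pinned at zero).  A sequential ANOVA of
``fishing ~ at_sea + port + class`` supports the grouping.  Both R-squared
conventions are reported per group: the uncentered one implied by the
zero-intercept fit (1 - SSE/sum(y^2), which flatters the fit) and the usual
centered one (1 - SSE/sum((y-ybar)^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "trips_to_at_sea_days",
    "AtSeaEffortModel",
    "EffortResults",
    "fit_effort_model",
    "effort_anova",
    "predict_fishing_days",
]


def trips_to_at_sea_days(
    trips: pd.DataFrame, max_duration_days: int = 60
) -> pd.DataFrame:
    """Screen raw trip records and derive at-sea days.

    At-sea days = number of distinct local calendar dates intersected by
    [depart, return].  Screening drops trips with return <= depart,
    durations over ``max_duration_days``, overlapping duplicate trips per
    vessel, and unparseable rows; dropped rows land in
    ``out.attrs["rejects"]`` with a reason, never silently.
    """
    df = trips.copy()
    rejects = []

    def _reject(mask, reason):
        nonlocal df
        bad = df[mask].assign(reject_reason=reason)
        if len(bad):
            rejects.append(bad)
        df = df[~mask]

    for col in ("depart", "return_"):
        parsed = pd.to_datetime(df[col], errors="coerce")
        _reject(parsed.isna(), f"unparseable {col}")
        df[col] = pd.to_datetime(df[col])

    _reject(df["return_"] <= df["depart"], "return before depart")
    dur = (df["return_"] - df["depart"]).dt.total_seconds() / 86400.0
    _reject(dur > max_duration_days, f"duration > {max_duration_days} d")

    # overlapping trips of one vessel: keep the earlier departure
    df = df.sort_values(["vessel_id", "depart"]).reset_index(drop=True)
    overlap = np.zeros(len(df), dtype=bool)
    last_ret = {}
    for i, r in enumerate(df.itertuples()):
        prev = last_ret.get(r.vessel_id)
        if prev is not None and r.depart < prev:
            overlap[i] = True
        else:
            last_ret[r.vessel_id] = r.return_
    _reject(pd.Series(overlap, index=df.index), "overlaps previous trip")

    df["at_sea_days"] = (
        df["return_"].dt.normalize() - df["depart"].dt.normalize()
    ).dt.days + 1
    out = df.reset_index(drop=True)
    out.attrs["rejects"] = (
        pd.concat(rejects, ignore_index=True).to_dict("records") if rejects else []
    )
    return out


def zero_intercept_slope(x, y):
    """Least-squares slope through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all-zero regressor")
    return float(np.sum(x * y) / sxx)


class AtSeaEffortModel:
    """Zero-intercept regressions of fishing days on at-sea days, by group.

    Parameters
    ----------
    data : DataFrame with columns ``at_sea_days``, ``fishing_days``,
        ``port``, ``vessel_class``.
    """

    def __init__(self, data: pd.DataFrame):
        need = {"at_sea_days", "fishing_days", "port", "vessel_class"}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "AtSeaEffortModel":
        return cls(data)

    def fit(self) -> "EffortResults":
        rows = {}
        for (port, cls_), g in self.data.groupby(["port", "vessel_class"], sort=True):
            x = g["at_sea_days"].to_numpy(dtype=float)
            y = g["fishing_days"].to_numpy(dtype=float)
            if len(g) < 2 or np.all(x == 0):
                warnings.warn(
                    f"group ({port}, {cls_}) skipped (n={len(g)} or all-zero at-sea)"
                )
                continue
            slope = zero_intercept_slope(x, y)
            resid = y - slope * x
            sse = float(np.sum(resid**2))
            ssy = float(np.sum(y**2))
            ssc = float(np.sum((y - y.mean()) ** 2))
            rows[(port, cls_)] = {
                "slope": slope,
                "r2_zero_intercept": 1.0 - sse / ssy if ssy > 0 else np.nan,
                "r2_centered": 1.0 - sse / ssc if ssc > 0 else np.nan,
                "n": int(len(g)),
            }
        if not rows:
            raise ValueError("no fittable (port, vessel_class) group")
        return EffortResults(self, rows)


@dataclass
class EffortResults:
    """Fitted per-(port, class) slopes with both R-squared conventions."""

    model: AtSeaEffortModel
    groups: dict

    @property
    def params(self) -> pd.DataFrame:
        recs = [
            {"port": p, "vessel_class": c, **v} for (p, c), v in self.groups.items()
        ]
        return pd.DataFrame(recs)

    def slope(self, port, vessel_class) -> float:
        return self.groups[(port, vessel_class)]["slope"]

    def _pooled_port_slope(self, port) -> float:
        sub = self.model.data[self.model.data["port"] == port]
        if len(sub) == 0:
            raise KeyError(f"no data for port {port!r}")
        return zero_intercept_slope(sub["at_sea_days"], sub["fishing_days"])

    def predict(self, trips: pd.DataFrame) -> pd.Series:
        """Estimated fishing days = slope x at-sea days, clipped to at-sea.

        Trips whose (port, class) group was not fitted fall back to the
        pooled port-level slope; the count of fallbacks is recorded in
        ``result.attrs['n_fallback']``.
        """
        est = np.empty(len(trips))
        n_fallback = 0
        for i, r in enumerate(trips.itertuples()):
            key = (r.port, r.vessel_class)
            if key in self.groups:
                s = self.groups[key]["slope"]
            else:
                s = self._pooled_port_slope(r.port)
                n_fallback += 1
            est[i] = min(s * r.at_sea_days, r.at_sea_days)
        out = pd.Series(est, index=trips.index, name="fishing_days_est")
        out.attrs["n_fallback"] = n_fallback
        return out

    def anova(self) -> pd.DataFrame:
        """Sequential (type-I) ANOVA of fishing ~ at_sea + port + class."""
        return effort_anova(self.model.data)

    def summary(self) -> str:
        lines = [
            "Zero-intercept fishing-day ~ at-sea-day regressions",
            f"{'port':<10}{'class':<7}{'slope':>8}{'R2(0)':>8}{'R2(c)':>8}{'n':>7}",
        ]
        for (p, c), v in sorted(self.groups.items()):
            lines.append(
                f"{p:<10}{c:<7}{v['slope']:>8.3f}{v['r2_zero_intercept']:>8.3f}"
                f"{v['r2_centered']:>8.3f}{v['n']:>7d}"
            )
        return "\n".join(lines)


def effort_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Sequential sums of squares for fishing ~ at_sea + port + class.

    Factor order mirrors the fitted grouping: the continuous at-sea term
    first, then port, then vessel class.  Factors with a single level are
    dropped with a warning.
    """
    terms = [("at_sea_days", "at_sea_days", 1)]
    for col, term in (("port", "C(port)"), ("vessel_class", "C(vessel_class)")):
        k = data[col].nunique()
        if k >= 2:
            terms.append((col, term, k - 1))
        else:
            warnings.warn(f"factor {col} has < 2 levels; dropped from ANOVA")
    # nested fits in the declared order give the sequential decomposition
    # (patsy's own term ordering would put the covariate last)
    fits, rhs = [], []
    for _, term, _ in terms:
        rhs.append(term)
        fits.append(smf.ols("fishing_days ~ " + " + ".join(rhs), data=data).fit())
    full = fits[-1]
    mse = full.ssr / full.df_resid
    rows = []
    prev_ssr = smf.ols("fishing_days ~ 1", data=data).fit().ssr
    for (name, _, df_t), fit in zip(terms, fits):
        ss = prev_ssr - fit.ssr
        f = (ss / df_t) / mse
        p = stats.f.sf(f, df_t, full.df_resid)
        rows.append({"source": name, "df": df_t, "sum_sq": ss, "mean_sq": ss / df_t,
                     "F": f, "PR(>F)": p})
        prev_ssr = fit.ssr
    rows.append({"source": "Residual", "df": int(full.df_resid), "sum_sq": full.ssr,
                 "mean_sq": mse, "F": np.nan, "PR(>F)": np.nan})
    return pd.DataFrame(rows).set_index("source")


# --- functional wrappers -------------------------------------------------

def fit_effort_model(data: pd.DataFrame) -> EffortResults:
    return AtSeaEffortModel(data).fit()


def predict_fishing_days(trips: pd.DataFrame, results: EffortResults) -> pd.Series:
    return results.predict(trips)
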