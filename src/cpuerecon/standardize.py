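"""Delta-lognormal CPUE standardization with mixed-model year effects.

Trip-level CPUE (fish per fishing day) from this fishery is zero-heavy:
the probability of a positive catch is modelled by a binomial GLMM on all
trips (zero-proportion model, ZPM) and the magnitude of positive catches by
a Gaussian mixed model on log CPUE (positive-catch model, PCM).  Candidate
fixed factors are year (always kept), month, vessel size class and — in the
area-combined design — fishing area; year-by-month and year-by-class
interactions enter as random intercepts.  Variable selection runs backward
over fixed mains then forward over random interactions under AIC or BIC.
The standardized annual index is the product of the two components' year
least-squares means, the lognormal one back-transformed with the usual
exp(sigma^2/2) bias correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import fishnum
from .mixedglm import (
    CategoricalDesign,
    GaussianMixedML,
    LaplaceLogisticMixed,
    MixedFit,
)

__all__ = [
    "ModelSpec",
    "DeltaLognormalModel",
    "DeltaLognormalResults",
    "assign_area",
    "aggregate_trips",
    "fit_delta_models",
    "stepwise_select",
    "bias_corrected_index",
]


def assign_area(records: pd.DataFrame, cutoff_deg: float = 24.3) -> pd.Series:
    """Assign each record to the north or south fishing ground.

    Records with a latitude use the cutoff (>= cutoff -> north); records
    without one fall back to the departure port (the northern ground is
    worked by Suao vessels, the southern by Singang and Tungkang).
    """
    has_lat = "lat" in records.columns
    has_port = "port" in records.columns
    if not has_lat and not has_port:
        raise ValueError("records need a 'lat' or 'port' column to assign areas")
    out = np.empty(len(records), dtype=object)
    for i, r in enumerate(records.itertuples()):
        lat = getattr(r, "lat", None) if has_lat else None
        if lat is not None and not pd.isna(lat):
            out[i] = "north" if lat >= cutoff_deg else "south"
        elif has_port and not pd.isna(getattr(r, "port", None)):
            out[i] = "north" if r.port == "Suao" else "south"
        else:
            raise ValueError(f"record {i} has neither latitude nor port")
    return pd.Series(out, index=records.index, name="area")


def aggregate_trips(
    events: pd.DataFrame,
    trips: pd.DataFrame,
    months=(5, 6, 7),
) -> pd.DataFrame:
    """Aggregate catch events onto trips and compute trip-level CPUE.

    ``events`` needs ``trip_id`` and ``n_fish``; ``trips`` needs
    ``trip_id, year, month, area, vessel_class, fishing_days``.  Trips
    outside the fishing-season months are excluded (count in
    ``attrs['n_excluded']``); events without a matching trip land in
    ``attrs['orphans']``.
    """
    known = set(trips["trip_id"])
    orphan_mask = ~events["trip_id"].isin(known)
    orphans = events[orphan_mask]
    catches = (
        events[~orphan_mask].groupby("trip_id")["n_fish"].sum()
    )
    out = trips.copy()
    out["catch_n"] = out["trip_id"].map(catches).fillna(0.0)
    in_season = out["month"].isin(months)
    n_excluded = int((~in_season).sum())
    out = out[in_season].reset_index(drop=True)
    if (out["fishing_days"] <= 0).any():
        raise ValueError("trips must have positive fishing_days")
    out["cpue"] = out["catch_n"] / out["fishing_days"]
    out.attrs["orphans"] = orphans.to_dict("records")
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A delta-component formulation: fixed mains plus random interactions."""

    component: str                     # "ZPM" | "PCM"
    fixed_terms: tuple = ("year",)
    random_terms: tuple = ()
    aic: float = np.nan
    bic: float = np.nan
    converged: bool = None

    def __post_init__(self):
        if self.component not in ("ZPM", "PCM"):
            raise ValueError(f"component must be ZPM or PCM, got {self.component!r}")
        if "year" not in self.fixed_terms:
            raise ValueError("year must be a fixed term")

    def label(self) -> str:
        parts = [t.replace("vessel_class", "Vessel size").capitalize() for t in self.fixed_terms]
        parts += [t.replace(":", " x ").replace("vessel_class", "Vessel size").title()
                  for t in self.random_terms]
        return " + ".join(parts)


def _check_records(records: pd.DataFrame):
    need = {"year", "month", "vessel_class", "fishing_days", "cpue"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records["year"].nunique() < 2:
        raise ValueError("need at least two year levels to estimate a year effect")
    pos = records[records["cpue"] > 0]
    empty_years = sorted(set(records["year"]) - set(pos["year"]))
    if empty_years:
        raise ValueError(
            f"years with zero positive catches: {empty_years}; "
            "the positive-catch year effect is undefined there"
        )


def _fit_component(records: pd.DataFrame, spec: ModelSpec) -> MixedFit:
    """Fit one delta component under a given formulation."""
    design = CategoricalDesign(records, spec.fixed_terms, spec.random_terms)
    if spec.component == "ZPM":
        df = records
        y = (df["cpue"] > 0).astype(float).to_numpy()
        X, names = design.fixed_matrix(df)
        rnd = design.random_codes(df)
        fit = LaplaceLogisticMixed(
            y, X, [c for _, c, _ in rnd], [q for _, _, q in rnd], [n for n, _, _ in rnd]
        ).fit()
    else:
        df = records[records["cpue"] > 0].reset_index(drop=True)
        y = np.log(df["cpue"].to_numpy(dtype=float))
        X, names = design.fixed_matrix(df)
        rnd = design.random_codes(df)
        fit = GaussianMixedML(
            y, X, [c for _, c, _ in rnd], [q for _, _, q in rnd], [n for n, _, _ in rnd]
        ).fit()
    fit.design = design
    fit.param_names = names
    return fit


class DeltaLognormalModel:
    """Delta-lognormal standardization model for trip-level CPUE records.

    Parameters
    ----------
    records : DataFrame with year, month, vessel_class, fishing_days, cpue
        (and area for the area-combined design).
    zpm_spec, pcm_spec : ModelSpec, optional
        Formulations of the two components; default Year + Month for both.
    """

    def __init__(self, records: pd.DataFrame, zpm_spec: ModelSpec = None,
                 pcm_spec: ModelSpec = None):
        _check_records(records)
        self.records = records.reset_index(drop=True)
        self.zpm_spec = zpm_spec or ModelSpec("ZPM", ("year", "month"))
        self.pcm_spec = pcm_spec or ModelSpec("PCM", ("year", "month"))

    @classmethod
    def from_dataframe(cls, records, **kw):
        return cls(records, **kw)

    def fit(self) -> "DeltaLognormalResults":
        zpm = _fit_component(self.records, self.zpm_spec)
        pcm = _fit_component(self.records, self.pcm_spec)
        for fit, spec in ((zpm, self.zpm_spec), (pcm, self.pcm_spec)):
            if not fit.converged:
                warnings.warn(
                    f"{spec.component} fit ({spec.label()}) did not converge"
                )
        return DeltaLognormalResults(self, zpm, pcm)


@dataclass
class DeltaLognormalResults:
    model: DeltaLognormalModel
    zpm: MixedFit
    pcm: MixedFit

    @property
    def years(self):
        return list(self.zpm.design.levels["year"])

    def _lsmean_grid(self, fit: MixedFit):
        """Year-by-other-levels prediction grid with count-proportional
        weights over the non-year margins (margins fixed across years)."""
        records = self.model.records
        others = [t for t in fit.design.fixed_terms if t != "year"]
        # include random-factor partners so year:month BLUPs vary over the grid
        for t in fit.design.random_terms:
            partner = t.split(":")[1]
            if partner not in others:
                others.append(partner)
        if others:
            combos = records.groupby(others, sort=True).size().reset_index(name="w")
        else:
            combos = pd.DataFrame({"w": [len(records)]})
        combos["w"] = combos["w"] / combos["w"].sum()
        return others, combos

    def lsmeans_year(self, component: str) -> pd.DataFrame:
        """Per-year marginal (least-squares) means with variances.

        ZPM means are on the probability scale; PCM means on the log-CPUE
        scale.  Other-factor levels are averaged with weights proportional
        to their observation counts, the same margins for every year.
        """
        fit = self.zpm if component == "ZPM" else self.pcm
        others, combos = self._lsmean_grid(fit)
        rows = []
        for y in self.years:
            grid = combos.copy()
            grid["year"] = y
            # satisfy design lookups for factors absent from the grid
            for t in fit.design.fixed_terms:
                if t != "year" and t not in grid.columns:
                    grid[t] = fit.design.levels[t][0]
            X, _ = fit.design.fixed_matrix(grid)
            eta = fit.predict_eta(grid, include_random=True)
            w = grid["w"].to_numpy()
            if component == "ZPM":
                p = 1.0 / (1.0 + np.exp(-eta))
                mean = float(np.sum(w * p))
                a = (w * p * (1.0 - p)) @ X          # delta-method gradient
            else:
                mean = float(np.sum(w * eta))
                a = w @ X
            var = float(a @ fit.cov_params @ a)
            rows.append({"year": y, "mean": mean, "var": max(var, 0.0)})
        return pd.DataFrame(rows)

    def index(self) -> pd.DataFrame:
        """The standardized annual index and its relative series.

        index_y = p_pos_y * exp(mu_y + sigma2/2) with mu_y the PCM year
        LSmean, sigma2 the PCM residual variance, p_pos_y the ZPM year
        LSmean; 95% CI by the delta method on the log scale.
        """
        zp = self.lsmeans_year("ZPM")
        pc = self.lsmeans_year("PCM")
        return bias_corrected_index(
            p_pos=zp["mean"].to_numpy(),
            mu=pc["mean"].to_numpy(),
            sigma2=np.full(len(pc), self.pcm.sigma2),
            var_mu=pc["var"].to_numpy(),
            var_p=zp["var"].to_numpy(),
            years=self.years,
        )

    def residual_diagnostics(self) -> dict:
        """Standardized PCM residuals, a QQ slope, and a KS test vs normal."""
        records = self.model.records
        pos = records[records["cpue"] > 0].reset_index(drop=True)
        resid = np.log(pos["cpue"].to_numpy(dtype=float)) - self.pcm.predict_eta(pos)
        sd = resid.std(ddof=1)
        if sd < 1e-10:  # saturated or constant fit
            return {"degenerate": True, "residuals": resid}
        z = (resid - resid.mean()) / sd
        n = len(z)
        qn = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        qq_slope = float(np.polyfit(qn, np.sort(z), 1)[0])
        ks = fishnum.ks_two_sample(z, qn)
        return {"degenerate": False, "residuals": resid, "qq_slope": qq_slope, "ks": ks}

    def summary(self) -> str:
        lines = ["Delta-lognormal CPUE standardization", ""]
        for name, fit, spec in (
            ("Zero-proportion model", self.zpm, self.model.zpm_spec),
            ("Positive-catch model", self.pcm, self.model.pcm_spec),
        ):
            lines.append(
                f"{name}: {spec.label()}  n={fit.nobs}  "
                f"AIC={fit.aic:.1f}  BIC={fit.bic:.1f}  converged={fit.converged}"
            )
        lines.append("")
        idx = self.index()
        lines.append(f"{'year':>6}{'p_pos':>8}{'mu':>8}{'index':>9}{'rel':>7}")
        for r in idx.itertuples():
            lines.append(
                f"{r.year:>6}{r.p_pos:>8.3f}{r.mu:>8.3f}{r.index:>9.3f}{r.relative_index:>7.3f}"
            )
        return "\n".join(lines)


def bias_corrected_index(p_pos, mu, sigma2, var_mu=None, var_p=None, years=None):
    """Combine the two delta components into a standardized index.

    index = p_pos * exp(mu + sigma2/2); the relative index is scaled to its
    series mean.  CIs use var(log index) ~= var_mu + var_p / p_pos^2.
    """
    p_pos = np.asarray(p_pos, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be nonnegative")
    index = p_pos * np.exp(mu + sigma2 / 2.0)
    rel = index / index.mean()
    out = pd.DataFrame(
        {
            "year": years if years is not None else np.arange(len(index)),
            "p_pos": p_pos,
            "mu": mu,
            "sigma2": sigma2,
            "index": index,
            "relative_index": rel,
        }
    )
    if var_mu is not None and var_p is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            vlog = np.asarray(var_mu) + np.where(
                p_pos > 0, np.asarray(var_p) / p_pos**2, np.nan
            )
        half = 1.96 * np.sqrt(vlog)
        out["lo95"] = index * np.exp(-half)
        out["hi95"] = index * np.exp(half)
    return out


def fit_delta_models(records, spec_zpm: ModelSpec, spec_pcm: ModelSpec):
    """Fit both delta components; returns a DeltaLognormalResults."""
    return DeltaLognormalModel(records, spec_zpm, spec_pcm).fit()


def stepwise_select(
    records: pd.DataFrame,
    component: str,
    criterion: str = "AIC",
    include_area: bool = False,
    random_candidates=("year:month", "year:vessel_class"),
) -> ModelSpec:
    """Backward-then-forward selection of one delta component.

    Starts from the full fixed main-effects model (year kept always),
    removes fixed mains while the criterion improves, then adds random
    year-by-factor interactions while it improves.  Nonconvergent
    candidates are skipped with a warning.
    """
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be AIC or BIC")

    def score(spec):
        try:
            fit = _fit_component(records, spec)
        except Exception as e:  # singular designs etc.
            warnings.warn(f"candidate {spec.label()} failed: {e}")
            return None, np.inf
        if not fit.converged:
            warnings.warn(f"candidate {spec.label()} did not converge; skipped")
            return None, np.inf
        return fit, fit.aic if crit == "AIC" else fit.bic

    fixed = ["year", "month", "vessel_class"]
    if include_area:
        fixed.append("area")
    spec = ModelSpec(component, tuple(fixed))
    fit, best = score(spec)
    if fit is None:
        raise RuntimeError("the full main-effects model did not converge")

    improved = True
    while improved:
        improved = False
        for t in [t for t in spec.fixed_terms if t != "year"]:
            cand = replace(spec, fixed_terms=tuple(x for x in spec.fixed_terms if x != t))
            f, s = score(cand)
            if s < best:
                spec, best, fit, improved = cand, s, f, True
                break

    improved = True
    while improved:
        improved = False
        for t in random_candidates:
            if t in spec.random_terms:
                continue
            cand = replace(spec, random_terms=spec.random_terms + (t,))
            f, s = score(cand)
            if s < best:
                spec, best, fit, improved = cand, s, f, True
                break

    return replace(spec, aic=fit.aic, bic=fit.bic, converged=fit.converged)
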