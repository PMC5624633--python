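"""Estimating missing fish counts from landing weights.

Early landing records report the offloaded weight but often not how many
fish it comprised.  Because single-fish landings are common in this fishery
and individual fish fall in a narrow 80-350 kg band, the per-record weight
of single-count landings yields an empirical weight-per-fish (WPF)
distribution.  Summing k bootstrap draws from it (k = 1..50, many
replicates) builds a simulated total-weight band per fish count; a record
with missing count is then assigned a count drawn in proportion to how often
each count's simulated totals land in the record's weight bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WPFSample",
    "KSResult",
    "WeightByCountTable",
    "build_wpf",
    "ks_two_sample",
    "choose_wpf_model",
    "simulate_weight_by_count",
    "assign_fish_counts",
]


class EmptySampleError(ValueError):
    pass


@dataclass
class WPFSample:
    """Per-fish weights (kg), one per selected landing record."""

    weights_kg: np.ndarray
    min_kg: float = 80.0
    max_kg: float = 350.0

    def __len__(self):
        return len(self.weights_kg)


@dataclass
class KSResult:
    d_stat: float
    p_value: float


@dataclass
class WeightByCountTable:
    """Simulated total-weight distributions by fish count.

    ``totals[k]`` holds ``n_rep`` simulated total weights of ``k`` fish,
    each a sum of ``k`` draws with replacement from the WPF sample; the
    sorted copies back fast histogram-bin lookups during assignment.
    """

    counts: np.ndarray
    totals: dict
    n_rep: int

    def bin_counts(self, w: float, bin_kg: float) -> np.ndarray:
        """Number of simulated totals of each count in [w-bin/2, w+bin/2)."""
        lo, hi = w - bin_kg / 2.0, w + bin_kg / 2.0
        out = np.empty(len(self.counts), dtype=float)
        for i, k in enumerate(self.counts):
            t = self.totals[int(k)]
            out[i] = np.searchsorted(t, hi, side="left") - np.searchsorted(
                t, lo, side="left"
            )
        return out


def build_wpf(landings: pd.DataFrame, min_kg: float = 80.0, max_kg: float = 350.0) -> WPFSample:
    """Construct the WPF sample: one weight per record within [min_kg, max_kg].

    Each selected record is assumed to stand for a single fish; records
    outside the band are excluded.
    """
    if len(landings) == 0:
        raise EmptySampleError("no landing records")
    w = np.asarray(landings["weight_kg"], dtype=float)
    sel = w[(w >= min_kg) & (w <= max_kg)]
    if len(sel) == 0:
        raise EmptySampleError(
            f"no records within [{min_kg}, {max_kg}] kg out of {len(w)}"
        )
    return WPFSample(np.sort(sel), min_kg, max_kg)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum of |ECDF_a - ECDF_b| over the pooled sample points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EmptySampleError("KS test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(min(max(res.pvalue, 0.0), 1.0)))


def choose_wpf_model(wpf: WPFSample):
    """Pick normal vs lognormal for the WPF sample by the smaller KS D.

    Both candidates are fitted by moment matching (the lognormal on log
    weights); each is compared with the sample by a two-sample KS test
    against an equal-sized quantile-grid sample from the fitted law.

    Returns ``(label, {"normal": KSResult, "lognormal": KSResult})``.
    """
    w = np.asarray(wpf.weights_kg, dtype=float)
    if len(w) < 30:
        raise EmptySampleError(f"need >= 30 weights to choose a model, got {len(w)}")
    if np.any(w <= 0):
        raise ValueError("nonpositive weights are incompatible with a lognormal model")
    n = len(w)
    q = (np.arange(1, n + 1) - 0.5) / n
    mu, sd = w.mean(), w.std(ddof=1)
    lmu, lsd = np.log(w).mean(), np.log(w).std(ddof=1)
    normal_draws = stats.norm(mu, sd).ppf(q)
    logn_draws = stats.lognorm(s=lsd, scale=math.exp(lmu)).ppf(q)
    results = {
        "normal": ks_two_sample(w, normal_draws),
        "lognormal": ks_two_sample(w, logn_draws),
    }
    label = "lognormal" if results["lognormal"].d_stat <= results["normal"].d_stat else "normal"
    return label, results


def simulate_weight_by_count(
    wpf: WPFSample,
    max_count: int = 50,
    n_rep: int = 10_000,
    seed: int = 0,
) -> WeightByCountTable:
    """Monte Carlo total-weight distribution for 1..max_count fish.

    For each count k, draws k weights with replacement from the empirical
    WPF sample and sums them, ``n_rep`` times.
    """
    if max_count < 1:
        raise ValueError(f"max_count must be >= 1, got {max_count}")
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    if len(wpf) == 0:
        raise EmptySampleError("empty WPF sample")
    rng = np.random.default_rng([int(seed), 71])
    w = np.asarray(wpf.weights_kg, dtype=float)
    totals = {}
    for k in range(1, max_count + 1):
        draws = rng.choice(w, size=(n_rep, k), replace=True)
        totals[k] = np.sort(draws.sum(axis=1))
    return WeightByCountTable(np.arange(1, max_count + 1), totals, n_rep)


def assign_fish_counts(
    landings: pd.DataFrame,
    table: WeightByCountTable,
    bin_kg: float = 10.0,
    seed: int = 0,
    count_weights=None,
) -> pd.DataFrame:
    """Impute missing fish counts from the simulated weight-by-count bands.

    For each record with missing ``fish_count`` and total weight w, a count
    k is drawn with probability proportional to the frequency of simulated
    k-fish totals inside [w - bin/2, w + bin/2), optionally re-weighted by a
    prior ``count_weights`` over counts.  Records whose bin holds no
    simulated totals for any count are flagged ``unassignable`` (not
    dropped).

    Returns a copy of ``landings`` with columns ``fish_count_imputed``
    (float; the observed count where present) and ``assign_flag`` in
    {"observed", "imputed", "unassignable"}.
    """
    if np.any(np.asarray(landings["weight_kg"], dtype=float) <= 0):
        raise ValueError("weights must be positive")
    if count_weights is not None:
        count_weights = np.asarray(count_weights, dtype=float)
        if len(count_weights) != len(table.counts):
            raise ValueError("count_weights length must match table counts")
    rng = np.random.default_rng([int(seed), 72])
    out = landings.copy()
    imputed = np.asarray(out["fish_count"], dtype=float).copy()
    flags = np.where(np.isnan(imputed), "imputed", "observed").astype(object)
    missing_idx = np.flatnonzero(np.isnan(imputed))
    for i in missing_idx:
        w = float(out["weight_kg"].iloc[i])
        freq = table.bin_counts(w, bin_kg)
        if count_weights is not None:
            freq = freq * count_weights
        s = freq.sum()
        if s == 0:
            flags[i] = "unassignable"
            continue
        k = rng.choice(table.counts, p=freq / s)
        imputed[i] = float(k)
    out["fish_count_imputed"] = imputed
    out["assign_flag"] = flags
    return out
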