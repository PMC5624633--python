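"""Seeded synthetic fishery data: landings, vessel tracks, trips, CPUE tables.

The generators emulate the data streams of a seasonal offshore longline
fishery targeting large bluefin-type tuna: market landing records whose fish
counts are partially missing, hourly vessel geolocation tracks with known
fishing/non-fishing day labels, port entry/exit trip records whose fishing
days are a near-proportional fraction of at-sea days, and trip-level CPUE
tables with a zero-catch process and multiplicative year/month/area effects.
Every generator is a pure function of a :class:`SimConfig`; identical
configurations (including the seed) give identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "gen_landings",
    "gen_tracks",
    "gen_trips",
    "gen_cpue",
    "truncated_lognormal_mean",
]

PORTS = ("Tungkang", "Suao", "Singang")
CLASSES = ("CT1", "CT2", "CT3", "CT4")
MONTHS = (5, 6, 7)
AREAS = ("south", "north")

# Per-generator stream ids so that e.g. regenerating tracks does not perturb
# the landings stream.
_STREAM_LANDINGS = 1
_STREAM_TRACKS = 2
_STREAM_TRIPS = 3
_STREAM_CPUE = 4

#: Fishing/at-sea ratios by (port, vessel class).  Northern-port vessels
#: fish closer to their grounds and lose fewer days to transit, the largest
#: southern-port class the most.
DEFAULT_EFFORT_SLOPES = {
    ("Suao", "CT2"): 0.828,
    ("Suao", "CT3"): 0.824,
    ("Suao", "CT4"): 0.797,
    ("Singang", "CT1"): 0.818,
    ("Singang", "CT2"): 0.816,
    ("Singang", "CT3"): 0.831,
    ("Singang", "CT4"): 0.791,
    ("Tungkang", "CT1"): 0.750,
    ("Tungkang", "CT2"): 0.810,
    ("Tungkang", "CT3"): 0.752,
    ("Tungkang", "CT4"): 0.693,
}


def _default_year_effects() -> dict:
    """A declining-then-rebounding 15-year abundance trajectory (2001-2015)."""
    years = range(2001, 2016)
    out = {}
    for i, y in enumerate(years):
        out[y] = float(np.exp(1.0 - 0.14 * i + 0.25 * math.sin(0.9 * i)))
    # normalise to geometric mean 1 so month/area effects set the scale
    logs = np.log(list(out.values()))
    shift = logs.mean()
    return {y: float(np.exp(np.log(v) - shift)) for y, v in out.items()}


@dataclass
class SimConfig:
    """Study conditions for the synthetic fishery.

    Weight-per-fish (WPF) is truncated lognormal on [wpf_min, wpf_max] kg;
    fish counts per landing follow a truncated geometric on 1..max_count
    (single-fish landings are the most common).  Track geometry: fishing
    days hold a morning deployment leg at ``operation_speed_kn``, a soak
    drift, a 120-180 degree turn and a slow retrieval leg at
    ``retrieval_speed_kn``; transit days are straight legs at
    ``transit_speed_kn``, a fraction of which steam slowly or stop at anchor
    (the realistic confounders of speed- and distance-based classifiers).
    """

    seed: int = 0

    # --- landings / weight-per-fish ---
    wpf_logmean: float = math.log(190.0)
    wpf_logsd: float = 0.25
    wpf_min: float = 80.0
    wpf_max: float = 350.0
    count_geom_p: float = 0.55     # P(k) ∝ (1-p)^(k-1), k = 1..max_count
    max_count: int = 50
    n_landings: int = 2000
    mask_fraction: float = 0.3     # fraction of records with count hidden
    landing_years: tuple = (2001, 2002, 2003)

    # --- tracks ---
    n_vessels: int = 10
    n_days: int = 50               # vessel-days per vessel
    fishing_day_prob: float = 0.7
    transit_speed_kn: float = 9.0
    operation_speed_kn: float = 6.0
    retrieval_speed_kn: float = 2.5
    soak_speed_kn: float = 2.5   # gear stays attached; the vessel keeps way on
    slow_transit_frac: float = 0.15   # straight but slow (~3 kn) transits
    anchored_transit_frac: float = 0.15  # short steam then dead stop
    heading_jitter_deg: float = 2.0
    speed_jitter_kn: float = 0.15

    # --- trips ---
    n_trips: int = 2000
    effort_slopes: dict = field(default_factory=lambda: dict(DEFAULT_EFFORT_SLOPES))
    trip_noise_sd: float = 0.5     # truncated-normal days of noise
    min_at_sea: int = 3
    max_at_sea: int = 20

    # --- CPUE ---
    year_effects: dict = field(default_factory=_default_year_effects)
    month_effects: dict = field(default_factory=lambda: {5: 1.2, 6: 1.0, 7: 0.8})
    area_effects: dict = field(default_factory=lambda: {"south": 1.2, "north": 0.8})
    class_effects: dict = field(default_factory=lambda: {c: 1.0 for c in CLASSES})
    p_zero: object = 0.3           # scalar, or mapping (year, month, area, class) -> prob
    pcm_logsd: float = 0.6
    ym_effect_logsd: float = 0.0   # SD of lognormal year-by-month deviates
    south_frac: float = 0.8

    def __post_init__(self):
        if not self.wpf_min < self.wpf_max:
            raise ValueError(
                f"wpf_min ({self.wpf_min}) must be < wpf_max ({self.wpf_max})"
            )
        for name in ("fishing_day_prob", "mask_fraction", "count_geom_p", "south_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for key, s in self.effort_slopes.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"effort slope {key}={s} outside (0, 1]")
        if isinstance(self.p_zero, (int, float)) and not 0.0 <= self.p_zero <= 1.0:
            raise ValueError(f"p_zero={self.p_zero} outside [0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _draw_truncated_lognormal(rng, logmean, logsd, lo, hi, size):
    """Draw from lognormal(logmean, logsd) truncated to [lo, hi] by inverse CDF."""
    if logsd == 0.0:
        w = math.exp(logmean)
        if not lo <= w <= hi:
            raise ValueError("degenerate WPF outside truncation bounds")
        return np.full(size, w)
    from scipy import stats

    dist = stats.lognorm(s=logsd, scale=math.exp(logmean))
    a, b = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(a, b, size=size)
    return dist.ppf(u)


def truncated_lognormal_mean(logmean, logsd, lo, hi):
    """Mean of a lognormal truncated to [lo, hi], by numerical integration."""
    from scipy import integrate, stats

    if logsd == 0.0:
        return math.exp(logmean)
    dist = stats.lognorm(s=logsd, scale=math.exp(logmean))
    z = dist.cdf(hi) - dist.cdf(lo)
    num, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi)
    return num / z


def _truncated_geometric_pmf(p, kmax):
    k = np.arange(1, kmax + 1)
    w = (1.0 - p) ** (k - 1)
    return w / w.sum()


def gen_landings(cfg: SimConfig):
    """Generate market landing records plus the hidden per-record truth.

    Returns ``(landings, truth)``: ``landings`` has columns
    ``vessel_id, date, port, weight_kg, fish_count`` with ``fish_count``
    missing (NaN) for a ``mask_fraction`` of records; ``truth`` retains
    every record's true count.
    """
    rng = cfg.rng(_STREAM_LANDINGS)
    n = cfg.n_landings
    pmf = _truncated_geometric_pmf(cfg.count_geom_p, cfg.max_count)
    counts = rng.choice(np.arange(1, cfg.max_count + 1), size=n, p=pmf)
    weights = np.empty(n)
    total_fish = int(counts.sum())
    per_fish = _draw_truncated_lognormal(
        rng, cfg.wpf_logmean, cfg.wpf_logsd, cfg.wpf_min, cfg.wpf_max, total_fish
    )
    idx = np.repeat(np.arange(n), counts)
    weights = np.bincount(idx, weights=per_fish, minlength=n)

    years = rng.choice(cfg.landing_years, size=n)
    months = rng.choice(MONTHS, size=n)
    days = rng.integers(1, 29, size=n)
    dates = pd.to_datetime(
        {"year": years, "month": months, "day": days}
    ).dt.date
    ports = rng.choice(PORTS, size=n, p=[0.5, 0.25, 0.25])
    vessels = np.array([f"V{v:03d}" for v in rng.integers(0, cfg.n_vessels, size=n)])

    masked = rng.random(n) < cfg.mask_fraction
    observed = counts.astype(float)
    observed[masked] = np.nan

    landings = pd.DataFrame(
        {
            "vessel_id": vessels,
            "date": dates,
            "port": ports,
            "weight_kg": weights,
            "fish_count": observed,
        }
    )
    truth = landings.drop(columns=["fish_count"]).assign(fish_count=counts)
    return landings, truth


# ---------------------------------------------------------------------------
# tracks

_EARTH_R = 6371.0
_KN_TO_KMH = 1.852


def _step(lat, lon, heading_deg, dist_km):
    """Advance one small step on a local flat-earth approximation."""
    th = math.radians(heading_deg)
    dlat = dist_km * math.cos(th) / (math.pi * _EARTH_R / 180.0)
    dlon = dist_km * math.sin(th) / (
        math.pi * _EARTH_R / 180.0 * max(math.cos(math.radians(lat)), 1e-6)
    )
    return lat + dlat, lon + dlon


def _day_profile(cfg: SimConfig, rng, fishing: bool):
    """Hourly (speed_kn, heading_deg) profile for one vessel-day."""
    jit = lambda sd: rng.normal(0.0, sd)
    base = rng.uniform(0.0, 360.0)
    speeds, headings = [], []
    if fishing:
        turn = rng.uniform(120.0, 180.0) * rng.choice([-1.0, 1.0])
        for h in range(24):
            if h < 5:  # deployment leg
                sp, hd = cfg.operation_speed_kn, base
            elif h < 7:  # soak: reposition slowly toward the line start
                sp, hd = cfg.soak_speed_kn, base + turn + rng.normal(0.0, 15.0)
            elif h < 18:  # retrieval leg, reversed heading, slow
                sp, hd = cfg.retrieval_speed_kn, base + turn
            else:  # evening drift
                sp, hd = cfg.soak_speed_kn, rng.uniform(0.0, 360.0)
            speeds.append(max(sp + jit(cfg.speed_jitter_kn), 0.1))
            headings.append((hd + jit(cfg.heading_jitter_deg)) % 360.0)
    else:
        u = rng.random()
        if u < cfg.slow_transit_frac:
            mode = "slow"
        elif u < cfg.slow_transit_frac + cfg.anchored_transit_frac:
            mode = "anchored"
        else:
            mode = "steam"
        for h in range(24):
            if mode == "steam":
                sp = cfg.transit_speed_kn
            elif mode == "slow":
                sp = 2.8
            else:  # anchored: 10 h of steaming then a dead stop
                sp = cfg.transit_speed_kn if h < 10 else 0.0
            if sp > 0:
                sp = max(sp + jit(cfg.speed_jitter_kn), 0.1)
            speeds.append(sp)
            headings.append((base + jit(cfg.heading_jitter_deg)) % 360.0)
    return np.array(speeds), np.array(headings)


def gen_tracks(cfg: SimConfig):
    """Generate hourly track points plus ground-truth fishing-day labels.

    Returns ``(points, labels)``: ``points`` has columns
    ``vessel_id, timestamp, lat, lon, speed_kn`` (timestamps are UTC; the
    fishery's local day is UTC+8), ``labels`` has
    ``vessel_id, date, is_fishing`` with ``date`` the local calendar date.
    """
    rng = cfg.rng(_STREAM_TRACKS)
    rows = []
    label_rows = []
    start = pd.Timestamp("2010-05-01")
    for v in range(cfg.n_vessels):
        vid = f"V{v:03d}"
        lat = rng.uniform(21.5, 25.5)
        lon = rng.uniform(120.5, 123.0)
        for d in range(cfg.n_days):
            fishing = bool(rng.random() < cfg.fishing_day_prob)
            local_day = start + pd.Timedelta(days=d)
            speeds, headings = _day_profile(cfg, rng, fishing)
            for h in range(24):
                ts_local = local_day + pd.Timedelta(hours=h)
                rows.append(
                    (vid, ts_local - pd.Timedelta(hours=8), lat, lon, speeds[h])
                )
                lat, lon = _step(lat, lon, headings[h], speeds[h] * _KN_TO_KMH)
            # drift back toward the grounds so coordinates stay in range
            lat = min(max(lat, 20.0), 27.0)
            lon = min(max(lon, 119.0), 124.5)
            label_rows.append((vid, local_day.date(), fishing))
    points = pd.DataFrame(
        rows, columns=["vessel_id", "timestamp", "lat", "lon", "speed_kn"]
    )
    labels = pd.DataFrame(label_rows, columns=["vessel_id", "date", "is_fishing"])
    return points, labels


# ---------------------------------------------------------------------------
# trips

def gen_trips(cfg: SimConfig):
    """Generate port entry/exit trip records plus per-trip fishing-day truth.

    Returns ``(trips, truth)``: ``trips`` has columns
    ``trip_id, vessel_id, port, vessel_class, depart, return_``; ``truth``
    adds ``at_sea_days`` and ``fishing_days`` where
    ``fishing_days = slope(port, class) * at_sea_days + noise`` clipped to
    ``[0, at_sea_days]``.
    """
    rng = cfg.rng(_STREAM_TRIPS)
    n = cfg.n_trips
    combos = list(cfg.effort_slopes.keys())
    pick = rng.integers(0, len(combos), size=n)
    ports = np.array([combos[i][0] for i in pick])
    classes = np.array([combos[i][1] for i in pick])
    slopes = np.array([cfg.effort_slopes[combos[i]] for i in pick])

    at_sea = rng.integers(cfg.min_at_sea, cfg.max_at_sea + 1, size=n)
    noise = rng.normal(0.0, cfg.trip_noise_sd, size=n) if cfg.trip_noise_sd > 0 else np.zeros(n)
    fishing = np.clip(slopes * at_sea + noise, 0.0, at_sea.astype(float))

    # schedule sequentially per vessel so one vessel's trips never overlap;
    # depart 09:00 and return in the afternoon so the number of distinct
    # calendar dates intersected equals at_sea
    vessels = np.array([f"V{v:03d}" for v in rng.integers(0, cfg.n_vessels, size=n)])
    base = pd.Timestamp("2007-05-01 09:00")
    cursor = {}
    depart = np.empty(n, dtype="datetime64[ns]")
    gaps = rng.integers(1, 4, size=n)
    for i in range(n):
        v = vessels[i]
        depart[i] = cursor.get(v, base)
        cursor[v] = (
            depart[i]
            + np.timedelta64(int(at_sea[i] - 1 + gaps[i]), "D")
        )
    depart = pd.to_datetime(depart)
    ret = depart + pd.to_timedelta(at_sea - 1, unit="D") + pd.Timedelta(hours=8)
    trips = pd.DataFrame(
        {
            "trip_id": [f"T{i:06d}" for i in range(n)],
            "vessel_id": vessels,
            "port": ports,
            "vessel_class": classes,
            "depart": depart,
            "return_": ret,
        }
    )
    truth = trips.assign(at_sea_days=at_sea, fishing_days=fishing)
    return trips, truth


# ---------------------------------------------------------------------------
# CPUE

def _p_zero_of(cfg: SimConfig, year, month, area, vclass):
    if callable(cfg.p_zero):
        return cfg.p_zero(year, month, area, vclass)
    if isinstance(cfg.p_zero, dict):
        try:
            return cfg.p_zero[(year, month, area, vclass)]
        except KeyError as e:
            raise ValueError(
                f"p_zero missing level {(year, month, area, vclass)}"
            ) from e
    return float(cfg.p_zero)


def gen_cpue(cfg: SimConfig):
    """Generate a trip-level CPUE table with known multiplicative effects.

    Each trip is a zero catch with probability ``p_zero(covariates)``;
    positive trips have ``cpue = year * month * area * class effect *
    exp(N(0, pcm_logsd))``.  Catch is kept as ``cpue * fishing_days``
    (fractional, so the generating effects are exact); real landing data
    would have integer counts.

    Returns ``(records, truth)`` where ``truth`` maps years to generating
    effects and carries the per-trip positive probability.
    """
    rng = cfg.rng(_STREAM_CPUE)
    n = cfg.n_trips
    years = np.array(sorted(cfg.year_effects.keys()))
    if len(years) < 2:
        raise ValueError("need at least two year levels")
    for m in MONTHS:
        if m not in cfg.month_effects:
            raise ValueError(f"month_effects missing level {m}")
    for a in AREAS:
        if a not in cfg.area_effects:
            raise ValueError(f"area_effects missing level {a}")
    for c in CLASSES:
        if c not in cfg.class_effects:
            raise ValueError(f"class_effects missing level {c}")

    year = rng.choice(years, size=n)
    month = rng.choice(MONTHS, size=n)
    area = np.where(rng.random(n) < cfg.south_frac, "south", "north")
    vclass = rng.choice(CLASSES, size=n)
    fishing_days = rng.integers(3, 16, size=n).astype(float)

    pz = np.array(
        [_p_zero_of(cfg, y, m, a, c) for y, m, a, c in zip(year, month, area, vclass)]
    )
    zero = rng.random(n) < pz
    eff = (
        np.vectorize(cfg.year_effects.get)(year)
        * np.vectorize(cfg.month_effects.get)(month)
        * np.vectorize(cfg.area_effects.get)(area)
        * np.vectorize(cfg.class_effects.get)(vclass)
    )
    ym_dev = {}
    if cfg.ym_effect_logsd > 0:
        for y in years:
            for m in MONTHS:
                ym_dev[(int(y), m)] = float(
                    np.exp(rng.normal(0.0, cfg.ym_effect_logsd))
                )
        eff = eff * np.array([ym_dev[(int(y), m)] for y, m in zip(year, month)])
    err = (
        np.exp(rng.normal(0.0, cfg.pcm_logsd, size=n))
        if cfg.pcm_logsd > 0
        else np.ones(n)
    )
    cpue = np.where(zero, 0.0, eff * err)

    records = pd.DataFrame(
        {
            "trip_id": [f"T{i:06d}" for i in range(n)],
            "year": year,
            "month": month,
            "area": area,
            "vessel_class": vclass,
            "fishing_days": fishing_days,
            "catch_n": cpue * fishing_days,
            "cpue": cpue,
        }
    )
    truth = {
        "year_effects": dict(cfg.year_effects),
        "p_pos": {int(y): 1.0 - float(np.mean(pz[year == y])) for y in years},
        "ym_deviates": ym_dev,
    }
    return records, truth
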