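"""Synthetic herd, AMS visit-schedule and breath-gas generator.

The generator produces the three raw tables the processing pipeline
consumes — a cow table, an AMS visit log and a 15-s breath-gas log from a
single sampling point — together with the ground truth that produced
them, so parameter recovery can be checked exactly.

Generative model for the CH4:CO2 ratio of cow *j* on day *d*, sample *s*:

    r_jds = mean_ratio * exp(b_j) * exp(w_jd) * diurnal(hour_s) * eps_s

with ``b_j ~ N(-sb^2/2, sb^2)`` and ``w_jd ~ N(-sw^2/2, sw^2)`` log-normal
effects whose sigmas are chosen so the realized coefficients of variation
equal the configured ``cv_between`` / ``cv_within`` (sigma^2 = ln(1+cv^2)),
``diurnal`` a unit-mean cosine with trough at 04:00, and ``eps`` unit-mean
log-normal sample noise.  The between/within decomposition implies a true
repeatability of ``cv_b^2 / (cv_b^2 + cv_w^2)``.

CO2 at the sampling inlet is barn background plus a log-normal breath
plume; CH4 is background plus the sample ratio times the plume excess, so
the background-corrected sample ratio recovers ``r_jds`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ConfigurationError, FormulaCoefficients, SimulationConfig

__all__ = [
    "GroundTruth",
    "Campaign",
    "simulate_herd",
    "simulate_visits",
    "simulate_ground_truth",
    "simulate_gas_traces",
    "true_phenotypes",
    "simulate_campaign",
    "simulate_two_year",
    "write_campaign",
]

_BACKGROUND_WINDOW_MIN = 10.0  # instrument disconnected 10 min/day for barn air


class DataConsistencyError(ValueError):
    """Raised when simulation inputs do not line up (e.g. missing truth)."""


def _lognormal_sigma(cv_pct: float) -> float:
    """Log-scale SD such that a unit-mean log-normal has the given CV (%)."""
    cv = cv_pct / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


def _unit_lognormal(rng: np.random.Generator, cv_pct: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV (%)."""
    if cv_pct == 0:
        return np.ones(size)
    s = _lognormal_sigma(cv_pct)
    return np.exp(rng.normal(-0.5 * s * s, s, size))


def diurnal_factor(hour: np.ndarray | float, amplitude: float) -> np.ndarray | float:
    """Unit-mean cosine modulation of emission with trough at 04:00."""
    return 1.0 - amplitude * np.cos(2.0 * np.pi * (np.asarray(hour, dtype=float) - 4.0) / 24.0)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated measurement campaign."""

    cow_effects: pd.DataFrame      # cow_id, cow_effect (multiplicative, mean 1)
    cow_day: pd.DataFrame          # cow_id, date, realized_ratio
    true_cv_between: float         # %
    true_cv_within: float          # %

    @property
    def true_repeatability(self) -> float:
        b2 = self.true_cv_between ** 2
        w2 = self.true_cv_within ** 2
        return b2 / (b2 + w2) if (b2 + w2) > 0 else float("nan")


@dataclass
class Campaign:
    """One simulated measurement campaign (a year of the study)."""

    cows: pd.DataFrame
    visits: pd.DataFrame
    gas: pd.DataFrame
    truth: GroundTruth
    background_windows: pd.DataFrame   # date, start, end
    config: SimulationConfig
    start_date: pd.Timestamp
    year: int = 1


# ---------------------------------------------------------------------------
# herd

def simulate_herd(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the static cow table.

    Normal draws truncated at zero for the continuous covariates; the
    primiparous/multiparous split is deterministic
    (``round(n_cows * fraction)`` primiparous) for test stability; pregnancy
    days are uniform over the configured range, 0 meaning an open cow.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cows

    def trunc_normal(mean_sd: tuple[float, float], size: int) -> np.ndarray:
        mean, sd = mean_sd
        if sd == 0:
            return np.full(size, float(mean))
        a = (0.0 - mean) / sd  # truncate below zero
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)

    n_primi = int(round(n * config.parity_fraction_primiparous))
    parity = np.array(["primiparous"] * n_primi + ["multiparous"] * (n - n_primi))
    lo, hi = config.pregnancy_days_range
    cows = pd.DataFrame({
        "cow_id": [f"cow{i + 1:03d}" for i in range(n)],
        "bw_kg": np.round(trunc_normal(config.bw_mean_sd, n), 1),
        "parity": parity,
        "days_pregnant": rng.integers(lo, hi + 1, n),
        "milk_kg_day": np.round(trunc_normal(config.milk_mean_sd, n), 2),
        "fat_pct": np.round(trunc_normal(config.fat_pct_mean_sd, n), 2),
        "protein_pct": np.round(trunc_normal(config.protein_pct_mean_sd, n), 2),
        "concentrate_kg_dm": np.round(trunc_normal(config.concentrate_mean_sd, n), 2),
    })
    return cows


# ---------------------------------------------------------------------------
# visits

def _truncated_poisson_lambda(target_mean: float) -> float:
    """Rate of a Poisson truncated to {1,2,3,4} with the requested mean."""
    k = np.arange(1, 5)

    def mean_at(lam: float) -> float:
        w = stats.poisson.pmf(k, lam)
        return float(np.sum(k * w) / np.sum(w))

    if target_mean <= 1.0:
        return 1e-9
    if target_mean >= 4.0 - 1e-9:
        return 500.0
    return float(optimize.brentq(lambda lam: mean_at(lam) - target_mean, 1e-9, 500.0))


def _visit_count_pmf(visit_rate: float) -> np.ndarray:
    lam = _truncated_poisson_lambda(visit_rate)
    k = np.arange(1, 5)
    w = stats.poisson.pmf(k, lam)
    return w / w.sum()


def simulate_visits(
    cows: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    start_date: str | pd.Timestamp = "2022-05-09",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the AMS visit log and the daily barn-air sampling windows.

    There is a single sampling point, so visits never overlap — across
    cows, not only within a cow.  Per cow-day the visit count is a
    truncated Poisson on {1..4} matched to ``visit_rate``; the day's
    visits (all cows pooled) plus one 10-min background window are placed
    in shuffled order with Dirichlet-distributed idle gaps filling the
    remaining time.  Times have 1-s resolution.

    Returns ``(visit_log, background_windows)``.
    """
    if cows.empty:
        raise ConfigurationError("cow table is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    start = pd.Timestamp(start_date).normalize()
    pmf = _visit_count_pmf(config.visit_rate)
    lo_min, hi_min = config.visit_duration_min

    rows: list[dict] = []
    windows: list[dict] = []
    day_seconds = 86400.0
    for day in range(config.n_days):
        day_start = start + pd.Timedelta(days=day)
        counts = rng.choice([1, 2, 3, 4], size=len(cows), p=pmf)
        items: list[tuple[str | None, float]] = [(None, _BACKGROUND_WINDOW_MIN * 60.0)]
        for cow_id, c in zip(cows["cow_id"], counts):
            for _ in range(c):
                items.append((cow_id, float(rng.uniform(lo_min, hi_min) * 60.0)))
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        total = sum(d for _, d in items)
        if total > day_seconds - len(items):  # overcrowded day: shrink visits
            scale = (day_seconds - len(items)) / total
            items = [(cid, d * scale) for cid, d in items]
            total = sum(d for _, d in items)
        slack = day_seconds - total
        gaps = rng.dirichlet(np.ones(len(items) + 1)) * slack
        t = gaps[0]
        day_concentrate = dict(zip(cows["cow_id"], cows["concentrate_kg_dm"]))
        day_milk = dict(zip(cows["cow_id"], cows["milk_kg_day"]))
        n_visits_cow = dict(zip(cows["cow_id"], counts))
        for i, (cow_id, dur) in enumerate(items):
            entry = day_start + pd.Timedelta(seconds=round(t))
            exit_ = day_start + pd.Timedelta(seconds=round(t + dur))
            if cow_id is None:
                windows.append({"date": day_start.date(), "start": entry, "end": exit_})
            else:
                rows.append({
                    "cow_id": cow_id,
                    "entry_time": entry,
                    "exit_time": exit_,
                    "concentrate_kg_dm": round(day_concentrate[cow_id] / n_visits_cow[cow_id], 3),
                    "milk_kg": round(day_milk[cow_id] / n_visits_cow[cow_id], 3),
                })
            t += dur + gaps[i + 1]
    visit_log = pd.DataFrame(
        rows, columns=["cow_id", "entry_time", "exit_time", "concentrate_kg_dm", "milk_kg"]
    )
    if not visit_log.empty:
        visit_log = visit_log.sort_values("entry_time", ignore_index=True)
    visit_log.insert(0, "visit_id", [f"v{i:05d}" for i in range(len(visit_log))])
    windows_df = pd.DataFrame(windows, columns=["date", "start", "end"])
    return visit_log, windows_df


# ---------------------------------------------------------------------------
# ground truth and gas traces

def simulate_ground_truth(
    cows: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    start_date: str | pd.Timestamp = "2022-05-09",
    cow_log_z: np.ndarray | None = None,
) -> GroundTruth:
    """Draw the latent cow effects and realized cow-day ratios.

    ``cow_log_z`` optionally supplies the standard-normal scores behind
    the cow effects (used to correlate cow effects across years).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    start = pd.Timestamp(start_date).normalize()
    sb = _lognormal_sigma(config.cv_between)
    sw = _lognormal_sigma(config.cv_within)
    n = len(cows)
    if cow_log_z is None:
        cow_log_z = rng.standard_normal(n)
    cow_eff = np.exp(sb * cow_log_z - 0.5 * sb * sb)
    cow_effects = pd.DataFrame({"cow_id": cows["cow_id"], "cow_effect": cow_eff})

    dates = [start + pd.Timedelta(days=d) for d in range(config.n_days)]
    day_eff = np.exp(rng.normal(-0.5 * sw * sw, sw, (n, config.n_days))) if sw > 0 else np.ones((n, config.n_days))
    records = []
    for i, cow_id in enumerate(cows["cow_id"]):
        for d, date in enumerate(dates):
            records.append({
                "cow_id": cow_id,
                "date": date.date(),
                "realized_ratio": config.mean_ratio * cow_eff[i] * day_eff[i, d],
            })
    cow_day = pd.DataFrame(records, columns=["cow_id", "date", "realized_ratio"])
    return GroundTruth(cow_effects, cow_day, config.cv_between, config.cv_within)


def simulate_gas_traces(
    visits: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    background_windows: pd.DataFrame | None = None,
    background: Literal["full", "windows", "none"] = "full",
) -> pd.DataFrame:
    """Generate the 15-s gas log for a visit schedule.

    Samples lie on a fixed grid (multiples of ``sample_interval_s`` from
    midnight).  Inside a visit the trace carries the cow's breath plume;
    ``background='full'`` also emits barn-air samples on the entire grid
    outside visits, ``'windows'`` only inside the daily disconnection
    windows (sufficient for background estimation, much smaller), and
    ``'none'`` suppresses them.
    """
    if visits.empty:
        raise ConfigurationError("visit log is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    step = int(config.sample_interval_s)
    ratio_map = {
        (r.cow_id, r.date): r.realized_ratio for r in truth.cow_day.itertuples()
    }

    def grid_in(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
        # first grid point >= start, half-open on the right
        first = start.ceil(f"{step}s")
        if first >= end:
            return pd.DatetimeIndex([])
        return pd.date_range(first, end - pd.Timedelta(seconds=1), freq=f"{step}s")

    frames: list[pd.DataFrame] = []
    for v in visits.itertuples():
        ts = grid_in(v.entry_time, v.exit_time)
        if len(ts) == 0:
            continue
        key = (v.cow_id, v.entry_time.date())
        if key not in ratio_map:
            raise DataConsistencyError(
                f"no ground-truth ratio for cow {v.cow_id} on {v.entry_time.date()}"
            )
        r_day = ratio_map[key]
        hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        dfac = diurnal_factor(hours.to_numpy(), config.diurnal_amplitude)
        plume = config.plume_co2_mean_ppm * _unit_lognormal(rng, config.plume_noise_cv, len(ts))
        r_sample = r_day * dfac * _unit_lognormal(rng, config.plume_noise_cv, len(ts))
        frames.append(pd.DataFrame({
            "timestamp": ts,
            "ch4_ppm": config.barn_ch4_ppm + r_sample * plume,
            "co2_ppm": config.barn_co2_ppm + plume,
        }))

    if background != "none":
        if background == "windows":
            if background_windows is None or background_windows.empty:
                raise ConfigurationError("background='windows' requires background windows")
            segments = [(w.start, w.end) for w in background_windows.itertuples()]
        else:
            lo = visits["entry_time"].min().normalize()
            hi = (visits["exit_time"].max().normalize() + pd.Timedelta(days=1))
            occupied = sorted((v.entry_time, v.exit_time) for v in visits.itertuples())
            segments = []
            cursor = lo
            for a, b in occupied:
                if a > cursor:
                    segments.append((cursor, a))
                cursor = max(cursor, b)
            if cursor < hi:
                segments.append((cursor, hi))
        for a, b in segments:
            ts = grid_in(a, b)
            if len(ts) == 0:
                continue
            noise_ch4 = _unit_lognormal(rng, config.plume_noise_cv / 10.0, len(ts))
            noise_co2 = _unit_lognormal(rng, config.plume_noise_cv / 10.0, len(ts))
            frames.append(pd.DataFrame({
                "timestamp": ts,
                "ch4_ppm": config.barn_ch4_ppm * noise_ch4,
                "co2_ppm": config.barn_co2_ppm * noise_co2,
            }))

    gas = pd.concat(frames, ignore_index=True).sort_values("timestamp", ignore_index=True)
    gas["ch4_ppm"] = gas["ch4_ppm"].round(4)
    gas["co2_ppm"] = gas["co2_ppm"].round(4)
    return gas


def true_phenotypes(
    truth: GroundTruth,
    cows: pd.DataFrame,
    config: SimulationConfig,
    coefficients: FormulaCoefficients | None = None,
) -> pd.DataFrame:
    """Daily CH4 (L/day) implied by the *true* ratios, bypassing gas noise.

    Applies the same heat-production / CO2 / CH4 chain the estimation
    stage uses, so pipeline output can be compared against it directly.
    """
    from . import emission  # local import to avoid a cycle

    coeffs = coefficients or FormulaCoefficients()
    merged = truth.cow_day.merge(cows, on="cow_id", how="left")
    hp = emission.heat_production(
        merged["bw_kg"], merged["milk_kg_day"], merged["days_pregnant"], coeffs
    )
    co2 = emission.daily_co2(hp, coeffs)
    return pd.DataFrame({
        "cow_id": merged["cow_id"],
        "date": merged["date"],
        "true_ratio": merged["realized_ratio"],
        "true_co2_l_day": co2,
        "true_ch4_l_day": emission.daily_ch4(merged["realized_ratio"], co2),
    })


# ---------------------------------------------------------------------------
# campaign bundles

def simulate_campaign(
    config: SimulationConfig,
    start_date: str | pd.Timestamp = "2022-05-09",
    background: Literal["full", "windows", "none"] = "full",
    year: int = 1,
    _cow_log_z: np.ndarray | None = None,
    _cows: pd.DataFrame | None = None,
) -> Campaign:
    """Simulate one full campaign: herd, visits, ground truth, gas log."""
    ss = np.random.SeedSequence([config.seed, year])
    rng_herd, rng_truth, rng_visits, rng_gas = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    cows = _cows if _cows is not None else simulate_herd(config, rng_herd)
    truth = simulate_ground_truth(cows, config, rng_truth, start_date, cow_log_z=_cow_log_z)
    if config.n_days == 0:
        visits = pd.DataFrame(
            columns=["visit_id", "cow_id", "entry_time", "exit_time", "concentrate_kg_dm", "milk_kg"]
        )
        windows = pd.DataFrame(columns=["date", "start", "end"])
        gas = pd.DataFrame(columns=["timestamp", "ch4_ppm", "co2_ppm"])
    else:
        visits, windows = simulate_visits(cows, config, rng_visits, start_date)
        gas = simulate_gas_traces(visits, truth, config, rng_gas, windows, background)
    return Campaign(cows, visits, gas, truth, windows, config, pd.Timestamp(start_date), year)


def simulate_two_year(
    config: SimulationConfig,
    year_correlation: float = 0.7,
    year2_config: SimulationConfig | None = None,
    background: Literal["full", "windows", "none"] = "full",
) -> dict[int, Campaign]:
    """Simulate the same herd measured in two consecutive years.

    Cow effects in the two years are standard-bivariate-normal on the log
    scale with the given correlation; milk yield shifts to the second-year
    herd mean while staying correlated (r=0.6) with the first year, and
    cows gain ~15 kg.  The second year uses its own barn background
    (25.8 ppm CH4 / 625.5 ppm CO2 unless overridden).
    """
    if not (-1.0 <= year_correlation <= 1.0):
        raise ConfigurationError("year_correlation must lie in [-1, 1]")
    cfg2 = year2_config or config.replace(
        milk_mean_sd=(33.4, 6.0), barn_ch4_ppm=25.8, barn_co2_ppm=625.5
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
    n = config.n_cows
    z1 = rng.standard_normal(n)
    z2 = year_correlation * z1 + np.sqrt(max(0.0, 1.0 - year_correlation ** 2)) * rng.standard_normal(n)

    camp1 = simulate_campaign(config, "2022-05-09", background, year=1, _cow_log_z=z1)
    # same animals one year later: grow, re-draw milk correlated with year 1
    cows2 = camp1.cows.copy()
    cows2["bw_kg"] = np.round(cows2["bw_kg"] + rng.normal(15.0, 5.0, n), 1)
    m1_mean, m1_sd = config.milk_mean_sd
    m2_mean, m2_sd = cfg2.milk_mean_sd
    r_milk = 0.6
    milk2 = (
        m2_mean
        + r_milk * (cows2["milk_kg_day"] - m1_mean) * (m2_sd / max(m1_sd, 1e-9))
        + np.sqrt(1 - r_milk ** 2) * m2_sd * rng.standard_normal(n)
    )
    cows2["milk_kg_day"] = np.round(np.clip(milk2, 1.0, None), 2)
    camp2 = simulate_campaign(cfg2, "2023-05-08", background, year=2, _cow_log_z=z2, _cows=cows2)
    return {1: camp1, 2: camp2}


def write_campaign(campaign: Campaign, out_dir: str | Path, suffix: str = "") -> dict[str, Path]:
    """Write the campaign tables as CSV; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gas": out / f"gas_log{suffix}.csv",
        "visits": out / f"visit_log{suffix}.csv",
        "cows": out / f"cow_table{suffix}.csv",
        "truth_cow_day": out / f"ground_truth_cow_day{suffix}.csv",
        "truth_cow": out / f"ground_truth_cow{suffix}.csv",
        "background_windows": out / f"background_windows{suffix}.csv",
    }
    campaign.gas.to_csv(paths["gas"], index=False)
    campaign.visits.to_csv(paths["visits"], index=False)
    campaign.cows.to_csv(paths["cows"], index=False)
    campaign.truth.cow_day.to_csv(paths["truth_cow_day"], index=False)
    campaign.truth.cow_effects.to_csv(paths["truth_cow"], index=False)
    campaign.background_windows.to_csv(paths["background_windows"], index=False)
    return paths
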