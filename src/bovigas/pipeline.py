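"""End-to-end orchestration: simulate -> process -> estimate -> analyze.

One :func:`run_pipeline` call reproduces a whole measurement campaign
(optionally two years of it), writing every stage's tables, a run
manifest with checksums and row bookkeeping, and a human-readable
summary report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import breath, emission, varstats
from .config import FeedContext, PipelineConfig
from .simulate import Campaign, simulate_campaign, simulate_two_year, write_campaign

__all__ = ["run_pipeline", "render_report", "RunManifest", "process_campaign"]


@dataclass
class RunManifest:
    """Bookkeeping record emitted for every pipeline run."""

    config: dict
    version: str
    generated_at: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, dict]

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_campaign(campaign: Campaign, config: PipelineConfig) -> dict:
    """Run Steps I-III on one campaign; returns ratios + phenotype tables."""
    processed = breath.process_gas_log(
        campaign.gas, campaign.visits, campaign.background_windows,
        threshold_ppm=config.co2_threshold_ppm,
        background_mode=config.background_mode,
        aggregation=config.ratio_aggregation,
    )
    feed = FeedContext(
        tmr_herd_mean=campaign.config.tmr_herd_mean,
        concentrate_herd_mean=float(campaign.cows["concentrate_kg_dm"].mean()),
    )
    day_ratios = processed["ratios"]["day"].rename(columns={"n": "n_visits"})
    phen = emission.build_daily_phenotypes(
        day_ratios, campaign.cows, feed,
        coefficients=config.coefficients, ecm_reference=config.ecm_reference,
    )
    phen["year"] = campaign.year
    hourly = emission.hourly_phenotypes(processed["ratios"]["visit"], phen)
    hourly["year"] = campaign.year
    return {"processed": processed, "phenotypes": phen, "hourly": hourly, "feed": feed}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = config.simulation.replace(seed=config.seed)
    if config.two_year:
        campaigns = simulate_two_year(sim, config.year_correlation)
    else:
        campaigns = {1: simulate_campaign(sim)}

    if config.dry_run:
        manifest = RunManifest(
            config=config.to_dict(), version=_version,
            generated_at=datetime.now(timezone.utc).isoformat(),
            input_checksums={}, stage_counts={"dry_run": {}},
        )
        manifest.to_json(out / "manifest.json")
        return {"manifest": manifest}

    checksums: dict[str, str] = {}
    stage_counts: dict[str, dict] = {}
    results: dict[int, dict] = {}
    phen_frames, hourly_frames = [], []
    for year, campaign in campaigns.items():
        suffix = f"_y{year}"
        paths = write_campaign(campaign, out, suffix)
        checksums.update({p.name: _sha256(p) for p in paths.values()})
        res = process_campaign(campaign, config)
        results[year] = res
        stage_counts[f"year{year}"] = res["processed"]["counts"]
        res["phenotypes"].to_csv(out / f"daily_phenotypes{suffix}.csv", index=False)
        for lvl, table in res["processed"]["ratios"].items():
            table.to_csv(out / f"ratios_{lvl}{suffix}.csv", index=False)
        phen_frames.append(res["phenotypes"])
        hourly_frames.append(res["hourly"])

    phen = pd.concat(phen_frames, ignore_index=True)
    report_df = varstats.variance_report(
        phen, responses=config.responses, alpha=config.alpha, r2_mode=config.r2_mode,
    )
    report_df.to_csv(out / "variance_report.csv", index=False)

    correlations = {}
    if len(campaigns) >= 2:
        for col, label in (("ch4_l_day", "actual"), ("ch4_std_l_day", "adjusted"),
                           ("ratio", "ratio_actual"), ("ratio_std", "ratio_adjusted")):
            if col in phen.columns:
                try:
                    r, p, n = varstats.pearson_between_years(phen, col)
                    correlations[label] = {"r": r, "p": p, "n": n}
                except varstats.EstimationError:
                    pass

    diurnal = {}
    for year, res in results.items():
        try:
            prof = varstats.diurnal_profile(res["hourly"])
            prof["hourly"].to_csv(out / f"diurnal_profile_y{year}.csv", index=False)
            diurnal[year] = prof
        except Exception:
            diurnal[year] = None

    levels = varstats.levels_of_variation(results[min(results)]["processed"]["ratios"])
    levels["cv_by_level"].to_csv(out / "cv_by_level.csv", index=False)

    report_text = render_report(report_df, diurnal, correlations, phen, levels)
    (out / "report.txt").write_text(report_text)

    if config.make_plots:
        _make_plots(phen, diurnal, out)

    manifest = RunManifest(
        config=config.to_dict(), version=_version,
        generated_at=datetime.now(timezone.utc).isoformat(),
        input_checksums=checksums, stage_counts=stage_counts,
    )
    manifest.to_json(out / "manifest.json")
    return {
        "campaigns": campaigns, "results": results, "phenotypes": phen,
        "variance_report": report_df, "correlations": correlations,
        "diurnal": diurnal, "levels": levels, "manifest": manifest,
        "report_text": report_text,
    }


def _herd_summary(phen: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for year, sub in phen.groupby("year"):
        cows = sub.groupby("cow_id").first()
        rows.append({
            "year": year,
            "n_cows": len(cows),
            "bw_kg": f"{cows['bw_kg'].mean():.0f} ± {cows['bw_kg'].std(ddof=1):.1f}",
            "milk_kg_day": f"{cows['milk_kg_day'].mean():.1f} ± {cows['milk_kg_day'].std(ddof=1):.2f}",
            "ecm_kg_day": f"{cows['ecm_kg_day'].mean():.1f} ± {cows['ecm_kg_day'].std(ddof=1):.2f}",
            "edmi_kg_day": f"{cows['edmi_kg_day'].mean():.1f} ± {cows['edmi_kg_day'].std(ddof=1):.2f}",
        })
    return pd.DataFrame(rows)


def render_report(
    variance_report: pd.DataFrame,
    diurnal: dict,
    correlations: dict,
    phenotypes: pd.DataFrame,
    levels: dict | None = None,
) -> str:
    """Plain-text summary: herd table, variance/repeatability table,
    between-year correlations, diurnal intervals, levels of variation."""
    lines: list[str] = []
    lines.append("bovigas pipeline report")
    lines.append("=" * 60)
    lines.append("")
    lines.append("Herd summary (cow-level means ± s.d. per year)")
    lines.append(_herd_summary(phenotypes).to_string(index=False))
    lines.append("")
    lines.append("Variance and repeatability per response")
    vr = variance_report.copy()
    for col in ("mean", "cv_bc", "cv_wc"):
        vr[col] = vr[col].map(lambda v: f"{v:.2f}")
    for col in ("r_within", "r_between_years"):
        vr[col] = vr[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "-")
    lines.append(vr.to_string(index=False))
    lines.append("")
    if correlations:
        lines.append("Between-year Pearson correlations of cow means")
        for label, c in correlations.items():
            lines.append(f"  {label:>15}: r = {c['r']:.2f} (P = {c['p']:.3g}, n = {c['n']})")
        lines.append("")
    for year, prof in (diurnal or {}).items():
        if prof is None or prof["intervals"].empty:
            lines.append(f"Diurnal profile year {year}: no hourly data")
            continue
        lines.append(f"Diurnal 6-h interval means (L/h), year {year}")
        tbl = prof["intervals"].copy()
        tbl["adjusted_mean"] = tbl["adjusted_mean"].map(lambda v: f"{v:.2f}")
        tbl["se"] = tbl["se"].map(lambda v: f"{v:.2f}")
        lines.append(tbl.to_string(index=False))
        lines.append("")
    if levels is not None:
        lines.append("Levels of variation (CV of pooled CH4:CO2 ratios, year 1)")
        tbl = levels["cv_by_level"].copy()
        tbl["cv_pct"] = tbl["cv_pct"].map(lambda v: f"{v:.1f}")
        lines.append(tbl.to_string(index=False))
        lines.append(f"  herd precision (2·CV_period/√n): {levels['precision_pct']:.1f}%")
        lines.append("")
    return "\n".join(lines) + "\n"


def _make_plots(phen: pd.DataFrame, diurnal: dict, out: Path) -> None:
    """Optional diagnostic figures (year-vs-year scatter, hourly profile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if phen["year"].nunique() >= 2:
        means = phen.groupby(["cow_id", "year"])["ch4_l_day"].mean().unstack()
        if means.shape[1] >= 2:
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(means.iloc[:, 0], means.iloc[:, 1], s=25)
            ax.set_xlabel("CH4 (L/day), year 1")
            ax.set_ylabel("CH4 (L/day), year 2")
            r = means.iloc[:, 0].corr(means.iloc[:, 1])
            ax.set_title(f"Cow means across years (r = {r:.2f})")
            fig.tight_layout()
            fig.savefig(out / "year_scatter.png", dpi=120)
            plt.close(fig)
    for year, prof in (diurnal or {}).items():
        if prof is None:
            continue
        tbl = prof["hourly"].dropna(subset=["adjusted_mean"])
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(tbl["hour"], tbl["adjusted_mean"], yerr=tbl["se"], fmt="o-")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("CH4 (L/h), adjusted")
        ax.set_title(f"Diurnal profile, year {year}")
        fig.tight_layout()
        fig.savefig(out / f"diurnal_y{year}.png", dpi=120)
        plt.close(fig)
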