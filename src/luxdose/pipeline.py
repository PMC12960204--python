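"""Orchestration: run the whole analysis from an input directory of text files.

Input layout (as emitted by :meth:`luxdose.cohort.SimulatedCohort.write`):

* ``sites.yaml`` — site registry (name, lat, lon, tz) and epoch_seconds;
* ``participants.csv`` — participant_id, site_id;
* ``light_<participant>.csv`` — the logger dialect (timestamp, mel_edi_lux,
  optional photopic_lux);
* ``leba.csv`` — one row per assessment, columns leba_q01..leba_q23;
* ``psqi.csv`` — one row per participant.

``run_pipeline`` executes clean -> solar -> metrics -> questionnaires ->
compliance -> stats and writes one delimited-text table per stage plus a
JSON run log with versions, seeds and exclusion counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compliance import (
    RecommendationSpec,
    build_compliance_windows,
    compliance_fractions,
    aggregate_compliance,
)
from .metrics import daily_metrics_table, participant_metrics
from .questionnaires import (
    LEBAResponse,
    PSQIResponse,
    derive_sleep_schedule,
    score_leba,
    score_psqi,
)
from .solar import GeoSite, civil_dawn_dusk
from .stats import (
    CorrelationTask,
    bootstrap_item_stability,
    circular_correlation,
    compare_site_correlations,
    spearman_fdr,
    window_average_metrics,
)
from .timeseries import (
    CleaningPolicy,
    apply_exclusions,
    read_logger_csv,
    regularize,
    split_valid_days,
)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_PAIRS", "load_sites"]

log = logging.getLogger(__name__)

# Default item/metric pair map: the outdoor, device, bedtime-light and
# morning-light items against the metrics they plausibly move, with the
# hypothesised sign. Overridable via PipelineConfig.pairs.
DEFAULT_PAIRS: list[CorrelationTask] = [
    CorrelationTask("leba_q04", "PAT1000", -1),
    CorrelationTask("leba_q07", "PAT1000", +1),
    CorrelationTask("leba_q07", "TAT1000", +1),
    CorrelationTask("leba_q08", "M10m", +1),
    CorrelationTask("leba_q08", "PAT1000", +1),
    CorrelationTask("leba_q08", "TAT1000", +1),
    CorrelationTask("leba_q08", "TAT250", +1),
    CorrelationTask("leba_q13", "LLiT250", +1),
    CorrelationTask("leba_q23", "FLiT250", -1),
    CorrelationTask("F2", "TAT1000", +1),
]


@dataclass
class PipelineConfig:
    """Everything a run needs beyond the input files; fully serialisable."""

    cleaning: CleaningPolicy = field(default_factory=CleaningPolicy)
    recommendations: RecommendationSpec = field(default_factory=RecommendationSpec)
    pairs: list[CorrelationTask] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    family_size: int | None = None  # None -> n_pairs x n_sites
    scheme_by_site: dict[str, str] = field(default_factory=dict)  # default 'windowed'
    n_boot: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "cleaning": vars(self.cleaning).copy(),
            "recommendations": vars(self.recommendations).copy(),
            "pairs": [vars(t).copy() for t in self.pairs],
            "family_size": self.family_size,
            "scheme_by_site": dict(self.scheme_by_site),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def load_sites(path: str | Path) -> tuple[dict[str, GeoSite], int]:
    """Read the site registry YAML; returns ({name: GeoSite}, epoch_seconds)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sites = {
        s["name"]: GeoSite(s["name"], float(s["lat"]), float(s["lon"]), s["tz"])
        for s in raw["sites"]
    }
    return sites, int(raw.get("epoch_seconds", 60))


def _read_leba(path: Path) -> list[LEBAResponse]:
    df = pd.read_csv(path, parse_dates=["assessment_date"])
    out = []
    for _, row in df.iterrows():
        items = tuple(int(row[f"leba_q{i:02d}"]) for i in range(1, 24))
        out.append(
            LEBAResponse(
                participant_id=str(row["participant_id"]),
                assessment_date=row["assessment_date"].date(),
                items=items,
            )
        )
    return out


def _read_psqi(path: Path) -> list[PSQIResponse]:
    df = pd.read_csv(path, parse_dates=["assessment_date"])
    out = []
    for _, row in df.iterrows():
        out.append(
            PSQIResponse(
                participant_id=str(row["participant_id"]),
                assessment_date=row["assessment_date"].date(),
                bedtime=float(row["bedtime"]),
                latency_min=float(row["latency_min"]),
                waketime=float(row["waketime"]),
                sleep_hours=float(row["sleep_hours"]),
                latency_problem=int(row["latency_problem"]),
                disturbances=tuple(int(v) for v in str(row["disturbances"]).split(";")),
                quality=int(row["quality"]),
                medication=int(row["medication"]),
                sleepiness=int(row["sleepiness"]),
                enthusiasm_problem=int(row["enthusiasm_problem"]),
            )
        )
    return out


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute every stage and write one table per output; returns them all."""
    config = config or PipelineConfig()
    indir = Path(input_dir)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites, epoch_s = load_sites(indir / "sites.yaml")
    roster = pd.read_csv(indir / "participants.csv", dtype=str)
    site_of = dict(zip(roster["participant_id"], roster["site_id"]))

    run_log: dict = {
        "luxdose_version": __version__,
        "config": config.to_dict(),
        "exclusions": {},
    }
    results: dict[str, pd.DataFrame] = {}

    # ---- questionnaires ----------------------------------------------------
    leba_responses = _read_leba(indir / "leba.csv")
    leba_rows = []
    for resp in leba_responses:
        scored = score_leba(resp)
        row = {"participant_id": resp.participant_id,
               "assessment_date": resp.assessment_date}
        row.update({f"leba_q{i:02d}": v for i, v in enumerate(resp.items, 1)})
        row.update(scored.as_dict())
        leba_rows.append(row)
    leba_df = pd.DataFrame(leba_rows)

    psqi_responses = _read_psqi(indir / "psqi.csv")
    psqi_rows, schedules = [], {}
    for resp in psqi_responses:
        scored = score_psqi(resp)
        schedule = derive_sleep_schedule(resp.bedtime, resp.latency_min, resp.waketime)
        schedules[resp.participant_id] = schedule
        psqi_rows.append(
            {"participant_id": resp.participant_id,
             "assessment_date": resp.assessment_date,
             **{f"C{i}": c for i, c in enumerate(scored.components, 1)},
             "global": scored.global_score, "poor_sleep": scored.poor_sleep,
             "sleep_onset": schedule.onset, "sleep_offset": schedule.offset,
             "sleep_duration": schedule.duration, "mid_sleep": schedule.mid_sleep}
        )
    psqi_df = pd.DataFrame(psqi_rows)

    # ---- clean -> solar -> metrics -> compliance, per participant ---------
    daily_frames, participant_rows, compliance_days = [], [], []
    solar_rows = []
    for pid, site_id in site_of.items():
        site = sites[site_id]
        path = indir / f"light_{pid}.csv"
        ts = read_logger_csv(path, site, epoch_s, participant_id=pid)
        ts = regularize(ts)
        ts = apply_exclusions(ts, config.cleaning)
        days = split_valid_days(ts, config.cleaning)
        run_log["exclusions"][pid] = {
            "n_epochs": len(ts.data),
            "n_missing": ts.n_missing,
            "n_days": len(days),
            "n_valid_days": int(sum(d.valid for d in days)),
        }
        solar_by_date = {
            d.local_date: civil_dawn_dusk(d.local_date, site) for d in days
        }
        for sd in solar_by_date.values():
            solar_rows.append(
                {"site_id": site_id, "date": sd.local_date,
                 "dawn": sd.civil_dawn, "dusk": sd.civil_dusk,
                 "photoperiod_h": sd.photoperiod_h, "centre": sd.centre}
            )
        table = daily_metrics_table(days, solar_by_date, pid)
        daily_frames.append(table)
        pm = participant_metrics(ts, days, solar_by_date)
        participant_rows.append(
            {"participant_id": pid, "site_id": site_id, **pm}
        )
        schedule = schedules.get(pid)
        if schedule is not None:
            for day in days:
                if not day.valid:
                    continue
                windows = build_compliance_windows(
                    schedule, day.local_date, site.tzinfo, config.recommendations
                )
                compliance_days.append(
                    compliance_fractions(
                        ts, windows, config.recommendations, pid, day.local_date
                    )
                )

    daily_df = pd.concat(daily_frames, ignore_index=True)
    participant_df = pd.DataFrame(participant_rows)
    solar_df = pd.DataFrame(solar_rows).drop_duplicates(["site_id", "date"])
    results["daily_metrics"] = daily_df
    results["participant_metrics"] = participant_df
    results["solar"] = solar_df
    results["leba_scores"] = leba_df
    results["psqi_scores"] = psqi_df

    per_part, per_site = aggregate_compliance(compliance_days, site_of)
    results["compliance_participants"] = per_part
    # Table-1 shape: site rows, percentage columns, 0 decimals
    table1 = per_site[["site_id", "day", "evening", "night", "overall"]].copy()
    for col in ("day", "evening", "night", "overall"):
        table1[col] = (table1[col] * 100).round(0).astype(int)
    results["compliance_sites"] = table1

    # ---- correlations ------------------------------------------------------
    leba_df = leba_df.copy()
    leba_df["site_id"] = leba_df["participant_id"].map(site_of)
    family = config.family_size or len(config.pairs) * leba_df["site_id"].nunique()
    site_results: dict[str, pd.DataFrame] = {}
    corr_frames = []
    for site_id, site_leba in leba_df.groupby("site_id"):
        scheme = config.scheme_by_site.get(site_id, "windowed")
        merged = window_average_metrics(
            daily_df[daily_df["participant_id"].isin(site_leba["participant_id"])],
            site_leba.drop(columns="site_id"),
            scheme=scheme,
        )
        res = spearman_fdr(config.pairs, merged, family_size=family)
        res.insert(0, "site_id", site_id)
        site_results[site_id] = res
        corr_frames.append(res)
    results["correlations"] = pd.concat(corr_frames, ignore_index=True)

    if len(site_results) == 2:
        (a, ra), (b, rb) = site_results.items()
        comp = compare_site_correlations(ra, rb)
        comp.insert(0, "site_a", a)
        comp.insert(1, "site_b", b)
        results["site_comparison"] = comp

    # chronotype vs mean light timing, circular, per site
    chrono_rows = []
    mid_sleep = psqi_df.drop_duplicates("participant_id").set_index(
        "participant_id"
    )["mid_sleep"]
    dd = daily_df.dropna(subset=["MLiT250"]).copy()
    dd["site_id"] = dd["participant_id"].map(site_of)
    dd["mid_sleep"] = dd["participant_id"].map(mid_sleep)
    for site_id, grp in dd.groupby("site_id"):
        if len(grp) >= 5:
            r, p = circular_correlation(
                grp["mid_sleep"].to_numpy(), grp["MLiT250"].to_numpy()
            )
            chrono_rows.append({"site_id": site_id, "r": r, "p": p, "n": len(grp)})
    results["chronotype_mlit"] = pd.DataFrame(chrono_rows)

    # ---- LEBA item stability (bootstrap) -----------------------------------
    item_cols = [f"leba_q{i:02d}" for i in range(1, 24)] + [
        "F1", "F2", "F3", "F4", "F5"
    ]
    stab = bootstrap_item_stability(
        leba_df[["participant_id", "assessment_date"] + item_cols],
        n_boot=config.n_boot,
        seed=np.random.SeedSequence(config.seed),
    )
    results["stability_items"] = stab.per_item
    results["stability_participants"] = stab.per_participant

    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)
    return results
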