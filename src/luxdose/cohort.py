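"""Seeded two-site synthetic cohort generator.

Emulates month-long chest-worn light-logger recordings plus questionnaire
answers for two contrasting sites: a Basel-like mid-latitude site (long
summer photoperiod, bright days, dim early evenings, earlier mid-sleep) and
a Kuala-Lumpur-like equatorial site (~12.7 h photoperiod, dimmer days,
brighter later evenings, later mid-sleep).

Each participant-day is a piecewise lognormal process:

* night level during the sleep episode;
* an indoor lognormal level during waking daytime hours;
* outdoor bouts (von Mises-timed, lognormal total duration) during which the
  level rises toward daylight magnitude scaled by a half-sine solar
  elevation proxy, capped at 10^5 lux;
* an evening level after dusk, decaying geometrically to the night level
  across a dim-lead window before sleep onset;
* a fixed-clock-time daily charging gap blanked to missing;
* a photopic channel equal to mel-EDI times a participant ratio with noise.

Questionnaire answers are drawn from ordered-categorical distributions whose
latent locations are monotone in the matching behavioural parameters; in
particular the outdoor-time items share a Gaussian-copula correlation with
the participant's outdoor propensity, tuned so that the population Spearman
correlation between the key outdoor item and time above 1000 lux is a
configurable target (default 0.6).

One global seed is split hierarchically (numpy SeedSequence.spawn) per
participant and per day, so regenerating any one participant is stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .questionnaires import LEBAResponse, PSQIResponse
from .solar import GeoSite, civil_dawn_dusk
from .timeseries import LightTimeseries, write_logger_csv

__all__ = [
    "BehaviourProfile",
    "SitePreset",
    "SimConfig",
    "GroundTruth",
    "SimulatedParticipant",
    "SimulatedCohort",
    "simulate_participant",
    "simulate_cohort",
    "BASEL_LIKE",
    "KL_LIKE",
]

# Ordinal cut points on the standardised latent scale -> answers 1..5.
_LIKERT_CUTS = np.array([-1.1, -0.4, 0.4, 1.1])

DAYLIGHT_CAP_LUX = 1e5


def _spearman_to_pearson_latent(rs: float) -> float:
    """Gaussian-copula latent correlation giving Spearman ``rs`` for
    bivariate-normal margins (rho = 2 sin(pi rs / 6)), inflated by 6% to
    offset the attenuation from cutting one margin into 5 ordinal levels."""
    return min(0.98, 2.0 * math.sin(math.pi * rs / 6.0) * 1.06)


@dataclass(frozen=True)
class BehaviourProfile:
    """One participant's behavioural ground truth."""

    participant_id: str
    site_id: str
    mid_sleep_h: float
    sleep_duration_h: float
    outdoor_bouts_per_day: float
    outdoor_total_min_median: float  # median total outdoor minutes per day
    outdoor_day_sigma: float  # day-to-day lognormal sigma (natural log)
    bout_timing_mu_h: float
    bout_timing_kappa: float
    indoor_day_median_lux: float
    indoor_log10_sigma: float
    evening_median_lux: float
    evening_log10_sigma: float
    dim_lead_h: float
    night_lux: float
    daylight_peak_lux: float
    mp_ratio: float
    charging_start_h: float
    charging_duration_h: float
    z_outdoor: float  # latent outdoor propensity (standard normal)
    z_evening: float  # latent evening brightness
    z_dim: float  # latent screen/ambient dimming habit
    z_morning: float  # latent morning light use
    answer_noise: float  # SD of per-assessment latent jitter

    @property
    def sleep_onset_h(self) -> float:
        return (self.mid_sleep_h - self.sleep_duration_h / 2.0) % 24.0

    @property
    def sleep_offset_h(self) -> float:
        return (self.mid_sleep_h + self.sleep_duration_h / 2.0) % 24.0


@dataclass(frozen=True)
class SitePreset:
    """Population-level parameters from which participant profiles are drawn."""

    site_id: str
    mid_sleep_mean_h: float
    mid_sleep_sd_h: float
    sleep_duration_mean_h: float
    sleep_duration_sd_h: float
    outdoor_bouts_per_day: float
    outdoor_total_min_median: float
    outdoor_between_sigma: float  # scales z_outdoor into total outdoor time
    outdoor_day_sigma: float
    bout_timing_mu_h: float
    bout_timing_kappa: float
    indoor_day_median_lux: float
    indoor_log10_sigma: float
    evening_median_lux: float
    evening_between_sigma: float
    evening_log10_sigma: float
    dim_lead_mean_h: float
    night_lux: float
    daylight_peak_lux: float
    mp_ratio_mean: float
    answer_noise: float = 0.35


# Two-site study conditions: a long-photoperiod mid-latitude site with bright
# days and dim, early-curfew evenings, and an equatorial site with dimmer
# days and brighter, later evenings.
BASEL_LIKE = SitePreset(
    site_id="CH",
    mid_sleep_mean_h=3.75,
    mid_sleep_sd_h=0.8,
    sleep_duration_mean_h=8.0,
    sleep_duration_sd_h=0.5,
    outdoor_bouts_per_day=3.0,
    outdoor_total_min_median=80.0,
    outdoor_between_sigma=0.6,
    outdoor_day_sigma=0.35,
    bout_timing_mu_h=13.0,
    bout_timing_kappa=1.5,
    indoor_day_median_lux=150.0,
    indoor_log10_sigma=0.25,
    evening_median_lux=4.0,
    evening_between_sigma=0.5,
    evening_log10_sigma=0.3,
    dim_lead_mean_h=1.5,
    night_lux=0.3,
    daylight_peak_lux=20_000.0,
    mp_ratio_mean=1.3,
)

KL_LIKE = SitePreset(
    site_id="MY",
    mid_sleep_mean_h=4.95,
    mid_sleep_sd_h=1.4,
    sleep_duration_mean_h=7.5,
    sleep_duration_sd_h=0.6,
    outdoor_bouts_per_day=2.0,
    outdoor_total_min_median=40.0,
    outdoor_between_sigma=0.6,
    outdoor_day_sigma=0.35,
    bout_timing_mu_h=12.5,
    bout_timing_kappa=1.5,
    indoor_day_median_lux=80.0,
    indoor_log10_sigma=0.25,
    evening_median_lux=18.0,
    evening_between_sigma=0.5,
    evening_log10_sigma=0.3,
    dim_lead_mean_h=0.3,
    night_lux=0.3,
    daylight_peak_lux=15_000.0,
    mp_ratio_mean=1.3,
)

BASEL_SITE = GeoSite("CH", 47.5585, 7.5839, "Europe/Zurich")
KL_SITE = GeoSite("MY", 3.0650, 101.6009, "Asia/Kuala_Lumpur")


@dataclass(frozen=True)
class SimConfig:
    """Full cohort recipe; the seed fixes every draw bit-for-bit."""

    sites: tuple[GeoSite, ...] = (BASEL_SITE, KL_SITE)
    presets: tuple[SitePreset, ...] = (BASEL_LIKE, KL_LIKE)
    n_per_site: tuple[int, ...] = (20, 19)
    date_ranges: tuple[tuple[Date, Date], ...] = (
        (Date(2023, 7, 3), Date(2023, 8, 1)),
        (Date(2023, 11, 6), Date(2023, 12, 5)),
    )
    epoch_s: int = 60
    seed: int = 0
    induced_outdoor_tat_r: float = 0.6
    assessment_interval_days: tuple[int, ...] = (3, 4)


@dataclass
class GroundTruth:
    """Everything needed to predict the metrics of a simulated participant."""

    profile: BehaviourProfile
    bout_schedule: dict  # date iso -> list of (start_h, end_h) outdoor bouts
    induced_outdoor_tat_r: float


@dataclass
class SimulatedParticipant:
    timeseries: LightTimeseries
    leba: list[LEBAResponse]
    psqi: PSQIResponse
    truth: GroundTruth


def _draw_profile(
    preset: SitePreset, pid: str, rng: np.random.Generator
) -> BehaviourProfile:
    z_outdoor, z_evening, z_dim, z_morning = rng.standard_normal(4)
    mid_sleep = rng.normal(preset.mid_sleep_mean_h, preset.mid_sleep_sd_h) % 24.0
    duration = float(np.clip(
        rng.normal(preset.sleep_duration_mean_h, preset.sleep_duration_sd_h), 5.0, 10.0
    ))
    return BehaviourProfile(
        participant_id=pid,
        site_id=preset.site_id,
        mid_sleep_h=float(mid_sleep),
        sleep_duration_h=duration,
        outdoor_bouts_per_day=preset.outdoor_bouts_per_day,
        outdoor_total_min_median=float(
            preset.outdoor_total_min_median
            * math.exp(preset.outdoor_between_sigma * z_outdoor)
        ),
        outdoor_day_sigma=preset.outdoor_day_sigma,
        bout_timing_mu_h=preset.bout_timing_mu_h,
        bout_timing_kappa=preset.bout_timing_kappa,
        indoor_day_median_lux=float(
            preset.indoor_day_median_lux * math.exp(0.3 * rng.standard_normal())
        ),
        indoor_log10_sigma=preset.indoor_log10_sigma,
        evening_median_lux=float(
            preset.evening_median_lux * math.exp(preset.evening_between_sigma * z_evening)
        ),
        evening_log10_sigma=preset.evening_log10_sigma,
        dim_lead_h=float(np.clip(
            preset.dim_lead_mean_h * math.exp(0.3 * z_dim), 0.05, 4.0
        )),
        night_lux=preset.night_lux,
        daylight_peak_lux=preset.daylight_peak_lux,
        mp_ratio=float(preset.mp_ratio_mean * math.exp(0.1 * rng.standard_normal())),
        charging_start_h=float(rng.uniform(20.0, 23.0)),
        charging_duration_h=1.0,
        z_outdoor=float(z_outdoor),
        z_evening=float(z_evening),
        z_dim=float(z_dim),
        z_morning=float(z_morning),
        answer_noise=preset.answer_noise,
    )


def _simulate_day_levels(
    profile: BehaviourProfile,
    clock_h: np.ndarray,
    dawn_h: float,
    dusk_h: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """mel-EDI levels for one local day (clock-hour grid), plus bout intervals."""
    n = clock_h.size
    onset = profile.sleep_onset_h
    offset = profile.sleep_offset_h

    asleep = ((clock_h - onset) % 24.0) < profile.sleep_duration_h
    into_dim = (onset - clock_h) % 24.0  # hours until sleep onset
    in_dim = (~asleep) & (into_dim <= profile.dim_lead_h)
    daytime = (clock_h >= dawn_h) & (clock_h < dusk_h)

    # baseline: indoor during daylight, evening level otherwise (awake, dark)
    levels = np.where(
        daytime,
        profile.indoor_day_median_lux
        * 10 ** rng.normal(0.0, profile.indoor_log10_sigma, n),
        profile.evening_median_lux
        * 10 ** rng.normal(0.0, profile.evening_log10_sigma, n),
    )

    # outdoor bouts: lognormal total duration split over a Poisson bout count,
    # centres drawn von Mises around the preferred clock time
    total_min = profile.outdoor_total_min_median * math.exp(
        rng.normal(0.0, profile.outdoor_day_sigma)
    )
    total_min = min(total_min, (dusk_h - dawn_h) * 60.0)
    n_bouts = max(1, int(rng.poisson(profile.outdoor_bouts_per_day)))
    shares = rng.dirichlet(np.ones(n_bouts))
    centres = (
        rng.vonmises(
            (profile.bout_timing_mu_h / 24.0) * 2 * np.pi - np.pi,
            profile.bout_timing_kappa,
            n_bouts,
        )
        + np.pi
    ) / (2 * np.pi) * 24.0
    sin_elev = np.clip(
        np.sin(np.pi * (clock_h - dawn_h) / max(dusk_h - dawn_h, 0.1)), 0.0, None
    )
    daylight = np.minimum(
        profile.daylight_peak_lux * sin_elev * 10 ** rng.normal(0.0, 0.2, n),
        DAYLIGHT_CAP_LUX,
    )
    bouts: list[tuple[float, float]] = []
    for share, centre in zip(shares, centres):
        half = share * total_min / 120.0  # minutes -> half-width hours
        lo, hi = centre - half, centre + half
        bouts.append((float(lo), float(hi)))
        mask = (clock_h >= lo) & (clock_h < hi)
        levels[mask] = np.maximum(levels[mask], daylight[mask])

    # dim lead: geometric decay from the evening level down to night level
    frac = np.clip(1.0 - into_dim / max(profile.dim_lead_h, 1e-6), 0.0, 1.0)
    dim_level = profile.evening_median_lux * (
        profile.night_lux / max(profile.evening_median_lux, 1e-9)
    ) ** frac
    levels = np.where(in_dim, dim_level * 10 ** rng.normal(0.0, 0.15, n), levels)

    # sleep: night level
    levels = np.where(
        asleep, profile.night_lux * 10 ** rng.normal(0.0, 0.1, n), levels
    )
    return levels, bouts


def _likert(latents: np.ndarray) -> np.ndarray:
    return 1 + np.searchsorted(_LIKERT_CUTS, latents).astype(int)


def _leba_items(
    profile: BehaviourProfile, rho_outdoor: float, rng: np.random.Generator
) -> tuple[int, ...]:
    """One assessment's 23 answers; latent locations monotone in behaviour."""
    noise = lambda: rng.normal(0.0, profile.answer_noise)  # noqa: E731
    resid = math.sqrt(max(1.0 - rho_outdoor**2, 1e-9))
    out_latent = lambda: rho_outdoor * profile.z_outdoor + resid * rng.standard_normal()  # noqa: E731
    items = np.zeros(23)
    # F1 (1-3): blue-light filter use -- independent of the light record
    items[0:3] = rng.standard_normal(3) * 0.8 - 0.5
    # F2 (4-9): outdoor time; item 4 is the reverse-worded "<=30 min outside"
    items[3] = -out_latent() + noise()
    for i in range(4, 9):
        items[i] = out_latent() + noise()
    # F3 (10-14): devices in bed -- brighter-evening participants score higher
    items[9:14] = 0.6 * profile.z_evening + rng.standard_normal(5) * 0.7
    # F4 (15-19): dimming/controlling light before bed -- tied to dim lead
    items[14:19] = 0.6 * profile.z_dim + rng.standard_normal(5) * 0.7
    # F5 (20-23): morning/daytime light use
    items[19:23] = 0.6 * profile.z_morning + rng.standard_normal(4) * 0.7
    return tuple(int(v) for v in _likert(items))


def _psqi_from_schedule(
    profile: BehaviourProfile, assessment_date: Date, rng: np.random.Generator
) -> PSQIResponse:
    """PSQI answers consistent with the participant's sleep schedule."""
    latency_min = float(rng.uniform(5.0, 30.0))
    onset = profile.sleep_onset_h
    bedtime = (onset - latency_min / 60.0) % 24.0
    sleep_hours = max(4.0, profile.sleep_duration_h - rng.uniform(0.0, 0.7))
    return PSQIResponse(
        participant_id=profile.participant_id,
        assessment_date=assessment_date,
        bedtime=bedtime,
        latency_min=latency_min,
        waketime=profile.sleep_offset_h,
        sleep_hours=float(sleep_hours),
        latency_problem=int(rng.integers(0, 2)),
        disturbances=tuple(int(v) for v in rng.integers(0, 2, 9)),
        quality=int(rng.integers(0, 2)),
        medication=0,
        sleepiness=int(rng.integers(0, 2)),
        enthusiasm_problem=int(rng.integers(0, 2)),
    )


def simulate_participant(
    profile: BehaviourProfile,
    site: GeoSite,
    dates: tuple[Date, Date],
    epoch_s: int,
    seed: np.random.SeedSequence | int,
    induced_outdoor_tat_r: float = 0.6,
    assessment_interval_days: tuple[int, ...] = (3, 4),
) -> SimulatedParticipant:
    """Simulate one participant's recording, questionnaires and ground truth."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    start, end = dates
    n_days = (end - start).days + 1
    day_seeds = ss.spawn(n_days + 2)
    rng_q = np.random.default_rng(day_seeds[-1])
    rng_p = np.random.default_rng(day_seeds[-2])
    tz = site.tzinfo
    rho = _spearman_to_pearson_latent(induced_outdoor_tat_r)

    frames = []
    bout_schedule: dict[str, list[tuple[float, float]]] = {}
    for k in range(n_days):
        d = start + timedelta(days=k)
        sd = civil_dawn_dusk(d, site)
        day_start = datetime.combine(d, time.min, tzinfo=tz)
        day_end = datetime.combine(d + timedelta(days=1), time.min, tzinfo=tz)
        idx = pd.date_range(day_start, day_end, freq=f"{epoch_s}s", inclusive="left")
        clock_h = (
            idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
            + idx.second.to_numpy() / 3600.0
        )
        rng = np.random.default_rng(day_seeds[k])
        dawn_h = sd.civil_dawn.hour + sd.civil_dawn.minute / 60 + sd.civil_dawn.second / 3600
        dusk_h = sd.civil_dusk.hour + sd.civil_dusk.minute / 60 + sd.civil_dusk.second / 3600
        mel, bouts = _simulate_day_levels(profile, clock_h, dawn_h, dusk_h, rng)
        bout_schedule[d.isoformat()] = bouts
        photopic = mel * profile.mp_ratio * 10 ** rng.normal(0.0, 0.05, mel.size)
        gap = (
            (clock_h >= profile.charging_start_h)
            & (clock_h < profile.charging_start_h + profile.charging_duration_h)
        )
        mel = np.where(gap, np.nan, mel)
        photopic = np.where(gap, np.nan, photopic)
        frames.append(pd.DataFrame({"mel_edi": mel, "photopic": photopic}, index=idx))

    data = pd.concat(frames)
    ts = LightTimeseries(
        participant_id=profile.participant_id,
        site_id=site.name,
        epoch_s=epoch_s,
        data=data,
    )

    leba: list[LEBAResponse] = []
    a_date = start
    i = 0
    while a_date <= end:
        if a_date > start:  # first questionnaire after the first interval
            leba.append(
                LEBAResponse(
                    participant_id=profile.participant_id,
                    assessment_date=a_date,
                    items=_leba_items(profile, rho, rng_q),
                )
            )
        a_date += timedelta(days=int(assessment_interval_days[i % len(assessment_interval_days)]))
        i += 1

    psqi = _psqi_from_schedule(profile, start, rng_p)
    truth = GroundTruth(
        profile=profile,
        bout_schedule=bout_schedule,
        induced_outdoor_tat_r=induced_outdoor_tat_r,
    )
    return SimulatedParticipant(timeseries=ts, leba=leba, psqi=psqi, truth=truth)


@dataclass
class SimulatedCohort:
    config: SimConfig
    participants: list[SimulatedParticipant] = field(default_factory=list)

    def site_of(self) -> dict[str, str]:
        return {p.timeseries.participant_id: p.timeseries.site_id
                for p in self.participants}

    def leba_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            for resp in p.leba:
                row = {"participant_id": resp.participant_id,
                       "assessment_date": resp.assessment_date}
                row.update({f"leba_q{i:02d}": v for i, v in enumerate(resp.items, 1)})
                rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Emit the cohort in the text formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        registry = []
        for site in self.config.sites:
            registry.append(
                {"name": site.name, "lat": site.latitude, "lon": site.longitude,
                 "tz": site.tz}
            )
        import yaml

        with open(outdir / "sites.yaml", "w") as fh:
            yaml.safe_dump({"sites": registry, "epoch_seconds": self.config.epoch_s}, fh)
        self.leba_table().to_csv(outdir / "leba.csv", index=False)
        psqi_rows = []
        for p in self.participants:
            row = asdict(p.psqi)
            row["disturbances"] = ";".join(str(v) for v in row["disturbances"])
            psqi_rows.append(row)
        pd.DataFrame(psqi_rows).to_csv(outdir / "psqi.csv", index=False)
        pd.DataFrame(
            [{"participant_id": pid, "site_id": sid}
             for pid, sid in self.site_of().items()]
        ).to_csv(outdir / "participants.csv", index=False)
        truths = {}
        for p in self.participants:
            write_logger_csv(
                p.timeseries, outdir / f"light_{p.timeseries.participant_id}.csv"
            )
            truths[p.timeseries.participant_id] = {
                "profile": asdict(p.truth.profile),
                "bout_schedule": p.truth.bout_schedule,
                "induced_outdoor_tat_r": p.truth.induced_outdoor_tat_r,
            }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truths, fh, indent=1)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate all participants at every configured site."""
    root = np.random.SeedSequence(config.seed)
    cohort = SimulatedCohort(config=config)
    site_seeds = root.spawn(len(config.sites))
    for site, preset, n, dates, sseed in zip(
        config.sites, config.presets, config.n_per_site, config.date_ranges, site_seeds
    ):
        part_seeds = sseed.spawn(max(n, 1) * 2)
        rng_profiles = np.random.default_rng(part_seeds[0])
        for j in range(n):
            pid = f"{site.name}{j + 1:02d}"
            profile = _draw_profile(preset, pid, rng_profiles)
            cohort.participants.append(
                simulate_participant(
                    profile,
                    site,
                    dates,
                    config.epoch_s,
                    part_seeds[j + 1],
                    induced_outdoor_tat_r=config.induced_outdoor_tat_r,
                    assessment_interval_days=config.assessment_interval_days,
                )
            )
    return cohort
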