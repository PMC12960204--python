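"""Correlation, stability and sensitivity procedures.

* assessment-window averaging of daily metrics before correlation (so one
  questionnaire answer meets one averaged metric value, never many);
* tie-corrected Spearman correlations with Benjamini-Hochberg step-up
  control of the false-discovery rate over an explicit family size;
* circular correlation (Jammalamadaka-SenGupta) for clock-time variables
  such as mid-sleep and mean light timing;
* Fisher r-to-z comparison of correlation coefficients between sites;
* bootstrap assessment of questionnaire item stability over repeated
  administrations (percentile CIs of the within-participant SD);
* the missing-data sensitivity analysis that selects the daily gap
  threshold under which chosen metrics remain within the original
  mean +/- 2 SE band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationTask",
    "window_average_metrics",
    "spearman_fdr",
    "bh_adjust",
    "circular_correlation",
    "compare_site_correlations",
    "bootstrap_item_stability",
    "missing_data_sensitivity",
]


@dataclass(frozen=True)
class CorrelationTask:
    """One questionnaire-item/metric pair to correlate, with expected sign."""

    item: str
    metric: str
    hypothesised_sign: int = 0  # +1, -1, or 0 (no prior)


def window_average_metrics(
    daily: pd.DataFrame,
    assessments: pd.DataFrame,
    scheme: str = "windowed",
) -> pd.DataFrame:
    """Average daily metrics into one row per questionnaire assessment.

    ``daily`` needs columns participant_id, local_date plus metric columns;
    ``assessments`` needs participant_id, assessment_date (plus any item
    columns, which are carried through).

    windowed scheme: each assessment's window is (previous assessment date,
    assessment date] within the participant -- the first assessment's window
    opens at the start of that participant's recording. whole-period scheme:
    one row per participant -- the final assessment paired with the grand
    mean over all valid days (used when the questionnaire's recall covers
    the entire collection).
    """
    if scheme not in ("windowed", "whole-period"):
        raise ValueError(f"unknown scheme {scheme!r}")
    metric_cols = [c for c in daily.columns if c not in ("participant_id", "local_date")]
    out_rows = []
    for pid, arows in assessments.groupby("participant_id"):
        arows = arows.sort_values("assessment_date")
        if scheme == "whole-period":
            arows = arows.tail(1)
        drows = daily[daily["participant_id"] == pid]
        prev = None
        for _, arow in arows.iterrows():
            a_date = arow["assessment_date"]
            if scheme == "whole-period":
                sel = drows
            else:
                sel = drows[drows["local_date"] <= a_date]
                if prev is not None:
                    sel = sel[sel["local_date"] > prev]
                prev = a_date
            rec = dict(arow)
            if sel.empty:
                rec.update({c: math.nan for c in metric_cols})
            else:
                rec.update(sel[metric_cols].mean().to_dict())
            out_rows.append(rec)
    return pd.DataFrame(out_rows)


def bh_adjust(pvalues: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` may exceed len(pvalues) when the tested pairs are a
    subset of a larger declared family; the missing tests are treated as
    having p = 1 (they can only make adjustment more conservative).
    """
    p = np.asarray(pvalues, dtype=float)
    m = family_size if family_size is not None else p.size
    if m < p.size:
        raise ValueError("family_size smaller than the number of p-values")
    padded = np.concatenate([p, np.ones(m - p.size)])
    adj = multipletests(padded, method="fdr_bh")[1][: p.size]
    return adj


def spearman_fdr(
    tasks: list[CorrelationTask],
    data: pd.DataFrame,
    family_size: int | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Tie-corrected Spearman rho per task, BH-adjusted over the family.

    ``data`` holds one row per observation unit with both item and metric
    columns. p-values come from the asymptotic t-approximation. Pairs with
    fewer than ``min_n`` complete observations, or zero variance in either
    variable, get NaN r and p = 1 for adjustment purposes.
    """
    rows = []
    for task in tasks:
        sub = data[[task.item, task.metric]].dropna()
        n = len(sub)
        if n < min_n or sub[task.item].nunique() < 2 or sub[task.metric].nunique() < 2:
            rows.append(
                {"item": task.item, "metric": task.metric,
                 "hypothesised_sign": task.hypothesised_sign,
                 "r": math.nan, "p": 1.0, "n": n}
            )
            continue
        r, p = sps.spearmanr(sub[task.item], sub[task.metric])
        rows.append(
            {"item": task.item, "metric": task.metric,
             "hypothesised_sign": task.hypothesised_sign,
             "r": float(r), "p": float(p), "n": n}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy(), family_size)
    return out


def circular_correlation(
    a_hours: np.ndarray, b_hours: np.ndarray, min_n: int = 5
) -> tuple[float, float]:
    """Jammalamadaka-SenGupta circular correlation of two clock-hour samples.

    Hours are mapped to angles by 2*pi/24. r = sum sin(a - abar) sin(b -
    bbar) / sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar)), invariant under
    rotation of either variable; the p-value uses the standard asymptotic
    normal approximation. Returns (NaN, NaN) for degenerate angular
    variance.
    """
    a = np.asarray(a_hours, dtype=float) * (2 * np.pi / 24.0)
    b = np.asarray(b_hours, dtype=float) * (2 * np.pi / 24.0)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    n = a.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {n}")
    abar = math.atan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = math.atan2(np.sin(b).sum(), np.cos(b).sum())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = math.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return (math.nan, math.nan)
    r = float(np.sum(sa * sb) / denom)
    l20 = np.mean(sa**2)
    l02 = np.mean(sb**2)
    l22 = np.mean(sa**2 * sb**2)
    if l22 == 0:
        return (r, math.nan)
    z = math.sqrt(n * l20 * l02 / l22) * r
    p = 2 * (1 - sps.norm.cdf(abs(z)))
    return (r, float(p))


def compare_site_correlations(
    results_a: pd.DataFrame, results_b: pd.DataFrame, family_size: int | None = None
) -> pd.DataFrame:
    """Two-sample Fisher r-to-z test per pair, BH-adjusted across pairs.

    Both inputs are spearman_fdr outputs over the same (item, metric) pair
    list, one per site. Pairs with n <= 3 in either site are skipped.
    z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with z_i = atanh(r_i).
    """
    merged = results_a.merge(
        results_b, on=["item", "metric"], suffixes=("_a", "_b")
    )
    rows = []
    for _, row in merged.iterrows():
        if row["n_a"] <= 3 or row["n_b"] <= 3 or math.isnan(row["r_a"]) or math.isnan(row["r_b"]):
            continue
        z1 = math.atanh(np.clip(row["r_a"], -0.999999, 0.999999))
        z2 = math.atanh(np.clip(row["r_b"], -0.999999, 0.999999))
        se = math.sqrt(1.0 / (row["n_a"] - 3) + 1.0 / (row["n_b"] - 3))
        z = (z1 - z2) / se
        p = 2 * (1 - sps.norm.cdf(abs(z)))
        rows.append(
            {"item": row["item"], "metric": row["metric"],
             "r_a": row["r_a"], "r_b": row["r_b"],
             "n_a": row["n_a"], "n_b": row["n_b"], "z": z, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy(), family_size)
    return out


@dataclass
class StabilityResult:
    """Bootstrap stability of questionnaire answers over repeated assessments."""

    per_participant: pd.DataFrame  # participant_id, item, sd, ci_lo, ci_hi, significant
    per_item: pd.DataFrame = field(init=False)  # item, prop_significant, stable

    def __post_init__(self) -> None:
        if self.per_participant.empty:
            self.per_item = pd.DataFrame(
                columns=["item", "prop_significant", "stable"]
            )
            return
        g = self.per_participant.groupby("item")["significant"].mean().reset_index()
        g = g.rename(columns={"significant": "prop_significant"})
        g["stable"] = g["prop_significant"] <= 0.5
        self.per_item = g


def bootstrap_item_stability(
    responses: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    min_assessments: int = 3,
) -> StabilityResult:
    """Does an item's answer vary over time within participants?

    ``responses`` has participant_id, assessment_date and one column per
    item. Per participant and item, assessments are resampled with
    replacement ``n_boot`` times; the 2.5/97.5 percentile CI of the
    resampled SD is formed and the variation is called significant when the
    CI excludes 0. An item is *stable* when at most half the participants
    show significant variation. Participants with fewer than
    ``min_assessments`` assessments are skipped.
    """
    rng = np.random.default_rng(seed)
    item_cols = [c for c in responses.columns
                 if c not in ("participant_id", "assessment_date")]
    rows = []
    for pid, grp in responses.groupby("participant_id"):
        values = grp.sort_values("assessment_date")[item_cols].to_numpy(dtype=float)
        k = values.shape[0]
        if k < min_assessments:
            continue
        picks = rng.integers(0, k, size=(n_boot, k))
        for j, item in enumerate(item_cols):
            samples = values[:, j][picks]  # (n_boot, k)
            sds = samples.std(axis=1, ddof=1)
            lo, hi = np.percentile(sds, [2.5, 97.5])
            rows.append(
                {"participant_id": pid, "item": item,
                 "sd": float(values[:, j].std(ddof=1)),
                 "ci_lo": float(lo), "ci_hi": float(hi),
                 "significant": bool(lo > 0)}
            )
    return StabilityResult(per_participant=pd.DataFrame(rows))


def default_sensitivity_metrics() -> dict:
    """The default metric set for the gap-sensitivity analysis.

    Day-level intradaily variability (hourly bins within the day), the last
    clock hour at-or-below 10 lx, and the photopic/melanopic ratio -- three
    metrics of different character (fragmentation, timing, spectral), so a
    gap threshold that leaves all three unbiased is a meaningful choice.
    Each function maps a DayRecord to a float (NaN when undefined).
    """

    def day_iv(day) -> float:
        binned = day.data["mel_edi"].resample("60min").mean()
        x = binned.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        n = int(ok.sum())
        if n < 2:
            return math.nan
        denom = np.nansum((x - np.nanmean(x)) ** 2)
        if denom == 0:
            return math.nan
        diffs = (x[1:] - x[:-1])[ok[1:] & ok[:-1]]
        if diffs.size == 0:
            return math.nan
        return float(n * np.sum(diffs**2) / ((n - 1) * denom))

    def last_below_10(day) -> float:
        mel = day.data["mel_edi"]
        mask = mel.le(10.0) & mel.notna()
        if not mask.any():
            return math.nan
        t = day.data.index[mask.to_numpy()][-1]
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def mp(day) -> float:
        if "photopic" not in day.data.columns:
            return math.nan
        paired = day.data[["mel_edi", "photopic"]].dropna()
        if paired.empty or paired["mel_edi"].mean() == 0:
            return math.nan
        return float(paired["photopic"].mean() / paired["mel_edi"].mean())

    return {"IV": day_iv, "LT10": last_below_10, "MPratio": mp}


def missing_data_sensitivity(
    days: list,
    metric_fns: dict,
    gap_grid_h: list[float],
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Select the largest tolerable daily gap by resampling injected gaps.

    ``days`` are complete (gap-free) DayRecords; ``metric_fns`` maps metric
    name -> function(DayRecord) -> float. Baseline: the metric per day, its
    mean and mean +/- 2 SE band. For each gap duration g, ``n_boot``
    resamples each pick a day at random, blank one contiguous block of
    length g placed uniformly within it, and recompute the metric; the
    resampled mean is compared with the band. The selected threshold is the
    largest g for which every metric stays within its band (rows carry a
    ``within_band`` flag; selection is left to the caller or the
    convenience column ``selected``).
    """
    import copy

    if any(g < 0 or g > 24 for g in gap_grid_h):
        raise ValueError("gap durations must lie within [0, 24] h")
    rng = np.random.default_rng(seed)
    baseline = {
        name: np.array([fn(d) for d in days], dtype=float)
        for name, fn in metric_fns.items()
    }
    bands = {}
    for name, vals in baseline.items():
        vals = vals[~np.isnan(vals)]
        mean = vals.mean()
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        bands[name] = (mean, mean - 2 * se, mean + 2 * se)

    rows = []
    for g in sorted(gap_grid_h):
        day_idx = rng.integers(0, len(days), size=n_boot)
        sums = {name: 0.0 for name in metric_fns}
        counts = {name: 0 for name in metric_fns}
        for i in day_idx:
            day = days[int(i)]
            n_epochs = len(day.data)
            gap_epochs = int(round(g * 3600 / day.epoch_s))
            mutated = day
            if gap_epochs > 0:
                start = int(rng.integers(0, max(1, n_epochs - gap_epochs + 1)))
                mutated = copy.copy(day)
                data = day.data.copy()
                data.iloc[start : start + gap_epochs,
                          data.columns.get_loc("mel_edi")] = np.nan
                mutated.data = data
            for name, fn in metric_fns.items():
                v = fn(mutated)
                if not math.isnan(v):
                    sums[name] += v
                    counts[name] += 1
        for name in metric_fns:
            mean, lo, hi = bands[name]
            resampled = sums[name] / counts[name] if counts[name] else math.nan
            # tolerance keeps zero-width bands (identical days) from failing
            # on float accumulation drift
            tol = 1e-9 * max(1.0, abs(mean))
            rows.append(
                {"metric": name, "gap_h": g, "resampled_mean": resampled,
                 "baseline_mean": mean, "band_lo": lo, "band_hi": hi,
                 "within_band": bool(lo - tol <= resampled <= hi + tol)
                 if not math.isnan(resampled) else False}
            )
    out = pd.DataFrame(rows)
    ok_by_gap = out.groupby("gap_h")["within_band"].all()
    passing = [g for g, ok in ok_by_gap.items() if ok]
    out.attrs["selected_threshold_h"] = max(passing) if passing else math.nan
    return out
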