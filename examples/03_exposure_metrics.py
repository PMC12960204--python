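"""The light-exposure metric battery for one simulated participant.

Per-day metrics (time/timing above thresholds, crossings, extreme windows)
with photoperiod correction, and the per-participant rhythm metrics IS, IV
and the photopic/melanopic ratio.
"""

from datetime import date

from luxdose.cohort import BASEL_SITE, SimConfig, simulate_cohort
from luxdose.metrics import daily_metrics_table, participant_metrics
from luxdose.solar import civil_dawn_dusk
from luxdose.timeseries import split_valid_days

cfg = SimConfig(n_per_site=(1, 0), seed=8,
                date_ranges=((date(2023, 7, 3), date(2023, 7, 12)),) * 2)
p = simulate_cohort(cfg).participants[0]
days = split_valid_days(p.timeseries)
solar = {d.local_date: civil_dawn_dusk(d.local_date, BASEL_SITE) for d in days}

table = daily_metrics_table(days, solar, "CH01")
cols = ["TAT250", "TAT1000", "TAT1000_ph", "MLiT250", "LLiT10", "FcT250", "PAT1000", "M10m"]
print(table[["local_date"] + cols].round(2).to_string(index=False))

pm = participant_metrics(p.timeseries, days, solar)
print(f"\nIS = {pm['IS']:.3f} (24-h regularity, 0..1; field data are typically <0.3)")
print(f"IV = {pm['IV']:.3f} (hour-to-hour fragmentation; ~2 for white noise)")
print(f"MPratio = {pm['MPratio']:.2f} (photopic vs melanopic content of the light diet)")
print("-> TAT1000_ph is seconds above 1000 lx per hour of civil photoperiod,")
print("   the photoperiod-corrected daylight-exposure dose.")
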