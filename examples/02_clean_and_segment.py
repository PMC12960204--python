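"""Cleaning a logger file: regularisation, exclusions, valid-day splitting.

Simulates one participant, writes the logger CSV, reads it back and applies
the cleaning rules: implicit gaps made explicit, photopic readings at the
130,000-lux device ceiling excluded, and days with more than 6 h missing
flagged invalid.
"""

import tempfile
from datetime import date
from pathlib import Path

from luxdose.cohort import BASEL_SITE, SimConfig, simulate_cohort
from luxdose.timeseries import CleaningPolicy, apply_exclusions, read_logger_csv, regularize, split_valid_days

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(n_per_site=(1, 0), seed=4,
                    date_ranges=((date(2023, 7, 3), date(2023, 7, 9)),) * 2)
    simulate_cohort(cfg).write(tmp)
    ts = read_logger_csv(Path(tmp) / "light_CH01.csv", BASEL_SITE, 60, "CH01")

ts = regularize(ts)
ts = apply_exclusions(ts, CleaningPolicy())
days = split_valid_days(ts)
print(f"{len(ts.data)} epochs, {ts.n_missing} missing "
      f"({ts.n_missing / len(ts.data):.1%}, the daily charging hour)")
for d in days:
    print(f"  {d.local_date}: missing {d.missing_fraction:.1%} -> "
          f"{'valid' if d.valid else 'EXCLUDED (>6 h missing)'}")
print("-> every day here has a single 1-h charging gap, well under the 6-h rule.")
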