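"""Relating self-reported light behaviour to measured exposure.

Runs the full pipeline on a simulated cohort: assessment-window averaging,
Spearman correlations with Benjamini-Hochberg adjustment, the between-site
Fisher r-to-z comparison, the circular chronotype/light-timing correlation,
and the bootstrap item-stability analysis.
"""

import tempfile
from datetime import date

from luxdose.cohort import SimConfig, simulate_cohort
from luxdose.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(
        n_per_site=(8, 8),
        date_ranges=(
            (date(2023, 7, 3), date(2023, 7, 23)),
            (date(2023, 11, 6), date(2023, 11, 26)),
        ),
        epoch_s=300,
        seed=6,
    )
    simulate_cohort(cfg).write(f"{tmp}/in")
    results = run_pipeline(
        f"{tmp}/in", f"{tmp}/out",
        PipelineConfig(n_boot=1000, seed=6,
                       scheme_by_site={"CH": "windowed", "MY": "whole-period"}),
    )

corr = results["correlations"]
sig = corr[corr["p_adj"] <= 0.05]
print(corr[["site_id", "item", "metric", "r", "p_adj", "n"]].round(3).to_string(index=False))
print(f"\n{len(sig)} of {len(corr)} pair tests BH-significant; the outdoor items")
print("(q04 reversed, q07, q08) track TAT1000/PAT1000 because the generator ties")
print("outdoor-time answers and bright-light exposure to one latent propensity.")

stab = results["stability_items"]
print(f"\nstable items: {int(stab['stable'].sum())}/{len(stab)} "
      "(bootstrap CI of the within-participant SD includes 0 for most items)")
print(results["chronotype_mlit"].round(3).to_string(index=False))
print("-> circular correlation of mid-sleep with mean light timing per site.")
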