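"""End-to-end cohort analysis: which motion metric detects ischemia best?

Simulates the default 11-subject cohort (each with baseline and ischemia
recordings; 4 subjects also get dobutamine with and without ischemia),
runs all three motion metrics (STAc, DYNc displacement; ROT rotation),
fits a random-intercept logistic model per metric and reports clustered
ROC statistics plus paired DeLong comparisons.

At the default between-subject variability every metric separates the
classes perfectly (all AUC 1.0); doubling the biological variability
(re_sd_scale=2.0) moves the problem off the ceiling and reveals the
ordering: rotation > static displacement > dynamic displacement.
"""

from cardimu.io import RunConfig
from cardimu.pipeline import run_pipeline

config = RunConfig(
    seed=0,
    out_dir="scratch/cohort_out",
    projections=["circumferential"],
    re_sd_scale=2.0,
)
bundle = run_pipeline(config, write=False)

roc = bundle["summary"]["roc"]["circumferential"]
print("method   AUC    sens@spec0.8")
for m in ("ROT", "STAc", "DYNc"):
    r = roc["per_method"][m]
    print(f"{m:6s} {r['auc']:6.3f}   {r['sensitivity_at_spec']:.3f}")

print("\npaired DeLong comparisons (z, p):")
for pair, d in roc["delong"].items():
    print(f"  {pair:14s} z = {d['z']:+6.2f}, p = {d['p']:.3g}")

work = bundle["work_table"]
med = work.groupby("intervention")["work"].median()
print("\nmedian regional work (mmHg%):")
for name, v in med.items():
    print(f"  {name:11s} {v:8.1f}")
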