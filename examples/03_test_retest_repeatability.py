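"""Test-retest repeatability on a simulated control cohort.

Ten sedentary control subjects are imaged twice; per-subject truth is drawn
from the population, each visit adds within-subject variation, and every
curve is pushed through the actual estimation pipeline.  The table reports
the between-subject coefficient of variation (CV = 100 * SD / |mean|) per
visit and a paired t-test across visits, per muscle and parameter.
"""

import muscleox as mx
from muscleox.pipeline import repeatability_frame

spec = mx.CohortSpec(
    group_sizes={"controls": 10},
    muscles=("gastrocnemius", "soleus"),
    noise_sd=1.0,
    seed=42,
)
records = mx.simulate_cohort(spec)
table = repeatability_frame(mx.repeatability_table(records))

pretty = table.copy()
for col in pretty.columns:
    if col.startswith("visit"):
        pretty[col] = pretty[col].round(1)
pretty["paired_p"] = pretty["paired_p"].round(3)
print(pretty.to_string(index=False))

print("\nCVs of 25-60 % are typical for these indices at n = 10: the")
print("between-subject spread is large relative to the mean.  Paired p-values")
print("well above 0.05 indicate no systematic visit-1 vs visit-2 shift, i.e.")
print("the measurement is repeatable.")
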