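"""Group comparison and the link between peak hyperemia and jump performance.

Simulates the full three-group study (two athlete groups trained at high
volume, plus sedentary controls), compares gastrocnemius PHV across groups
with one-way ANOVA + Tukey HSD, and correlates PHV with maximal vertical
jump pooled across subjects.
"""

import muscleox as mx

spec = mx.CohortSpec(muscles=("gastrocnemius",), seed=7)
records = mx.simulate_cohort(spec)

res = [r for r in mx.group_muscle_anova(records, "phv") if r.factor == "group"][0]
print("gastrocnemius PHV by group (visit 1):")
for name, cell in res.cells.items():
    print(f"  {name:15s} n={cell.n:2d}  {cell.mean:5.1f} +/- {cell.sd:4.1f} %")
print(f"one-way ANOVA: F = {res.anova_f:.2f}, p = {res.anova_p:.4g}")
if res.posthoc:
    for (a, b), p in res.posthoc.items():
        print(f"  Tukey {a} vs {b}: p = {p:.4g}")

corr = mx.jump_correlation(records, "gastrocnemius", "vertical")
print(f"\nPHV vs maximal vertical jump: r = {corr.r:.2f}, p = {corr.p:.3g}, n = {corr.n}")
print("\nA low control-group PHV with significant Tukey contrasts against both")
print("athlete groups reproduces the expected training effect; the positive r")
print("reflects both the within-group coupling and the athlete/control contrast.")
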