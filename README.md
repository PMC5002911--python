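# muscleox

Quantitative analysis of **skeletal muscle oxygenation dynamics** from
blood-oxygen-level-dependent (BOLD) MR imaging during a cuff occlusion /
reactive hyperemia paradigm.

BOLD signal intensity in muscle rises with microvascular oxyhemoglobin
content. Inflating a thigh cuff above systolic pressure produces transient
ischemia (signal falls); rapid deflation produces reactive hyperemia
(signal overshoots, then returns to baseline). The shape of this response,
resolved per calf muscle, is a noninvasive probe of microvascular function —
useful to exercise physiologists comparing trained and untrained subjects,
and to imaging groups validating oximetric biomarkers for peripheral
vascular disease.

`muscleox` is a library (plus a thin `muscleox` CLI) that implements the
full analysis chain for such studies:

- **I/O** — 4-D BOLD NIfTI series and coregistered integer label masks
  marking muscle volumes of interest (gastrocnemius, soleus, anterior
  tibialis, peroneus longus).
- **Time courses** — per-VOI mean signal `SI(t)`, normalized to percent
  change from resting baseline:
  `pct(t) = 100 · (SI(t) − SI_base) / SI_base`.
- **Dynamic indices** — per VOI:
  - `MIV` (minimum ischemic value, %): lowest short-window average during
    occlusion;
  - `PHV` (peak hyperemic value, %): highest short-window (default 3 s)
    average after cuff deflation;
  - `TTP` (time to peak, s): deflation → peak;
  - `TTR` (time to recovery, s): deflation → first return of the unsmoothed
    signal to baseline (linearly interpolated; flagged unrecovered if it
    never returns).
- **Cohort statistics** — test-retest repeatability (per-visit mean ± SD,
  CV = 100·SD/|mean|, paired t-test), one-way ANOVA across groups and
  muscles with D'Agostino–Pearson normality checks and Tukey HSD post hocs,
  and Pearson correlation of PHV with maximal vertical/broad jump.
- **Synthetic data** — a ground-truthed generative model (piecewise
  exponential-plus-half-cosine response curves), a 4-D digital calf phantom
  with the study's acquisition geometry (128×64 matrix, 6 slices, 300
  frames at TR = 3 s), and a study-shaped cohort simulator, so every stage
  is testable without scanner data.

## Worked example

```python
import muscleox as mx

spec = mx.PhantomSpec(shape=(64, 32, 3), seed=1)   # noise-free phantom
series, mask, truth = mx.simulate_phantom(spec)

raw = mx.extract_voi_timecourse(series, mask, "soleus")
ntc = mx.percent_change_normalize(raw, spec.timing)
idx = mx.compute_indices(ntc, spec.timing)
print(idx)
```

```
BoldIndices(phv=12.89, ttp=22.5, miv=-12.31, ttr=136.5, recovered=True, muscle='soleus')
```

The phantom's soleus was generated with PHV 12.9 %, TTP 21 s, MIV −12.4 %,
TTR 134.1 s. The estimates land within one frame (3 s) for the two times
and within 0.1 % for the two amplitudes: times can only be located to the
TR grid, and the sampled curve is read slightly off-peak. The
`examples/` directory holds four short scripts, one per capability
(phantom + extraction, index recovery, test-retest repeatability, group
comparison + jump correlation); each prints its numbers with a line on what
they mean.

From the shell, the same pipeline is:

```bash
muscleox simulate phantom --out-dir ph/
muscleox indices --series ph/bold.nii.gz --mask ph/labels.nii.gz \
         --legend ph/legend.json --out-dir ph/out/
```

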