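"""Recover the four dynamic BOLD indices from a noise-free phantom.

PHV (peak hyperemic value) and MIV (minimum ischemic value) are short-window
extrema of the percent-change signal; TTP and TTR are the times from cuff
deflation to the peak and to the return to baseline.  On a noise-free
phantom the estimates should land within one frame (3 s) of the generative
truth, which is what this script demonstrates.
"""

import muscleox as mx

spec = mx.PhantomSpec(shape=(64, 32, 3), seed=1)
series, mask, truth = mx.simulate_phantom(spec)
timing = spec.timing

print(f"{'muscle':18s} {'PHV est/true (%)':>18s} {'TTP est/true (s)':>18s} "
      f"{'MIV est/true (%)':>18s} {'TTR est/true (s)':>18s}")
for row in truth.itertuples():
    raw = mx.extract_voi_timecourse(series, mask, row.muscle)
    ntc = mx.percent_change_normalize(raw, timing)
    idx = mx.compute_indices(ntc, timing)
    print(f"{row.muscle:18s} {idx.phv:8.2f}/{row.phv_true:<6.1f} "
          f"{idx.ttp:8.1f}/{row.ttp_true:<6.1f} "
          f"{idx.miv:8.2f}/{row.miv_true:<6.1f} "
          f"{idx.ttr:8.1f}/{row.ttr_true:<6.1f}")

print("\nTimes differ from truth by at most one TR (3 s): the peak and the")
print("baseline crossing can only be located to the frame grid.  Amplitudes")
print("differ by < 0.1 % because the curve is sampled slightly off-peak.")
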