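"""Simulate a full detection-threshold study and recover the thresholds.

A cohort of 51 synthetic observers (latent psychometric functions in log10
concentration) runs the adaptive 3-AFC staircase on the twelve-level
ladder.  Each trial log is collapsed into per-level tallies, levels are
classified against the 1-in-3 guessing rate (exact binomial tail,
alpha = 0.05), and the detection threshold is the geometric mean of the
lowest true-positive and the highest incorrect concentration below it.
"""

import numpy as np

from fattaste import (
    CohortSpec,
    assign_groups,
    simulate_threshold_study,
    study2_series,
    threshold_from_log,
)

series = study2_series()
spec = CohortSpec(n_observers=51, series=series, sigma=0.25, lapse=0.01)
logs, truth = simulate_threshold_study(spec, rng=7)

results = [threshold_from_log(log, series) for log in logs]
grouping = assign_groups(results, series)

print("participant  latent mu   estimate (mM)  censored  group")
for res, mu in list(zip(results, truth["mu"]))[:8]:
    print(
        f"{res.participant_id:>11}  {10**mu:9.3f}   {res.threshold_mM:12.3f}  "
        f"{res.censored:>8}  {grouping.labels[res.participant_id]}"
    )

uncensored = [r for r in results if r.censored == "none"]
errors = [
    abs(np.log10(r.threshold_mM) - mu)
    for r, mu in zip(results, truth["mu"])
    if r.censored == "none"
]
counts = {g: sum(v == g for v in grouping.labels.values()) for g in ("high", "medium", "low")}
print(f"\nuncensored estimates: {len(uncensored)}/51")
print(f"median |log10 error|: {np.median(errors):.3f} (one ladder step = {series.log_step})")
print(f"sensitivity groups: {counts}")
print(
    "\nThe median error below 0.25 log units means the staircase typically "
    "pins the latent threshold to within one ladder step."
)
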