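"""Score sleep/wake and compute nightly sleep parameters.

Applies the weighted-moving-window threshold scorer to raw counts inside a
nightly in-bed interval (23:00-07:00 here) and derives TST, WASO, SE, SOL and
average wake bout length, averaged over nights per subject.
"""

from actirar import SimConfig, generate_cohort
from actirar.pipeline import nominal_rest_intervals, sleep_metrics_by_subject

cohort = generate_cohort(SimConfig(rng_seed=42))
subjects = cohort.subjects[:5]
intervals = nominal_rest_intervals(subjects, lights_out_hour=23.0, rise_hour=7.0)
by_subject = sleep_metrics_by_subject(subjects, intervals, threshold=40.0)

print(f"{'subject':<10}{'TST(min)':>10}{'WASO':>8}{'SE(%)':>8}{'SOL':>7}"
      f"{'wake bout':>11}")
for sid, p in by_subject.items():
    print(f"{sid:<10}{p.TST:>10.1f}{p.WASO:>8.1f}{p.SE:>8.1f}{p.SOL:>7.1f}"
          f"{p.avg_wake_bout:>11.2f}")
print("\nTST = minutes asleep after onset; WASO = wake after sleep onset; "
      "SE = % of the in-bed interval asleep; SOL = minutes from lights-out "
      "to onset.")
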