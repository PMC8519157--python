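"""Function-on-scalar regression: where in the day do the groups differ?

Regresses each subject's mean 24-h profile on group status (adjusting for
age, sex, education), then reports the clock-time windows where the
pointwise and the stricter simultaneous 95% bands exclude zero, and the
permutation global F-test.
"""

import numpy as np

from actirar import (
    SimConfig,
    build_design,
    fit_fosr,
    generate_cohort,
    global_f_test,
    pointwise_band,
    preprocess_subject,
    significant_windows,
    simultaneous_band,
    subject_rar,
)

cohort = generate_cohort(SimConfig(rng_seed=42))
matrices = [preprocess_subject(s) for s in cohort.subjects]
rars = [subject_rar(m) for m in matrices if not m.excluded_from_rar]

design = build_design(rars, cohort.covariates, outcome="mean", n_basis=8)
fit = fit_fosr(design)
print(f"fitted {len(rars)} subjects x {len(design.grid)} bins, "
      f"smoothing lambda {fit.lambda_:.3g}, effective df {fit.edf:.1f}")

j = design.column("abeta")
t_max = design.grid[int(np.argmax(fit.coef[j]))]
print(f"group effect beta(t): max {fit.coef[j].max():+.3f} log units at "
      f"{t_max:.2f} h, min {fit.coef[j].min():+.3f}")

for kind, band in [
    ("pointwise", pointwise_band(fit, "abeta", alpha=0.05)),
    ("simultaneous", simultaneous_band(fit, "abeta", alpha=0.05,
                                       n_sim=10_000, seed=1)),
]:
    windows = significant_windows(band, design.grid, 30)
    txt = ", ".join(str(w) for w in windows) or "none"
    print(f"{kind:>13} 95% band excludes zero: {txt}")

F, p = global_f_test(design, "abeta", fit=fit, n_perm=1999, seed=2)
print(f"global permutation F-test: F = {F:.2f}, p = {p:.4f}")
print("\nWindows marked (+) are clock times where the positive group is more "
      "active; (-) less. The injected effects sit near 01:15 (-), 06:30 (+) "
      "and 15:00 (+).")
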