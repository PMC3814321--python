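"""Asynchronous culture time course and effective-p calibration.

Simulates unsynchronized fibroblast-like growth (17 h doubling time) with
Cre active from time zero, then fits the effective per-division activation
probability back from the simulated 24 h / 48 h labeled fractions.
"""

import pandas as pd

from tloxtrace import (
    DivisionSchedule,
    ModelParams,
    fit_effective_p_timeseries,
    simulate_culture,
)

schedule = DivisionSchedule(doubling_time=17.0, duration=48.0, cre_start=0.0)
params = ModelParams(c=0.75, variant="exact", seed=42)
ts = simulate_culture(schedule, params, n_initial=20_000, seed=42)

sampled = ts[ts.time_h.isin([0.0, 24.0, 48.0])]
print("Culture time course (c = 0.75, exact model):")
print(sampled.to_string(index=False))

observed = sampled[sampled.time_h > 0].rename(columns={"n_cells": "n_total"})
fit = fit_effective_p_timeseries(
    observed[["time_h", "n_labeled", "n_total"]], doubling_time=17.0
)
print(f"\nEffective per-division activation probability fitted from the "
      f"time course:\n  p_eff = {fit.p_hat:.3f} "
      f"(95% CI {fit.ci_low:.3f}-{fit.ci_high:.3f})")
print("p_eff < 0.25 means labeling under-reports true proliferation — the")
print("observed fraction is a lower bound on divisions undergone.")
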