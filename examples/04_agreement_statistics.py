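"""Repeatability, reproducibility and accuracy of per-section counts.

Simulates repeated blinded counts of the same sections, computes
Bland-Altman limits of agreement (bias ± 1.96·SD of the paired
differences), correlates one method's counts against the consensus
reference, and compares linear models explaining the count differences
(analysis time turns out to drive them, as constructed).
"""

import numpy as np
import pandas as pd

import cordquant as cq

rng = np.random.default_rng(8)
n_sections = 30

# repeated counts: shared true value + per-pass noise that grows with
# the time the analysis takes
# sections range from heavily injured to control-like
true_counts = np.round(rng.uniform(30, 450, n_sections))
time_min = rng.uniform(2, 60, n_sections)
noise_sd = 5.0 + 0.8 * time_min
count_1 = true_counts + rng.normal(0, noise_sd)
count_2 = true_counts + rng.normal(0, noise_sd)

ba = cq.bland_altman(count_1, count_2)
print("repeatability (two blinded passes):")
print(f"  bias {ba.bias:+.2f} neurons, limits of agreement "
      f"[{ba.loa_low:.1f}, {ba.loa_high:.1f}], n={ba.n}")

# accuracy: noisy estimates against the consensus reference
reference = true_counts
estimates = true_counts + rng.normal(0, 20.0, n_sections)
r, p = cq.accuracy_correlation(estimates, reference)
print(f"\naccuracy vs consensus reference: Pearson r = {r:.3f} (p = {p:.2g})")

# which factors explain the disagreement between repeated counts?
data = pd.DataFrame(
    {
        "abs_diff": np.abs(count_1 - count_2),
        "mean_count": (count_1 + count_2) / 2,
        "time_min": time_min,
        "condition": rng.choice(["control", "injury"], n_sections),
    }
)
models = cq.repeatability_model(
    data, "abs_diff",
    [["mean_count"], ["time_min"], ["condition"], ["time_min", "mean_count"]],
)
print("\ncandidate models for |count difference| (sorted by adjusted R^2):")
print(models.table[["formula", "adj_r2"]].to_string(index=False))
print(f"best model: {models.best}")
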