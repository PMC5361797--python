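"""Method comparison on a synthetic cohort: pipeline fat mass vs a noisy
EchoMRI-like reference readout, mirroring an 8-animal validation design."""

from dataclasses import replace

from fishfat import cohort_validation, make_cohort
from fishfat.phantom import (
    DEFAULT_COHORT_MASS_RANGE,
    build_truth_volumes,
    default_spec,
    sigma_for_peak_snr,
)

base = default_spec()
fat, water, _ = build_truth_volumes(base)
base = replace(base, sigma=sigma_for_peak_snr(base, 20.0, fat, water))

cohort = make_cohort(8, DEFAULT_COHORT_MASS_RANGE, base, seed=1, reference_cv=0.02)
pairs, report = cohort_validation(cohort)

print("fish  pipeline (mg)  reference (mg)")
for i, (a, b) in enumerate(zip(pairs.a, pairs.b)):
    print(f"{i:4d}  {a:13.1f}  {b:14.1f}")
print(f"\nR^2 = {report.r_squared:.4f} (p = {report.p_value:.2e}), "
      f"slope = {report.slope:.3f}, intercept = {report.intercept:.1f} mg")
print(f"mean relative difference = {100 * report.mean_relative_difference:+.1f}%")
print("A tight linear relation (R^2 near 1) shows the image-based fat mass "
      "tracks the reference across a >5-fold range of adiposity.")
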