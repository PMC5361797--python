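"""Simulate a noisy CHESS fat/water acquisition of the default obese-fish
phantom and quantify its body fat with the full pipeline."""

from dataclasses import replace

from fishfat import (
    build_truth_volumes,
    default_spec,
    quantify_pair,
    sigma_for_peak_snr,
    simulate_chess_pair,
)

spec = default_spec(seed=42)
fat, water, truth = build_truth_volumes(spec)
noisy = replace(spec, sigma=sigma_for_peak_snr(spec, 20.0, fat, water))
fat_stack, water_stack = simulate_chess_pair(fat, water, noisy)

result = quantify_pair(fat_stack, water_stack)

print(f"ground truth : {truth.fat_volume_mm3:8.2f} mm^3  {truth.fat_mass_mg:7.2f} mg")
print(f"pipeline     : {result.fat_volume_mm3:8.2f} mm^3  {result.fat_mass_mg:7.2f} mg")
print(f"noise sigma  : fat {result.noise['fat'].sigma:.2f}, "
      f"water {result.noise['water'].sigma:.2f} (true {noisy.sigma:.2f})")
err = 100 * (result.fat_mass_mg / truth.fat_mass_mg - 1)
print(f"relative error {err:+.1f}% — the residual Rician noise floor over the "
      "water-only agarose biases the estimate slightly high at this SNR.")
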