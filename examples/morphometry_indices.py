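"""Body condition indices and adipocyte morphometry for a small mock
cohort of control, normal-fat-overfed and high-fat-overfed fish."""

import numpy as np

from fishfat import (
    AdipocyteFieldOfView,
    FishRecord,
    adipocyte_summary,
)
from fishfat.morphometry import fish_table

records = [
    FishRecord("c1", "control", weight_g=0.42, length_cm=2.9, fat_mass_mg=45),
    FishRecord("n1", "NFD-OF", weight_g=0.81, length_cm=3.2, fat_mass_mg=210),
    FishRecord("h1", "HFD-OF", weight_g=0.72, length_cm=3.1, fat_mass_mg=195),
]
print(fish_table(records).to_string(index=False))

# two histology fields of view with square mock adipocyte outlines
rng = np.random.default_rng(0)
square = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
fovs = [
    AdipocyteFieldOfView(
        "visceral", pixel_size_um=2.5,
        outlines=[square * rng.uniform(8, 20) for _ in range(5)],
    ),
    AdipocyteFieldOfView(
        "subcutaneous", pixel_size_um=2.5,
        outlines=[square * rng.uniform(5, 12) for _ in range(7)],
    ),
]
for depot, s in adipocyte_summary(fovs).items():
    print(f"{depot}: {s.total_count} adipocytes, "
          f"mean area {s.mean_area_um2:.0f} um^2, "
          f"median {s.median_area_um2:.0f} um^2")
print("Larger mean adipocyte area at similar counts indicates hypertrophic "
      "(rather than hyperplastic) fat expansion.")
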