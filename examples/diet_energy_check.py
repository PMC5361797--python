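"""Atwater energy content of the three daily rations (control maintenance,
normal-fat overfeeding, high-fat overfeeding)."""

from fishfat import diet_energy
from fishfat.morphometry import default_diets

for group, components in default_diets().items():
    kcal = diet_energy(components)
    parts = " + ".join(f"{c.daily_amount_mg:.0f} mg {c.name}" for c in components)
    print(f"{group:8s} {parts:35s} -> {kcal:.4f} kcal/day")

diets = default_diets()
nfd, hfd = diet_energy(diets["NFD-OF"]), diet_energy(diets["HFD-OF"])
print(f"\nNFD-OF vs HFD-OF energy ratio with 9/4/4 kcal/g factors: "
      f"{nfd / hfd:.3f}")
print("With standard Atwater factors the two overfeeding rations differ by "
      f"{100 * (nfd / hfd - 1):.0f}% in energy, so their 'isocaloric' design "
      "must rest on different energy coefficients.")
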