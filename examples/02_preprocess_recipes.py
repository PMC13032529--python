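"""Apply the packaged preprocessing recipes.

Each modality/analysis pair has a fixed, named recipe (truncation,
baseline handling, Savitzky-Golay differentiation, normalisation or
(E)MSC). Recipes are immutable and serialise to plain text so a run can
record exactly what was applied.
"""

from specflux.axes import FT_RAMAN, HTS_FTIR
from specflux.preprocess import RECIPES, apply_recipe, get_recipe
from specflux.synthetic import Design, medium, simulate_design_dataset

print("packaged recipes:")
for name, rec in RECIPES.items():
    steps = " -> ".join(s for s, _ in rec.step_list())
    print(f"  {name:20s} {steps}")

design = Design(media=(medium("nGlu"), medium("iGlu")),
                timepoints=(24.0, 60.0), replicates=3,
                modalities=(HTS_FTIR, FT_RAMAN))
datasets = simulate_design_dataset(design, seed=2)

ftir = apply_recipe(datasets[HTS_FTIR], "htsftir_bandratio")
print(f"\nhtsftir_bandratio output: {ftir.intensities.shape}, "
      f"derivative order {ftir.derivative_order}, "
      f"{ftir.wavenumbers[0]:.0f}-{ftir.wavenumbers[-1]:.0f} cm^-1")

raman = apply_recipe(datasets[FT_RAMAN], "ftraman_mva")
print(f"ftraman_mva output:       {raman.intensities.shape}, "
      f"derivative order {raman.derivative_order}")

print("\nrecipe as text (what a run log records):")
print(get_recipe("htsftir_bandratio").to_text())
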