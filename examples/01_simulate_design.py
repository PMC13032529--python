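"""Simulate the full bulk experimental design.

Seven glucose/glycerol media (glucose either ¹²C or ¹³C) x six harvest
times x three technical replicates, measured by HTS-FTIR and FT-Raman.
The generator returns one dataset per modality, with the ground-truth
biomass composition attached for validation work.
"""

from specflux import default_axis
from specflux.axes import FT_RAMAN, HTS_FTIR
from specflux.synthetic import default_design, simulate_design_dataset

design = default_design()
print(f"media:               {[m.name for m in design.media]}")
print(f"timepoints (h):      {list(design.timepoints)}")
print(f"biological samples:  {design.n_samples}")
print(f"spectra/modality:    {design.n_spectra_per_modality}")

datasets = simulate_design_dataset(design, seed=1)

for modality in (HTS_FTIR, FT_RAMAN):
    ds = datasets[modality]
    axis = default_axis(modality)
    print(f"\n{modality}: {ds.intensities.shape[0]} spectra x "
          f"{ds.intensities.shape[1]} wavenumbers "
          f"({axis.range_hi:.0f}-{axis.range_lo:.0f} cm^-1, "
          f"step {axis.spacing:.3f})")
    print(ds.meta.head(3).to_string(index=False))

truth = datasets[HTS_FTIR].truth
print("\nGround-truth composition (first rows):")
cols = ["medium", "timepoint_h", "w_TAG", "f13_TAG", "w_polyphosphate"]
print(truth[cols].head(6).round(3).to_string(index=False))
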