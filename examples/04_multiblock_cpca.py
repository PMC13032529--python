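"""Consensus PCA across the two bulk modalities.

Technical replicates are averaged so HTS-FTIR and FT-Raman blocks line
up sample-to-sample; each mean-centred block is Frobenius-scaled and the
concatenated super-matrix decomposed by SVD. Global scores summarise the
consensus sample structure; per-block explained variances show how much
each technique contributes; correlation loadings identify the bands that
drive each component.
"""

import numpy as np

from specflux.axes import FT_RAMAN, HTS_FTIR
from specflux.chemometrics import correlation_loadings, cpca_fit
from specflux.preprocess import apply_recipe
from specflux.synthetic import Design, medium, simulate_design_dataset

design = Design(
    media=tuple(medium(m) for m in ("nGlu", "iGlu", "nGlu1:Gly7", "Gly")),
    timepoints=(8.0, 24.0, 60.0, 120.0), replicates=3,
    modalities=(HTS_FTIR, FT_RAMAN))
datasets = simulate_design_dataset(design, seed=4)

blocks = {}
for modality, recipe in ((HTS_FTIR, "htsftir_mva"), (FT_RAMAN, "ftraman_mva")):
    pre = apply_recipe(datasets[modality], recipe)
    blocks[modality] = pre.average_replicates().intensities
    print(f"{modality}: block shape {blocks[modality].shape}")

model = cpca_fit(blocks, ncomp=4)
print("\nglobal explained variance (%):",
      np.round(model.pct_variance_global, 1))
for name in model.block_names:
    print(f"  {name:8s} per-block (%):",
          np.round(model.pct_variance_per_block[name], 1))

corr = correlation_loadings(model, blocks)
strong = np.sum(np.abs(corr.r[:, 0]) > np.sqrt(0.5))
print(f"\nvariables with >50% variance explained by PC1: {strong} "
      f"of {corr.r.shape[0]}")
print("global scores of the first samples:")
print(np.round(model.global_scores[:4, :2], 3))
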