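"""Generate a radiomics-like synthetic dataset and inspect its structure.

Builds a high-dimensional matrix (more features than samples) with
correlated feature blocks, a planted signal, and sparse missing values,
then verifies the planted properties empirically.
"""

import numpy as np

from cvleak import DatasetSpec, generate_dataset

spec = DatasetSpec(
    n_samples=150,
    n_features=600,          # samples per feature = 0.25: high-dimensional
    prevalence=0.35,
    n_informative=10,
    effect_size=0.8,
    block_size=20,
    within_block_correlation=0.8,
    missing_rate=0.005,
    seed=42,
)
ds = generate_dataset(spec)

print(f"dataset: {ds.n_samples} samples x {ds.n_features} features")
print(f"samples per feature: {ds.samples_per_feature:.3f}")
print(f"positive fraction: {ds.outcome.mean():.3f} (target {spec.prevalence})")
print(f"missing cells: {np.isnan(ds.features).sum()} "
      f"({np.isnan(ds.features).mean():.4%} of the matrix)")

block = ds.features[:, 20:40]
block = block[~np.isnan(block).any(axis=1)]
corr = np.corrcoef(block, rowvar=False)
print(f"mean within-block correlation: {corr[np.triu_indices(20, 1)].mean():.3f} "
      f"(target {spec.within_block_correlation})")

# The first 10 columns carry the signal: their class-conditional means differ.
pos = ds.outcome == 1
shift = np.nanmean(ds.features[pos, :10], axis=0) - np.nanmean(
    ds.features[~pos, :10], axis=0
)
print(f"mean shift of informative features: {shift.mean():.3f} "
      f"(target {spec.effect_size})")
print("Interpretation: the generator reproduces the dimensionality, "
      "redundancy, prevalence and sparse missingness of radiomics tables.")
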