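"""Generate a synthetic three-origin NIR dataset and inspect its structure.

Builds 130 abdomen spectra per origin class (Weishan/Tuo/Hongze lakes) on
a coarsened acquisition grid, then shows where the class information
lives: the between-class mean differences are confined to the two
planted discriminative bands (10,000-9500 and 9000-8500 cm^-1).
"""

import numpy as np

from crabspec import SyntheticConfig, WavenumberGrid, generate_dataset, write_spectra_csv

grid = WavenumberGrid(10_000, 3_800, 20)  # 311 points
config = SyntheticConfig(grid=grid, site="abdomen", seed=1)
dataset = generate_dataset(config)

print(f"dataset: {dataset.n_samples} samples x {len(dataset.grid)} wavelengths")
classes, counts = np.unique(dataset.labels, return_counts=True)
print(f"classes: {dict(zip(map(str, classes), map(int, counts)))}")

bands = np.concatenate([grid.band_indices(10_000, 9_500), grid.band_indices(9_000, 8_500)])
outside = np.setdiff1d(np.arange(len(grid)), bands)
means = {c: dataset.absorbance[dataset.labels == c].mean(axis=0) for c in ("WL", "TL", "HL")}
gap_in = max(np.abs(means[a] - means[b])[bands].max() for a in means for b in means if a < b)
gap_out = max(np.abs(means[a] - means[b])[outside].max() for a in means for b in means if a < b)
print(f"largest class-mean gap inside the planted bands:  {gap_in:.4f} AU")
print(f"largest class-mean gap outside the planted bands: {gap_out:.4f} AU")
print("-> origin information is concentrated in the two planted bands;")
print("   outside them the gap is consistent with averaged instrument noise.")

write_spectra_csv(dataset, "scratch_example_spectra.csv")
print("wrote scratch_example_spectra.csv (wavenumber header + one row per sample)")
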