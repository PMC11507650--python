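"""Wavelength selection: CARS and UVE recover the planted bands.

Both selectors score wavelengths through PLS regression coefficients on
integer class codes and keep the set with the lowest cross-validated
RMSE.  On data whose origin signal is planted in 10,000-9500 and
9000-8500 cm^-1, the selected sets concentrate there.
"""

import numpy as np

from crabspec import (
    SyntheticConfig,
    WavenumberGrid,
    band_enrichment_pvalue,
    cars_select,
    encode_labels,
    fit_msc_reference,
    generate_dataset,
    msc,
    spxy_split,
    uve_select,
)

grid = WavenumberGrid(10_000, 3_800, 20)
ds = generate_dataset(SyntheticConfig(grid=grid, seed=1))
part = spxy_split(ds.absorbance, ds.labels, 310)
reference = fit_msc_reference(ds.absorbance[part.train_idx])
X = msc(ds.absorbance, reference)[part.train_idx]
y = encode_labels(ds.labels[part.train_idx], ("WL", "TL", "HL"))

bands = np.concatenate([grid.band_indices(10_000, 9_500), grid.band_indices(9_000, 8_500)])
print(f"{len(bands)} of {len(grid)} grid points lie in the planted bands "
      f"({100 * len(bands) / len(grid):.1f}% uniform null)")

for name, result in (
    ("CARS", cars_select(X, y, n_runs=100, folds=5, seed=1)),
    ("UVE", uve_select(X, y, folds=5, seed=1)),
):
    frac = 100 * np.isin(result.selected_idx, bands).mean()
    pval = band_enrichment_pvalue(result.selected_idx, bands, len(grid))
    print(f"{name}: kept {result.selected_idx.size} wavelengths, "
          f"{frac:.0f}% in the planted bands (hypergeometric p = {pval:.1e})")
print("-> both selected sets are enriched in the planted bands far beyond chance.")
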