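"""Dataset-size ablation: fewer crabs per origin, weaker models.

Subsamples the 390-sample study down to 300 and 240 samples (100 and 80
per origin), reruns the MSC -> CARS -> SVM pipeline on each and compares
test accuracies.
"""

from crabspec import PipelineConfig, SyntheticConfig, WavenumberGrid, ablate_dataset_size

grid = WavenumberGrid(10_000, 3_800, 20)
config = PipelineConfig(
    synthetic=SyntheticConfig(grid=grid, seed=1),
    pretreatment="msc",
    selection="cars",
    model="svm",
    seed=1,
)

results = ablate_dataset_size(config, sizes=[130, 100, 80])
for per_class, res in results.items():
    total = 3 * per_class
    print(f"dataset-{total} ({per_class}/origin): "
          f"test accuracy {100 * res.report.acc:.2f}% "
          f"on {res.report.n_total} held-out samples")
print("-> a single seed is noisy; averaged over seeds the accuracy shrinks")
print("   with the dataset (see tests and scripts/acceptance.py).")
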