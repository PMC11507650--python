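"""End-to-end origin classification: MSC -> CARS -> SVM.

Runs the best-performing configuration of the factorial design and
prints the one-vs-rest evaluation of the 80 held-out test samples.
"""

import json

from crabspec import PipelineConfig, SyntheticConfig, WavenumberGrid, run_pipeline

grid = WavenumberGrid(10_000, 3_800, 20)
config = PipelineConfig(
    synthetic=SyntheticConfig(grid=grid, site="abdomen", seed=1),
    pretreatment="msc",
    selection="cars",
    model="svm",  # C=1.0, gamma=0.5, RBF kernel by default
    seed=1,
)
result = run_pipeline(config)

report = result.report.to_dict()
print(f"selected wavelengths: {result.selection.selected_idx.size} "
      f"(best CARS iteration {result.selection.best_iteration})")
print(f"test accuracy: {report['acc']:.2f}%")
print(f"{'class':>8} {'n':>4} {'P%':>7} {'R%':>7} {'F1%':>7}")
for cls in report["classes"]:
    print(f"{cls['label']:>8} {cls['n']:>4} {cls['P']:>7.2f} {cls['R']:>7.2f} {cls['F1']:>7.2f}")
print("confusion matrix (rows true WL/TL/HL, cols predicted):")
print(json.dumps(report["confusion"]))
print("-> with an 80-sample test set the accuracy fluctuates a few points")
print("   around the generator's 95% ideal ceiling (about 92% when averaged")
print("   over seeds); each F1 is the harmonic mean of its P and R.")
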