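"""End-to-end run: synthetic dataset -> features -> nested-CV linear SVM.

Generates a small two-class texture dataset (classes differ in spatial
correlation scale), extracts the 140-feature combined descriptor from every
volume, and evaluates with nested 10-fold cross-validation: inner folds
pick the number of FDR-ranked features, outer folds estimate performance.
Runs in about a minute; for the full desk-scale setting (32^3, 30 per
class) drop the dims/n_per_class/max_k overrides.
"""

import tempfile

from voxtex.pipeline import RunConfig, run_full_pipeline
from voxtex.synthdata import SynthParams, generate_dataset

params = SynthParams(seed=5, dims=(16, 16, 16), n_per_class=12,
                     smoothing_lengths=(1.0, 2.5))
with tempfile.TemporaryDirectory() as tmp:
    _, manifest = generate_dataset(params, tmp)
    report = run_full_pipeline(manifest, RunConfig(seed=5, max_k=20))

print(f"outer folds: {len(report.per_fold)}  (positive class: {report.positive_label})")
print(f"accuracy    {report.acc_mean:.4f} +/- {report.acc_sd:.4f}")
print(f"sensitivity {report.sens_mean:.4f} +/- {report.sens_sd:.4f}")
print(f"specificity {report.spec_mean:.4f} +/- {report.spec_sd:.4f}")
print(f"features kept (mean +/- SD over folds): "
      f"{report.n_features_mean:.1f} +/- {report.n_features_sd:.1f}")
print("\nHigh accuracy with only a handful of the 140 features means the")
print("texture contrast between the classes is concentrated in a few riu bins.")
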