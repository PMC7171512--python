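"""Quality-gated tissue classification (normal vs cancer).

Trains an L1-feature-selected linear SVM on SNV spectra with
patient-grouped five-fold cross-validation, once on all spectra and once
keeping only spectra above the calibrated QF threshold.
"""

import tempfile
import warnings

from sklearn.exceptions import ConvergenceWarning

from ramanqf import (
    SimConfig,
    generate_dataset,
    process_dataset,
    roc_quality,
    train_gated_classifier,
)

warnings.filterwarnings("ignore", category=ConvergenceWarning)

with tempfile.TemporaryDirectory() as td:
    generate_dataset(SimConfig(seed=3), td)
    dataset = process_dataset(td)

gate = roc_quality(dataset.records).optimal_threshold
ungated = train_gated_classifier(dataset, qf_gate=0.0, seed=0)
gated = train_gated_classifier(dataset, qf_gate=gate, seed=0)

print(f"calibrated gate: QF > {gate:.0f}")
print(f"{'':14s}{'QF > 0':>10s}{'QF > gate':>12s}")
print(f"{'n used':14s}{ungated.n_used:>10d}{gated.n_used:>12d}")
for metric in ("accuracy", "sensitivity", "specificity"):
    print(f"{metric:14s}{getattr(ungated, metric):>10.1%}{getattr(gated, metric):>12.1%}"
          f"   (fold std {ungated.fold_std(metric):.3f} -> {gated.fold_std(metric):.3f})")
print()
print("Restricting training and evaluation to high-QF spectra removes the")
print("noise-dominated measurements that dilute and destabilize the model:")
print("accuracy rises and the across-fold variability shrinks.")
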