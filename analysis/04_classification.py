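#!/usr/bin/env python
"""Sliding-window classification under repeated stratified cross-validation.

For each stored subject x paradigm epoch set: 31 window anchors, mean +
slope features, shrinkage LDA and linear SVM, chromophore sets HbR / HbO /
HbR+HbO (meta-fusion), 10 x 5-fold CV with shared splits.  Writes per-fold
accuracies and per-trial predictions and prints each subject's maximum
accuracy in the 5-25 s range.
"""
import argparse
from pathlib import Path

from nirsbci.config import PipelineConfig
from nirsbci.evaluate import accuracy_curve, max_accuracy
from nirsbci.io import read_epochs_dir
from nirsbci.pipeline import classify_subject, cv_seed

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "cohort_config.yaml")
for edir in sorted((args.out / "preprocess").iterdir()):
    sid, paradigm = edir.name.rsplit("_", 1)
    epochs = read_epochs_dir(edir)
    res = classify_subject(
        epochs, cfg, seed=cv_seed(cfg.seed, int(sid[1:]) - 1, paradigm)
    )
    cdir = args.out / "classify" / edir.name
    cdir.mkdir(parents=True, exist_ok=True)
    res.accuracies.to_csv(cdir / "accuracies.csv", index=False)
    res.predictions.to_csv(cdir / "predictions.csv", index=False)
    for clf in cfg.cv.classifiers:
        for cs in cfg.cv.chromo_sets:
            best, at = max_accuracy(accuracy_curve(res, clf, cs))
            print(f"{sid} {paradigm} {clf} {cs}: max {best:.1f}% at {at:g} s")
print(f"CV results under {args.out / 'classify'}")
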