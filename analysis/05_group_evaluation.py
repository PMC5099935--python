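#!/usr/bin/env python
"""Group-level evaluation of the stored cross-validation results.

Per-subject maximum accuracies (5-25 s), grand-average accuracy curves,
the eyes-open vs eyes-closed paired t-test, the LDA-vs-SVM comparison in
the 9-13 s peak window, and the mutual information between the two
classifiers' outputs regressed against accuracy.
"""
import argparse
from pathlib import Path

import pandas as pd

from nirsbci.classify import CVResult, CVScheme
from nirsbci.config import PipelineConfig
from nirsbci.evaluate import (
    classifier_agreement_mi,
    compare_classifiers,
    paired_test,
    regress_accuracy_on_mi,
    window_mean_accuracy,
)
from nirsbci.pipeline import evaluate_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.out / "cohort_config.yaml")
cv_results = {}
for cdir in sorted((args.out / "classify").iterdir()):
    sid, paradigm = cdir.name.rsplit("_", 1)
    cv_results[(sid, paradigm)] = CVResult(
        accuracies=pd.read_csv(cdir / "accuracies.csv"),
        predictions=pd.read_csv(cdir / "predictions.csv"),
        scheme=CVScheme(seed=cfg.seed),
    )

summary = evaluate_cohort(cv_results, cfg, out=args.out)
print(summary.to_string(index=False))

# EO vs EC on per-subject maxima (meta-fused LDA)
sel = summary[(summary.classifier == "lda") & (summary.chromophores == "both")]
eo = sel[sel.paradigm == "EO"].set_index("subject")["max_accuracy_pct"]
ec = sel[sel.paradigm == "EC"].set_index("subject")["max_accuracy_pct"]
common = eo.index.intersection(ec.index)
if len(common) >= 2:
    t = paired_test(eo[common], ec[common], kind="t")
    print(f"\nEO vs EC (LDA, HbR+HbO): mean {eo[common].mean():.1f} vs "
          f"{ec[common].mean():.1f}%, paired t p = {t.p:.4f}")

# MI between LDA and SVM outputs vs accuracy (9-13 s)
mi_rows = []
for (sid, paradigm), res in cv_results.items():
    mi = classifier_agreement_mi(res, "hbr", (9.0, 13.0))
    acc = window_mean_accuracy(res, "lda", "hbr", (9.0, 13.0))
    mi_rows.append((sid, paradigm, mi, acc))
mi_df = pd.DataFrame(mi_rows, columns=["subject", "paradigm", "mi_bits", "acc_pct"])
if mi_df.mi_bits.nunique() > 1:
    slope, intercept = regress_accuracy_on_mi(mi_df.mi_bits, mi_df.acc_pct)
    print(f"accuracy vs classifier-agreement MI: slope {slope:.1f} %/bit, "
          f"intercept {intercept:.1f}%")
print(f"\nsummaries under {args.out}")
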