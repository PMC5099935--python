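#!/usr/bin/env python
"""Point-biserial separability maps over channels x time.

Reads the stored epochs, computes r / p / Bonferroni-adjusted signed
log10(p) per channel and time sample and per canonical 5 s task period,
writes tidy CSVs, and reports where separability peaks.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nirsbci.io import read_epochs_dir
from nirsbci.statmaps import period_map, rvalue_map

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

rows, period_rows = [], []
for edir in sorted((args.out / "preprocess").iterdir()):
    sid, paradigm = edir.name.rsplit("_", 1)
    epochs = read_epochs_dir(edir)
    for chromo in ("hbr", "hbo"):
        smap = rvalue_map(epochs, chromo)
        logp = smap.signed_logp
        for c, ch in enumerate(smap.channel_names):
            for i, t in enumerate(smap.times):
                rows.append((sid, paradigm, chromo, ch, t, smap.r[c, i],
                             smap.p_adj[c, i], logp[c, i]))
        post = (smap.times >= 5) & (smap.times <= 20)
        peak_c = int(np.argmax(np.abs(smap.r[:, post]).max(axis=1)))
        print(f"{sid} {paradigm} {chromo}: max |r| at {smap.channel_names[peak_c]} "
              f"(|r| = {np.abs(smap.r[peak_c, post]).max():.2f})")
        pmap = period_map(epochs, chromo, periods=[(0, 5), (5, 10), (10, 15)])
        for c, ch in enumerate(pmap.channel_names):
            for j, mid in enumerate(pmap.times):
                period_rows.append((sid, paradigm, chromo, ch, mid,
                                    pmap.r[c, j], pmap.signed_logp[c, j]))

pd.DataFrame(rows, columns=["subject", "paradigm", "chromophore", "channel",
                            "time_s", "r", "p_adj", "signed_logp"]
             ).to_csv(args.out / "separability_maps.csv", index=False)
pd.DataFrame(period_rows, columns=["subject", "paradigm", "chromophore", "channel",
                                   "period_mid_s", "r", "signed_logp"]
             ).to_csv(args.out / "separability_periods.csv", index=False)
print(f"maps under {args.out}")
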