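#!/usr/bin/env python
"""Abundance correlation screening and the community-environment Mantel test.

log10(x+1)-transformed Pearson correlations per functional-group pair with
Bonferroni correction, classified into positive / negative / strong
(r > 0.7) pairs; then a one-sided permutation Mantel test between Bray-Curtis
community distances and Euclidean distances on z-scored environment."""

import sys
from pathlib import Path

import pandas as pd

import fgniche as fg
from fgniche.core_data import read_env, read_fg_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/data")
OUT = Path("results")

rows = []
for name in ("stable_reservoir", "disturbed_reservoir", "independent"):
    stem = f"{name}_seed{SEED}"
    tab = read_fg_table(DATA / f"{stem}_abundance.csv")
    env = read_env(DATA / f"{stem}_env.csv")
    cm = fg.pearson_pairs(fg.log_transform(tab))
    cm["r"].to_csv(OUT / f"05_correlation_r_{name}.csv")
    counts = fg.classify_pairs(cm["r"], cm["p_adj"])
    res = fg.mantel(fg.bray_curtis(tab), fg.env_distance(env), n_perm=999, seed=SEED)
    rows.append({"scenario": name, **counts, "mantel_r": res.r, "mantel_p": res.p})
    print(
        f"{name}: {counts['positive']} positive / {counts['negative']} negative "
        f"correlations, {counts['strong_positive']} strong (r > 0.7); "
        f"Mantel r = {res.r:.3f}, p = {res.p:.3f}"
    )

pd.DataFrame(rows).to_csv(OUT / "05_correlation_mantel_summary.csv", index=False)
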