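#!/usr/bin/env python
"""Dominance screening of the generated scenarios.

Computes the Y index (relative abundance × occurrence frequency, dominant at
Y > 0.02) per functional group and the biomass-share rule (dominant when the
share of total biomass strictly exceeds 5%)."""

import sys
from pathlib import Path

import fgniche as fg
from fgniche.core_data import read_fg_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/data")
OUT = Path("results")

for name in ("stable_reservoir", "disturbed_reservoir", "independent"):
    stem = f"{name}_seed{SEED}"
    tab = read_fg_table(DATA / f"{stem}_abundance.csv", DATA / f"{stem}_biomass.csv")
    rec = fg.dominance_index(tab)
    rec.to_csv(OUT / f"02_dominance_index_{name}.csv")
    shares = fg.dominant_fgs(tab, metric="biomass")
    shares.to_csv(OUT / f"02_fg_shares_{name}.csv", index=False)
    dom_y = rec.index[rec["dominant"]].tolist()
    dom_share = shares.loc[shares["dominant"].fillna(False).astype(bool), "fg"].tolist()
    print(f"{name}: dominant by Y>{0.02}: {dom_y}; by biomass share>5%: {dom_share}")
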