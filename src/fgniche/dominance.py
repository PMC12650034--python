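"""Dominance screening: the Y index for taxa and the >5%-share rule for FGs.

Y_i = (n_i / N) · f_i, where n_i is the summed density of unit i over all
sites, N the grand total over all units, and f_i the fraction of sites where
the unit occurs.  A unit with Y > 0.02 is dominant.  At the functional-group
level a group is dominant within a scope when its share of the scope's total
(abundance or biomass) strictly exceeds 5%.
"""

from __future__ import annotations

import pandas as pd

from .core_data import AbundanceTable, FGTable, ValidationError

Y_THRESHOLD = 0.02
SHARE_THRESHOLD_PCT = 5.0


def dominance_index(tab: AbundanceTable, threshold: float = Y_THRESHOLD) -> pd.DataFrame:
    """One DominanceRecord row per unit: n_i, f_i, Y and a dominant verdict.

    Occurrence frequency f_i counts sites with strictly positive density.
    Raises on an all-zero table (the grand total is then undefined).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    totals = tab.values.sum(axis=0)
    grand = float(totals.sum())
    if grand == 0:
        raise ValidationError("all-zero table: dominance index undefined (N = 0)")
    freq = (tab.values > 0).mean(axis=0)
    y = totals / grand * freq
    return pd.DataFrame(
        {
            "unit": tab.units,
            "n_i": totals.to_numpy(),
            "f_i": freq.to_numpy(),
            "Y": y.to_numpy(),
            "dominant": (y > threshold).to_numpy(),
        }
    ).set_index("unit")


def dominant_fgs(
    tab: FGTable,
    threshold_pct: float = SHARE_THRESHOLD_PCT,
    metric: str = "biomass",
    scope: str = "pooled",
) -> pd.DataFrame:
    """Per-scope FG shares (%) and the strict >threshold dominance verdict.

    ``scope`` is ``"pooled"`` (all sites together) or ``"per-reservoir"``.
    A scope with zero total is flagged (``share`` NaN, no verdict) rather
    than judged.
    """
    layer = tab.layer(metric)
    if scope == "pooled":
        groups = {"all": layer}
    elif scope == "per-reservoir":
        groups = {
            res: layer.loc[idx.index]
            for res, idx in tab.meta.groupby("reservoir", sort=True, observed=True)
        }
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rows = []
    for name, sub in groups.items():
        totals = sub.sum(axis=0)
        grand = float(totals.sum())
        for fg in sub.columns:
            if grand == 0:
                rows.append({"scope": name, "fg": fg, "share_pct": float("nan"),
                             "dominant": pd.NA})
            else:
                share = 100.0 * totals[fg] / grand
                rows.append({"scope": name, "fg": fg, "share_pct": share,
                             "dominant": bool(share > threshold_pct)})
    return pd.DataFrame(rows)
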