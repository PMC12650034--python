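"""Levins niche breadth and pairwise niche overlap of functional groups.

Each group's site-use profile p_ij (its density at quadrat j divided by its
total over the scope) gives a breadth B_i = 1/Σ_j p_ij² between 1 (single
quadrat) and r (uniform over all r quadrats).  The default overlap is the
proportional-similarity (Schoener) form O_ik = 1 − ½ Σ_j |p_ij − p_kj|; the
product-moment Pianka form is available as a comparator since the two are
frequently conflated in the plankton literature.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .core_data import FGTable

logger = logging.getLogger(__name__)

OVERLAP_CUTOFF = 0.7
_NORM_TOL = 1e-9


def niche_proportions(tab: FGTable, layer: str = "abundance") -> pd.DataFrame:
    """FG × site matrix of proportional site use; zero-total FGs are dropped.

    Rows sum to 1.  Dropped groups are reported via a logged notice and the
    ``attrs['excluded']`` list on the result.
    """
    mat = tab.layer(layer)
    totals = mat.sum(axis=0)
    excluded = totals.index[totals == 0].tolist()
    if excluded:
        logger.info("excluding zero-total functional groups from niche profiles: %s", excluded)
    kept = totals.index[totals > 0]
    props = (mat[kept] / totals[kept]).T  # FG rows, site columns
    props.attrs["excluded"] = excluded
    return props


def levins_breadth(p: np.ndarray) -> float:
    """Levins B = 1/Σp² for one proportion vector (must sum to 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError("levins_breadth expects a non-negative vector summing to 1")
    return 1.0 / float(np.sum(p * p))


def breadth_table(props: pd.DataFrame) -> pd.DataFrame:
    """Levins breadth per FG row of a proportions matrix."""
    r = props.shape[1]
    return pd.DataFrame(
        {"B": [levins_breadth(props.loc[fg].to_numpy()) for fg in props.index], "r": r},
        index=props.index.rename("fg"),
    )


def overlap_printed(p_i: np.ndarray, p_k: np.ndarray) -> float:
    """Proportional-similarity overlap 1 − ½ Σ|p_ij − p_kj| ∈ [0, 1]."""
    p_i, p_k = np.asarray(p_i, float), np.asarray(p_k, float)
    if p_i.shape != p_k.shape:
        raise ValueError("proportion vectors cover different quadrat sets")
    return 1.0 - 0.5 * float(np.abs(p_i - p_k).sum())


def overlap_pianka(p_i: np.ndarray, p_k: np.ndarray) -> float:
    """Pianka product-moment overlap Σp_i p_k / √(Σp_i² Σp_k²) ∈ [0, 1]."""
    p_i, p_k = np.asarray(p_i, float), np.asarray(p_k, float)
    if p_i.shape != p_k.shape:
        raise ValueError("proportion vectors cover different quadrat sets")
    denom = np.sqrt(np.sum(p_i**2) * np.sum(p_k**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(p_i * p_k) / denom)


def overlap_matrix(props: pd.DataFrame, method: str = "printed") -> pd.DataFrame:
    """Symmetric FG × FG overlap matrix with unit diagonal."""
    fn = {"printed": overlap_printed, "pianka": overlap_pianka}.get(method)
    if fn is None:
        raise ValueError(f"unknown overlap method {method!r}")
    fgs = props.index
    out = pd.DataFrame(np.eye(len(fgs)), index=fgs, columns=fgs)
    for i, k in itertools.combinations(fgs, 2):
        o = fn(props.loc[i].to_numpy(), props.loc[k].to_numpy())
        out.loc[i, k] = out.loc[k, i] = o
    return out


def high_overlap_pairs(m: pd.DataFrame, cutoff: float = OVERLAP_CUTOFF) -> pd.DataFrame:
    """Unordered pairs with O > cutoff (strict), sorted descending by O."""
    rows = [
        {"fg_i": i, "fg_k": k, "O": float(m.loc[i, k])}
        for i, k in itertools.combinations(m.index, 2)
        if m.loc[i, k] > cutoff
    ]
    df = pd.DataFrame(rows, columns=["fg_i", "fg_k", "O"])
    return df.sort_values("O", ascending=False, kind="stable").reset_index(drop=True)
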