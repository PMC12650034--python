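"""Abundance correlation screening, Bray–Curtis distances and the Mantel test.

Densities are log10(x+1)-transformed before Pearson correlation (counts are
heavily right-skewed and contain true zeros).  Pairwise p-values get a
Bonferroni correction over the number of distinct pairs.  Community structure
vs environment is tested with a one-sided permutation Mantel test between the
Bray–Curtis community distance matrix and a Euclidean distance matrix on
z-scored environmental variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core_data import EnvTable, FGTable

STRONG_CUTOFF = 0.7


def log_transform(tab: FGTable, offset: float = 1.0, layer: str = "abundance") -> pd.DataFrame:
    """Elementwise log10(x + offset); zero-preserving and monotone at offset 1."""
    mat = tab.layer(layer)
    if (mat.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative densities")
    return np.log10(mat + offset)


def pearson_pairs(t: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over FG columns of a site × FG table.

    Constant columns give NaN (undefined) entries for their pairs.  Returns
    {'r': ..., 'p': ..., 'p_adj': ...} with unit diagonal on r.
    """
    if t.shape[0] < 3:
        raise ValueError("pearson_pairs needs at least 3 sites")
    fgs = t.columns
    r = pd.DataFrame(np.eye(len(fgs)), index=fgs, columns=fgs)
    p = pd.DataFrame(np.nan, index=fgs, columns=fgs)
    pairs = list(itertools.combinations(fgs, 2))
    for i, k in pairs:
        x, y = t[i].to_numpy(), t[k].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rv, pv = float("nan"), float("nan")
        else:
            res = stats.pearsonr(x, y)
            rv, pv = float(res.statistic), float(res.pvalue)
        r.loc[i, k] = r.loc[k, i] = rv
        p.loc[i, k] = p.loc[k, i] = pv
    return {"r": r, "p": p, "p_adj": bonferroni(p, len(pairs))}


def bonferroni(p_matrix: pd.DataFrame, m: int) -> pd.DataFrame:
    """p_adj = min(1, p·m); NaN passes through."""
    return (p_matrix * m).clip(upper=1.0)


def classify_pairs(
    r: pd.DataFrame,
    p_adj: pd.DataFrame | None = None,
    strong_cutoff: float = STRONG_CUTOFF,
    alpha: float = 0.05,
) -> dict:
    """Sign/strength counts over unordered pairs; undefined pairs reported.

    strong is magnitude-based (r > cutoff, strict); significant (when p_adj
    given) is inference-based — the two are deliberately separate.
    """
    pos = neg = strong = sig = undef = 0
    for i, k in itertools.combinations(r.index, 2):
        rv = r.loc[i, k]
        if np.isnan(rv):
            undef += 1
            continue
        if rv > 0:
            pos += 1
        elif rv < 0:
            neg += 1
        if rv > strong_cutoff:
            strong += 1
        if p_adj is not None and not np.isnan(p_adj.loc[i, k]) and p_adj.loc[i, k] < alpha:
            sig += 1
    return {
        "positive": pos,
        "negative": neg,
        "strong_positive": strong,
        "significant": sig,
        "undefined": undef,
    }


def bray_curtis(tab: FGTable, layer: str = "abundance") -> pd.DataFrame:
    """Site × site Bray–Curtis distance matrix, d = Σ|x−y| / Σ(x+y) ∈ [0, 1].

    A pair of all-zero sites has no defined composition contrast; its
    distance is set to 0 and the pair recorded in ``attrs['zero_pairs']``.
    """
    mat = tab.layer(layer)
    x = mat.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    zero_pairs = []
    if np.isnan(d).any():
        ii, kk = np.nonzero(np.isnan(d))
        zero_pairs = sorted(
            {(mat.index[i], mat.index[k]) for i, k in zip(ii, kk) if i < k}
        )
        d = np.nan_to_num(d, nan=0.0)
    out = pd.DataFrame(d, index=mat.index, columns=mat.index)
    out.attrs["metric"] = "braycurtis"
    out.attrs["zero_pairs"] = zero_pairs
    return out


def env_distance(env: EnvTable, columns=None) -> pd.DataFrame:
    """Euclidean distances on per-variable z-scored environmental data.

    Columns with missing values are z-scored on their observed entries and
    NaNs excluded pairwise (distance scaled to the shared dimension count).
    """
    mat = env.values if columns is None else env.values[list(columns)]
    z = (mat - mat.mean()) / mat.std(ddof=0)
    arr = z.to_numpy()
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i, k in itertools.combinations(range(n), 2):
        ok = ~(np.isnan(arr[i]) | np.isnan(arr[k]))
        if not ok.any():
            raise ValueError("no shared observed environmental variables for a site pair")
        diff = arr[i, ok] - arr[k, ok]
        # rescale to full dimensionality so sparsity does not shrink distances
        d[i, k] = d[k, i] = np.sqrt(np.sum(diff**2) * arr.shape[1] / ok.sum())
    out = pd.DataFrame(d, index=mat.index, columns=mat.index)
    out.attrs["metric"] = "euclidean-zscored"
    return out


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    method: str


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(d, k=1)
    return d[iu]


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "pearson",
) -> MantelResult:
    """One-sided (greater) permutation Mantel test between two distance matrices.

    r is the correlation of the upper-triangle vectors; p applies the +1
    correction, p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), permuting rows and
    columns of d2 jointly.  Deterministic for a fixed seed.
    """
    if d1.shape != d2.shape or not d1.index.equals(d2.index):
        raise ValueError("distance matrices must share the same site set and order")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}.get(method)
    if corr is None:
        raise ValueError(f"unknown method {method!r}")
    a1 = d1.to_numpy(dtype=float)
    a2 = d2.to_numpy(dtype=float)
    v1 = _offdiag(a1)
    r_obs = float(corr(v1, _offdiag(a2)).statistic)
    rng = np.random.default_rng(seed)
    n = a1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = float(corr(v1, _offdiag(a2[np.ix_(perm, perm)])).statistic)
        if r_perm >= r_obs:
            count += 1
    return MantelResult(
        r=r_obs,
        p=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed if seed is not None else -1,
        method=method,
    )
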