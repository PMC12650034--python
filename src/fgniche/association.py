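"""Interspecific association from presence/absence of functional groups.

Overall association uses the variance-ratio test: with p_i the occurrence
frequency of group i and T_j the number of groups at site j,

    sigma2_T = sum_i p_i (1 - p_i)        (expected richness variance under
                                           independent occurrences)
    S2_T     = (1/N) sum_j (T_j - tbar)^2 (observed richness variance)
    VR       = S2_T / sigma2_T,  W = VR * N

VR > 1 indicates overall positive association, VR < 1 negative; W is gated
against the chi-square distribution (N degrees of freedom by default,
matching the inequality W < chi2_{0.95}(N) or W > chi2_{0.05}(N)).

Pairwise association builds a 2x2 contingency table per group pair
(a co-presence, b only-second, c only-first, d co-absence) and reports the
point correlation coefficient (phi), the Yates-corrected chi-square with its
p-value, and the three-branch association coefficient AC.  Degenerate tables
(a zero margin) yield explicit NaN records, never silent drops.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import FGTable

ALPHA = 0.05


def to_presence(tab: FGTable, eps: float = 0.0) -> pd.DataFrame:
    """Site × FG 0/1 matrix; present iff density > eps (strict)."""
    return (tab.values > eps).astype(int)


@dataclass(frozen=True)
class Contingency2x2:
    """Joint occurrence counts over N = a+b+c+d sites for an (A, B) pair.

    a: both present; b: only B; c: only A; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        a, b, c, d = self.a, self.b, self.c, self.d
        return (a + b, c + d, a + c, b + d)


def contingency(presence: pd.DataFrame, i: str, k: str) -> Contingency2x2:
    """2×2 table for FG pair (i=A, k=B) from a binary occurrence matrix."""
    for col in (i, k):
        if col not in presence.columns:
            raise KeyError(f"unknown functional group {col!r}")
    x = presence[i].to_numpy().astype(bool)
    y = presence[k].to_numpy().astype(bool)
    return Contingency2x2(
        a=int((x & y).sum()),
        b=int((~x & y).sum()),
        c=int((x & ~y).sum()),
        d=int((~x & ~y).sum()),
    )


def pcc(t: Contingency2x2) -> float:
    """Point correlation coefficient (phi) in [-1, 1]; NaN if a margin is 0."""
    m = t.margins
    if 0 in m:
        return float("nan")
    return (t.a * t.d - t.b * t.c) / math.sqrt(math.prod(m))


def yates_chi2(t: Contingency2x2, correction: bool = True) -> tuple[float, float]:
    """2×2 chi-square (Yates-corrected by default) and its 1-df p-value.

    The corrected statistic N(|ad−bc| − N/2)² / Π(margins) is clamped to 0
    when |ad−bc| ≤ N/2.  Without correction the statistic equals N·phi².
    Returns (NaN, NaN) on a zero margin.
    """
    m = t.margins
    if 0 in m:
        return float("nan"), float("nan")
    n = t.n
    diff = abs(t.a * t.d - t.b * t.c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / math.prod(m)
    return stat, float(stats.chi2.sf(stat, df=1))


def ac(t: Contingency2x2) -> float:
    """Three-branch association coefficient in [-1, 1]; NaN on zero denominator.

    ad ≥ bc:            (ad−bc)/((a+b)(b+d))
    bc > ad and a ≤ d:  (ad−bc)/((a+b)(a+c))
    bc > ad and a > d:  (ad−bc)/((b+d)(c+d))
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    num = a * d - b * c
    if num >= 0:
        denom = (a + b) * (b + d)
    elif a <= d:
        denom = (a + b) * (a + c)
    else:
        denom = (b + d) * (c + d)
    if denom == 0:
        return float("nan")
    return num / denom


@dataclass(frozen=True)
class OverallAssociation:
    S: int
    N: int
    sigma2_T: float
    S2_T: float
    VR: float
    W: float


def variance_ratio(presence: pd.DataFrame) -> OverallAssociation:
    """Schluter variance-ratio statistics from a site × FG binary matrix.

    Raises when sigma2_T = 0 (every group ubiquitous or absent), where VR is
    undefined.
    """
    b = presence.to_numpy().astype(float)
    n_sites, n_fgs = b.shape
    if n_sites < 2:
        raise ValueError("variance_ratio needs at least 2 sites")
    p = b.mean(axis=0)
    sigma2 = float(np.sum(p * (1.0 - p)))
    if sigma2 == 0.0:
        raise ValueError("sigma2_T = 0: all groups ubiquitous or absent, VR undefined")
    t_j = b.sum(axis=1)
    s2 = float(np.mean((t_j - t_j.mean()) ** 2))
    vr = s2 / sigma2
    return OverallAssociation(
        S=n_fgs, N=n_sites, sigma2_T=sigma2, S2_T=s2, VR=vr, W=vr * n_sites
    )


def vr_bounds(n: int, alpha_per_tail: float = ALPHA, df: str = "N") -> tuple[float, float]:
    """(lower, upper) chi-square bounds for W: chi2_{1-α}(df) and chi2_{α}(df)."""
    dof = n if df == "N" else n - 1
    return (
        float(stats.chi2.ppf(alpha_per_tail, dof)),
        float(stats.chi2.ppf(1.0 - alpha_per_tail, dof)),
    )


def vr_verdict(o: OverallAssociation, alpha_per_tail: float = ALPHA, df: str = "N") -> str:
    """Five-level verdict: sign from VR vs 1, significance from W vs bounds."""
    if o.VR == 1.0:
        return "none"
    lo, hi = vr_bounds(o.N, alpha_per_tail, df)
    significant = o.W < lo or o.W > hi
    sign = "positive" if o.VR > 1.0 else "negative"
    return f"{'significant' if significant else 'ns'}-{sign}"


def pair_associations(
    presence: pd.DataFrame,
    correction: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-pair 2×2 statistics with Bonferroni-adjusted chi-square p-values.

    Raw p is always reported alongside p_adj = min(1, p·m) over the m pairs.
    The sign label follows ad − bc; undefined statistics propagate as NaN.
    """
    pairs = list(itertools.combinations(presence.columns, 2))
    m = len(pairs)
    rows = []
    for i, k in pairs:
        t = contingency(presence, i, k)
        phi = pcc(t)
        chi2_stat, p = yates_chi2(t, correction=correction)
        det = t.a * t.d - t.b * t.c
        rows.append(
            {
                "fg_i": i, "fg_k": k,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "pcc": phi, "chi2": chi2_stat, "p": p,
                "p_adj": min(1.0, p * m) if not math.isnan(p) else float("nan"),
                "ac": ac(t),
                "sign": "positive" if det > 0 else ("negative" if det < 0 else "zero"),
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["p_adj"] < alpha
    return df


def association_network(pairs: pd.DataFrame, include_rule: str = "all", strength: str = "pcc"):
    """Edge list (and counts) from a pair table, for network rendering.

    include_rule: 'all' (every defined pair), 'significant' (adjusted p < α
    already flagged in the table), or 'nonzero' (sign ≠ zero).  Returns
    (edges DataFrame, node list, {'positive': n+, 'negative': n-}).
    """
    rules = {
        "all": lambda r: not math.isnan(r[strength]),
        "significant": lambda r: bool(r["significant"]) and not math.isnan(r[strength]),
        "nonzero": lambda r: r["sign"] != "zero" and not math.isnan(r[strength]),
    }
    if include_rule not in rules:
        raise ValueError(f"unknown include_rule {include_rule!r}")
    keep = pairs[[rules[include_rule](r) for _, r in pairs.iterrows()]].copy()
    edges = pd.DataFrame(
        {
            "source": keep["fg_i"],
            "target": keep["fg_k"],
            "sign": keep["sign"],
            "weight": keep[strength].abs(),
            "significant": keep["significant"],
        }
    ).reset_index(drop=True)
    nodes = sorted(set(pairs["fg_i"]) | set(pairs["fg_k"]))
    counts = {
        "positive": int((edges["sign"] == "positive").sum()),
        "negative": int((edges["sign"] == "negative").sum()),
    }
    return edges, nodes, counts


def network_graphml(edges: pd.DataFrame, nodes, path) -> None:
    """Write the association network as GraphML via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for _, e in edges.iterrows():
        g.add_edge(
            e["source"], e["target"],
            sign=str(e["sign"]), weight=float(e["weight"]),
            significant=bool(e["significant"]),
        )
    nx.write_graphml(g, path)
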