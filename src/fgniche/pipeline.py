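"""End-to-end orchestration: data → dominance → niche → association →
correlation/Mantel → report bundle.

Every stage writes one or more CSVs into the output directory plus a run
manifest (config echo, versions, seed) from which the bundle is reproducible
bit-for-bit apart from the manifest timestamp.  Stages that hit undefined
inputs within a scope (e.g. a zero-total group) record a note and continue.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc_mod
from . import correlation as corr_mod
from . import dominance as dom_mod
from . import niche as niche_mod
from . import synthetic as syn_mod
from .core_data import (
    EnvTable,
    FGTable,
    FunctionalGroupMap,
    aggregate_to_fg,
    read_abundance,
    read_env,
    read_fg_table,
    write_abundance,
    write_env,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a run, echoed verbatim into the manifest."""

    scenario: str | None = None
    abundance_path: str | None = None
    fg_map_path: str | None = None
    env_path: str | None = None
    is_fg_table: bool = False  # abundance_path already holds FG columns
    scope: str = "per-reservoir"  # or "pooled"
    dominance_threshold: float = 0.02
    share_threshold_pct: float = 5.0
    dominance_metric: str = "biomass"
    overlap_cutoff: float = 0.7
    overlap_method: str = "printed"
    strong_r_cutoff: float = 0.7
    alpha: float = 0.05
    presence_eps: float = 0.0
    log_offset: float = 1.0
    n_perm: int = 999
    seed: int | None = None
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        for name, val, lo, hi in [
            ("dominance_threshold", self.dominance_threshold, 0, 1),
            ("share_threshold_pct", self.share_threshold_pct, 0, 100),
            ("overlap_cutoff", self.overlap_cutoff, 0, 1),
            ("strong_r_cutoff", self.strong_r_cutoff, 0, 1),
            ("alpha", self.alpha, 0, 1),
        ]:
            if not lo < val < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}), got {val}")
        if self.scenario is not None and self.seed is None:
            raise ValueError("a seed is mandatory when generating a scenario")
        if self.scenario is None and self.abundance_path is None:
            raise ValueError("provide either a scenario name or input paths")


def _load_inputs(cfg: PipelineConfig):
    """Return (FGTable, EnvTable | None, truth | None) per the config."""
    if cfg.scenario is not None:
        scfg = syn_mod.scenario(cfg.scenario)
        tab, truth = syn_mod.generate_community(scfg, cfg.seed)
        truth.scenario = cfg.scenario
        env = syn_mod.generate_env(scfg, cfg.seed + 1, tab, truth)
        return tab, env, truth
    if cfg.is_fg_table:
        tab = read_fg_table(cfg.abundance_path)
    else:
        if cfg.fg_map_path is None:
            raise FileNotFoundError("fg_map_path is required to aggregate a taxon table")
        raw = read_abundance(cfg.abundance_path)
        tab = aggregate_to_fg(raw, FunctionalGroupMap.from_csv(cfg.fg_map_path))
    env = read_env(cfg.env_path) if cfg.env_path else None
    return tab, env, None


def _scopes(tab: FGTable, scope: str):
    yield "pooled", tab
    if scope == "per-reservoir":
        for res, grp in tab.meta.groupby("reservoir", sort=True, observed=True):
            if tab.meta["reservoir"].nunique() > 1:
                yield str(res), tab.subset(grp.index)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write the bundle, return a result summary dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    tab, env, truth = _load_inputs(cfg)
    write_abundance(tab, out / "fg_abundance.csv")
    if tab.biomass is not None:
        bio = FGTable(tab.biomass, tab.meta)
        write_abundance(bio, out / "fg_biomass.csv")
    if env is not None:
        write_env(env, out / "env.csv")
    if truth is not None:
        truth.to_json(out / "truth.json")

    summary: dict = {"scopes": {}}

    # dominance (pooled Y index + per-scope shares)
    dom = dom_mod.dominance_index(tab, cfg.dominance_threshold)
    dom.to_csv(out / "dominance_index.csv")
    metric = cfg.dominance_metric if tab.biomass is not None else "abundance"
    if metric != cfg.dominance_metric:
        notes.append("no biomass layer; dominant-group shares computed on abundance")
    shares = dom_mod.dominant_fgs(
        tab, cfg.share_threshold_pct, metric=metric,
        scope="per-reservoir" if cfg.scope == "per-reservoir" else "pooled",
    )
    shares.to_csv(out / "fg_shares.csv", index=False)
    summary["dominant_units_Y"] = dom.index[dom["dominant"]].tolist()

    for scope_name, sub in _scopes(tab, cfg.scope):
        sc: dict = {}
        try:
            props = niche_mod.niche_proportions(sub)
            breadth = niche_mod.breadth_table(props)
            overlap = niche_mod.overlap_matrix(props, cfg.overlap_method)
            pairs_hi = niche_mod.high_overlap_pairs(overlap, cfg.overlap_cutoff)
            breadth.to_csv(out / f"niche_breadth_{scope_name}.csv")
            overlap.to_csv(out / f"niche_overlap_{scope_name}.csv")
            pairs_hi.to_csv(out / f"high_overlap_pairs_{scope_name}.csv", index=False)
            sc["high_overlap_pairs"] = len(pairs_hi)
            if props.attrs.get("excluded"):
                notes.append(f"{scope_name}: zero-total groups excluded from niche: "
                             f"{props.attrs['excluded']}")
        except Exception as exc:  # undefined niche inputs are recorded, not fatal
            notes.append(f"{scope_name}: niche stage skipped ({exc})")

        try:
            presence = assoc_mod.to_presence(sub, cfg.presence_eps)
            overall = assoc_mod.variance_ratio(presence)
            verdict = assoc_mod.vr_verdict(overall, cfg.alpha)
            lo, hi = assoc_mod.vr_bounds(overall.N, cfg.alpha)
            pd.DataFrame(
                [{**asdict(overall), "chi2_lower": lo, "chi2_upper": hi, "verdict": verdict}]
            ).to_csv(out / f"overall_association_{scope_name}.csv", index=False)
            pairs = assoc_mod.pair_associations(presence, alpha=cfg.alpha)
            pairs.to_csv(out / f"pair_association_{scope_name}.csv", index=False)
            edges, nodes, counts = assoc_mod.association_network(pairs)
            edges.to_csv(out / f"association_edges_{scope_name}.csv", index=False)
            assoc_mod.network_graphml(edges, nodes, out / f"association_{scope_name}.graphml")
            sc.update(
                vr=overall.VR, w=overall.W, verdict=verdict,
                positive_pairs=counts["positive"], negative_pairs=counts["negative"],
            )
        except Exception as exc:
            notes.append(f"{scope_name}: association stage skipped ({exc})")

        try:
            logged = corr_mod.log_transform(sub, cfg.log_offset)
            cm = corr_mod.pearson_pairs(logged)
            cm["r"].to_csv(out / f"correlation_r_{scope_name}.csv")
            cm["p_adj"].to_csv(out / f"correlation_p_adj_{scope_name}.csv")
            counts = corr_mod.classify_pairs(
                cm["r"], cm["p_adj"], cfg.strong_r_cutoff, cfg.alpha
            )
            sc["correlation_counts"] = counts
        except Exception as exc:
            notes.append(f"{scope_name}: correlation stage skipped ({exc})")

        summary["scopes"][scope_name] = sc

    # Mantel: community vs environment, pooled scope
    if env is not None:
        try:
            d_comm = corr_mod.bray_curtis(tab)
            d_env = corr_mod.env_distance(env)
            d_comm.to_csv(out / "bray_curtis.csv")
            res = corr_mod.mantel(
                d_comm, d_env, n_perm=cfg.n_perm,
                seed=(cfg.seed if cfg.seed is not None else 0) + 17,
            )
            pd.DataFrame([asdict(res)]).to_csv(out / "mantel.csv", index=False)
            summary["mantel"] = {"r": res.r, "p": res.p}
        except Exception as exc:
            notes.append(f"mantel stage skipped ({exc})")

    summary["notes"] = notes
    _write_summary(out / "summary.txt", cfg, summary)
    manifest = {
        "package": "fgniche",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


def _write_summary(path: Path, cfg: PipelineConfig, summary: dict) -> None:
    lines = [
        "fgniche pipeline summary",
        f"scope mode: {cfg.scope}",
        f"dominant units (Y > {cfg.dominance_threshold}): "
        + ", ".join(summary["dominant_units_Y"]),
    ]
    for name, sc in summary["scopes"].items():
        lines.append(f"[{name}]")
        if "vr" in sc:
            lines.append(
                f"  VR = {sc['vr']:.4f}, W = {sc['w']:.4f}, verdict = {sc['verdict']}; "
                f"pairs: {sc['positive_pairs']} positive / {sc['negative_pairs']} negative"
            )
        if "high_overlap_pairs" in sc:
            lines.append(f"  high-overlap pairs (O > {cfg.overlap_cutoff}): {sc['high_overlap_pairs']}")
        if "correlation_counts" in sc:
            c = sc["correlation_counts"]
            lines.append(
                f"  correlations: {c['positive']} positive, {c['negative']} negative, "
                f"{c['strong_positive']} strong (r > {cfg.strong_r_cutoff}), "
                f"{c['significant']} significant"
            )
    if "mantel" in summary:
        lines.append(
            f"Mantel (community vs environment): r = {summary['mantel']['r']:.4f}, "
            f"p = {summary['mantel']['p']:.4f}"
        )
    for note in summary["notes"]:
        lines.append(f"note: {note}")
    path.write_text("\n".join(lines) + "\n")
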