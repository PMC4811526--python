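"""End-to-end orchestration: run every stability method on every analysis
group and merge the rankings into a consensus.

The consensus rank of a gene within a group is the geometric mean of its
competition ranks under geNorm, NormFinder and BestKeeper (the community-
standard RefFinder-style aggregation; an extension over running the three
tools side by side, and flagged as such in the report header).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bestkeeper, genorm, normfinder
from .cp_data import (AnalysisGroup, CpTable, collapse_technical_replicates,
                      default_groups, read_cp_table, to_relative_quantities)

log = logging.getLogger(__name__)

CONSENSUS_HEADER = ("# consensus rank = geometric mean of geNorm/NormFinder/"
                    "BestKeeper competition ranks (RefFinder-style extension)")


@dataclass
class RunConfig:
    """Configuration of a full analysis run (file paths, methods, knobs)."""

    input: str | Path | None = None
    layout: str = "long"
    control_class: str = "control"
    groups: list[AnalysisGroup] | None = None
    methods: tuple[str, ...] = ("genorm", "normfinder", "bestkeeper")
    collapse: str | None = "mean"           # technical-replicate rule
    sd_convention: str = "mad"              # BestKeeper dispersion
    nf_mode: str = "grouped"                # NormFinder default mode
    v_cutoff: float = 0.15
    efficiencies: Mapping[str, float] | None = None
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.methods) - {"genorm", "normfinder", "bestkeeper"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.v_cutoff <= 0:
            raise ValueError("v_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        groups = raw.pop("groups", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if groups:
            cfg.groups = [
                AnalysisGroup(g["name"], frozenset(g["member_classes"]),
                              g.get("subgroup_labels"))
                for g in groups
            ]
        return cfg


def _method_ranks(table: CpTable, group: AnalysisGroup,
                  config: RunConfig) -> tuple[dict, pd.DataFrame]:
    """Run the configured methods on one group; return results and ranks."""
    results: dict = {}
    ranks = {}
    if "genorm" in config.methods or "vfit" in config.methods:
        q = to_relative_quantities(table, group,
                                   efficiencies=config.efficiencies)
        gn = genorm.rank_genes(q, group=group.name)
        results["genorm"] = gn
        results["v_curve"] = genorm.v_curve(q, gn, cutoff=config.v_cutoff)
        ranks["genorm"] = gn.ranks()
    if "normfinder" in config.methods:
        x = normfinder.log_expression(table, group,
                                      efficiencies=config.efficiencies)
        if config.nf_mode == "grouped":
            labels = normfinder.default_subgroups(table, group,
                                                  config.control_class)
            n_labels = labels.nunique()
            if n_labels >= 2 and (labels.value_counts() >= 2).sum() >= 2:
                nf = normfinder.grouped_stability(x, labels, group=group.name)
            else:
                nf = normfinder.ungrouped_stability(x, group=group.name)
        else:
            nf = normfinder.ungrouped_stability(x, group=group.name)
        results["normfinder"] = nf
        ranks["normfinder"] = nf.ranks()
    if "bestkeeper" in config.methods:
        bk = bestkeeper.rank_group(table, group, config.sd_convention)
        results["bestkeeper"] = bk
        ranks["bestkeeper"] = bk["rank"].reindex(table.genes)
    rank_df = pd.DataFrame(ranks)
    return results, rank_df


def consensus_ranks(rank_df: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean aggregation of per-method competition ranks."""
    gmean = np.exp(np.log(rank_df.astype(float)).mean(axis=1))
    out = rank_df.copy()
    out["geo_mean_rank"] = gmean
    out["consensus_rank"] = gmean.rank(method="min").astype(int)
    return out.sort_values(["consensus_rank", "geo_mean_rank"],
                           kind="mergesort")


def run_all(config: RunConfig, table: CpTable | None = None) -> dict:
    """Execute the full analysis; returns a report bundle keyed by group.

    The bundle maps group name -> {genorm, v_curve, normfinder, bestkeeper,
    consensus}; output is a pure function of (input table, config).
    """
    if table is None:
        if config.input is None:
            raise ValueError("RunConfig.input or an in-memory table required")
        table = read_cp_table(config.input, layout=config.layout)
    if config.collapse:
        table = collapse_technical_replicates(table, config.collapse)
    groups = config.groups or default_groups(table.classes,
                                             control=config.control_class)
    bundle: dict = {"groups": {}, "config": config}
    for group in groups:
        try:
            results, rank_df = _method_ranks(table, group, config)
        except (ValueError, KeyError) as exc:
            raise RuntimeError(
                f"analysis failed in group {group.name!r}: {exc}") from exc
        results["consensus"] = consensus_ranks(rank_df)
        bundle["groups"][group.name] = results
    return bundle


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the report bundle as delimited text plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for name, res in bundle["groups"].items():
        safe = name.replace(":", "_")
        gsum: dict = {}
        if "genorm" in res:
            gn = res["genorm"]
            gn.m_values_full.to_csv(out / f"{safe}.genorm_m.tsv", sep="\t")
            pd.DataFrame({
                "excluded_gene": gn.exclusion_order,
                "m_at_exclusion": gn.m_trajectory,
            }).to_csv(out / f"{safe}.genorm_exclusion.tsv", sep="\t",
                      index=False)
            gsum["genorm_final_pair"] = list(gn.final_pair)
        if "v_curve" in res:
            vc = res["v_curve"]
            pd.DataFrame({"V": vc.v, "below_cutoff": vc.below_cutoff}) \
                .to_csv(out / f"{safe}.genorm_v.tsv", sep="\t",
                        index_label="n")
            gsum["optimal_n"] = vc.optimal_n
            gsum["v23"] = float(vc.v.iloc[0])
        if "normfinder" in res:
            nf = res["normfinder"]
            nf.stability.sort_values().to_csv(out / f"{safe}.normfinder.tsv",
                                              sep="\t")
            gsum["normfinder_top"] = nf.ranking[0]
            gsum["normfinder_top_stability"] = float(nf.stability.min())
        if "bestkeeper" in res:
            res["bestkeeper"].to_csv(out / f"{safe}.bestkeeper.tsv", sep="\t")
            gsum["bestkeeper_top"] = res["bestkeeper"].index[0]
        cons = res["consensus"]
        with open(out / f"{safe}.consensus.tsv", "w") as fh:
            fh.write(CONSENSUS_HEADER + "\n")
            cons.to_csv(fh, sep="\t", index_label="gene")
        gsum["consensus_top"] = cons.index[0]
        summary[name] = gsum
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
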