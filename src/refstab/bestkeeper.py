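"""BestKeeper-style descriptive stability statistics on raw Cp values.

Unlike the ratio-based methods, these statistics are computed directly on the
crossing-point scale: a gene's dispersion (the original tool reports the mean
absolute deviation from the mean Cp, labelled "SD [+- Cp]") and its
coefficient of variation CV% = 100 * dispersion / mean Cp.  A dispersion
above one cycle (a two-fold expression swing) flags a gene as inconsistent.
The BestKeeper index is the per-sample geometric mean Cp of candidate genes;
each gene's Pearson correlation with the index summarises how well it tracks
the panel consensus.  Because no per-sample normalization is involved, these
statistics are deliberately NOT invariant to sample-loading differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cp_data import AnalysisGroup, CpTable

log = logging.getLogger(__name__)

#: dispersion above this many cycles marks a gene as inconsistent
INCONSISTENT_SD = 1.0


@dataclass(frozen=True)
class BestKeeperGeneStats:
    gene: str
    n: int
    geo_mean: float
    arith_mean: float
    minimum: float
    maximum: float
    sd: float
    cv_percent: float
    inconsistent: bool


def gene_stats(cp, gene: str = "", sd_convention: str = "mad") -> BestKeeperGeneStats:
    """Descriptive Cp statistics for one gene.

    ``sd_convention='mad'`` (default, the original tool's "SD"): mean
    absolute deviation from the arithmetic mean.  ``'sd'``: n-1 sample SD.
    """
    v = pd.Series(np.asarray(cp, float)).dropna()
    if v.size < 2:
        raise ValueError(f"gene {gene or '?'}: need >=2 non-missing Cp values")
    if (v <= 0).any():
        raise ValueError(f"gene {gene or '?'}: non-positive Cp "
                         "(geometric mean undefined)")
    mean = float(v.mean())
    if sd_convention == "mad":
        sd = float((v - mean).abs().mean())
    elif sd_convention == "sd":
        sd = float(v.std(ddof=1))
    else:
        raise ValueError("sd_convention must be 'mad' or 'sd'")
    return BestKeeperGeneStats(
        gene=gene,
        n=int(v.size),
        geo_mean=float(stats.gmean(v)),
        arith_mean=mean,
        minimum=float(v.min()),
        maximum=float(v.max()),
        sd=sd,
        cv_percent=100.0 * sd / mean,
        inconsistent=sd > INCONSISTENT_SD,
    )


def rank_group(
    t: CpTable,
    group: AnalysisGroup | None = None,
    sd_convention: str = "mad",
) -> pd.DataFrame:
    """Per-gene stats in a group, most stable (lowest CV, then SD) first.

    Ties beyond (CV, SD) keep input order.  Inconsistent genes (SD > 1 cycle)
    are flagged, never silently removed.
    """
    sub = t if group is None else t.subset(group.member_classes)
    if len(sub.genes) < 2:
        raise ValueError("ranking requires >=2 genes")
    rows = [gene_stats(sub.cp.loc[g], g, sd_convention) for g in sub.genes]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("gene")
    df = df.sort_values(["cv_percent", "sd"], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class BestKeeperIndexResult:
    group: str | None
    member_genes: list[str]
    index: pd.Series                 # per-sample geometric mean Cp
    r: pd.Series                     # per-gene Pearson r vs the index
    p_value: pd.Series


def bestkeeper_index(
    t: CpTable,
    group: AnalysisGroup | None = None,
    members: Sequence[str] | None = None,
) -> BestKeeperIndexResult:
    """BestKeeper index and per-gene correlations against it.

    The index is defined only over samples complete for every member gene;
    fewer than three such samples is an error (a correlation needs df > 0).
    """
    sub = t if group is None else t.subset(group.member_classes)
    members = list(members) if members is not None else list(sub.genes)
    unknown = set(members) - set(sub.genes)
    if unknown:
        raise KeyError(f"member genes not in table: {sorted(unknown)}")
    if len(members) < 2:
        raise ValueError("index requires >=2 member genes")
    mat = sub.cp.loc[members]
    complete = mat.columns[mat.notna().all(axis=0)]
    if len(complete) < 3:
        raise ValueError("index requires >=3 samples complete for all members")
    idx = pd.Series(stats.gmean(mat[complete].to_numpy(), axis=0),
                    index=complete, name="bestkeeper_index")
    r, p = {}, {}
    for g in sub.genes:
        v = sub.cp.loc[g, complete]
        ok = v.notna()
        if ok.sum() < 3 or v[ok].nunique() == 1:
            log.warning("gene %s: correlation with index undefined", g)
            r[g], p[g] = np.nan, np.nan
            continue
        res = stats.pearsonr(v[ok], idx[ok])
        r[g], p[g] = float(res.statistic), float(res.pvalue)
    return BestKeeperIndexResult(
        group=group.name if group else None,
        member_genes=members,
        index=idx,
        r=pd.Series(r).reindex(sub.genes),
        p_value=pd.Series(p).reindex(sub.genes),
    )
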