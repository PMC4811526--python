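"""Model-based (NormFinder-style) stability estimation.

Log-scale expression of gene i in sample j is modelled additively,

    x_ij = mu_i + s_j + eps_ij,      Var(eps_ij) = sigma_i^2,

where s_j is a sample effect (mRNA loading, cDNA yield) common to all genes
and sigma_i^2 is the gene-specific biological+technical variance that makes a
candidate unsuitable as a reference.  Because s_j is shared, the naive
per-gene residual variance from double-centering is biased: each gene's
residuals absorb a share of every other gene's noise.  A method-of-moments
correction under the model, E[s_i^2] = sigma_i^2 (1 - 2/k) + sigma_bar^2 / k,
recovers unbiased sigma_i^2 estimates for k >= 3 genes (negative estimates
truncated at zero).

In grouped mode the design adds a gene x subgroup interaction d_ig (a gene
that responds to the treatment is systematically off in one subgroup).  The
raw deviations d_ig are double-centered (so they sum to zero over genes
within each subgroup) and shrunk toward zero in proportion to their sampling
variance; the stability value combines the absolute shrunken deviation with
the intragroup standard error:

    rho_i = mean_g( |d_ig~| + sqrt(sigma_ig^2 / n_g) ).

Lower rho means more stable.  In ungrouped mode rho_i = sigma_i (the
estimated SD itself).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cp_data import AnalysisGroup, CpTable

log = logging.getLogger(__name__)


def log_expression(
    t: CpTable,
    group: AnalysisGroup | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Gene x sample log2-expression matrix from Cp values.

    x = -Cp (log2 expression up to an additive per-gene constant, which
    cancels in every downstream statistic).  With per-gene efficiencies,
    x = -Cp * log2(1+E); the default E = 1 reduces to -Cp.
    """
    sub = t if group is None else t.subset(group.member_classes)
    x = -sub.cp.copy()
    if efficiencies:
        for g, e in efficiencies.items():
            if g in x.index:
                x.loc[g] = -sub.cp.loc[g] * np.log2(1.0 + e)
    return x


@dataclass
class NormFinderResult:
    group: str | None
    mode: str                                  # 'ungrouped' | 'grouped'
    stability: pd.Series                       # rho per gene, ascending = stable
    intragroup_var: pd.DataFrame               # gene x subgroup sigma^2 estimates
    intergroup_dev: pd.DataFrame | None        # shrunken d~ (grouped mode)
    ranking: list[str]                         # genes ascending by rho
    intergroup_dev_raw: pd.DataFrame | None = None  # d before shrinkage

    def ranks(self) -> pd.Series:
        """Competition ranks by stability value (ties share the lower rank)."""
        return (self.stability.rank(method="min")
                .astype(int).rename("normfinder_rank"))


def _complete_cases(x: pd.DataFrame) -> pd.DataFrame:
    keep = x.columns[x.notna().all(axis=0)]
    dropped = x.shape[1] - len(keep)
    if dropped:
        log.warning("dropping %d samples with missing values for NormFinder",
                    dropped)
    return x[keep]


def _corrected_variances(x: np.ndarray,
                         truncate: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Raw double-centered residual variances and bias-corrected sigma^2.

    The method-of-moments correction is unbiased as is; the default
    truncation at zero (standard practice before taking square roots)
    introduces a small upward bias for variances near zero.
    """
    k, n = x.shape
    r = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) \
        + x.mean()
    s2 = (r ** 2).sum(axis=1) / (n - 1)
    sbar2 = k / (k - 1) * s2.mean()
    sigma2 = (s2 - sbar2 / k) * k / (k - 2)
    return s2, np.clip(sigma2, 0.0, None) if truncate else sigma2


def ungrouped_stability(x: pd.DataFrame, group: str | None = None) -> NormFinderResult:
    """Stability without subgroup structure: rho_i = estimated sigma_i."""
    x = _complete_cases(x)
    k, n = x.shape
    if k < 3:
        raise ValueError("NormFinder bias correction requires >= 3 genes")
    if n < 3:
        raise ValueError("ungrouped stability requires >= 3 samples")
    _, sigma2 = _corrected_variances(x.to_numpy())
    rho = pd.Series(np.sqrt(sigma2), index=x.index, name="stability")
    ranking = list(rho.sort_values(kind="mergesort").index)
    return NormFinderResult(
        group=group,
        mode="ungrouped",
        stability=rho,
        intragroup_var=pd.DataFrame({"all": sigma2}, index=x.index),
        intergroup_dev=None,
        ranking=ranking,
    )


def grouped_stability(
    x: pd.DataFrame,
    subgroups: Mapping[str, str] | pd.Series,
    group: str | None = None,
) -> NormFinderResult:
    """Stability with subgroup (e.g. control vs treated) structure.

    Subgroups with fewer than two samples are excluded with a warning.  With
    a single usable subgroup the intergroup term vanishes and the ranking
    degenerates to the ungrouped ordering within that subgroup.
    """
    x = _complete_cases(x)
    if x.shape[0] < 3:
        raise ValueError("NormFinder bias correction requires >= 3 genes")
    labels = pd.Series(dict(subgroups) if not isinstance(subgroups, pd.Series)
                       else subgroups).reindex(x.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a subgroup label")
    usable = []
    for lab, cols in labels.groupby(labels).groups.items():
        if len(cols) < 2:
            log.warning("subgroup %r has <2 samples; excluded", lab)
        else:
            usable.append(lab)
    if not usable:
        raise ValueError("no subgroup with >= 2 samples")
    genes = list(x.index)
    k = len(genes)
    sigma2 = {}
    means = {}
    n_g = {}
    for lab in usable:
        cols = labels.index[labels == lab]
        xg = x[cols].to_numpy()
        _, s2g = _corrected_variances(xg)
        sigma2[lab] = s2g
        means[lab] = xg.mean(axis=1)
        n_g[lab] = xg.shape[1]
    sig = pd.DataFrame(sigma2, index=genes)          # gene x subgroup
    m = pd.DataFrame(means, index=genes)             # subgroup mean expression
    G = len(usable)
    d_hat = None
    if G == 1:
        d_shrunk = pd.DataFrame(0.0, index=genes, columns=usable)
    else:
        # raw interaction: double-center the gene x subgroup mean matrix
        d_hat = m.sub(m.mean(axis=1), axis=0).sub(m.mean(axis=0), axis=1) \
                 + m.to_numpy().mean()
        d_shrunk = pd.DataFrame(index=genes, columns=usable, dtype=float)
        for lab in usable:
            samp_var = sig[lab] / n_g[lab]
            gamma2 = max(0.0, d_hat[lab].var(ddof=1) - samp_var.mean())
            denom = gamma2 + samp_var
            with np.errstate(invalid="ignore"):
                w = np.where(denom > 0, gamma2 / denom, 0.0)
            d_shrunk[lab] = d_hat[lab] * w
    se = np.sqrt(sig / pd.Series(n_g))
    rho = (d_shrunk.abs() + se).mean(axis=1).rename("stability")
    ranking = list(rho.sort_values(kind="mergesort").index)
    return NormFinderResult(
        group=group,
        mode="grouped",
        stability=rho,
        intragroup_var=sig,
        intergroup_dev=d_shrunk if G > 1 else None,
        intergroup_dev_raw=d_hat,
        ranking=ranking,
    )


def default_subgroups(t: CpTable, group: AnalysisGroup,
                      control: str = "control") -> pd.Series:
    """Default subgroup labels for one analysis group.

    Single-treatment groups split into {control, treated}; multi-class groups
    (Tissue, Total) are subgrouped by condition class.
    """
    if group.subgroup_labels is not None:
        return pd.Series(dict(group.subgroup_labels))
    sub = t.subset(group.member_classes)
    classes = sub.samples["condition_class"]
    non_control = sorted(set(classes) - {control})
    if len(non_control) <= 1:
        lab = classes.map(lambda c: "control" if c == control else "treated")
    else:
        lab = classes.copy()
    lab.name = "subgroup"
    return lab
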