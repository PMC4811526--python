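"""geNorm expression-stability measure M, iterative ranking and the
pairwise-variation criterion for the optimal number of reference genes.

The stability measure of gene j is the arithmetic mean, over all other
candidates k, of the standard deviation of log2(q_j/q_k) across samples: a
gene that co-varies with the panel (as pure mRNA-loading differences would
make it) has low M.  Ranking proceeds by repeatedly discarding the
highest-M gene and recomputing M on the remainder until two genes are left;
those two cannot be ordered further and are reported as the jointly most
stable pair.

How many reference genes are enough is decided from normalization factors
NF_n (per-sample geometric mean of the n most stable genes' quantities):
V_n/n+1 = SD(log2(NF_n / NF_n+1)); when V falls below a cutoff
(conventionally 0.15), adding gene n+1 no longer changes normalization
materially.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cp_data import RelativeQuantityTable

_TIE_EPS = 1e-12


def _as_q_frame(q) -> pd.DataFrame:
    if isinstance(q, RelativeQuantityTable):
        return q.q
    return q


def pairwise_variation(qj, qk) -> float:
    """SD (n-1) of log2 expression ratios of two genes over paired samples."""
    a = np.asarray(qj, float)
    b = np.asarray(qk, float)
    if a.shape != b.shape:
        raise ValueError("quantity vectors differ in length")
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        raise ValueError("pairwise variation needs >=2 complete pairs")
    if np.any(a[mask] <= 0) or np.any(b[mask] <= 0):
        raise ValueError("quantities must be positive")
    return float(np.std(np.log2(a[mask] / b[mask]), ddof=1))


def m_values(q, genes: Sequence[str] | None = None) -> pd.Series:
    """Mean pairwise variation M_j of each gene against all others in the subset."""
    qf = _as_q_frame(q)
    genes = list(qf.index) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("M requires at least 2 genes")
    sub = qf.loc[genes]
    m = {}
    for j in genes:
        vs = [pairwise_variation(sub.loc[j], sub.loc[k]) for k in genes if k != j]
        m[j] = float(np.mean(vs))
    return pd.Series(m, name="M").reindex(genes)


@dataclass
class GeNormResult:
    """Outcome of iterative geNorm ranking on one analysis group."""

    group: str | None
    genes: list[str]
    m_values_full: pd.Series          # M of every gene before any exclusion
    exclusion_order: list[str]        # least stable first
    m_trajectory: list[float]         # M of each excluded gene at its step
    final_pair: tuple[str, str]       # jointly most stable (rank 1-2)

    @property
    def stability_order(self) -> list[str]:
        """Most stable first; the final pair leads, in input order."""
        return list(self.final_pair) + list(reversed(self.exclusion_order))

    def ranks(self) -> pd.Series:
        """Competition ranks: the final pair shares rank 1, next gene rank 3."""
        ranks = {self.final_pair[0]: 1, self.final_pair[1]: 1}
        for i, g in enumerate(reversed(self.exclusion_order)):
            ranks[g] = 3 + i
        return pd.Series(ranks, name="genorm_rank").reindex(self.genes)


def rank_genes(q, group: str | None = None) -> GeNormResult:
    """Iteratively exclude the highest-M gene until two remain.

    Ties in the maximal M are broken by excluding the gene appearing later
    in input order (deterministic and documented).
    """
    qf = _as_q_frame(q)
    genes = list(qf.index)
    if len(genes) < 3:
        raise ValueError("ranking requires at least 3 genes")
    m_full = m_values(qf, genes)
    remaining = list(genes)
    exclusion, trajectory = [], []
    while len(remaining) > 2:
        m = m_values(qf, remaining)
        worst_val = m.max()
        tied = [g for g in remaining if m[g] >= worst_val - _TIE_EPS]
        worst = tied[-1]  # later in input order
        exclusion.append(worst)
        trajectory.append(float(m[worst]))
        remaining.remove(worst)
    return GeNormResult(
        group=group,
        genes=genes,
        m_values_full=m_full,
        exclusion_order=exclusion,
        m_trajectory=trajectory,
        final_pair=(remaining[0], remaining[1]),
    )


@dataclass
class PairwiseVariationCurve:
    """V_n/n+1 series with the optimal-number-of-genes decision."""

    group: str | None
    stability_order: list[str]
    nf: pd.DataFrame                  # rows n=2..k, per-sample NF_n
    v: pd.Series                      # index n=2..k-1, value V_n/n+1
    below_cutoff: pd.Series           # boolean per n
    cutoff: float
    optimal_n: int


def v_curve(q, ranking: GeNormResult, cutoff: float = 0.15) -> PairwiseVariationCurve:
    """Pairwise variation between successive normalization factors.

    NF_n is the per-sample geometric mean of the n most stable genes'
    relative quantities (geNorm rank order); V_n/n+1 is the SD (n-1) of
    log2(NF_n/NF_n+1).  The optimal n is the smallest with V below the
    cutoff, or k-1 when none passes.
    """
    qf = _as_q_frame(q)
    order = ranking.stability_order
    if set(order) != set(qf.index):
        raise ValueError("ranking does not cover the quantity table's genes")
    if len(order) < 3:
        raise ValueError("V curve requires at least 3 genes")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    logq = np.log2(qf.loc[order].to_numpy())
    k = len(order)
    # log2 NF_n = running mean of the top-n genes' log2 quantities
    log_nf = {n: np.nanmean(logq[:n], axis=0) for n in range(2, k + 1)}
    v_vals, flags = {}, {}
    for n in range(2, k):
        diff = log_nf[n] - log_nf[n + 1]
        diff = diff[np.isfinite(diff)]
        v = float(np.std(diff, ddof=1))
        v_vals[n] = v
        flags[n] = v < cutoff
    v_series = pd.Series(v_vals, name="V")
    below = pd.Series(flags, name="below_cutoff")
    passing = [n for n, ok in flags.items() if ok]
    optimal_n = min(passing) if passing else k - 1
    nf = pd.DataFrame({n: np.exp2(log_nf[n]) for n in range(2, k + 1)}).T
    nf.columns = list(qf.columns)
    return PairwiseVariationCurve(
        group=ranking.group,
        stability_order=order,
        nf=nf,
        v=v_series,
        below_cutoff=below,
        cutoff=cutoff,
        optimal_n=optimal_n,
    )
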