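"""Relative quantification of a target gene by the 2^-ddCt method.

Per biological replicate (technical replicates collapsed first), the
reference Ct is the arithmetic mean of the normalizer genes' Cp — on the
quantity scale this is the geometric mean, exactly the multi-gene
normalization factor convention.  dCt = Ct_target - Ct_ref; ddCt subtracts
the mean control dCt, so the control-condition mean fold change is 1 by
construction; fold = 2^-ddCt.  Per-gene amplification efficiencies switch
the computation to the efficiency-corrected (Pfaffl-style) ratio, which
coincides with 2^-ddCt at E = 100%.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cp_data import CpTable, collapse_technical_replicates

log = logging.getLogger(__name__)

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.05, "*"))


@dataclass
class ExpressionResult:
    target: str
    normalizers: list[str]
    control_class: str
    treated_class: str
    control_folds: pd.Series       # per biological replicate
    treated_folds: pd.Series
    mean_fold: float               # mean over treated biological replicates
    sem: float


def significance_tier(p: float) -> str:
    """Fig-style significance label: *** p<0.001, * p<0.05, else N.S."""
    for alpha, label in SIGNIFICANCE_TIERS:
        if p < alpha:
            return label
    return "N.S."


def ddct(
    t: CpTable,
    target: str,
    normalizers: Sequence[str],
    control_class: str = "control",
    treated_class: str | None = None,
    efficiencies: Mapping[str, float] | None = None,
    collapse: str | None = "mean",
) -> ExpressionResult:
    """Fold change of ``target`` in treated vs control samples.

    ``normalizers`` may hold one or several reference genes.  Biological
    replicates missing the target (or all normalizers) are dropped with a
    warning.  ``collapse=None`` skips technical-replicate averaging (e.g.
    when the table is already collapsed).
    """
    if not normalizers:
        raise ValueError("at least one normalizer gene is required")
    missing = {target, *normalizers} - set(t.genes)
    if missing:
        raise KeyError(f"genes not in table: {sorted(missing)}")
    if treated_class is None:
        others = [c for c in t.classes if c != control_class]
        if len(others) != 1:
            raise ValueError("treated_class required when table has several "
                             "non-control classes")
        treated_class = others[0]
    work = collapse_technical_replicates(t, collapse) if collapse else t
    eff = dict(efficiencies or {})

    def _log2_quantity(gene: str) -> pd.Series:
        base = 1.0 + eff.get(gene, 1.0)
        return -work.cp.loc[gene] * np.log2(base)

    target_q = _log2_quantity(target)
    ref_q = pd.concat([_log2_quantity(g) for g in normalizers], axis=1).mean(axis=1)
    log_ratio = target_q - ref_q             # log2 (target / reference)
    cls = work.samples["condition_class"]
    folds = {}
    for label, wanted in (("control", control_class), ("treated", treated_class)):
        ids = cls.index[cls == wanted]
        if ids.empty:
            raise ValueError(f"no samples of class {wanted!r}")
        vals = log_ratio[ids]
        dropped = vals.isna().sum()
        if dropped:
            log.warning("%s: %d %s replicates dropped (missing Cp)",
                        target, dropped, label)
        folds[label] = vals.dropna()
    calibrator = folds["control"].mean()
    control_folds = np.exp2(folds["control"] - calibrator)
    treated_folds = np.exp2(folds["treated"] - calibrator)
    n = len(treated_folds)
    sem = float(treated_folds.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return ExpressionResult(
        target=target,
        normalizers=list(normalizers),
        control_class=control_class,
        treated_class=treated_class,
        control_folds=control_folds,
        treated_folds=treated_folds,
        mean_fold=float(treated_folds.mean()),
        sem=sem,
    )


@dataclass(frozen=True)
class NormalizerComparison:
    t_statistic: float
    p_value: float
    tier: str


def compare_normalizers(
    a: ExpressionResult,
    b: ExpressionResult,
    equal_var: bool = True,
) -> NormalizerComparison:
    """Student's t-test between two normalizer choices' treated fold changes.

    Equal-variance t by default; Welch via ``equal_var=False``.  No
    multiple-testing correction is applied across comparisons.
    """
    if a.target != b.target:
        raise ValueError("comparisons must share the target gene")
    if len(a.treated_folds) < 2 or len(b.treated_folds) < 2:
        raise ValueError("t-test needs >=2 biological replicates per side")
    if np.allclose(a.treated_folds, b.treated_folds):
        return NormalizerComparison(0.0, 1.0, "N.S.")
    res = stats.ttest_ind(a.treated_folds, b.treated_folds, equal_var=equal_var)
    return NormalizerComparison(float(res.statistic), float(res.pvalue),
                                significance_tier(float(res.pvalue)))
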