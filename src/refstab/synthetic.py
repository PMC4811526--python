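"""Seeded generator of Cp tables with known ground-truth stability.

The generator reproduces the statistical structure a reference-gene study
assumes: each biological sample carries an mRNA-loading factor common to all
genes (log2 scale; more template = lower Cp), each gene has a baseline Cp, a
condition-specific expression shift (its treatment responsiveness, the
between-group component of instability), biological noise on the log2 scale,
and technical replicate noise in cycles:

    Cp = baseline - loading + shift + bio_noise + tech_noise.

One Cp cycle equals one log2 expression unit (100% amplification
efficiency), matching the 2^-dCt transform downstream.  The ground truth
orders genes by the composite instability sqrt(sigma^2 + var_g(shift)) —
the generator's own definition of what a stability method should recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bestkeeper, genorm, normfinder
from .cp_data import CpTable, collapse_technical_replicates, to_relative_quantities


@dataclass(frozen=True)
class GeneDesign:
    """One simulated gene: baseline Cp, biological noise SD (log2 units),
    and per-condition-class Cp shifts (cycles = log2 units; positive =
    higher Cp = lower expression)."""

    name: str
    baseline_cp: float
    noise_sd: float
    responses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 10.0 <= self.baseline_cp <= 35.0:
            raise ValueError(f"{self.name}: baseline Cp outside [10, 35]")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: negative noise SD")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full study design: genes, classes with biological-replicate counts,
    technical replication, loading and technical noise, and the seed."""

    genes: tuple[GeneDesign, ...]
    classes: Mapping[str, int]
    tech_reps: int = 3
    loading_sd: float = 0.5
    tech_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tech_reps < 1:
            raise ValueError("tech_reps must be >= 1")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in design")

    @property
    def n_values(self) -> int:
        n_bio = sum(self.classes.values())
        return len(self.genes) * n_bio * self.tech_reps


@dataclass
class SyntheticTruth:
    design: SyntheticDesign
    true_instability: pd.Series        # composite, lower = more stable
    true_stability_order: list[str]    # most stable first
    loading_factors: pd.Series         # per biological sample, log2 units


def true_instability(design: SyntheticDesign) -> pd.Series:
    """Composite instability sqrt(sigma^2 + population variance of shifts).

    The shift variance is taken over all condition classes in the design
    (zero shift for unresponsive classes), population (n) denominator.
    """
    classes = list(design.classes)
    vals = {}
    for g in design.genes:
        deltas = np.array([g.responses.get(c, 0.0) for c in classes])
        vals[g.name] = float(np.sqrt(g.noise_sd ** 2 + deltas.var()))
    return pd.Series(vals, name="true_instability")


def generate(design: SyntheticDesign,
             seed: int | None = None) -> tuple[CpTable, SyntheticTruth]:
    """Draw one Cp table; bit-identical for a fixed (design, seed)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = design.genes
    k = len(genes)
    sample_ids, meta = [], []
    loading = {}
    cols = []
    for cls, n_bio in design.classes.items():
        for b in range(1, n_bio + 1):
            load = rng.normal(0.0, design.loading_sd)
            loading[f"{cls}.b{b}"] = load
            bio_noise = rng.normal(0.0, [g.noise_sd for g in genes])
            base = np.array([
                g.baseline_cp - load + g.responses.get(cls, 0.0)
                for g in genes
            ]) + bio_noise
            for r in range(1, design.tech_reps + 1):
                tech = rng.normal(0.0, design.tech_sd, size=k)
                cols.append(base + tech)
                sample_ids.append(f"{cls}.b{b}.t{r}")
                meta.append((cls, b, r))
    cp = pd.DataFrame(np.column_stack(cols),
                      index=[g.name for g in genes], columns=sample_ids)
    samples = pd.DataFrame(meta, index=sample_ids,
                           columns=["condition_class", "biological_replicate",
                                    "technical_replicate"])
    table = CpTable(cp, samples)
    inst = true_instability(design)
    order = list(inst.sort_values(kind="mergesort").index)
    truth = SyntheticTruth(
        design=design,
        true_instability=inst,
        true_stability_order=order,
        loading_factors=pd.Series(loading, name="log2_loading"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# stock designs
# ---------------------------------------------------------------------------

#: the candidate panel of a typical plant reference-gene survey; baselines
#: span the observed 17-28 cycle range, noise SDs and treatment shifts chosen
#: so that classical housekeeping genes (GAPDH, TUB6) are the least stable.
_DEFAULT_GENES = (
    GeneDesign("SAND", 25.0, 0.15),
    GeneDesign("ACT2", 22.5, 0.18),
    GeneDesign("UBC9", 21.0, 0.22),
    GeneDesign("PP2A", 24.0, 0.25),
    GeneDesign("PTBP1", 26.5, 0.25),
    GeneDesign("NCBP20", 27.0, 0.30),
    GeneDesign("TIP41", 24.5, 0.35, {"cold": 1.0, "H2O2": 0.8}),
    GeneDesign("CYP2", 27.7, 0.40, {"NaCl": 0.8}),
    GeneDesign("eIF-4a", 23.5, 0.45, {"hot": 1.0}),
    GeneDesign("EF-1a", 17.5, 0.50, {"tissue:root": 1.5, "tissue:leaf": -1.0}),
    GeneDesign("TUB6", 23.0, 0.55, {"NaCl": 2.0, "SA": 1.5, "hot": 1.5}),
    GeneDesign("GAPDH", 19.7, 0.60,
               {"PEG": 2.0, "MeJA": 1.8, "cold": 1.5, "tissue:root": 1.2}),
)

_DEFAULT_CLASSES = {
    "control": 3, "PEG": 3, "NaCl": 3, "CuSO4": 3, "H2O2": 3,
    "MeJA": 3, "SA": 3, "cold": 3, "hot": 3,
    "tissue:root": 3, "tissue:leaf": 3,
}


def default_design(seed: int = 0) -> SyntheticDesign:
    """12 genes x 11 condition classes x 3 biological x 3 technical
    replicates = 1188 Cp values, emulating a full abiotic-stress +
    hormone + tissue reference-gene survey."""
    return SyntheticDesign(genes=_DEFAULT_GENES, classes=_DEFAULT_CLASSES,
                           tech_reps=3, loading_sd=0.5, tech_sd=0.15,
                           seed=seed)


def well_separated_design(seed: int = 0, k: int = 8,
                          n_samples: int = 30) -> SyntheticDesign:
    """Benchmark design with strictly ordered noise SDs (0.1-1.5 log2 units)
    and no treatment shifts.

    All genes share one baseline so that BestKeeper's CV ranking is not
    confounded by baseline differences, and loading is kept small (SD 0.2)
    because BestKeeper operates on raw Cp and is not loading-invariant.
    """
    sds = np.linspace(0.1, 1.5, k)
    genes = tuple(GeneDesign(f"G{i+1:02d}", 24.0, float(s))
                  for i, s in enumerate(sds))
    return SyntheticDesign(genes=genes, classes={"control": n_samples},
                           tech_reps=1, loading_sd=0.2, tech_sd=0.05,
                           seed=seed)


# ---------------------------------------------------------------------------
# estimator recovery benchmarking
# ---------------------------------------------------------------------------

def _estimated_instability(table: CpTable, method: str) -> pd.Series:
    """Run one stability estimator on a generated table; higher = less stable."""
    collapsed = collapse_technical_replicates(table)
    if method == "genorm":
        q = to_relative_quantities(collapsed)
        return genorm.m_values(q)
    if method == "normfinder":
        x = normfinder.log_expression(collapsed)
        return normfinder.ungrouped_stability(x).stability
    if method == "bestkeeper":
        df = bestkeeper.rank_group(collapsed)
        return df["cv_percent"].reindex(collapsed.genes)
    raise ValueError(f"unknown method {method!r}")


def recovery_report(
    design: SyntheticDesign,
    n_seeds: int,
    seed: int = 0,
    methods: Sequence[str] = ("genorm", "normfinder", "bestkeeper"),
) -> dict:
    """Monte-Carlo benchmark: how well each method recovers the true order.

    For ``n_seeds`` independent tables, computes the Spearman correlation
    between each method's instability statistic and the design's true
    composite instability, plus how often the true two most and two least
    stable genes are exactly recovered.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    truth = true_instability(design)
    order = list(truth.sort_values(kind="mergesort").index)
    top2, bottom2 = set(order[:2]), set(order[-2:])
    rhos = {m: [] for m in methods}
    top2_hits = {m: 0 for m in methods}
    bottom2_hits = {m: 0 for m in methods}
    for i in range(n_seeds):
        table, _ = generate(design, seed=seed + i)
        for m in methods:
            est = _estimated_instability(table, m).reindex(truth.index)
            if truth.nunique() == 1:  # exchangeable genes: rho undefined
                rho = np.nan
            else:
                rho = stats.spearmanr(truth, est).statistic
            rhos[m].append(float(rho))
            est_order = list(est.sort_values(kind="mergesort").index)
            top2_hits[m] += set(est_order[:2]) == top2
            bottom2_hits[m] += set(est_order[-2:]) == bottom2
    return {
        m: {
            "spearman_mean": float(np.mean(rhos[m])),
            "spearman_sd": float(np.std(rhos[m], ddof=1))
                           if not np.isnan(rhos[m]).any() else float("nan"),
            "top2_recovery": top2_hits[m] / n_seeds,
            "bottom2_recovery": bottom2_hits[m] / n_seeds,
        }
        for m in methods
    }
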