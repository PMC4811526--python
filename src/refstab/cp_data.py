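"""Annotated crossing-point (Cp/Ct) tables: data model, I/O and transforms.

A qPCR experiment yields one Cp value per (gene, sample) reaction, where a
sample is identified by its condition class (an abiotic stress, a hormone
treatment, a tissue, or the untreated control), a biological replicate and a
technical replicate.  This module holds those values in a validated
genes x samples matrix, collapses technical replicates, subsets analysis
groups, converts Cp to relative quantities via the 2^-dCt transform, and
reads/writes delimited-text layouts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order of the long text layout
LONG_COLUMNS = ("gene", "sample", "condition_class", "bio_rep", "tech_rep", "cp")

#: sample-annotation columns of the wide layout (one extra column per gene)
WIDE_META_COLUMNS = ("sample", "condition_class", "bio_rep", "tech_rep")


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of a single qPCR observation (one well, one cDNA)."""

    sample_id: str
    condition_class: str
    biological_replicate: int
    technical_replicate: int = 1

    def __post_init__(self) -> None:
        if self.biological_replicate < 1 or self.technical_replicate < 1:
            raise ValueError(
                f"replicate indices must be positive: {self.sample_id!r}"
            )


class CpTable:
    """A genes x samples matrix of raw Cp values with sample annotations.

    Parameters
    ----------
    cp : DataFrame
        Rows indexed by gene name, columns by sample id.  Missing reactions
        are NaN; every non-missing Cp must be positive (PCR cycles).
    samples : DataFrame
        Indexed by sample id with columns ``condition_class``,
        ``biological_replicate``, ``technical_replicate``.
    """

    def __init__(self, cp: pd.DataFrame, samples: pd.DataFrame) -> None:
        cp = cp.astype(float)
        if cp.index.has_duplicates:
            raise ValueError("duplicate gene names")
        if cp.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if list(cp.columns) != list(samples.index):
            samples = samples.reindex(cp.columns)
            if samples.isna().any().any():
                raise ValueError("sample annotations do not cover all columns")
        key = samples[["condition_class", "biological_replicate",
                       "technical_replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].index.tolist()
            raise ValueError(
                f"(condition_class, bio_rep, tech_rep) not unique: {dup}"
            )
        vals = cp.to_numpy()
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("non-missing Cp values must be positive")
        self.cp = cp
        self.samples = samples

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.cp.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cp.columns)

    @property
    def classes(self) -> list[str]:
        """Condition classes in order of first appearance."""
        return list(dict.fromkeys(self.samples["condition_class"]))

    @property
    def n_values(self) -> int:
        """Count of non-missing Cp observations."""
        return int(self.cp.notna().to_numpy().sum())

    def subset(self, classes: Iterable[str]) -> "CpTable":
        """Restrict to samples whose condition class is in ``classes``."""
        wanted = set(classes)
        missing = wanted - set(self.samples["condition_class"])
        if missing:
            raise KeyError(f"condition classes not in table: {sorted(missing)}")
        keep = self.samples.index[self.samples["condition_class"].isin(wanted)]
        return CpTable(self.cp[keep], self.samples.loc[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CpTable({len(self.genes)} genes x {len(self.sample_ids)} "
                f"samples, {self.n_values} Cp values)")


@dataclass(frozen=True)
class AnalysisGroup:
    """A named set of condition classes analysed together.

    ``subgroup_labels`` optionally maps sample id -> subgroup label for
    model-based (NormFinder-style) grouped analysis; when absent, pipelines
    derive a default {control, treated} split.
    """

    name: str
    member_classes: frozenset[str]
    subgroup_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.member_classes:
            raise ValueError(f"group {self.name!r} has no member classes")


def default_groups(
    classes: Sequence[str],
    control: str = "control",
    tissue_prefix: str = "tissue:",
    include_control: bool = True,
) -> list[AnalysisGroup]:
    """Build the standard analysis groups from the condition classes present.

    One group per single treatment (treated plus, by default, the untreated
    control), one Tissue group covering all tissue classes, and a Total group
    of everything.  Membership of the control in each group is configurable
    because a stability study can be run either on treated samples alone or on
    the treated-vs-control contrast.
    """
    classes = list(dict.fromkeys(classes))
    tissues = [c for c in classes if c.startswith(tissue_prefix)]
    treatments = [c for c in classes if c != control and c not in tissues]
    groups = []
    for t in treatments:
        members = {t, control} if include_control and control in classes else {t}
        groups.append(AnalysisGroup(t, frozenset(members)))
    if tissues:
        members = set(tissues)
        if include_control and control in classes:
            members.add(control)
        groups.append(AnalysisGroup("Tissue", frozenset(members)))
    groups.append(AnalysisGroup("Total", frozenset(classes)))
    return groups


class RelativeQuantityTable:
    """Per-gene relative quantities q = (1+E)^-dCt, q in (0, 1], max per gene 1."""

    def __init__(self, q: pd.DataFrame, samples: pd.DataFrame) -> None:
        vals = q.to_numpy()
        finite = vals[np.isfinite(vals)]
        if np.any(finite <= 0):
            raise ValueError("relative quantities must be positive")
        mx = np.nanmax(vals, axis=1)
        if not np.allclose(mx, 1.0, atol=1e-9):
            raise ValueError("per-gene maximum relative quantity must be 1")
        self.q = q.astype(float)
        self.samples = samples.reindex(q.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    import csv

    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_cp_table(path, layout: str = "long", sep: str | None = None) -> CpTable:
    """Read a delimited-text Cp table.

    ``layout='long'`` expects exactly the columns
    ``gene, sample, condition_class, bio_rep, tech_rep, cp``;
    ``layout='wide'`` expects ``sample, condition_class, bio_rep, tech_rep``
    followed by one column per gene.  The delimiter is auto-detected among
    comma/tab/semicolon unless given.  Non-numeric Cp cells become missing
    with a logged warning; duplicate (gene, sample) records are an error.
    """
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=str.strip)

    if layout == "long":
        if set(df.columns) != set(LONG_COLUMNS):
            raise ValueError(
                f"long layout requires columns {list(LONG_COLUMNS)}, "
                f"got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["gene", "sample"])
        if dup.any():
            raise ValueError(
                f"duplicate (gene, sample) records: "
                f"{df.loc[dup, ['gene', 'sample']].to_records(index=False).tolist()}"
            )
        cp_num = pd.to_numeric(df["cp"], errors="coerce")
        bad = cp_num.isna() & df["cp"].notna() & (df["cp"].str.strip() != "")
        if bad.any():
            log.warning("%d non-numeric Cp cells treated as missing", bad.sum())
        n_missing = int(cp_num.isna().sum())
        if n_missing:
            log.warning("%d missing Cp values in %s", n_missing, path)
        df = df.assign(cp=cp_num)
        genes = list(dict.fromkeys(df["gene"]))
        sample_ids = list(dict.fromkeys(df["sample"]))
        cp = (df.pivot(index="gene", columns="sample", values="cp")
                .reindex(index=genes, columns=sample_ids))
        meta = (df.drop_duplicates("sample")
                  .set_index("sample")[["condition_class", "bio_rep", "tech_rep"]]
                  .reindex(sample_ids))
        samples = pd.DataFrame({
            "condition_class": meta["condition_class"],
            "biological_replicate": meta["bio_rep"].astype(int),
            "technical_replicate": meta["tech_rep"].astype(int),
        })
        cp.index.name = None
        cp.columns.name = None
        return CpTable(cp, samples)

    if layout == "wide":
        missing = set(WIDE_META_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(
                f"wide layout requires columns {list(WIDE_META_COLUMNS)} plus "
                f"one per gene; missing {sorted(missing)}"
            )
        gene_cols = [c for c in df.columns if c not in WIDE_META_COLUMNS]
        if not gene_cols:
            raise ValueError("wide layout has no gene columns")
        if df["sample"].duplicated().any():
            raise ValueError("duplicate sample rows in wide layout")
        cp = df[gene_cols].apply(pd.to_numeric, errors="coerce")
        cp.index = df["sample"]
        samples = pd.DataFrame({
            "condition_class": df["condition_class"].to_numpy(),
            "biological_replicate": df["bio_rep"].astype(int).to_numpy(),
            "technical_replicate": df["tech_rep"].astype(int).to_numpy(),
        }, index=df["sample"])
        cp = cp.T
        cp.index.name = None
        cp.columns.name = None
        samples.index.name = None
        return CpTable(cp, samples)

    raise ValueError(f"unknown layout {layout!r}")


def write_cp_table(t: CpTable, path, layout: str = "long", sep: str = ",") -> None:
    """Write a CpTable as delimited text (inverse of :func:`read_cp_table`)."""
    if layout == "long":
        rows = []
        for gene in t.genes:
            for sid in t.sample_ids:
                s = t.samples.loc[sid]
                rows.append((gene, sid, s["condition_class"],
                             s["biological_replicate"], s["technical_replicate"],
                             t.cp.at[gene, sid]))
        out = pd.DataFrame(rows, columns=LONG_COLUMNS)
        out.to_csv(path, sep=sep, index=False, float_format="%.6f")
    elif layout == "wide":
        out = t.cp.T.copy()
        out.insert(0, "tech_rep", t.samples["technical_replicate"].to_numpy())
        out.insert(0, "bio_rep", t.samples["biological_replicate"].to_numpy())
        out.insert(0, "condition_class", t.samples["condition_class"].to_numpy())
        out.insert(0, "sample", t.sample_ids)
        out.to_csv(path, sep=sep, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def collapse_technical_replicates(t: CpTable, method: str = "mean") -> CpTable:
    """Average (or take the median of) technical replicates per biological sample.

    Missing technical replicates are ignored; a cell whose replicates are all
    missing stays missing.  Output sample ids are ``<class>.b<rep>``.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    agg = np.nanmean if method == "mean" else np.nanmedian
    key = list(zip(t.samples["condition_class"],
                   t.samples["biological_replicate"]))
    order = list(dict.fromkeys(key))
    new_ids, cols, meta = [], [], []
    arr = t.cp.to_numpy()
    for cls, bio in order:
        idx = [i for i, k in enumerate(key) if k == (cls, bio)]
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cols.append(agg(arr[:, idx], axis=1))
        new_ids.append(f"{cls}.b{bio}")
        meta.append((cls, bio, 1))
    cp = pd.DataFrame(np.column_stack(cols), index=t.genes, columns=new_ids)
    samples = pd.DataFrame(meta, index=new_ids,
                           columns=["condition_class", "biological_replicate",
                                    "technical_replicate"])
    return CpTable(cp, samples)


def to_relative_quantities(
    t: CpTable,
    group: AnalysisGroup | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> RelativeQuantityTable:
    """2^-dCt transform within an analysis group.

    Per gene, dCt = Cp - min(Cp) over the group's samples and
    q = (1+E)^-dCt, so the sample with the lowest Cp (highest expression)
    gets q = 1.  The default E = 1 gives the classical 2^-dCt; per-gene
    efficiencies (fractions in (0.5, 1.5]) apply an efficiency-corrected base.
    Genes with fewer than two non-missing observations in the group are
    dropped with a warning (stability statistics are undefined for them).
    """
    sub = t if group is None else t.subset(group.member_classes)
    eff = dict(efficiencies or {})
    for g, e in eff.items():
        if not (0.5 < e <= 1.5):
            raise ValueError(f"efficiency for {g!r} out of (0.5, 1.5]: {e}")
    rows, kept = [], []
    for gene in sub.genes:
        cp = sub.cp.loc[gene]
        if cp.notna().sum() < 2:
            log.warning("gene %s dropped: <2 observations in group %s",
                        gene, group.name if group else "(all)")
            continue
        base = 1.0 + eff.get(gene, 1.0)
        dct = cp - cp.min()
        rows.append(np.power(base, -dct))
        kept.append(gene)
    if not rows:
        raise ValueError("no genes with >=2 observations in group")
    q = pd.DataFrame(rows, index=kept)
    return RelativeQuantityTable(q, sub.samples)


def summarize_cp(t: CpTable) -> pd.DataFrame:
    """Per-gene descriptive statistics of raw Cp (for box-plot style overviews).

    Returns n, mean, sd (n-1 sample SD), min, q25, median, q75, max over all
    non-missing values per gene.
    """
    recs = {}
    for gene in t.genes:
        v = t.cp.loc[gene].dropna()
        if v.empty:
            raise ValueError(f"gene {gene} has no observations")
        recs[gene] = {
            "n": int(v.size),
            "mean": v.mean(),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "min": v.min(),
            "q25": v.quantile(0.25),
            "median": v.median(),
            "q75": v.quantile(0.75),
            "max": v.max(),
        }
    return pd.DataFrame.from_dict(recs, orient="index").reindex(t.genes)
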