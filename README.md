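# refstab

Reference-gene stability analysis for quantitative real-time PCR.

Accurate qRT-PCR quantification of a gene of interest requires dividing out
sample-to-sample differences in RNA amount, RT yield and loading, which is
done by normalizing against one or more *reference* ("housekeeping") genes.
A reference gene that itself responds to the experimental treatment silently
distorts every downstream fold change, so candidate references must be
screened for expression stability first.  `refstab` implements the three
standard screening statistics side by side, decides how many reference genes
a normalization needs, and validates the choice on a target gene — starting
from nothing but a delimited-text table of raw crossing-point (Cp/Ct)
values annotated with condition class, biological and technical replicate.

## Methods at a glance

Let q<sub>ij</sub> = 2<sup>−ΔCt</sup> be gene *i*'s relative quantity in
sample *j* (ΔCt = Cp − min Cp per gene), and x<sub>ij</sub> = −Cp<sub>ij</sub>
its log2 expression.

* **geNorm** — stability M<sub>i</sub> = mean over partners *k* of
  SD<sub>j</sub>[ log2(q<sub>ij</sub>/q<sub>kj</sub>) ]; the highest-M gene
  is dropped and M recomputed until the two jointly most stable genes
  remain.  Normalization factors NF<sub>n</sub> (geometric mean of the top
  *n* genes) give the pairwise variation
  V<sub>n/n+1</sub> = SD[ log2(NF<sub>n</sub>/NF<sub>n+1</sub>) ];
  V < 0.15 means *n* genes suffice.
* **NormFinder** — fits x<sub>ij</sub> = μ<sub>i</sub> + s<sub>j</sub> +
  ε<sub>ij</sub> with gene-specific Var(ε) = σ²<sub>i</sub>, bias-corrects
  the per-gene variance estimates by method of moments, and (in grouped
  mode) adds the shrunken intergroup deviation |d̃<sub>ig</sub>|:
  ρ<sub>i</sub> = mean<sub>g</sub>( |d̃<sub>ig</sub>| +
  √(σ̂²<sub>ig</sub>/n<sub>g</sub>) ).  Lower ρ = more stable.
* **BestKeeper** — works on raw Cp: dispersion SD (mean absolute deviation
  by default, the original tool's convention) and CV% = 100·SD/mean; SD > 1
  cycle flags a gene as inconsistent.  The BestKeeper index (per-sample
  geometric-mean Cp) is correlated against each gene.
* **2<sup>−ΔΔCt</sup> validation** — fold change of a target gene under any
  single- or multi-gene normalizer, with SEM over biological replicates and
  Student's t-tests between normalizer choices.
* **Standard curves** — amplification efficiency
  E = 10<sup>−1/slope</sup> − 1 and R² from serial-dilution OLS fits.

A consensus report aggregates the three methods' competition ranks by
geometric mean (RefFinder-style).  A seeded synthetic Cp generator with
known ground-truth stability ordering makes every estimator testable
end to end; see `docs/methods.md` for the model and its limits.

## Worked example

Simulate a full survey — 12 candidate genes across control, eight stress /
hormone treatments and two tissues, 3 biological × 3 technical replicates
(1188 Cp values) — then rank stability in the salt-stress group:

```
$ refstab simulate -o demo.csv --seed 42
wrote 1188 Cp values (12 genes x 99 wells) to demo.csv

$ refstab genorm -i demo.csv -g NaCl
               M  rank
GAPDH   0.414028     1
eIF-4a  0.427231     1
SAND    0.408899     3
...
TUB6    1.453985    12
most stable pair: eIF-4a, GAPDH
V: V2/3=0.0685, V3/4=0.0518, ...
optimal number of reference genes: 2
```

Each gene's M is its mean pairwise log-ratio SD against the other
candidates at the step it was considered; rank 1–2 is the final pair the
iterative exclusion cannot separate (here TUB6, simulated with a strong
salt response, is correctly last, M ≈ 1.45, while V2/3 = 0.069 < 0.15 says
two reference genes are enough for this group).  The same table feeds
`refstab normfinder`, `refstab bestkeeper`, `refstab validate` (2^−ΔΔCt of
a target), and `refstab run-all`, which writes per-group TSV reports plus a
consensus ranking and `summary.json`.

The library API mirrors the CLI (`refstab.rank_genes`, `refstab.v_curve`,
`refstab.ungrouped_stability`, `refstab.gene_stats`, `refstab.ddct`,
`refstab.generate`, ...), operating on pandas-backed `CpTable` /
`RelativeQuantityTable` objects.

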