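"""geNorm M values, iterative ranking and the pairwise-variation curve."""
import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.genorm import m_values, pairwise_variation, rank_genes, v_curve
from refstab.synthetic import GeneDesign, SyntheticDesign


# -- independent oracles ------------------------------------------------------

def oracle_v(qj, qk):
    ratios = [math.log2(a / b) for a, b in zip(qj, qk)]
    return statistics.stdev(ratios)


def oracle_m(q: pd.DataFrame):
    genes = list(q.index)
    return {j: statistics.mean(oracle_v(q.loc[j], q.loc[k])
                               for k in genes if k != j)
            for j in genes}


def oracle_exclusion(q: pd.DataFrame):
    """Recompute every M from scratch each step (no incremental updates)."""
    remaining = list(q.index)
    order = []
    while len(remaining) > 2:
        m = oracle_m(q.loc[remaining])
        worst_val = max(m.values())
        worst = [g for g in remaining if m[g] >= worst_val - 1e-12][-1]
        order.append(worst)
        remaining.remove(worst)
    return order, remaining


# -- pairwise variation -------------------------------------------------------

@pytest.mark.parametrize("qj,qk,expected", [
    ((1, 2, 4), (2, 4, 8), 0.0),
    ((1, 2), (2, 1), 1.4142),
    ((1, 2, 2), (1, 1, 1), 0.5774),
])
def test_pairwise_variation_hand_values(qj, qk, expected):
    assert pairwise_variation(qj, qk) == pytest.approx(expected, abs=1e-4)


def test_pairwise_variation_needs_two_complete_pairs():
    with pytest.raises(ValueError):
        pairwise_variation([1.0], [2.0])
    with pytest.raises(ValueError):
        pairwise_variation([1.0, np.nan], [2.0, 1.0])


# -- M values -----------------------------------------------------------------

def test_m_hand_example():
    q = pd.DataFrame([[1, 2, 4], [2, 4, 8], [1, 1, 2]],
                     index=["A", "B", "C"], dtype=float)
    m = m_values(q)
    assert m["A"] == pytest.approx(0.2887, abs=1e-4)
    assert m["B"] == pytest.approx(0.2887, abs=1e-4)
    assert m["C"] == pytest.approx(0.5774, abs=1e-4)


def test_identical_vectors_give_zero_m():
    q = pd.DataFrame([[1, 0.5, 0.25]] * 4, index=list("ABCD"))
    assert (m_values(q) == 0).all()


def test_m_and_v_scaling_invariance():
    rng = np.random.default_rng(3)
    q = pd.DataFrame(np.exp2(rng.normal(0, 0.5, (5, 12))),
                     index=[f"G{i}" for i in range(5)])
    m0 = m_values(q)
    # multiply one gene by a positive constant
    q2 = q.copy()
    q2.loc["G2"] *= 37.5
    pd.testing.assert_series_equal(m_values(q2), m0, atol=1e-9, rtol=0)
    # per-sample scaling of all genes (loading)
    q3 = q * np.exp2(rng.normal(0, 1, 12))
    pd.testing.assert_series_equal(m_values(q3), m0, atol=1e-9, rtol=0)
    r0, r3 = rank_genes(q), rank_genes(q3)
    assert r0.exclusion_order == r3.exclusion_order
    v0, v3 = v_curve(q, r0), v_curve(q3, r3)
    assert v3.v.to_numpy() == pytest.approx(v0.v.to_numpy(), abs=1e-9)


# -- iterative ranking --------------------------------------------------------

def test_duplicated_pair_wins():
    rng = np.random.default_rng(5)
    base = np.exp2(rng.normal(0, 0.2, 10))
    q = pd.DataFrame({
        "A": base, "B": base * 3.0,  # perfectly proportional
        "C": base * np.exp2(rng.normal(0, 1.0, 10)),
        "D": base * np.exp2(rng.normal(0, 1.0, 10)),
    }).T
    res = rank_genes(q)
    assert set(res.final_pair) == {"A", "B"}
    assert res.exclusion_order[0] in {"C", "D"}


@pytest.mark.parametrize("k", [4, 5, 6])
def test_ranking_matches_bruteforce_oracle(k):
    rng = np.random.default_rng(k)
    q = pd.DataFrame(np.exp2(rng.normal(0, rng.uniform(0.1, 1, (k, 1)),
                                        (k, 15))),
                     index=[f"G{i}" for i in range(k)])
    res = rank_genes(q)
    order, pair = oracle_exclusion(q)
    assert res.exclusion_order == order
    assert list(res.final_pair) == pair


def test_tie_broken_toward_later_gene():
    # B is an exact copy of A shifted in scale; C likewise: ties everywhere
    q = pd.DataFrame([[1, 2, 4], [2, 4, 8], [0.5, 1, 2]],
                     index=["A", "B", "C"], dtype=float)
    res = rank_genes(q)
    assert res.exclusion_order == ["C"]
    assert res.final_pair == ("A", "B")


def test_competition_ranks_final_pair_shares_rank_one():
    rng = np.random.default_rng(11)
    q = pd.DataFrame(np.exp2(rng.normal(0, 0.4, (5, 10))),
                     index=[f"G{i}" for i in range(5)])
    ranks = rank_genes(q).ranks()
    assert sorted(ranks) == [1, 1, 3, 4, 5]


# -- V curve ------------------------------------------------------------------

def test_v_zero_when_next_gene_copies_nf():
    # gene ranked third = exact geometric mean of the top pair
    # => NF_2 == NF_3 => V_2/3 = 0
    from refstab.genorm import GeNormResult

    rng = np.random.default_rng(9)
    g1 = np.exp2(rng.normal(0, 0.3, 8))
    g2 = np.exp2(rng.normal(0, 0.3, 8))
    g3 = np.sqrt(g1 * g2)
    g4 = np.exp2(rng.normal(0, 1.5, 8))
    q = pd.DataFrame([g1, g2, g3, g4], index=["A", "B", "C", "D"])
    ranking = GeNormResult(group=None, genes=list("ABCD"),
                           m_values_full=m_values(q),
                           exclusion_order=["D", "C"], m_trajectory=[0, 0],
                           final_pair=("A", "B"))
    vc = v_curve(q, ranking)
    assert vc.v[2] == pytest.approx(0.0, abs=1e-12)
    assert vc.optimal_n == 2


def test_v_curve_matches_direct_oracle():
    rng = np.random.default_rng(17)
    q = pd.DataFrame(np.exp2(rng.normal(0, 0.6, (5, 12))),
                     index=[f"G{i}" for i in range(5)])
    res = rank_genes(q)
    vc = v_curve(q, res)
    order = res.stability_order
    for n in range(2, 5):
        nf_n = [statistics.geometric_mean(q.loc[order[:n], c])
                for c in q.columns]
        nf_n1 = [statistics.geometric_mean(q.loc[order[:n + 1], c])
                 for c in q.columns]
        v = statistics.stdev(math.log2(a / b) for a, b in zip(nf_n, nf_n1))
        assert vc.v[n] == pytest.approx(v, abs=1e-12)


def test_optimal_n_is_smallest_passing_else_k_minus_1():
    rng = np.random.default_rng(23)
    q = pd.DataFrame(np.exp2(rng.normal(0, 2.5, (4, 10))),
                     index=list("ABCD"))
    q = q.div(q.max(axis=1), axis=0)
    res = rank_genes(q)
    vc = v_curve(q, res, cutoff=1e-9)  # nothing passes
    assert vc.optimal_n == 3
    assert not vc.below_cutoff.any()


# -- noise-order recovery -----------------------------------------------------

def test_step0_m_order_recovers_noise_order():
    """With strictly ordered per-gene noise and no group effects, the initial
    M ordering matches the true SD ordering in >= 90% of seeds (k=4, n=30;
    panel size set by a power analysis of what n=30 can resolve)."""
    sds = np.linspace(0.1, 1.2, 4)
    genes = tuple(GeneDesign(f"G{i}", 24.0, float(s))
                  for i, s in enumerate(sds))
    design = SyntheticDesign(genes=genes, classes={"c": 30}, tech_reps=1,
                             loading_sd=0.5, tech_sd=0.0)
    hits = 0
    for s in range(50):
        table, _ = rs.generate(design, seed=1000 + s)
        m = m_values(rs.to_relative_quantities(table))
        hits += list(m.sort_values().index) == [g.name for g in genes]
    assert hits / 50 >= 0.9
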