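"""Cp-table data model, I/O round trips and the 2^-dCt transform."""
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.cp_data import (AnalysisGroup, CpTable,
                             collapse_technical_replicates, default_groups,
                             read_cp_table, summarize_cp,
                             to_relative_quantities, write_cp_table)
from .conftest import make_table


class TestValidation:
    def test_rejects_nonpositive_cp(self):
        with pytest.raises(ValueError, match="positive"):
            make_table([[20.0, -1.0]])

    def test_rejects_duplicate_replicate_annotation(self):
        with pytest.raises(ValueError, match="not unique"):
            make_table([[20, 21]], bio=[1, 1])

    def test_minimal_single_cell_table(self):
        t = make_table([[20.0]])
        assert t.n_values == 1
        assert t.genes == ["G1"]


@pytest.mark.parametrize("layout", ["long", "wide"])
@pytest.mark.parametrize("sep", [",", "\t", ";"])
def test_roundtrip_preserves_values_and_annotations(tmp_path, layout, sep):
    rng = np.random.default_rng(7)
    t = make_table(rng.uniform(15, 30, size=(3, 6)),
                   classes=["control"] * 3 + ["PEG"] * 3,
                   bio=[1, 2, 3, 1, 2, 3])
    t.cp.iloc[1, 2] = np.nan
    path = tmp_path / "cp.txt"
    write_cp_table(t, path, layout=layout, sep=sep)
    # delimiter auto-detected, not passed
    back = read_cp_table(path, layout=layout)
    pd.testing.assert_frame_equal(back.cp, t.cp, atol=1e-6, rtol=0,
                                  check_names=False)
    assert list(back.samples["condition_class"]) == \
        list(t.samples["condition_class"])
    assert list(back.samples["biological_replicate"]) == \
        list(t.samples["biological_replicate"])


def test_read_long_errors_and_missing(tmp_path, caplog):
    p = tmp_path / "bad_cols.csv"
    p.write_text("gene,sample,condition_class,bio_rep,tech_rep,cq\nA,s1,c,1,1,20\n")
    with pytest.raises(ValueError, match="long layout requires columns"):
        read_cp_table(p, layout="long")

    p2 = tmp_path / "dup.csv"
    p2.write_text("gene,sample,condition_class,bio_rep,tech_rep,cp\n"
                  "A,s1,c,1,1,20\nA,s1,c,1,1,21\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_cp_table(p2, layout="long")

    p3 = tmp_path / "blank.csv"
    p3.write_text("gene,sample,condition_class,bio_rep,tech_rep,cp\n"
                  "A,s1,c,1,1,20\nA,s2,c,2,1,\n")
    with caplog.at_level(logging.WARNING):
        t = read_cp_table(p3, layout="long")
    assert t.n_values == 1
    assert "missing" in caplog.text


class TestCollapse:
    def test_mean_median_and_missing(self):
        t = make_table([[20.0, 20.0, 23.0]], bio=[1, 1, 1], tech=[1, 2, 3])
        assert collapse_technical_replicates(t, "mean").cp.iloc[0, 0] == \
            pytest.approx(21.0)
        assert collapse_technical_replicates(t, "median").cp.iloc[0, 0] == \
            pytest.approx(20.0)
        t2 = make_table([[21.0, np.nan, 23.0]], bio=[1, 1, 1], tech=[1, 2, 3])
        assert collapse_technical_replicates(t2).cp.iloc[0, 0] == \
            pytest.approx(22.0)

    def test_all_missing_cell_stays_missing(self):
        t = make_table([[np.nan, np.nan], [20.0, 21.0]],
                       bio=[1, 1], tech=[1, 2])
        out = collapse_technical_replicates(t)
        assert np.isnan(out.cp.iloc[0, 0])
        assert out.cp.iloc[1, 0] == pytest.approx(20.5)

    def test_one_column_per_biological_sample(self):
        t = make_table(np.full((2, 6), 20.0), bio=[1, 1, 1, 2, 2, 2],
                       tech=[1, 2, 3, 1, 2, 3])
        out = collapse_technical_replicates(t)
        assert len(out.sample_ids) == 2


class TestRelativeQuantities:
    def test_powers_of_two(self):
        t = make_table([[20.0, 21.0, 23.0]])
        q = to_relative_quantities(t).q.iloc[0]
        assert list(q) == pytest.approx([1.0, 0.5, 0.125])

    def test_efficiency_corrected_base(self):
        t = make_table([[20.0, 21.0]])
        q = to_relative_quantities(t, efficiencies={"G1": 0.9}).q.iloc[0]
        assert list(q) == pytest.approx([1.0, 1 / 1.9])

    def test_constant_cp_gives_all_ones(self):
        t = make_table([[22.0] * 4])
        assert (to_relative_quantities(t).q.iloc[0] == 1.0).all()

    def test_gene_with_single_observation_dropped(self, caplog):
        t = make_table([[20.0, 21.0], [19.0, np.nan]])
        with caplog.at_level(logging.WARNING):
            q = to_relative_quantities(t)
        assert q.genes == ["G1"]
        assert "dropped" in caplog.text

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=12, max_value=34), min_size=3,
                    max_size=10),
           st.floats(min_value=-3, max_value=3))
    def test_per_gene_shift_preserves_ranking(self, cps, shift):
        t = make_table([cps])
        q1 = to_relative_quantities(t).q.iloc[0]
        t2 = make_table([list(np.asarray(cps) + abs(shift) + 0.1)])
        q2 = to_relative_quantities(t2).q.iloc[0]
        assert np.nanmax(q1) == pytest.approx(1.0)
        # ranking of samples unchanged by a per-gene additive Cp constant
        assert list(q1.rank(method="first")) == list(q2.rank(method="first"))


class TestSummarize:
    def test_symmetric_triple(self):
        s = summarize_cp(make_table([[20.0, 21.0, 22.0]])).loc["G1"]
        assert s["mean"] == pytest.approx(21.0)
        assert s["sd"] == pytest.approx(1.0)
        assert (s["min"], s["max"], s["median"]) == (20.0, 22.0, 21.0)

    def test_collapse_then_summarize_matches_direct_formula(self):
        # 3-gene hand fixture: collapse tech reps, then summary must equal
        # statistics computed directly on the per-biological means
        cp = [[20, 20, 23, 24, 25, 26],
              [18, 19, 20, 21, 22, 23],
              [30, 30, 30, 28, 28, 28]]
        t = make_table(cp, bio=[1, 1, 1, 2, 2, 2], tech=[1, 2, 3, 1, 2, 3])
        s = summarize_cp(collapse_technical_replicates(t))
        direct = np.array([[np.mean(r[:3]), np.mean(r[3:])] for r in cp])
        assert s["mean"].to_numpy() == pytest.approx(direct.mean(axis=1))
        assert s["sd"].to_numpy() == pytest.approx(direct.std(axis=1, ddof=1))


class TestGroups:
    def test_default_groups_structure(self):
        classes = ["control", "PEG", "NaCl", "tissue:root", "tissue:leaf"]
        groups = {g.name: g for g in default_groups(classes)}
        assert set(groups) == {"PEG", "NaCl", "Tissue", "Total"}
        assert groups["PEG"].member_classes == frozenset({"PEG", "control"})
        assert groups["Total"].member_classes == frozenset(classes)
        assert "tissue:root" in groups["Tissue"].member_classes

    def test_subset_unknown_class_raises(self):
        t = make_table([[20, 21]])
        with pytest.raises(KeyError):
            t.subset({"PEG"})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            AnalysisGroup("x", frozenset())
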