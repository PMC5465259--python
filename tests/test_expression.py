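"""Comparative-CT arithmetic and the expression table contract."""
from __future__ import annotations

import logging
import math
import random

import pytest
from hypothesis import given, strategies as st

from trioqpcr import (ComputationError, CtRecord, aggregate_replicates,
                      delta_ct, delta_delta_ct, expression_table, fold_change)

from conftest import REF, ct_records_for_sample

finite = st.floats(min_value=-30, max_value=30, allow_nan=False)


@pytest.mark.parametrize("cts,mean,sd", [
    ([24.9, 25.0, 25.1], 25.0, 0.1),
    ([30.0], 30.0, 0.0),
    ([20.0, 20.0, 20.0], 20.0, 0.0),
])
def test_replicate_aggregation(cts, mean, sd):
    recs = [CtRecord("P1", "shoot", "stress", "gA", i + 1, ct)
            for i, ct in enumerate(cts)]
    out = aggregate_replicates(recs)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["ct_mean"] == pytest.approx(mean)
    assert row["ct_sd"] == pytest.approx(sd)
    assert row["n_replicates"] == len(cts)


@pytest.mark.parametrize("target,ref,expected", [
    (25.0, 20.0, 5.0), (20.0, 20.0, 0.0), (18.5, 20.0, -1.5),
])
def test_delta_ct(target, ref, expected):
    assert delta_ct(target, ref) == expected


@pytest.mark.parametrize("s,c,expected", [
    (5.0, 5.0, 0.0), (4.0, 5.0, -1.0), (7.25, 5.0, 2.25),
])
def test_delta_delta_ct(s, c, expected):
    assert delta_delta_ct(s, c) == expected


@pytest.mark.parametrize("ddct,expected", [
    (0.0, 1.0), (-1.0, 2.0), (3.0, 0.125),
])
def test_fold_change(ddct, expected):
    assert fold_change(ddct) == expected


@pytest.mark.parametrize("fn,args", [
    (delta_ct, (math.nan, 20.0)), (delta_delta_ct, (5.0, math.inf)),
    (fold_change, (math.nan,)),
])
def test_nonfinite_inputs_rejected(fn, args):
    with pytest.raises(ComputationError):
        fn(*args)


@given(finite)
def test_no_change_between_conditions_gives_unity_fold(x):
    assert fold_change(delta_delta_ct(x, x)) == 1.0


@given(st.floats(min_value=-20, max_value=20, allow_nan=False))
def test_log2_of_fold_change_is_minus_ddct(ddct):
    assert math.log2(fold_change(ddct)) == pytest.approx(-ddct, abs=1e-12)


def test_fold_change_strictly_decreasing():
    grid = [(-5 + i) * 0.5 for i in range(21)]
    folds = [fold_change(x) for x in grid]
    assert all(a > b for a, b in zip(folds, folds[1:]))


class TestExpressionTable:
    def test_complete_fixture_row_count(self):
        recs = []
        for genotype in ("P1", "P2"):
            recs += ct_records_for_sample(genotype, "shoot",
                                          {"gA": 2.0, "gB": 0.5})
        out = expression_table(recs, REF)
        assert len(out) == 4
        by_key = {(r.genotype_id, r.gene_id): r for r in out}
        assert by_key[("P1", "gA")].rel_abundance == pytest.approx(2.0, rel=1e-12)
        assert by_key[("P1", "gB")].log2_rel_abundance == pytest.approx(-1.0,
                                                                        rel=1e-12)

    def test_missing_condition_omits_and_warns(self, caplog):
        recs = ct_records_for_sample("P1", "shoot", {"gA": 2.0, "gB": 4.0})
        recs = [r for r in recs
                if not (r.gene_id == "gB" and r.condition.value == "control")]
        with caplog.at_level(logging.WARNING, logger="trioqpcr"):
            out = expression_table(recs, REF)
        assert [r.gene_id for r in out] == ["gA"]
        assert "gB" in caplog.text

    def test_identical_cts_give_unity(self):
        recs = [CtRecord("P1", "shoot", cond, gene, rep, 25.0)
                for cond in ("stress", "control")
                for gene in ("gA", REF) for rep in (1, 2, 3)]
        out = expression_table(recs, REF)
        assert len(out) == 1
        assert out[0].rel_abundance == 1.0

    def test_permutation_invariance(self):
        recs = []
        for genotype, rel in (("P1", 3.0), ("P2", 0.25), ("H1", 1.5)):
            for tissue in ("shoot", "root"):
                recs += ct_records_for_sample(genotype, tissue,
                                              {"gA": rel, "gB": rel * 2})
        base = expression_table(recs, REF)
        shuffled = recs[:]
        random.Random(7).shuffle(shuffled)
        assert expression_table(shuffled, REF) == base
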