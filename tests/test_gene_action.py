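"""The d/a dominance ratio, its classification, and the summary tallies."""
from __future__ import annotations

import math

import pytest
from hypothesis import given, strategies as st

from trioqpcr import (ActionClass, Direction, GeneActionResult, PedigreeEntry,
                      RelativeExpression, classify_gene_action, da_ratio,
                      gene_action_table, mid_parent, nonadditive_fraction,
                      tally_influence)
from trioqpcr.datasets import study_pedigree

pheno = st.floats(min_value=-100, max_value=100, allow_nan=False)


@pytest.mark.parametrize("p1,p2,expected", [
    (4.0, 2.0, 3.0), (7.5, 7.5, 7.5), (0.0, 10.0, 5.0),
])
def test_mid_parent(p1, p2, expected):
    assert mid_parent(p1, p2) == expected


@pytest.mark.parametrize("p1,p2,f1,mu,d,a,r", [
    (10.0, 2.0, 10.0, 6.0, 4.0, 4.0, 1.0),    # F1 = maternal parent
    (10.0, 2.0, 2.0, 6.0, -4.0, 4.0, -1.0),   # F1 = paternal parent
    (10.0, 2.0, 6.0, 6.0, 0.0, 4.0, 0.0),     # F1 = mid-parent
    (4.0, 2.0, 5.0, 3.0, 2.0, 1.0, 2.0),      # beyond the maternal parent
])
def test_da_ratio_components(p1, p2, f1, mu, d, a, r):
    assert da_ratio(p1, p2, f1) == (mu, d, a, r)


def test_da_ratio_undefined_for_equal_parents():
    mu, d, a, r = da_ratio(3.0, 3.0, 5.0)
    assert (mu, d, a) == (3.0, 2.0, 0.0)
    assert math.isnan(r)


@pytest.mark.parametrize("p1,p2,f1,klass,direction", [
    (10.0, 2.0, 10.0, ActionClass.DOMINANT, Direction.MATERNAL),
    (10.0, 2.0, 2.0, ActionClass.DOMINANT, Direction.PATERNAL),
    (10.0, 2.0, 6.0, ActionClass.ADDITIVE, Direction.NONE),
    (2.0, 4.0, 5.0, ActionClass.OVERDOMINANT, Direction.PATERNAL),
    (4.0, 2.0, 3.5, ActionClass.ADDITIVE, Direction.NONE),   # r = 0.5 boundary
    (4.0, 2.0, 4.0, ActionClass.DOMINANT, Direction.MATERNAL),  # r = 1 boundary
    (4.0, 2.0, 4.5, ActionClass.OVERDOMINANT, Direction.MATERNAL),
    (2.0, 4.0, 1.5, ActionClass.OVERDOMINANT, Direction.MATERNAL),  # below both
])
def test_classification_cases(p1, p2, f1, klass, direction):
    mu, d, a, _ = da_ratio(p1, p2, f1)
    assert classify_gene_action(d, a) == (klass, direction)


def test_degenerate_parents():
    assert classify_gene_action(d=0.0, a=0.0) == (ActionClass.ADDITIVE,
                                                  Direction.NONE)
    assert classify_gene_action(d=2.0, a=0.0) == (ActionClass.UNDETERMINED,
                                                  Direction.NONE)


@given(pheno, pheno, pheno)
def test_parent_swap_antisymmetry(p1, p2, f1):
    """Swapping maternal and paternal labels negates a and d/a, keeps mu and
    d, preserves the class and swaps the direction."""
    mu1, d1, a1, r1 = da_ratio(p1, p2, f1)
    mu2, d2, a2, r2 = da_ratio(p2, p1, f1)
    assert mu2 == mu1 and d2 == d1
    assert a2 == pytest.approx(-a1, rel=1e-12, abs=1e-12)
    if abs(a1) > 1e-6:
        assert r2 == pytest.approx(-r1, rel=1e-9, abs=1e-12)
        if min(abs(abs(r1) - 0.5), abs(abs(r1) - 1.0)) < 1e-9:
            return  # exactly on a class boundary: rounding may flip the call
        c1, dir1 = classify_gene_action(d1, a1)
        c2, dir2 = classify_gene_action(d2, a2)
        assert c1 == c2
        swap = {Direction.MATERNAL: Direction.PATERNAL,
                Direction.PATERNAL: Direction.MATERNAL,
                Direction.NONE: Direction.NONE}
        assert dir2 == swap[dir1]


@given(pheno, pheno, pheno,
       st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
def test_scale_invariance_of_ratio(p1, p2, f1, lam):
    """Multiplying all three phenotypes by a positive factor leaves d/a
    unchanged (the ratio is scale-free on the linear scale)."""
    _, d, a, r = da_ratio(p1, p2, f1)
    _, ds, as_, rs = da_ratio(lam * p1, lam * p2, lam * f1)
    if abs(a) > 1e-6 and abs(as_) > 1e-9:
        assert rs == pytest.approx(r, rel=1e-9, abs=1e-12)


def _expr(genotype, tissue, gene, rel):
    return RelativeExpression(genotype, tissue, gene, 0.0, 0.0, 0.0,
                              rel, math.log2(rel))


class TestGeneActionTable:
    pedigree = [PedigreeEntry("H1", "P1", "P2")]

    def test_identity_trio_is_additive(self):
        expr = [_expr(g, "shoot", "gA", 1.0) for g in ("P1", "P2", "H1")]
        (res,) = gene_action_table(expr, self.pedigree)
        assert res.action_class is ActionClass.ADDITIVE
        assert res.direction is Direction.NONE
        assert math.isnan(res.da_ratio)  # equal parents: ratio undefined

    def test_full_design_count(self):
        pedigree = study_pedigree()
        genotypes = {p for e in pedigree for p in
                     (e.hybrid_id, e.maternal_id, e.paternal_id)}
        genes = [f"g{i}" for i in range(3)]
        expr = [_expr(g, t, gene, 1.0 + 0.1 * i)
                for i, g in enumerate(sorted(genotypes))
                for t in ("shoot", "root") for gene in genes]
        results = gene_action_table(expr, pedigree)
        assert len(results) == 5 * 2 * 3

    def test_incomplete_trio_omitted_with_warning(self, caplog):
        expr = [_expr("P1", "shoot", "gA", 2.0), _expr("H1", "shoot", "gA", 3.0)]
        import logging
        with caplog.at_level(logging.WARNING, logger="trioqpcr"):
            assert gene_action_table(expr, self.pedigree) == []
        assert "H1" in caplog.text

    def test_absent_hybrid_skipped_with_warning(self, caplog):
        expr = [_expr("P1", "shoot", "gA", 2.0), _expr("P2", "shoot", "gA", 1.0)]
        import logging
        with caplog.at_level(logging.WARNING, logger="trioqpcr"):
            assert gene_action_table(expr, self.pedigree) == []
        assert "H1" in caplog.text

    def test_log2_scale_uses_log_phenotype(self):
        expr = [_expr("P1", "shoot", "gA", 8.0), _expr("P2", "shoot", "gA", 2.0),
                _expr("H1", "shoot", "gA", 4.0)]
        (lin,) = gene_action_table(expr, self.pedigree, scale="linear")
        (log,) = gene_action_table(expr, self.pedigree, scale="log2")
        # log2 phenotypes are 3, 1, 2: exactly mid-parent on that scale
        assert log.da_ratio == 0.0
        assert lin.da_ratio == pytest.approx(-1 / 3)


def _result(klass, direction, hybrid="H1", tissue="shoot", gene="gA"):
    return GeneActionResult(hybrid, tissue, gene, "", 1.0, 2.0, 1.5, 1.5,
                            0.0, -0.5, 0.0, klass, direction, "linear", False)


class TestTallies:
    def test_basic_counts(self):
        results = [_result(ActionClass.DOMINANT, Direction.MATERNAL),
                   _result(ActionClass.OVERDOMINANT, Direction.PATERNAL),
                   _result(ActionClass.ADDITIVE, Direction.NONE)]
        (t,) = tally_influence(results)
        assert (t.n_maternal, t.n_paternal, t.n_additive, t.n_undetermined) \
            == (1, 1, 1, 0)
        assert t.n_total == 3

    def test_partition_conserves_totals(self):
        results = [
            _result(ActionClass.DOMINANT, Direction.MATERNAL, hybrid="H1"),
            _result(ActionClass.DOMINANT, Direction.PATERNAL, hybrid="H2"),
            _result(ActionClass.ADDITIVE, Direction.NONE, hybrid="H2"),
            _result(ActionClass.UNDETERMINED, Direction.NONE, hybrid="H3"),
        ]
        (overall,) = tally_influence(results)
        groups = tally_influence(results, by="hybrid_id")
        assert len(groups) == 3
        for f in ("n_maternal", "n_paternal", "n_additive", "n_undetermined",
                  "n_total"):
            assert sum(getattr(g, f) for g in groups) == getattr(overall, f)

    def test_all_additive(self):
        results = [_result(ActionClass.ADDITIVE, Direction.NONE, gene=g)
                   for g in ("gA", "gB")]
        (t,) = tally_influence(results)
        assert t.n_maternal == t.n_paternal == 0 and t.n_additive == 2

    def test_empty_input(self):
        assert tally_influence([]) == []


def test_nonadditive_fraction():
    results = [_result(ActionClass.DOMINANT, Direction.MATERNAL),
               _result(ActionClass.ADDITIVE, Direction.NONE)]
    assert nonadditive_fraction(results) == 0.5
    assert nonadditive_fraction([_result(ActionClass.ADDITIVE,
                                         Direction.NONE)]) == 0.0
    assert nonadditive_fraction([_result(ActionClass.OVERDOMINANT,
                                         Direction.MATERNAL)]) == 1.0
    assert math.isnan(nonadditive_fraction([]))
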