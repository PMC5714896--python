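from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polyqnet.config import AnalysisConfig
from polyqnet.datatypes import ConsensusMatrix
from polyqnet.relationships import (
    direct_coexpression,
    functional_overlap,
    gene_family_overlap,
    polyq_mean_expression,
    relationship_table,
    shared_partner_test,
)


def hypergeom_upper_tail(k, N, K, n):
    """Exact P(X >= k) by rational enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def test_full_overlap_closed_form():
    a = {f"g{i}" for i in range(5)}
    overlap, p = shared_partner_test(a, set(a), background_n=20)
    assert overlap == 5
    assert p == pytest.approx(1 / comb(20, 5), rel=1e-12)


def test_zero_overlap_gives_p_one():
    overlap, p = shared_partner_test({"a", "b"}, {"c", "d"}, background_n=10)
    assert overlap == 0 and p == pytest.approx(1.0)


def test_half_probability_enumeration_case():
    a = {f"a{i}" for i in range(2)} | {f"s{i}" for i in range(3)}
    b = {f"b{i}" for i in range(2)} | {f"s{i}" for i in range(3)}
    overlap, p = shared_partner_test(a, b, background_n=10)
    assert overlap == 3
    assert p == pytest.approx(0.5, rel=1e-12)


def test_background_smaller_than_union_errors():
    with pytest.raises(ValueError, match="background"):
        shared_partner_test({"a", "b", "c"}, {"d", "e"}, background_n=4)


def test_symmetry():
    rng = np.random.default_rng(0)
    pool = [f"g{i}" for i in range(30)]
    a = set(rng.choice(pool, 12, replace=False))
    b = set(rng.choice(pool, 9, replace=False))
    assert shared_partner_test(a, b, 30) == shared_partner_test(b, a, 30)


def test_fisher_monotone_in_overlap():
    """With fixed margins, a larger overlap is strictly more surprising."""
    N, ka, kb = 40, 10, 8
    last = 2.0
    for k in range(0, min(ka, kb) + 1):
        a = {f"s{i}" for i in range(k)} | {f"a{i}" for i in range(ka - k)}
        b = {f"s{i}" for i in range(k)} | {f"b{i}" for i in range(kb - k)}
        _, p = shared_partner_test(a, b, N)
        assert p < last
        last = p


@given(
    N=st.integers(2, 60),
    data=st.data(),
)
def test_fisher_matches_enumeration(N, data):
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k_max = min(K, n)
    k = data.draw(st.integers(0, k_max)) if k_max else 0
    p_enum = hypergeom_upper_tail(k, N, K, n)
    from scipy.stats import hypergeom

    p = float(hypergeom.sf(k - 1, N, K, n))
    assert p == pytest.approx(p_enum, rel=1e-10, abs=1e-300)


@pytest.mark.parametrize("count,expected", [(10, True), (9, False)])
def test_functional_overlap_boundary(count, expected):
    terms_a = {f"t{i}" for i in range(count)} | {"extra_a"}
    terms_b = {f"t{i}" for i in range(count)} | {"extra_b"}
    n, flag = functional_overlap(terms_a, terms_b, min_shared_terms=10)
    assert n == count and flag is expected


def test_functional_overlap_empty_sets():
    assert functional_overlap(set(), {"t1"}) == (0, False)


def test_direct_coexpression_rejects_self_pair():
    cons = ConsensusMatrix(pd.Index(["a", "b"]), np.eye(2), 1, "roi")
    with pytest.raises(ValueError, match="distinct"):
        direct_coexpression(cons, ("a", "a"))


def _nine_gene_setup(rng, coupled=()):
    polyq = [f"P{i}" for i in range(9)]
    others = [f"g{i}" for i in range(60)]
    genes = polyq + others
    m = np.eye(len(genes))
    for a, b in coupled:
        ia, ib = genes.index(a), genes.index(b)
        m[ia, ib] = m[ib, ia] = 0.8
    cons = ConsensusMatrix(pd.Index(genes), m, 6, "roi")
    partner_sets = {p: set() for p in polyq}
    term_sets = {p: set() for p in polyq}
    return polyq, genes, cons, partner_sets, term_sets


def test_relationship_table_has_36_pairs_all_flags_false_when_empty():
    rng = np.random.default_rng(0)
    polyq, genes, cons, partners, terms = _nine_gene_setup(rng)
    table = relationship_table(cons, partners, terms, set(genes), polyq_genes=polyq)
    assert len(table) == 36
    assert not table["direct_flag"].any()
    assert not table["shared_flag"].any()
    assert not table["functional_flag"].any()
    assert (table["fisher_p"] == 1.0).all()


def test_relationship_table_excludes_pair_from_sets_and_background():
    polyq, genes, cons, partners, terms = _nine_gene_setup(np.random.default_rng(1))
    # P0 and P1 list each other and share the same 5 partners
    shared = {f"g{i}" for i in range(5)}
    partners["P0"] = shared | {"P1"}
    partners["P1"] = shared | {"P0"}
    cfg = AnalysisConfig()
    table = relationship_table(cons, partners, terms, set(genes), cfg, polyq)
    row = table[(table.gene_a == "P0") & (table.gene_b == "P1")].iloc[0]
    assert row["shared_count"] == 5
    expected = hypergeom_upper_tail(5, len(genes) - 2, 5, 5)
    assert row["fisher_p"] == pytest.approx(expected, rel=1e-10)
    cfg2 = AnalysisConfig(exclude_pair_from_partner_sets=False)
    table2 = relationship_table(cons, partners, terms, set(genes), cfg2, polyq)
    row2 = table2[(table2.gene_a == "P0") & (table2.gene_b == "P1")].iloc[0]
    # margins now include the seed genes themselves and the full universe
    assert row2["shared_count"] == 5
    assert row2["fisher_p"] == pytest.approx(
        hypergeom_upper_tail(5, len(genes), 6, 6), rel=1e-10
    )


def test_planted_triangle_flags_all_three_tiers(small_planted):
    """Three seed genes in one block form a clique in every representation."""
    from polyqnet.coexpression import coexpression_partners, region_consensus
    from polyqnet.datatypes import symbol_to_gene_id
    from polyqnet.enrichment import term_sets_for_polyq
    from polyqnet.probes import select_probes

    spec, dataset, genesets = small_planted
    cfg = AnalysisConfig()
    gene_exprs, _ = select_probes(list(dataset.donors.values()), dataset.probes, cfg)
    subset = dataset.samples[dataset.samples["structure_label"] == "HD_region"]
    cons = region_consensus(gene_exprs, subset, "HD_region", cfg)
    sym_map = symbol_to_gene_id(dataset.probes)
    polyq_ids = [sym_map[s] for s in cfg.polyq_genes]
    partners = {
        pid: coexpression_partners(cons, pid, cfg.coexpr_threshold) for pid in polyq_ids
    }
    universe = set(cons.genes)
    term_sets, _ = term_sets_for_polyq(partners, universe, genesets, cfg)
    table = relationship_table(cons, partners, term_sets, universe, cfg, polyq_ids)
    trio = {sym_map[s] for s in ("ATN1", "ATXN2", "HTT")}
    sub = table[table.gene_a.isin(trio) & table.gene_b.isin(trio)]
    assert len(sub) == 3
    assert sub["shared_flag"].all()
    assert sub["functional_flag"].all()
    assert sub["direct_flag"].all()


def test_gene_family_overlap_counts():
    rng = np.random.default_rng(3)
    family = {f"UBE2_{i}" for i in range(41)}
    partners = set(list(family)[:8]) | {f"x{i}" for i in range(20)}
    members, count = gene_family_overlap(partners, family)
    assert count == 8 and len(members) == 8
    assert gene_family_overlap({"a"}, {"b"})[1] == 0
    assert gene_family_overlap(family | {"y"}, family)[1] == len(family)
    with pytest.raises(ValueError, match="empty"):
        gene_family_overlap(partners, set())


def test_polyq_mean_expression_is_mean_of_donor_means():
    from tests.test_coexpression import gene_expr

    ge1 = gene_expr("d1", {"a": [1.0, 3.0], "b": [2.0, 2.0]})
    ge2 = gene_expr("d2", {"a": [5.0], "b": [0.0]})
    region = pd.concat([ge1.samples, ge2.samples], ignore_index=True)
    means = polyq_mean_expression({"d1": ge1, "d2": ge2}, region, ["a", "b"])
    assert means["a"] == pytest.approx((2.0 + 5.0) / 2)
    assert means["b"] == pytest.approx(1.0)
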