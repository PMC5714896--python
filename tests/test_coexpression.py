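import numpy as np
import pandas as pd
import pytest

from polyqnet.config import AnalysisConfig
from polyqnet.coexpression import (
    build_network,
    coexpression_partners,
    consensus_matrix,
    donor_correlation_matrix,
    load_consensus,
    region_consensus,
    save_consensus,
    threshold_sweep,
)
from polyqnet.datatypes import ConsensusMatrix, GeneExpression


def gene_expr(donor_id, values: dict):
    first = next(iter(values.values()))
    sample_ids = [f"{donor_id}_s{i}" for i in range(len(first))]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": donor_id,
            "structure_label": "x",
            "mni_x": 0.0,
            "mni_y": 0.0,
            "mni_z": 0.0,
        }
    )
    expr = pd.DataFrame(
        np.array([np.asarray(v, dtype=float) for v in values.values()]),
        index=list(values),
        columns=sample_ids,
    )
    return GeneExpression(donor_id=donor_id, expression=expr, samples=samples)


def make_consensus(matrix, genes, region="roi"):
    return ConsensusMatrix(
        genes=pd.Index(genes), values=np.asarray(matrix, dtype=float),
        n_donors_used=1, region_name=region,
    )


def test_pearson_examples():
    ge = gene_expr(
        "d1",
        {
            "a": [1, 2, 3, 4],
            "b": [2, 4, 6, 8],
            "c": [4, 3, 2, 1],
            "d": [1, 3, 2, 4],
        },
    )
    corr = donor_correlation_matrix(ge, ge.expression.columns)
    idx = {g: i for i, g in enumerate(ge.expression.index)}
    assert corr[idx["a"], idx["b"]] == pytest.approx(1.0)
    assert corr[idx["a"], idx["c"]] == pytest.approx(-1.0)
    assert corr[idx["a"], idx["d"]] == pytest.approx(0.8)


def test_pearson_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    values = {f"g{i}": rng.normal(size=15) for i in range(20)}
    ge = gene_expr("d1", values)
    corr = donor_correlation_matrix(ge, ge.expression.columns)
    mat = ge.expression.to_numpy()
    for i in range(20):
        for j in range(20):
            xi, xj = mat[i], mat[j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            assert abs(corr[i, j] - num / den) < 1e-12


def test_zero_variance_gene_gets_zero_correlations():
    ge = gene_expr("d1", {"a": [1, 2, 3], "flat": [5, 5, 5]})
    corr = donor_correlation_matrix(ge, ge.expression.columns)
    assert corr[0, 1] == 0.0 and corr[1, 0] == 0.0
    assert corr[1, 1] == 1.0


def test_subset_too_small_errors():
    ge = gene_expr("d1", {"a": [1, 2, 3]})
    with pytest.raises(ValueError, match=">= 3"):
        donor_correlation_matrix(ge, ge.expression.columns[:2])


def test_consensus_is_entrywise_mean():
    m1 = np.array([[1.0, 0.6], [0.6, 1.0]])
    m2 = np.array([[1.0, 0.4], [0.4, 1.0]])
    cons = consensus_matrix({"d1": m1, "d2": m2}, ["a", "b"])
    assert cons.r("a", "b") == pytest.approx(0.5)
    assert cons.n_donors_used == 2
    single = consensus_matrix({"d1": m1}, ["a", "b"])
    np.testing.assert_allclose(single.values, m1)
    with pytest.raises(ValueError, match="no donor"):
        consensus_matrix({}, ["a"])


def test_consensus_symmetry_and_unit_diagonal():
    rng = np.random.default_rng(1)
    mats = {}
    for d in range(4):
        ge = gene_expr(f"d{d}", {f"g{i}": rng.normal(size=10) for i in range(6)})
        mats[f"d{d}"] = donor_correlation_matrix(ge, ge.expression.columns)
    cons = consensus_matrix(mats, [f"g{i}" for i in range(6)])
    np.testing.assert_allclose(cons.values, cons.values.T)
    np.testing.assert_allclose(np.diag(cons.values), 1.0)
    assert (np.abs(cons.values) <= 1.0 + 1e-12).all()


def test_fisher_z_mode_differs_but_agrees_in_sign():
    m1 = np.array([[1.0, 0.9], [0.9, 1.0]])
    m2 = np.array([[1.0, 0.1], [0.1, 1.0]])
    plain = consensus_matrix({"a": m1, "b": m2}, ["x", "y"])
    zmode = consensus_matrix({"a": m1, "b": m2}, ["x", "y"], fisher_z=True)
    assert plain.r("x", "y") == pytest.approx(0.5)
    assert zmode.r("x", "y") != pytest.approx(0.5)
    assert zmode.r("x", "y") > 0


def test_partner_threshold_is_strict():
    cons = make_consensus(
        [[1.0, 0.5, 0.51], [0.5, 1.0, 0.2], [0.51, 0.2, 1.0]], ["g", "h", "k"]
    )
    partners = coexpression_partners(cons, "g", 0.5)
    assert partners == {"k"}
    with pytest.raises(KeyError, match="unknown"):
        coexpression_partners(cons, "unknown", 0.5)


def test_region_consensus_excludes_sparse_donors():
    rng = np.random.default_rng(2)
    gene_exprs = {
        d: gene_expr(d, {f"g{i}": rng.normal(size=8) for i in range(4)})
        for d in ("d1", "d2", "d3")
    }
    frames = [gene_exprs[d].samples for d in ("d1", "d2")]
    # only 2 samples from d3: below min_region_samples
    frames.append(gene_exprs["d3"].samples.iloc[:2])
    region = pd.concat(frames, ignore_index=True)
    cons = region_consensus(gene_exprs, region, "roi", AnalysisConfig())
    assert cons.n_donors_used == 2
    assert cons.donors_used == ("d1", "d2")


def _network_fixture(r_ab):
    genes = ["A", "B", "x", "y", "z", "w"]
    m = np.eye(6)

    def put(i, j, v):
        m[i, j] = m[j, i] = v

    put(0, 1, r_ab)   # A-B
    put(0, 2, 0.7)    # A-x
    put(0, 3, 0.6)    # A-y
    put(1, 3, 0.8)    # B-y
    put(1, 4, 0.55)   # B-z
    put(2, 3, 0.9)    # x-y partner-partner, must not appear
    return make_consensus(m, genes)


def test_build_network_counts_and_shared_partner():
    graph = build_network(_network_fixture(0.3), ["A", "B"], 0.5)
    assert set(graph.nodes) == {"A", "B", "x", "y", "z"}
    assert graph.number_of_edges() == 4
    assert graph.nodes["y"]["partner_of"] == "A;B"
    assert not graph.has_edge("x", "y")
    assert graph.has_edge("A", "x")
    assert graph.edges["A", "x"]["weight"] == pytest.approx(0.7)


def test_build_network_polyq_edge_and_isolates():
    graph = build_network(_network_fixture(0.6), ["A", "B"], 0.5)
    assert graph.has_edge("A", "B")
    lonely = make_consensus(np.eye(3), ["A", "B", "c"])
    graph2 = build_network(lonely, ["A", "B"], 0.5)
    assert set(graph2.nodes) == {"A", "B"}
    assert graph2.number_of_edges() == 0


def test_threshold_sweep_monotone_and_extremes():
    cons = _network_fixture(0.3)
    sweep = threshold_sweep(cons, ["A", "B"], [0.4, 0.5, 0.6])
    for gene in ("A", "B"):
        counts = sweep.loc[gene].to_numpy()
        assert (np.diff(counts) <= 0).all()
    extreme = threshold_sweep(cons, ["A"], [1.0, -1.0])
    assert extreme.loc["A", 1.0] == 0
    assert extreme.loc["A", -1.0] == len(cons.genes) - 1


def test_save_and_load_consensus_round_trip(tmp_path):
    cons = _network_fixture(0.42)
    save_consensus(cons, tmp_path / "roi")
    back = load_consensus(tmp_path / "roi")
    np.testing.assert_allclose(back.values, cons.values)
    assert list(back.genes) == list(cons.genes)


def test_planted_block_consensus_near_target(small_planted):
    from polyqnet.probes import select_probes

    spec, dataset, _ = small_planted
    gene_exprs, _ = select_probes(list(dataset.donors.values()), dataset.probes)
    subset = dataset.samples[dataset.samples["structure_label"] == "striatum"]
    cons = region_consensus(gene_exprs, subset, "striatum")
    members = sorted(dataset.truth.block_members("coexp_A"))
    sub = cons.to_dataframe().loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    # probe noise attenuates observed correlations below the latent 0.7
    assert 0.45 < sub[iu].mean() < 0.8
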