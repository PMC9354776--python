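"""Synthetic generators: planted structure, determinism, argument checking."""

import numpy as np
import pandas as pd
import pytest

from macsnet.synthetic import (generate_expression_dataset,
                               generate_metabolite_table, generate_pathway_db,
                               generate_target_gene_links)


def test_metabolite_table_shape_and_planted_count():
    table, truth = generate_metabolite_table(6, 200, 10, 2.0, seed=7)
    assert table.intensities.shape == (12, 200)
    assert len(truth.differential_metabolites) == 10
    assert set(truth.differential_metabolites) <= set(table.metabolite_ids)
    # both shift directions occur
    assert set(truth.shift_directions.values()) == {1, -1}


def test_metabolite_table_null_case():
    table, truth = generate_metabolite_table(5, 50, 0, 2.0, seed=1)
    assert truth.differential_metabolites == []
    # with no planted effect both groups share the generating distribution:
    # group-mean differences stay within sampling noise
    lo, hi = table.group_levels
    g = table.groups.to_numpy()
    logx = np.log(table.matrix())
    delta = logx[g == hi].mean(axis=0) - logx[g == lo].mean(axis=0)
    assert np.max(np.abs(delta)) < 5 * 0.3 * np.sqrt(2 / 5)


def test_metabolite_table_determinism():
    t1, tr1 = generate_metabolite_table(4, 30, 5, 1.5, seed=99)
    t2, tr2 = generate_metabolite_table(4, 30, 5, 1.5, seed=99)
    pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
    assert tr1.differential_metabolites == tr2.differential_metabolites
    t3, _ = generate_metabolite_table(4, 30, 5, 1.5, seed=100)
    assert not t1.intensities.equals(t3.intensities)


def test_metabolite_table_argument_errors():
    with pytest.raises(ValueError):
        generate_metabolite_table(2, 10, 0)
    with pytest.raises(ValueError):
        generate_metabolite_table(4, 0, 0)
    with pytest.raises(ValueError):
        generate_metabolite_table(4, 10, 11)


def test_pathway_db_minimal_case():
    pws, ann, _ = generate_pathway_db(1, (3, 3), 0, [f"M{i}" for i in range(10)],
                                      [], seed=0)
    assert len(pws) == 1
    assert len(pws[0].members) == 3
    assert len(pws[0].edges) >= 2
    g = pws[0].graph()
    import networkx as nx
    assert nx.is_connected(g)


def test_pathway_db_core_pathways_absorb_planted_metabolites():
    mets = [f"M{i:03d}" for i in range(80)]
    diff = mets[10:22]
    pws, ann, truth = generate_pathway_db(8, (4, 8), 3, mets, diff, seed=5)
    core_members = set()
    for pid in truth.planted_core_pathways:
        core_members |= set(truth.pathway_assignments[pid])
    covered = len(set(diff) & core_members) / len(diff)
    assert covered >= 0.5
    # every universe metabolite is annotated to at least one gene
    assert set(ann["metabolite_id"]) == set(mets)


def test_pathway_db_graphs_connected_and_deterministic():
    import networkx as nx
    mets = [f"M{i:03d}" for i in range(60)]
    args = (6, (3, 7), 2, mets, mets[:8])
    pws1, ann1, _ = generate_pathway_db(*args, seed=3)
    pws2, ann2, _ = generate_pathway_db(*args, seed=3)
    assert [p.edges for p in pws1] == [p.edges for p in pws2]
    pd.testing.assert_frame_equal(ann1, ann2)
    for p in pws1:
        assert nx.is_connected(p.graph())


def test_pathway_db_argument_errors():
    mets = [f"M{i}" for i in range(20)]
    with pytest.raises(ValueError, match="lower bound"):
        generate_pathway_db(2, (1, 5), 0, mets, [])
    with pytest.raises(ValueError):
        generate_pathway_db(2, (3, 5), 3, mets, [])
    with pytest.raises(ValueError, match="subset"):
        generate_pathway_db(2, (3, 5), 1, mets, ["absent"])


def test_expression_dataset_coupling_reaches_target():
    blocks = {"P0": [f"G{j}" for j in range(8)]}
    ds, truth = generate_expression_dataset(200, 4, blocks, ["t1", "t2"], 1, 0.9,
                                            seed=11)
    t = truth.informative_targets[0]
    # proxy for the unobserved factor: standardized block mean; its analytic
    # correlation with the factor at loading 0.7 over 8 genes
    lam, m = 0.7, 8
    act_factor_corr = lam * np.sqrt(m) / np.sqrt(m * lam**2 + 1 - lam**2)
    X = ds.subset("tumor")
    block = X[blocks["P0"]].to_numpy()
    proxy = ((block - block.mean(0)) / block.std(0, ddof=1)).mean(axis=1)
    r = np.corrcoef(X[t], proxy)[0, 1]
    assert r == pytest.approx(0.9 * act_factor_corr, abs=0.1)


def test_expression_dataset_zero_coupling_is_noise():
    blocks = {"P0": [f"G{j}" for j in range(6)]}
    ds, truth = generate_expression_dataset(150, 4, blocks, ["t1", "t2", "t3"],
                                            2, 0.0, seed=2)
    X = ds.subset("tumor")
    proxy = X[blocks["P0"]].mean(axis=1)
    for t in ["t1", "t2", "t3"]:
        assert abs(np.corrcoef(X[t], proxy)[0, 1]) < 0.25


def test_expression_dataset_determinism_and_errors():
    blocks = {"P0": ["G0", "G1"]}
    d1, _ = generate_expression_dataset(10, 5, blocks, ["t1"], 1, 0.5, seed=4)
    d2, _ = generate_expression_dataset(10, 5, blocks, ["t1"], 1, 0.5, seed=4)
    pd.testing.assert_frame_equal(d1.expression, d2.expression)
    with pytest.raises(ValueError):
        generate_expression_dataset(10, 5, blocks, [], 0, 0.5)
    with pytest.raises(ValueError):
        generate_expression_dataset(10, 5, blocks, ["t1"], 2, 0.5)
    with pytest.raises(ValueError):
        generate_expression_dataset(10, 5, blocks, ["t1"], 1, 1.0)


def test_target_gene_links_cover_every_target():
    blocks = {"P0": ["G0", "G1", "G2"]}
    ds, truth = generate_expression_dataset(10, 5, blocks, ["t1", "t2"], 1, 0.5,
                                            seed=6)
    links = generate_target_gene_links(["t1", "t2"], ["G0", "G1", "G2"], truth,
                                       pathway_genes=blocks, seed=0)
    assert set(links["target_id"]) == {"t1", "t2"}
    assert set(links["gene_id"]) <= {"G0", "G1", "G2"}
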