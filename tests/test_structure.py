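"""Imputation, allele encoding, PCA, MST and the 2N-constraint control."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

from clonalscope.genotype_io import GenotypeError, genotype_key, make_genotype
from clonalscope.group_assignment import assign_groups
from clonalscope.structure import (
    AllelePresenceMatrix,
    PcaResult,
    clustering_concordance,
    constrain_to_2n,
    encode_alleles,
    impute_missing_nn,
    minimum_spanning_tree,
    run_pca,
)
from clonalscope.synthetic import SimulationConfig, simulate_population
import dataclasses

from conftest import make_table


# --- nearest-neighbour imputation ------------------------------------------


def test_imputation_is_identity_without_missing_data(trio_table):
    out = impute_missing_nn(trio_table)
    assert out.records == trio_table.records
    assert out.imputed


def test_imputation_copies_from_forced_neighbour(panel, uniform_diploid_lists):
    other = list(uniform_diploid_lists)
    other[0] = (102, 150)
    holed = list(uniform_diploid_lists)
    holed[5] = None  # s3 misses locus 6 but matches s1 elsewhere
    table = make_table(
        panel,
        [("s1", uniform_diploid_lists), ("s2", other), ("s3", holed)],
    )
    out = impute_missing_nn(table)
    locus = panel.names[5]
    assert out.get("s3").genotype[locus] == table.get("s1").genotype[locus]
    # original untouched
    assert table.get("s3").genotype[locus] == frozenset()


def test_imputation_recovers_planted_values_in_clonal_groups():
    """With ~6% holes punched into a clonal cohort, >= 80% of imputed cells
    equal the pre-hole allele sets (regression threshold)."""
    cfg = dataclasses.replace(
        SimulationConfig().scaled(0.15),
        plate_offset_choices=(0,), plate_offset_probs=(1.0,),
    )
    table, truth = simulate_population(cfg, seed=21)
    out = impute_missing_nn(table)
    true_keys = dict(zip(truth.isolates.strain_id, truth.isolates.true_genotype_key))
    n_holes = n_correct = 0
    for rec in table:
        if rec.strain_id not in true_keys:
            continue  # plate-control replicate
        true_cells = true_keys[rec.strain_id].split(";")
        imputed = out.get(rec.strain_id)
        for locus, true_cell in zip(table.panel, true_cells):
            if rec.genotype[locus]:
                continue  # not a hole
            n_holes += 1
            truth_set = frozenset(int(a) for a in true_cell.split("/"))
            n_correct += imputed.genotype[locus] == truth_set
    assert n_holes > 50
    assert n_correct / n_holes >= 0.80


# --- encoding ---------------------------------------------------------------


def test_encoding_rows_and_columns(panel, trio_table):
    m = encode_alleles(trio_table)
    observed = {
        locus: set().union(*(r.genotype[locus] for r in trio_table))
        for locus in panel
    }
    assert m.data.shape == (3, sum(len(v) for v in observed.values()))
    # identical isolates -> identical rows
    assert (m.data.loc["s1"] == m.data.loc["s2"]).all()
    # each row has one 1 per carried allele
    assert m.data.loc["s1"].sum() == sum(
        len(trio_table.get("s1").genotype[l]) for l in panel
    )


def test_encoding_rejects_missing_cells(panel, trio_table):
    trio_table.records[0].genotype[panel.names[0]] = frozenset()
    with pytest.raises(GenotypeError, match="impute"):
        encode_alleles(trio_table)


# --- PCA --------------------------------------------------------------------


def _presence(df_values, ids=None):
    n, p = np.asarray(df_values).shape
    cols = pd.MultiIndex.from_tuples([("L", i) for i in range(p)])
    index = ids or [f"s{i}" for i in range(n)]
    return AllelePresenceMatrix(pd.DataFrame(df_values, index=index, columns=cols))


def test_two_distinct_isolates_put_all_variance_on_pc1():
    m = _presence([[1, 0, 1, 0], [0, 1, 0, 1]])
    p = run_pca(m, n_components=2)
    assert p.n_components == 1  # rank 1, truncated
    assert p.explained_variance[0] == pytest.approx(1.0)


def test_duplicate_rows_map_to_identical_coordinates():
    m = _presence([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
    p = run_pca(m, n_components=2)
    assert np.allclose(p.coordinates.iloc[0], p.coordinates.iloc[1])


def test_pca_matches_eigendecomposition_oracle():
    """Scores on a 5x8 fixture agree (up to sign) with a direct
    eigendecomposition of the covariance matrix."""
    rng = np.random.default_rng(4)
    X = rng.integers(0, 2, size=(5, 8)).astype(float)
    p = run_pca(_presence(X), n_components=3)
    Xc = X - X.mean(0)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    oracle_scores = Xc @ evecs[:, : p.n_components]
    assert np.allclose(
        np.abs(p.coordinates.to_numpy()), np.abs(oracle_scores), atol=1e-8
    )
    assert np.allclose(
        p.explained_variance, evals[: p.n_components] / evals.sum(), atol=1e-8
    )


def test_pca_explained_variance_invariant_to_row_order():
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(6, 9)).astype(float)
    p1 = run_pca(_presence(X), 3)
    p2 = run_pca(_presence(X[::-1], ids=[f"s{i}" for i in range(6)][::-1]), 3)
    assert np.allclose(p1.explained_variance, p2.explained_variance)


# --- MST --------------------------------------------------------------------


def _pca_from_points(points, ids):
    coords = pd.DataFrame(points, index=ids,
                          columns=[f"PC{i+1}" for i in range(len(points[0]))])
    ev = np.ones(len(points[0])) / len(points[0])
    return PcaResult(coords, ev)


def test_collinear_points_chain():
    p = _pca_from_points([[0.0], [1.0], [3.0]], ["a", "b", "c"])
    tree = minimum_spanning_tree(p, n_axes=1)
    assert sorted((a, b) for a, b, _ in tree.edges) == [("a", "b"), ("b", "c")]
    assert tree.total_weight == pytest.approx(3.0)


def test_tree_has_n_minus_one_edges_and_no_cycles():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(15, 2))
    tree = minimum_spanning_tree(_pca_from_points(pts.tolist(),
                                                  [f"s{i}" for i in range(15)]))
    assert len(tree.edges) == 14
    # acyclic + connected: union-find over edges must merge all 15 nodes
    parent = {f"s{i}": f"s{i}" for i in range(15)}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b, _ in tree.edges:
        ra, rb = find(a), find(b)
        assert ra != rb  # a cycle would revisit a component
        parent[ra] = rb
    assert len({find(k) for k in parent}) == 1


def _brute_force_mst_weight(points):
    n = len(points)
    pts = np.asarray(points)
    best = np.inf
    all_edges = list(itertools.combinations(range(n), 2))
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            w = sum(np.linalg.norm(pts[i] - pts[j]) for i, j in subset)
            best = min(best, w)
    return best


@pytest.mark.parametrize("n,seed", [(5, 1), (6, 2), (7, 3)])
def test_mst_weight_equals_exhaustive_optimum(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    tree = minimum_spanning_tree(
        _pca_from_points(pts.tolist(), [f"s{i}" for i in range(n)])
    )
    assert tree.total_weight == pytest.approx(_brute_force_mst_weight(pts))
    # independent library cross-check on the same points
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    assert tree.total_weight == pytest.approx(scipy_mst(D).sum())


def test_mst_weight_invariant_under_relabeling():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(8, 2)).tolist()
    t1 = minimum_spanning_tree(_pca_from_points(pts, [f"a{i}" for i in range(8)]))
    t2 = minimum_spanning_tree(_pca_from_points(pts, [f"z{7-i}" for i in range(8)]))
    assert t1.total_weight == pytest.approx(t2.total_weight)


# --- 2N constraint ----------------------------------------------------------


def _triploid_table(panel):
    lists = [(100, 104, 108)] * 6 + [(200, 204)] * 6
    return make_table(panel, [("t1", lists), ("t2", lists)])


def test_constraint_caps_ploidy_and_removes_one_allele_per_cell(panel):
    table = _triploid_table(panel)
    out = constrain_to_2n(table, seed=0)
    n_removed = 0
    for rec_in, rec_out in zip(table, out):
        for locus in panel:
            a_in, a_out = rec_in.genotype[locus], rec_out.genotype[locus]
            assert len(a_out) <= 2
            assert a_out <= a_in
            n_removed += len(a_in) - len(a_out)
    n_triploid_cells = sum(
        1 for rec in table for l in panel if len(rec.genotype[l]) == 3
    )
    assert n_removed == n_triploid_cells


def test_constraint_is_identity_on_diploid_table(trio_table):
    out = constrain_to_2n(trio_table, seed=3)
    assert out.records == trio_table.records


def test_constraint_is_seed_reproducible(panel):
    table = _triploid_table(panel)
    a = constrain_to_2n(table, seed=7)
    b = constrain_to_2n(table, seed=7)
    assert a.records == b.records
    c = constrain_to_2n(table, seed=8)
    assert any(x.genotype != y.genotype for x, y in zip(a, c))


def test_removed_allele_is_uniform_over_seeds(panel):
    """Across 3000 seeds each of the three alleles of one cell is removed
    about equally often (chi-square p > 0.01)."""
    table = make_table(panel, [("t1", [(228, 234, 240)] + [(100, 102)] * 11)])
    locus = panel.names[0]
    kept = {frozenset({228, 234}): 0, frozenset({228, 240}): 0, frozenset({234, 240}): 0}
    for seed in range(3000):
        out = constrain_to_2n(table, seed=seed)
        kept[out.get("t1").genotype[locus]] += 1
    chi2 = stats.chisquare(list(kept.values()))
    assert chi2.pvalue > 0.01


# --- concordance ------------------------------------------------------------


def test_concordance_of_identical_and_permuted_labels():
    from clonalscope.group_assignment import GroupAssignment

    a = [GroupAssignment(s, g, 0.0, 1.0) for s, g in
         [("s1", "A"), ("s2", "B"), ("s3", "A")]]
    same = clustering_concordance(a, a)
    assert same.overall == 1.0
    swapped = [GroupAssignment(x.strain_id, {"A": "B", "B": "A"}[x.group_name], 0, 1)
               for x in a]
    assert clustering_concordance(a, swapped).overall == 0.0


def test_constrained_reassignment_is_concordant_on_synthetic_cohort():
    """Deleting one allele from every triploid cell barely moves group
    labels when groups are well separated (>= 0.9 concordance)."""
    cfg = dataclasses.replace(
        SimulationConfig().scaled(0.15),
        plate_offset_choices=(0,), plate_offset_probs=(1.0,),
    )
    table, truth = simulate_population(cfg, seed=13)
    full = assign_groups(table, truth.founders)
    constrained_table = constrain_to_2n(table, seed=1)
    constrained = assign_groups(constrained_table, truth.founders)
    report = clustering_concordance(full, constrained)
    assert report.overall >= 0.9
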