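"""Ward agglomeration vs independent oracles, tree cutting, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from slecrit import (
    characterize,
    classification_columns,
    classify_all,
    cut_tree,
    plant_discordant_clusters,
    select_discordant,
    to_newick,
    ward_linkage,
)

_TIE_TOL = 1e-9


def ward_oracle(X):
    """From-scratch Ward agglomeration recomputing the ESS increase at every step.

    O(n^4): at each step every candidate merge's dESS is recomputed from the
    raw rows.  Heights are sqrt(2 * dESS), the same Euclidean-scale
    convention as the implementation; ties break on the lowest node-id pair.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best_val, best_pair = None, None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                a = X[clusters[i]]
                b = X[clusters[j]]
                ca, cb = a.mean(0), b.mean(0)
                d_ess = (len(a) * len(b) / (len(a) + len(b))) * np.sum((ca - cb) ** 2)
                if best_val is None or d_ess < best_val - _TIE_TOL * max(1, abs(best_val)):
                    best_val, best_pair = d_ess, (i, j)
        i, j = best_pair
        merges.append((i, j, np.sqrt(2 * best_val), len(clusters[i]) + len(clusters[j])))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestWardLinkage:
    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage([[1.0, 0.0]])

    def test_two_identical_rows_merge_at_zero(self):
        tree = ward_linkage([[1, 0, 1], [1, 0, 1]])
        assert tree.merges[0].height == 0.0

    def test_coincident_pair_merges_first(self):
        tree = ward_linkage([[0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        first = tree.merges[0]
        assert {first.left, first.right} == {1, 2} and first.height == 0.0

    def test_matches_oracle_on_small_binary_instances(self):
        """LW-updated tree identical to the O(n^4) from-scratch agglomeration, n <= 12."""
        rng = np.random.default_rng(31)
        for trial in range(25):
            n = int(rng.integers(3, 13))
            X = (rng.random((n, 6)) < 0.4).astype(float)
            tree = ward_linkage(X)
            oracle = ward_oracle(X)
            for got, exp in zip(tree.merges, oracle):
                assert {got.left, got.right} == {exp[0], exp[1]}
                assert got.height == pytest.approx(exp[2], abs=1e-10)
                assert got.size == exp[3]

    def test_matches_scipy_cophenetic_structure(self):
        """Independent cross-check against scipy's Ward on generic-position data."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(13)
        X = rng.random((24, 5))
        mine = ward_linkage(X).to_array()
        theirs = linkage(X, "ward")
        d_theirs = squareform(cophenet(theirs))
        members = {i: [i] for i in range(24)}
        d_mine = np.zeros((24, 24))
        for idx, (l, r, h, s) in enumerate(mine):
            left, right = members[int(l)], members[int(r)]
            for a in left:
                for b in right:
                    d_mine[a, b] = d_mine[b, a] = h
            members[24 + idx] = left + right
        assert np.allclose(d_mine, d_theirs)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            X = (rng.random((15, 8)) < 0.5).astype(float)
            h = [m.height for m in ward_linkage(X).merges]
            assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_permutation_stability(self):
        # generic-position (tie-free) data: merge choices are value-driven, so
        # the partition cannot depend on row order
        rng = np.random.default_rng(77)
        X = rng.random((18, 6))
        ids = [f"p{i}" for i in range(18)]
        perm = rng.permutation(18)
        sol1 = cut_tree(ward_linkage(X), 3, ids=ids)
        sol2 = cut_tree(ward_linkage(X[perm]), 3, ids=[ids[i] for i in perm])
        a1 = sol1.assignments
        a2 = sol2.assignments
        # identical partition of the same ids (labels may permute)
        groups1 = {}
        groups2 = {}
        for pid in ids:
            groups1.setdefault(a1[pid], set()).add(pid)
            groups2.setdefault(a2[pid], set()).add(pid)
        assert sorted(map(sorted, groups1.values())) == sorted(map(sorted, groups2.values()))


@pytest.fixture(scope="module")
def tree():
    rng = np.random.default_rng(3)
    X = rng.random((10, 4))
    return ward_linkage(X)


class TestCutTree:
    def test_k1_single_cluster(self, tree):
        sol = cut_tree(tree, 1)
        assert set(sol.labels) == {1} and sol.sizes == (10,)

    def test_k_equals_n_singletons(self, tree):
        sol = cut_tree(tree, 10)
        assert sorted(sol.labels) == list(range(1, 11))

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 11)

    def test_labels_ordered_by_descending_size(self, tree):
        sol = cut_tree(tree, 4)
        assert list(sol.sizes) == sorted(sol.sizes, reverse=True)

    def test_refining_k_splits_exactly_one_cluster(self, tree):
        for k in range(1, 9):
            coarse = cut_tree(tree, k).labels
            fine = cut_tree(tree, k + 1).labels
            # partition refinement: each fine cluster lies inside one coarse cluster
            pairs = {(f, c) for f, c in zip(fine, coarse)}
            assert len(pairs) == k + 1


class TestRecovery:
    def _profiles(self):
        hematologic = {"thrombocytopenia": 0.95, "hemolytic_anemia": 0.85,
                       "antiphospholipid": 0.9, "ana_positive": 0.95}
        mucocut_sero = {"acute_cutaneous": 0.95, "oral_nasal_ulcers": 0.9,
                        "anti_dsdna": 0.95, "ana_positive": 0.95}
        immunologic = {"low_c3": 0.95, "low_c4": 0.9, "anti_dsdna": 0.9,
                       "proteinuria": 0.9, "ana_positive": 0.95}
        mucocut_only = {"acute_cutaneous": 0.95, "photosensitivity": 0.9,
                        "alopecia": 0.9, "ana_positive": 0.95}
        return [hematologic, mucocut_sero, immunologic, mucocut_only]

    def test_planted_four_clusters_recovered(self):
        """Sizes (23, 15, 6, 11) with well-separated profiles recover at Rand >= 0.9."""
        cohort, truth = plant_discordant_clusters(
            [23, 15, 6, 11], self._profiles(), seed=2, background=0.02)
        tree = ward_linkage(cohort.feature_matrix().to_numpy(dtype=float))
        sol = cut_tree(tree, 4, ids=cohort.ids)
        assert rand_score(truth, sol.labels) >= 0.9

    def test_characterize_on_planted_truth(self):
        cohort, truth = plant_discordant_clusters(
            [23, 15, 6, 11], self._profiles(), seed=2, background=0.02)
        fm = cohort.feature_matrix()
        tree = ward_linkage(fm.to_numpy(dtype=float))
        sol = cut_tree(tree, 4, ids=cohort.ids)
        # synthesize a classification frame where one system misses exactly the
        # hematologic-dominant block and the others miss nobody
        miss_ids = {pid for pid, t in zip(cohort.ids, truth) if t == 1}
        class_bool = pd.DataFrame(True, index=cohort.ids,
                                  columns=["acr1997", "slicc2012", "eular_acr2019", "slerpi"])
        class_bool.loc[sorted(miss_ids), "acr1997"] = False
        summary = characterize(sol, fm, class_bool)
        counts = summary["miss_counts"]["acr1997"]
        top_cluster = counts.idxmax()
        assert counts[top_cluster] >= 0.9 * len(miss_ids)  # misses concentrate in one cluster
        assert summary["system_order"][0] in ("slicc2012", "eular_acr2019", "slerpi")
        assert summary["system_order"][-1] == "acr1997"

    def test_single_cluster_summary_equals_whole_subset(self):
        cohort, _ = plant_discordant_clusters([12], [self._profiles()[0]], seed=5)
        fm = cohort.feature_matrix()
        sol = cut_tree(ward_linkage(fm.to_numpy(dtype=float)), 1, ids=cohort.ids)
        class_bool = pd.DataFrame(True, index=cohort.ids, columns=["slerpi"])
        summary = characterize(sol, fm, class_bool)
        assert np.allclose(summary["feature_prevalence"].loc[1],
                           fm.mean() * 100.0)


class TestSelectDiscordant:
    def test_all_concordant_empty_selection(self, tiny_cohort):
        df = classify_all(tiny_cohort)
        class_bool = classification_columns(df)
        class_bool.loc[:, :] = True
        ids, mat = select_discordant(class_bool, tiny_cohort.reference().to_numpy(),
                                     tiny_cohort)
        assert ids == [] and len(mat) == 0

    def test_one_missed_case_selected(self, tiny_cohort):
        class_bool = classification_columns(classify_all(tiny_cohort))
        class_bool.loc[:, :] = True
        class_bool.loc["case_mid", "acr1997"] = False
        ids, mat = select_discordant(class_bool, tiny_cohort.reference().to_numpy(),
                                     tiny_cohort)
        assert ids == ["case_mid"]
        assert set(mat.columns) == set(tiny_cohort.feature_matrix().columns)


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(1)
    X = rng.random((6, 3))
    tree = ward_linkage(X)
    names = [f"leaf{i}" for i in range(6)]
    nwk = to_newick(tree, names)
    assert nwk.endswith(";")
    for n in names:
        assert n in nwk
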