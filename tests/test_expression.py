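"""Fold-change pipeline: correlations, clustering, synthetic generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cav1net.expression import (ATL_GROUPS, PLANTED_ATL, compute_fold_change,
                                correlate_with_reference,
                                generate_synthetic_foldchange,
                                hierarchical_cluster, pearson_correlation,
                                uncentered_correlation, write_cdt_gtr)


class TestFoldChange:
    def _matrix(self):
        data = pd.DataFrame(
            {"h1": [2.0, 10.0, 4.0], "h2": [2.0, 10.0, 4.0],
             "a1": [8.0, 2.5, 4.0]},
            index=["g1", "g2", "g3"])
        groups = {"h1": "Healthy", "h2": "Healthy", "a1": "ACUT"}
        return data, groups

    def test_log2_ratios(self):
        data, groups = self._matrix()
        fc = compute_fold_change(data, groups)
        assert fc.loc["g1", "ACUT"] == pytest.approx(2.0)    # 8 / 2
        assert fc.loc["g2", "ACUT"] == pytest.approx(-2.0)   # 2.5 / 10
        assert fc.loc["g3", "ACUT"] == pytest.approx(0.0)

    def test_control_column_excluded(self):
        data, groups = self._matrix()
        fc = compute_fold_change(data, groups)
        assert list(fc.columns) == ["ACUT"]

    def test_nonpositive_intensity_rejected(self):
        data, groups = self._matrix()
        data.loc["g1", "h1"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            compute_fold_change(data, groups)

    def test_ungrouped_sample_rejected(self):
        data, groups = self._matrix()
        del groups["a1"]
        with pytest.raises(ValueError, match="without a group"):
            compute_fold_change(data, groups)

    def test_missing_control_rejected(self):
        data, groups = self._matrix()
        with pytest.raises(ValueError, match="control"):
            compute_fold_change(data, groups, control_group="Normal")


class TestPearson:
    def test_perfect_positive(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_correlation([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_partial(self):
        # direct formula: cov 4.0, sd^2 5 each -> 4/5
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            0.8, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=8),
           st.floats(0.1, 5), st.floats(-10, 10))
    def test_symmetry_bounds_affine_invariance(self, x, a, b):
        x = [float(v) for v in x]
        rng = np.random.default_rng(len(x))
        y = list(rng.normal(size=len(x)))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson_correlation(x, y)
        assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
        assert r == pytest.approx(pearson_correlation(y, x), abs=1e-9)
        scaled = [a * v + b for v in x]
        assert pearson_correlation(scaled, y) == pytest.approx(r, abs=1e-9)


class TestUncentered:
    def test_parallel_is_one(self):
        # 4 / (sqrt(2) * sqrt(8)) = 1
        assert uncentered_correlation([1, 1], [2, 2]) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_is_zero(self):
        assert uncentered_correlation([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_is_minus_one(self):
        assert uncentered_correlation([1, 2], [-1, -2]) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            uncentered_correlation([0, 0], [1, 2])


def _brute_force_upgma(data, metric):
    """Oracle: re-agglomerate, recomputing all pairwise average distances."""
    n = len(data)
    d = {(i, j): 1.0 - metric(data[i], data[j])
         for i in range(n) for j in range(i + 1, n)}

    def pair_dist(a, b):
        vals = []
        for p in a:
            for q in b:
                vals.append(d[(p, q)] if p < q else d[(q, p)])
        return sum(vals) / len(vals)

    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                dd = pair_dist(clusters[a], clusters[b])
                if best is None or dd < best[0] - 1e-12:
                    best = (dd, a, b)
        dd, a, b = best
        merges.append((a, b, 1.0 - dd))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestClustering:
    def test_identical_pair_merges_first_at_similarity_one(self):
        data = np.array([[1.0, 2.0, 3.0],
                         [2.0, 4.0, 6.0],   # parallel to row 0
                         [3.0, -2.0, 1.0]])
        tree = hierarchical_cluster(data)
        a, b, sim = tree.merges[0]
        assert {a, b} == {0, 1}
        assert sim == pytest.approx(1.0, abs=1e-12)

    def test_n_minus_one_merges(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0.5, 2.0, size=(6, 4))
        tree = hierarchical_cluster(data)
        assert len(tree.merges) == 5
        assert sorted(tree.leaf_order) == list(range(6))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0.1, 3.0, size=(5, 4))
        tree = hierarchical_cluster(data)
        oracle = _brute_force_upgma(data, uncentered_correlation)
        assert len(tree.merges) == len(oracle)
        for (a, b, s), (oa, ob, os) in zip(tree.merges, oracle):
            assert (a, b) == (oa, ob)
            assert s == pytest.approx(os, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_partitions_match_scipy_average_linkage(self, seed):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(100 + seed)
        data = rng.normal(size=(7, 5))
        tree = hierarchical_cluster(data, similarity="uncentered")
        Z = linkage(pdist(data, metric="cosine"), method="average")
        # same merge heights...
        mine = sorted(1.0 - s for _, _, s in tree.merges)
        theirs = sorted(Z[:, 2])
        assert np.allclose(mine, theirs, atol=1e-9)
        # ...and the same set of clusters overall
        scipy_members = {i: frozenset({i}) for i in range(7)}
        scipy_sets = set()
        for k, (a, b, _, _) in enumerate(Z):
            merged = scipy_members[int(a)] | scipy_members[int(b)]
            scipy_members[7 + k] = merged
            scipy_sets.add(merged)
        my_sets = {tree.members(7 + k) for k in range(len(tree.merges))}
        assert my_sets == scipy_sets

    def test_tie_breaks_toward_lowest_ids(self):
        data = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        tree = hierarchical_cluster(data)
        assert tree.merges[0][:2] == (0, 1)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0, 2.0]]))

    def test_cdt_gtr_output(self, tmp_path):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0.5, 2, size=(5, 4)),
                          index=[f"g{i}" for i in range(5)],
                          columns=list(ATL_GROUPS))
        tree = hierarchical_cluster(df)
        write_cdt_gtr(tree, df, tmp_path / "out")
        gtr = (tmp_path / "out.gtr").read_text().strip().splitlines()
        assert len(gtr) == 4
        assert gtr[0].startswith("NODE0X\t")
        cdt = (tmp_path / "out.cdt").read_text().strip().splitlines()
        assert cdt[0].split("\t")[:4] == ["GID", "UNIQID", "NAME", "GWEIGHT"]
        assert len(cdt) == 2 + 5  # header + eweight + items


class TestCorrelateWithReference:
    def _fc(self):
        z = np.array([1.0, -0.5, 2.0, 0.3])
        return pd.DataFrame(
            {"ASYM": [z[0], z[0], -z[0], 0.9],
             "SMLD": [z[1], z[1], -z[1], -0.4],
             "CHRN": [z[2], z[2], -z[2], 1.8],
             "ACUT": [z[3], z[3], -z[3], 0.5]},
            index=["CAV1", "twin", "mirror", "noisy"])

    def test_identical_profile_ranks_first_with_r_one(self):
        rep = correlate_with_reference(self._fc())
        assert rep.iloc[0]["gene"] in ("CAV1", "twin")
        assert rep[rep.gene == "twin"]["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_profile_ranks_last_with_r_minus_one(self):
        rep = correlate_with_reference(self._fc())
        assert rep.iloc[-1]["gene"] == "mirror"
        assert rep.iloc[-1]["r"] == pytest.approx(-1.0)

    def test_reference_absent_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            correlate_with_reference(self._fc(), reference_gene="GAPDH")

    def test_constant_profile_skipped_with_warning(self):
        fc = self._fc()
        fc.loc["flat"] = 0.7
        with pytest.warns(UserWarning, match="flat"):
            rep = correlate_with_reference(fc)
        assert "flat" not in set(rep["gene"])


class TestSyntheticGenerator:
    def test_seeded_reproducibility(self):
        a = generate_synthetic_foldchange(seed=3)
        b = generate_synthetic_foldchange(seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_default_columns_are_atl_subtypes(self):
        fc = generate_synthetic_foldchange(seed=0)
        assert list(fc.columns) == list(ATL_GROUPS)
        assert "CAV1" in fc.index and set(PLANTED_ATL) <= set(fc.index)

    def test_strong_planted_correlation_recovered(self):
        fc = generate_synthetic_foldchange({"g": 0.9}, n_columns=100, seed=4)
        r = pearson_correlation(fc.loc["CAV1"], fc.loc["g"])
        assert abs(r - 0.9) < 0.1

    def test_null_planted_correlation_small(self):
        rs = []
        for seed in range(10):
            fc = generate_synthetic_foldchange({"g": 0.0}, n_columns=100,
                                               seed=seed)
            rs.append(pearson_correlation(fc.loc["CAV1"], fc.loc["g"]))
        assert np.median(np.abs(rs)) < 3 / np.sqrt(100)

    def test_invalid_planted_r_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_foldchange({"g": 1.0}, seed=0)

    def test_four_column_design_runs_end_to_end(self):
        # the cohort's own width: runs and reports r, no accuracy claim
        fc = generate_synthetic_foldchange(seed=5)
        rep = correlate_with_reference(fc)
        assert ((rep["r"] >= -1.0) & (rep["r"] <= 1.0)).all()
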