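"""Signed network construction, TOM, clustering, tree cut, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage

from comodnet import (
    ModuleSpec,
    adjacency,
    average_linkage,
    correlation_with_p,
    dynamic_tree_cut,
    eigengene_matrix,
    feature_significance,
    generate_design,
    module_eigengene,
    module_trait_table,
    planted_labels,
    preprocess_pipeline,
    scale_free_fit,
    select_soft_power,
    signed_similarity,
    simulate_expression,
    tom_dissimilarity,
    topological_overlap,
)
from comodnet.coexpression import _scale_free_fit_from_k, coexpression_modules
from comodnet.errors import InputError, ParameterError
from comodnet.treecut import cut_tree_dynamic

from _oracles import tom_brute_force, upgma_brute_force
from conftest import make_log2_matrix


def dataframe_square(M, ids=None):
    ids = ids or [f"f{i}" for i in range(M.shape[0])]
    return pd.DataFrame(M, index=ids, columns=ids)


class TestSignedSimilarity:
    def test_constructed_correlations_map_correctly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        xc = x - x.mean()
        y = y - y.mean()
        y -= (y @ xc) / (xc @ xc) * xc  # exactly uncorrelated with x
        m = make_log2_matrix(np.vstack([x, -x, x, y]))
        S = signed_similarity(m)
        assert S.iloc[0, 2] == pytest.approx(1.0)  # r = +1 -> S = 1
        assert S.iloc[0, 1] == pytest.approx(0.0)  # r = -1 -> S = 0
        assert S.iloc[0, 3] == pytest.approx(0.5, abs=1e-9)  # r = 0 -> S = 0.5

    def test_zero_variance_features_excluded(self):
        m = make_log2_matrix(np.vstack([np.arange(5.0), np.ones(5)]))
        with pytest.warns(UserWarning):
            S = signed_similarity(m)
        assert list(S.index) == ["f0"]

    def test_symmetric_unit_interval(self, default_log2):
        S = signed_similarity(default_log2)
        M = S.to_numpy()
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert M.min() >= 0.0 and M.max() <= 1.0
        np.testing.assert_allclose(np.diag(M), 1.0)


class TestAdjacency:
    def test_powers(self):
        S = dataframe_square(np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 1.0], [0.0, 1.0, 1.0]]))
        A = adjacency(S, 10)
        assert A.iloc[0, 1] == pytest.approx(2.0**-10)
        assert A.iloc[0, 2] == 0.0
        assert A.iloc[1, 2] == 1.0
        assert A.iloc[0, 0] == 0.0  # diagonal zeroed for connectivity

    def test_invalid_beta(self):
        S = dataframe_square(np.eye(3))
        with pytest.raises(ParameterError):
            adjacency(S, 0)


class TestScaleFreeFit:
    def test_exact_power_law_scores_one(self):
        """A log-uniform degree sequence (p(k) ~ 1/k) is exactly linear in
        log-log after equal-count binning: signed R^2 = 1."""
        k = 10.0 ** np.linspace(0, 3, 500)
        assert _scale_free_fit_from_k(k) == pytest.approx(1.0, abs=1e-6)

    def test_constant_degrees_return_zero(self):
        with pytest.warns(UserWarning):
            assert _scale_free_fit_from_k(np.full(50, 3.0)) == 0.0

    def test_increasing_distribution_scores_negative(self):
        # mass concentrated at high k: slope positive -> signed R^2 < 0
        k = 1000.0 - 10.0 ** np.linspace(0, 3, 500)[::-1]
        assert _scale_free_fit_from_k(k) < 0

    def test_matches_independent_reimplementation(self, default_log2):
        S = signed_similarity(default_log2)
        A = adjacency(S, 10)
        M = A.to_numpy().copy()
        np.fill_diagonal(M, 0.0)
        k = M.sum(axis=1)
        # independent re-implementation of quantile binning + regression
        edges = np.quantile(k, np.linspace(0, 1, 11))
        xs, ys = [], []
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            sel = (k >= lo) & ((k < hi) if b < 9 else (k <= hi))
            if sel.sum() == 0 or hi - lo <= 0 or k[sel].mean() <= 0:
                continue
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / len(k) / (hi - lo)))
        res = stats.linregress(xs, ys)
        expected = res.rvalue**2 * (-np.sign(res.slope))
        assert scale_free_fit(A) == pytest.approx(expected, abs=1e-10)


class TestSelectSoftPower:
    def test_lowest_qualifying_power_selected(self, default_log2):
        S = signed_similarity(default_log2)
        report = select_soft_power(S)
        table = report.table
        qualifying = table[table["signed_r2"] > 0.8]["beta"]
        assert report.criterion_met
        assert report.selected_beta == int(qualifying.iloc[0])
        below = table[table["beta"] < report.selected_beta]["signed_r2"]
        assert (below <= 0.8).all()

    def test_fallback_flags_report_and_takes_argmax(self, default_log2):
        S = signed_similarity(default_log2)
        report = select_soft_power(S, r2_threshold=1.01)  # unattainable
        assert report.flagged
        best = report.table.loc[report.table["signed_r2"].idxmax()]
        assert report.selected_beta == int(best["beta"])


class TestTopologicalOverlap:
    def test_complete_graph_is_fully_overlapping(self):
        A = dataframe_square(np.ones((4, 4)) - np.eye(4))
        T = topological_overlap(A).to_numpy()
        np.testing.assert_allclose(T, 1.0)

    def test_empty_graph_has_no_overlap(self):
        A = dataframe_square(np.zeros((5, 5)))
        T = topological_overlap(A).to_numpy()
        assert T[np.triu_indices(5, 1)].max() == 0.0
        np.testing.assert_allclose(np.diag(T), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for n in (8, 12, 15):
            M = rng.uniform(0, 1, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            T = topological_overlap(dataframe_square(M)).to_numpy()
            np.testing.assert_allclose(T, tom_brute_force(M), atol=1e-12)

    def test_asymmetric_input_rejected(self):
        M = np.array([[0.0, 0.5], [0.1, 0.0]])
        with pytest.raises(InputError):
            topological_overlap(dataframe_square(M))

    def test_dissimilarity_complements_tom(self, rng):
        M = rng.uniform(0, 1, size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        T = topological_overlap(dataframe_square(M))
        D = tom_dissimilarity(T).to_numpy()
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0)
        np.testing.assert_allclose(D + T.to_numpy() - np.eye(6), 1.0 - np.eye(6), atol=1e-12)


class TestAverageLinkage:
    def test_identical_features_merge_at_zero(self):
        D = dataframe_square(np.zeros((2, 2)))
        Z = average_linkage(D)
        assert Z[0, 2] == 0.0

    def test_three_point_hand_example(self):
        M = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        Z = average_linkage(dataframe_square(M))
        np.testing.assert_allclose(sorted(Z[:, 2]), [0.1, 0.5])

    def test_matches_naive_upgma_oracle(self, rng):
        for n in (8, 10, 12):
            M = rng.uniform(0.1, 1, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            Z = average_linkage(dataframe_square(M))
            np.testing.assert_allclose(
                sorted(Z[:, 2]), upgma_brute_force(M), atol=1e-12
            )


def _blocks_dissimilarity(sizes, within, between, seed=11):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    M = np.full((n, n), between) + rng.uniform(-0.02, 0.02, size=(n, n))
    start = 0
    for s in sizes:
        M[start : start + s, start : start + s] = within + rng.uniform(
            -0.01, 0.01, size=(s, s)
        )
        start += s
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return dataframe_square(np.clip(M, 0.0, 1.0))


class TestDynamicTreeCut:
    def test_two_separated_blocks_two_modules_no_gray(self):
        D = _blocks_dissimilarity([10, 10], within=0.05, between=0.9, seed=11)
        Z = average_linkage(D)
        part = dynamic_tree_cut(Z, D.index)
        assert len(part.module_ids) == 2
        assert (part.labels == 0).sum() == 0
        assert sorted(part.sizes()) == [10, 10]

    def test_small_isolated_branch_goes_gray(self):
        D = _blocks_dissimilarity([12, 4], within=0.05, between=0.9, seed=11)
        Z = average_linkage(D)
        part = dynamic_tree_cut(Z, D.index, min_module_size=5)
        assert len(part.module_ids) == 1
        assert (part.labels == 0).sum() == 4

    def test_single_tight_block_is_one_module(self):
        D = _blocks_dissimilarity([30], within=0.2, between=0.9, seed=11)
        Z = average_linkage(D)
        part = dynamic_tree_cut(Z, D.index)
        assert len(part.module_ids) == 1
        assert part.sizes().iloc[0] == 30

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cut_height": 0.0},
            {"cut_height": 1.5},
            {"deep_split": 5},
            {"deep_split": -1},
            {"min_module_size": 1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        D = _blocks_dissimilarity([10], within=0.1, between=0.9)
        Z = average_linkage(D)
        with pytest.raises(ParameterError):
            cut_tree_dynamic(Z, D.index, **kwargs)

    def test_labels_ranked_by_size_and_colored(self):
        D = _blocks_dissimilarity([15, 8], within=0.05, between=0.9, seed=2)
        part = dynamic_tree_cut(average_linkage(D), D.index)
        sizes = part.sizes()
        assert sizes[1] >= sizes[2]
        assert part.colors[0] == "gray"
        assert part.colors[1] == "turquoise"

    def test_noise_only_mostly_gray(self):
        """Structureless data produce chained dendrograms: the large majority
        of features stays unassigned across seeds."""
        design = generate_design(7, seed=0)
        gray_fracs = []
        for seed in range(5):
            m = simulate_expression(design, [], n_features=300, seed=seed,
                                    n_replicates=1, flag_rate=0.0, output_scale="log2")
            part, _ = coexpression_modules(m)
            gray_fracs.append((part.labels == 0).mean())
        assert np.median(gray_fracs) > 0.8


class TestModuleEigengene:
    def _partitioned(self, values):
        m = make_log2_matrix(values)
        labels = pd.Series(1, index=m.values.index)
        from comodnet.treecut import ModulePartition

        part = ModulePartition(labels=labels, linkage=np.empty((0, 4)), colors={1: "blue"})
        return m, part

    def test_duplicated_profile_is_rank_one(self, rng):
        base = rng.normal(size=21)
        values = np.tile(base, (6, 1))
        m, part = self._partitioned(values)
        eg, ve = module_eigengene(m, part, 1)
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(eg, base)[0, 1]) == pytest.approx(1.0)

    def test_orientation_follows_mean_profile(self, rng):
        values = rng.normal(size=(12, 21))
        m, part = self._partitioned(values)
        eg, _ = module_eigengene(m, part, 1)
        X = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        assert np.corrcoef(eg, X.mean(axis=0))[0, 1] >= 0

    def test_matches_dense_eigensolver(self, rng):
        """First principal component and explained-variance ratio agree with
        an eigendecomposition of the sample-sample covariance to 1e-8."""
        values = rng.normal(size=(20, 21))
        m, part = self._partitioned(values)
        eg, ve = module_eigengene(m, part, 1)
        X = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        C = X.T @ X
        w, V = np.linalg.eigh(C)
        v1 = V[:, -1]
        assert ve == pytest.approx(w[-1] / w.sum(), abs=1e-8)
        aligned = v1 if np.dot(v1, eg) >= 0 else -v1
        np.testing.assert_allclose(np.abs(eg.to_numpy()), np.abs(aligned), atol=1e-8)

    def test_unit_norm_invariant(self, default_log2, default_modules):
        part, _ = default_modules
        egm = eigengene_matrix(default_log2, part)
        norms = np.linalg.norm(egm.values.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)


class TestCorrelationWithP:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = correlation_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-30  # clamped toward zero up to floating-point round-off

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, ])[: len(x)]
        y = y - y.mean()
        y = y - (y @ (x - x.mean())) / np.sum((x - x.mean()) ** 2) * (x - x.mean())
        r, p = correlation_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_known_r_matches_direct_t_formula(self):
        """r = 0.6 with n = 21: p equals the direct t-CDF evaluation."""
        n, r_target = 21, 0.6
        x = np.linspace(-1, 1, n)
        x = (x - x.mean()) / x.std()
        z = np.sin(np.arange(n) * 2.3)  # anything not collinear
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        r, p = correlation_with_p(x, y)
        assert r == pytest.approx(r_target, abs=1e-12)
        t = r_target * np.sqrt((n - 2) / (1 - r_target**2))
        assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            correlation_with_p(np.ones(10), np.arange(10.0))


class TestModuleTraitTable:
    def test_eigengene_as_its_own_trait(self, default_log2, default_modules):
        part, _ = default_modules
        egm = eigengene_matrix(default_log2, part)
        first = egm.values.index[0]
        traits = pd.DataFrame({first: egm.values.loc[first]})
        tab = module_trait_table(egm, traits)
        self_row = tab[tab["module"] == first]
        assert self_row["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_trait_correlation_recovered(self):
        """A module planted at trait_corr 0.7 recovers |r(ME, EoC)| within
        0.15 (median over 20 seeds)."""
        errors = []
        for seed in range(20):
            design = generate_design(7, seed=seed)
            mods = [ModuleSpec(1, 25, trait_corr=0.7), ModuleSpec(2, 25, trait_corr=0.0)]
            m = simulate_expression(design, mods, n_features=100, seed=seed,
                                    n_replicates=1, flag_rate=0.0, output_scale="log2")
            labels = planted_labels(m.values.index)
            from comodnet.treecut import ModulePartition

            part = ModulePartition(labels=labels, linkage=np.empty((0, 4)))
            egm = eigengene_matrix(m, part)
            from comodnet import trait_frame

            tab = module_trait_table(egm, trait_frame(design))
            r = tab[(tab["module"] == "ME1") & (tab["trait"] == "eoc")]["r"].iloc[0]
            errors.append(abs(abs(r) - 0.7))
        assert np.median(errors) < 0.15

    def test_permuted_trait_decorrelates(self, default_log2, default_modules):
        part, _ = default_modules
        egm = eigengene_matrix(default_log2, part)
        rng = np.random.default_rng(0)
        meds = []
        base = np.repeat([0.0, 1.0, 2.0], 7)
        for _ in range(20):
            perm = rng.permutation(base)
            traits = pd.DataFrame({"perm": perm}, index=egm.sample_ids)
            tab = module_trait_table(egm, traits)
            meds.append(tab["r"].abs().median())
        assert np.median(meds) < 0.3


class TestFeatureSignificance:
    def test_feature_equal_to_trait_ranks_first(self, design):
        trait = design.eoc
        values = np.vstack([trait.to_numpy(), np.random.default_rng(1).normal(size=(5, 21))])
        m = make_log2_matrix(values, sample_ids=design.sample_ids)
        tab = feature_significance(m, trait)
        assert tab.iloc[0]["feature_id"] == "f0"
        assert tab.iloc[0]["GS"] == pytest.approx(1.0)
        assert tab.iloc[0]["rank"] == 1

    def test_rank_sorted_by_absolute_gs(self, design, rng):
        m = make_log2_matrix(rng.normal(size=(30, 21)), sample_ids=design.sample_ids)
        tab = feature_significance(m, design.eoc)
        gs = tab["GS"].abs().to_numpy()
        assert (np.diff(gs) <= 1e-12).all()
        assert (np.diff(tab["rank"]) >= 0).all()
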