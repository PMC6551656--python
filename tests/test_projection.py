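"""PCA, reference projection, complete-linkage clustering, FAB tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import methylotype as mt


class TestPCAFit:
    def test_collinear_toy(self):
        """Points (0,0),(2,2),(4,4): PC1 carries all variance, scores
        proportional to (-sqrt8, 0, sqrt8) -- hand eigendecomposition."""
        x = pd.DataFrame([[0, 0], [2, 2], [4, 4]], columns=["p1", "p2"],
                         index=["a", "b", "c"], dtype=float)
        model, scores = mt.pca_fit(x)
        assert model.explained[0] == pytest.approx(1.0)
        assert scores["PC1"].to_numpy() == pytest.approx(
            [-np.sqrt(8), 0.0, np.sqrt(8)]
        )

    def test_projection_of_fitting_samples_equals_scores(self, reference):
        beta, _, _ = reference
        model, scores = mt.pca_fit(beta.T)
        back = mt.pca_project(model, beta.T)
        np.testing.assert_allclose(back.to_numpy(), scores.to_numpy(), atol=1e-8)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.random((6, 40)))
        model, _ = mt.pca_fit(x)
        assert model.explained.sum() == pytest.approx(1.0)
        assert (np.diff(model.explained) <= 1e-12).all()

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.random((8, 30)))
        model, scores = mt.pca_fit(x)
        recon = scores.to_numpy() @ model.basis + model.center
        rel = np.linalg.norm(recon - x.to_numpy()) / np.linalg.norm(x.to_numpy())
        assert rel <= 1e-8

    def test_basis_orthonormal(self, reference):
        beta, _, _ = reference
        model, _ = mt.pca_fit(beta.T)
        gram = model.basis @ model.basis.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            mt.pca_fit(pd.DataFrame([[0.1, 0.2]]))


class TestPCAProject:
    def test_center_maps_to_origin(self, reference):
        beta, _, _ = reference
        model, _ = mt.pca_fit(beta.T)
        q = pd.DataFrame([model.center, model.center], columns=model.probe_ids,
                         index=["q1", "q2"])
        np.testing.assert_allclose(mt.pca_project(model, q).to_numpy(), 0.0, atol=1e-10)

    def test_probe_order_invariance(self, reference):
        beta, _, _ = reference
        model, scores = mt.pca_fit(beta.T)
        shuffled = beta.T.sample(frac=1.0, axis=1, random_state=0)
        np.testing.assert_allclose(
            mt.pca_project(model, shuffled).to_numpy(), scores.to_numpy(), atol=1e-8
        )

    def test_missing_probes_rejected(self, reference):
        beta, _, _ = reference
        model, _ = mt.pca_fit(beta.T)
        with pytest.raises(KeyError):
            mt.pca_project(model, beta.T.iloc[:, :-10])

    def test_progenitor_queries_land_near_progenitor_stages(self, reference):
        """Queries generated at progenitor (CMP/GMP) means project nearer
        the progenitor PC1 centroids than the differentiated ones."""
        beta, sheet, truth = reference
        model, scores = mt.pca_fit(beta.T)
        centroids = {
            stage: scores.loc[sheet.index[sheet["stage"] == stage], "PC1"].mean()
            for stage in truth.stage_order
        }
        rng = np.random.default_rng(5)
        hits = 0
        n_queries = 40
        for i in range(n_queries):
            stage = truth.stage_order[i % 2]  # CMP or GMP
            mean = beta[sheet.index[sheet["stage"] == stage]].mean(axis=1)
            q = np.clip(mean + rng.normal(0, 0.02, size=len(mean)), 0, 1)
            score = mt.pca_project(model, pd.DataFrame([q], columns=beta.index))
            pc1 = score["PC1"].iloc[0]
            dist = {s: abs(pc1 - c) for s, c in centroids.items()}
            nearest = min(dist, key=dist.get)
            hits += nearest in ("CMP", "GMP")
        assert hits / n_queries >= 0.95


def _naive_complete_linkage(points):
    """O(n^3) reference: track explicit member sets, merge the pair of
    clusters with the smallest maximum inter-point distance."""
    d = squareform(pdist(points))
    clusters = {i: {i} for i in range(len(points))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        clusters[min(a, b)] = clusters.pop(a) | clusters.pop(b)
        heights.append(h)
    return np.array(heights)


class TestHClustComplete:
    def test_line_points(self):
        x = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        d = mt.hclust_complete(x)
        assert d.merges[0][:3] == pytest.approx([0, 1, 1.0])
        assert d.merges[1][2] == pytest.approx(10.0)
        assert (np.diff(d.heights) >= 0).all()

    def test_duplicates_merge_first_at_zero(self):
        x = pd.DataFrame([[1.0], [5.0], [1.0]])
        d = mt.hclust_complete(x)
        assert d.merges[0][2] == 0.0
        assert {int(d.merges[0][0]), int(d.merges[0][1])} == {0, 2}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_oracle(self, seed):
        """Merge heights and cophenetic distances agree with scipy's
        complete linkage on random 12-point sets."""
        rng = np.random.default_rng(seed)
        pts = rng.random((12, 4))
        d = mt.hclust_complete(pd.DataFrame(pts))
        ref = linkage(pts, method="complete")
        np.testing.assert_allclose(np.sort(d.heights), np.sort(ref[:, 2]), atol=1e-10)
        np.testing.assert_allclose(
            squareform(_cophenetic(d)), cophenet(ref), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_oracle_heights(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.random((10, 3))
        d = mt.hclust_complete(pd.DataFrame(pts))
        np.testing.assert_allclose(d.heights, _naive_complete_linkage(pts), atol=1e-10)

    def test_two_planted_clusters_recovered(self):
        """k=2 cut on a planted two-group cohort recovers the labels
        (adjusted Rand = 1) using the top planted-contrast probes."""
        beta, _, sheet, truth = mt.simulate_cohort(
            10, 12, 2000, frac_dmp=0.1, delta=0.2, dispersion=0.02, seed=31
        )
        fit = mt.fit_groups(beta, sheet["idh_status"])
        table = mt.moderated_test(fit)
        top = mt.select_top_k(table, 200)
        dend = mt.hclust_complete(beta.loc[top].T)
        clusters = mt.cut_tree(dend, 2)
        truth_labels = sheet.loc[clusters.index, "idh_status"]
        assert adjusted_rand_score(truth_labels, clusters) == 1.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            mt.hclust_complete(pd.DataFrame([[0.0], [np.nan]]))

    def test_permuting_probe_columns_leaves_dendrogram_unchanged(self, small_cohort):
        beta = small_cohort[0].iloc[:100]
        d1 = mt.hclust_complete(beta.T)
        d2 = mt.hclust_complete(beta.sample(frac=1.0, random_state=7).T)
        np.testing.assert_allclose(d1.merges, d2.merges, atol=1e-10)


def _cophenetic(dend):
    """Pairwise cophenetic distances from a merge history."""
    n = len(dend.items)
    members = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for step, (a, b, h, _) in enumerate(dend.merges):
        ma, mb = members[int(a)], members[int(b)]
        for i in ma:
            for j in mb:
                coph[i, j] = coph[j, i] = h
        members[n + step] = ma + mb
    return coph


class TestCutTree:
    def test_k_equals_n_gives_singletons(self):
        x = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        d = mt.hclust_complete(x)
        assert mt.cut_tree(d, 3).nunique() == 3
        assert mt.cut_tree(d, 1).nunique() == 1

    def test_k2_on_line(self):
        x = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        cl = mt.cut_tree(mt.hclust_complete(x), 2)
        assert cl["a"] == cl["b"] != cl["c"]


class TestFabDistribution:
    def _sheet(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "idh_status", "fab_class"]).set_index(
            "sample_id"
        )

    def test_single_group_all_m1(self):
        sheet = self._sheet([["s1", "MUT", "M1"], ["s2", "MUT", "M1"]])
        out = mt.fab_distribution(sheet)
        assert out.loc["MUT", "prop_M1"] == 1.0
        assert out.loc["MUT", "n"] == 2

    def test_forced_proportions(self):
        sheet = self._sheet(
            [["s1", "WT", "M0"], ["s2", "WT", "M1"], ["s3", "WT", "M1"], ["s4", "WT", "M2"]]
        )
        out = mt.fab_distribution(sheet)
        assert out.loc["WT", ["prop_M0", "prop_M1", "prop_M2"]].to_list() == [0.25, 0.5, 0.25]

    def test_na_excluded_from_denominator(self):
        sheet = self._sheet([["s1", "WT", "M1"], ["s2", "WT", "NA"], ["s3", "WT", "M1"]])
        out = mt.fab_distribution(sheet)
        assert out.loc["WT", "n"] == 2
        assert out.loc["WT", "n_na"] == 1
        assert out.loc["WT", "prop_M1"] == 1.0

    def test_proportions_sum_to_one_per_group(self, small_cohort):
        _, _, sheet, _ = small_cohort
        sheet = sheet.copy()
        rng = np.random.default_rng(8)
        sheet["fab_class"] = rng.choice(["M0", "M1", "M2", "M4", "NA"], size=len(sheet))
        out = mt.fab_distribution(sheet)
        props = out[[c for c in out.columns if c.startswith("prop_")]]
        for g, row in props.iterrows():
            if out.loc[g, "n"] > 0:
                assert row.sum() == pytest.approx(1.0)


class TestCrossCluster:
    def test_all_probes_two_stage_reference_separates(self, reference):
        beta, sheet, _ = reference
        sub = sheet[sheet["stage"].isin(["CMP", "PMN"])]
        out = mt.cross_cluster(beta[sub.index], None, beta.index, sub["stage"])
        clusters = mt.cut_tree(out["dendrogram"], 2)
        assert adjusted_rand_score(sub.loc[clusters.index, "stage"], clusters) == 1.0
        assert out["silhouette"] > 0.5

    def test_orthogonal_selector_reports_silhouette_without_claim(self, reference):
        beta, sheet, _ = reference
        rng = np.random.default_rng(9)
        ids = beta.index[rng.choice(len(beta), size=50, replace=False)]
        out = mt.cross_cluster(beta, None, ids, sheet["stage"])
        assert "silhouette" in out
        assert out["n_probes"] == 50

    def test_differentiation_aligned_selector_coclusters_progenitors(self, reference):
        """Probes picked by a mutant-like contrast aligned with the
        differentiation axis separate CD34+ progenitors from mature cells."""
        beta, sheet, truth = reference
        # mutant-like cohort: progenitor-shifted vs differentiated-shifted
        rng = np.random.default_rng(10)
        prog = beta[sheet.index[sheet["stage"].isin(["CMP", "GMP"])]]
        diff = beta[sheet.index[sheet["stage"].isin(["PMC", "PMN"])]]
        labels = pd.Series(
            ["MUT"] * prog.shape[1] + ["WT"] * diff.shape[1],
            index=list(prog.columns) + list(diff.columns),
        )
        fit = mt.fit_groups(beta, labels)
        table = mt.moderated_test(fit)
        top = mt.select_top_k(table, 300)
        out = mt.cross_cluster(beta, None, top, sheet["stage"])
        clusters = mt.cut_tree(out["dendrogram"], 2)
        cd34 = sheet["stage"].isin(["CMP", "GMP"])
        assert adjusted_rand_score(cd34.loc[clusters.index], clusters) == 1.0

    def test_too_few_probes_rejected(self, reference):
        beta, _, _ = reference
        with pytest.raises(ValueError):
            mt.cross_cluster(beta, None, ["nonexistent"], None)
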