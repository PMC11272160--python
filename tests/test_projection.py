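"""LSI transform, pseudo-cell downsampling, embedding transfer, medoid,
nearest-cell assignment, and end-to-end label recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import amniowave as aw


class TestLSIModel:
    def test_idf_formula_extremes(self, atlas_bundle):
        atlas, _ = atlas_bundle
        model = atlas.lsi
        n = atlas.n_cells
        expressed_everywhere = (atlas.counts > 0).all(axis=1).to_numpy()
        assert expressed_everywhere.any()
        expected_min = np.log(1 + n / (1 + n))
        assert np.allclose(model.idf[expressed_everywhere], expected_min)
        assert model.idf.min() >= expected_min - 1e-12
        # a gene expressed in no cell would get the maximal weight log(1+N)
        silent = aw.ReferenceAtlas(
            counts=pd.concat(
                [
                    # shared background genes (past the cluster-marker blocks)
                    atlas.counts.iloc[600:640],
                    pd.DataFrame(0, index=["silent"], columns=atlas.cell_ids),
                ]
            ),
            labels=atlas.labels.copy(),
            embedding=atlas.embedding.copy(),
        )
        silent_model = aw.fit_lsi(silent, n_components=5)
        assert np.isclose(silent_model.idf[-1], np.log(1 + n))

    def test_reference_retransform_is_svd_consistent(self, atlas_bundle):
        """Pairwise distances among re-transformed reference cells match the
        U*S factor scores from the SVD itself."""
        atlas, _ = atlas_bundle
        model = atlas.lsi
        coords = aw.reference_lsi_coordinates(model, atlas)
        counts = atlas.counts.to_numpy(dtype=float)
        tf = counts / counts.sum(axis=0)
        X = np.log1p(tf * model.idf[:, None] * model.scale_constant).T
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        scores = (U * S)[:, : model.n_components]
        sub = np.arange(0, atlas.n_cells, 25)
        d1 = cdist(coords[sub], coords[sub])
        d2 = cdist(scores[sub], scores[sub])
        off = ~np.eye(len(sub), dtype=bool)
        assert np.allclose(d1[off], d2[off], rtol=1e-6)

    def test_components_orthonormal(self, atlas_bundle):
        model = atlas_bundle[0].lsi
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert (np.diff(model.singular_values) <= 1e-9).all()

    def test_json_round_trip(self, tmp_path, atlas_bundle):
        model = atlas_bundle[0].lsi
        model.to_json(tmp_path / "lsi.json")
        back = aw.LSIModel.from_json(tmp_path / "lsi.json")
        assert np.allclose(back.components, model.components)
        assert np.allclose(back.idf, model.idf)
        assert back.gene_ids == model.gene_ids


class TestTransformLSI:
    def test_reference_cell_maps_to_itself(self, atlas_bundle):
        atlas, _ = atlas_bundle
        model = atlas.lsi
        ref = aw.reference_lsi_coordinates(model, atlas)
        query = atlas.counts.iloc[:, [17]]
        coords = aw.transform_lsi(model, query)
        assert np.allclose(coords[0], ref[17], atol=1e-8)

    def test_tf_scale_invariance(self, atlas_bundle):
        atlas, _ = atlas_bundle
        model = atlas.lsi
        query = atlas.counts.iloc[:, [3]]
        doubled = query * 2
        assert np.allclose(
            aw.transform_lsi(model, query), aw.transform_lsi(model, doubled), atol=1e-10
        )

    def test_zero_overlap_raises(self, atlas_bundle):
        atlas, _ = atlas_bundle
        query = pd.DataFrame({"q": [5, 5]}, index=["alien1", "alien2"])
        with pytest.raises(ValueError, match="zero total"):
            aw.transform_lsi(atlas.lsi, query)


class TestDownsamplePseudocells:
    def test_columns_sum_to_depth(self):
        bulk = pd.Series([100, 300, 600], index=["a", "b", "c"], name="s1")
        pcs = aw.downsample_pseudocells(bulk, n_cells=20, depth=500, seed=1)
        assert (pcs.counts.sum(axis=0) == 500).all()
        assert pcs.n_cells == 20

    def test_deterministic_per_seed_and_index(self):
        bulk = pd.Series([10, 20, 30], index=["a", "b", "c"], name="s1")
        one = aw.downsample_pseudocells(bulk, n_cells=5, depth=100, seed=9)
        two = aw.downsample_pseudocells(bulk, n_cells=5, depth=100, seed=9)
        pd.testing.assert_frame_equal(one.counts, two.counts)
        # first cells coincide when seeds align through the seed + index rule
        shifted = aw.downsample_pseudocells(bulk, n_cells=5, depth=100, seed=10)
        assert np.array_equal(shifted.counts.iloc[:, 0], one.counts.iloc[:, 1])

    def test_mean_tracks_bulk_proportions(self, cluster_bulks):
        bulk = cluster_bulks.counts.iloc[:, 0]
        pcs = aw.downsample_pseudocells(bulk, n_cells=100, depth=10_000, seed=4)
        mean_profile = pcs.counts.mean(axis=1)
        proportions = bulk / bulk.sum()
        r = np.corrcoef(mean_profile, proportions)[0, 1]
        assert r > 0.99

    def test_bad_depth_raises(self):
        bulk = pd.Series([1, 2], index=["a", "b"], name="s")
        with pytest.raises(ValueError, match="depth"):
            aw.downsample_pseudocells(bulk, depth=0)


class TestUmapTransfer:
    def test_exact_match_copies_coordinates(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        emb = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        out = aw.umap_transfer(ref, emb, ref[[1]], k_neighbors=2)
        assert np.allclose(out[0], emb[1])

    def test_equidistant_pair_averages(self):
        ref = np.array([[0.0, 0.0], [2.0, 0.0]])
        emb = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = aw.umap_transfer(ref, emb, np.array([[1.0, 0.0]]), k_neighbors=2)
        assert np.allclose(out[0], [5.0, 0.0])

    def test_pseudocells_land_near_their_cluster(self, atlas_bundle, atlas_config):
        atlas, _ = atlas_bundle
        model = atlas.lsi
        ref = aw.reference_lsi_coordinates(model, atlas)
        emb = atlas.embedding.to_numpy()
        centers = aw.cluster_centers(atlas)
        bulk = aw.generate_bulk_from_cluster(atlas, "TBXTlow", 1, depth=10**6, seed=5)
        pcs = aw.downsample_pseudocells(
            bulk.counts.iloc[:, 0], n_cells=100, depth=atlas.median_cell_depth(), seed=6
        )
        placed = aw.umap_transfer(ref, emb, aw.transform_lsi(model, pcs.counts), 15)
        dists = cdist(placed, centers.to_numpy())
        own = list(centers.index).index("TBXTlow")
        assert (np.argmin(dists, axis=1) == own).mean() >= 0.95

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            aw.umap_transfer(np.empty((0, 3)), np.empty((0, 2)), np.ones((1, 3)))


class TestMedoid:
    def test_hand_example(self):
        index, point = aw.medoid(np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]))
        assert index == 1
        assert np.allclose(point, [1.0, 0.0])

    def test_single_point(self):
        index, point = aw.medoid(np.array([[4.2, -1.0]]))
        assert index == 0
        assert np.allclose(point, [4.2, -1.0])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(14)
        for trial in range(50):
            m = int(rng.integers(2, 60))
            points = rng.normal(size=(m, 2)).round(1)  # rounding provokes ties
            index, _ = aw.medoid(points)
            sums = [cdist(points[[i]], points).sum() for i in range(m)]
            best = min(range(m), key=lambda i: (sums[i], i))
            assert sums[index] == pytest.approx(sums[best])
            assert index <= best

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aw.medoid(np.empty((0, 2)))


class TestNearestReferenceCell:
    def test_exact_point_and_tie_break(self, atlas_bundle):
        atlas, _ = atlas_bundle
        cell = atlas.cell_ids[42]
        point = atlas.embedding.loc[cell].to_numpy()
        found, label, dist = aw.nearest_reference_cell(atlas, point)
        assert dist <= cdist([point], atlas.embedding.to_numpy()).min() + 1e-12
        assert label == atlas.labels[found]

    def test_tie_prefers_lowest_index(self):
        counts = pd.DataFrame(
            np.ones((3, 2), dtype=int), index=["g1", "g2", "g3"], columns=["c1", "c2"]
        )
        atlas = aw.ReferenceAtlas(
            counts=counts,
            labels=pd.Series(["A", "B"], index=["c1", "c2"]),
            embedding=pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0]}, index=["c1", "c2"]),
        )
        cell, label, dist = aw.nearest_reference_cell(atlas, (5.0, 0.0))
        assert (cell, label, dist) == ("c1", "A", 5.0)

    def test_matches_brute_force_scan(self, atlas_bundle):
        atlas, _ = atlas_bundle
        coords = atlas.embedding.to_numpy()
        rng = np.random.default_rng(15)
        queries = rng.uniform(-5, 45, size=(200, 2))
        for q in queries:
            cell, _, dist = aw.nearest_reference_cell(atlas, q)
            d = np.sqrt(((coords - q) ** 2).sum(axis=1))
            assert dist == pytest.approx(d.min())
            assert atlas.cell_ids.index(cell) == int(np.argmin(d))


class TestMapSamplesToAtlas:
    def test_cluster_bulks_recover_their_labels(self, atlas_bundle, cluster_bulks):
        atlas, _ = atlas_bundle
        results = aw.map_samples_to_atlas(atlas, cluster_bulks, seed=42)
        truth = cluster_bulks.sample_meta["condition"]
        correct = sum(r.transferred_label == truth[r.sample_id] for r in results)
        assert correct >= 19

    def test_deterministic_under_fixed_seed(self, atlas_bundle, cluster_bulks):
        atlas, _ = atlas_bundle
        subset = cluster_bulks.subset_samples(cluster_bulks.sample_ids[:3])
        one = aw.map_samples_to_atlas(atlas, subset, seed=7)
        two = aw.map_samples_to_atlas(atlas, subset, seed=7)
        for a, b in zip(one, two):
            assert a.medoid_xy == b.medoid_xy
            assert a.nearest_cell_id == b.nearest_cell_id
            assert a.euclidean_distance == b.euclidean_distance

    def test_exact_cell_copy_maps_to_that_cell(self, atlas_bundle):
        """A bulk equal to one reference cell's counts, split into a single
        pseudo-cell at that cell's depth, lands on (or next to) the cell."""
        atlas, _ = atlas_bundle
        cell = atlas.cell_ids[10]
        column = atlas.counts[cell]
        bulk = aw.CountMatrix(
            pd.DataFrame({"copy_of_cell": column}),
            pd.DataFrame(
                {"timepoint_hr": [np.nan], "condition": ["copy"], "replicate": [1]},
                index=pd.Index(["copy_of_cell"], name="sample_id"),
            ),
        )
        [result] = aw.map_samples_to_atlas(
            atlas, bulk, n_cells=1, depth=int(column.sum()), seed=3
        )
        assert result.transferred_label == atlas.labels[cell]
        assert result.euclidean_distance < 10  # below the cluster-separation scale

    def test_no_gene_overlap_raises(self, atlas_bundle):
        atlas, _ = atlas_bundle
        bulk = aw.CountMatrix(
            pd.DataFrame({"s": [1, 2]}, index=pd.Index(["x1", "x2"], name="gene_id")),
            pd.DataFrame(
                {"timepoint_hr": [np.nan], "condition": [""], "replicate": [1]},
                index=pd.Index(["s"], name="sample_id"),
            ),
        )
        with pytest.raises(ValueError, match="no genes"):
            aw.map_samples_to_atlas(atlas, bulk, seed=0)


class TestTrajectoryOrdering:
    def test_medoids_follow_cluster_order(self, atlas_bundle, cluster_bulks, atlas_config):
        """Bulks from the ordered trajectory clusters produce medoids whose
        x-positions march along the trajectory axis."""
        atlas, _ = atlas_bundle
        trajectory = atlas_config.clusters[:4]  # Epiblast ... Amnion
        results = aw.map_samples_to_atlas(atlas, cluster_bulks, seed=42)
        mean_x = {
            label: np.mean(
                [r.medoid_xy[0] for r in results if r.sample_id.startswith(label)]
            )
            for label in trajectory
        }
        xs = [mean_x[label] for label in trajectory]
        assert xs == sorted(xs)
        # and each cluster's medoids sit nearer their own center than any
        # non-adjacent center
        centers = aw.cluster_centers(atlas)
        for i, label in enumerate(trajectory):
            own = centers.loc[label].to_numpy()
            for r in results:
                if not r.sample_id.startswith(label):
                    continue
                d_own = np.hypot(*(np.array(r.medoid_xy) - own))
                for j, other in enumerate(trajectory):
                    if abs(i - j) >= 2:
                        d_other = np.hypot(*(np.array(r.medoid_xy) - centers.loc[other].to_numpy()))
                        assert d_own < d_other
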