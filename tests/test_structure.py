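import numpy as np
import pytest

import mbgp
from conftest import hwe_panel


def two_breed_panel(seed=0, n=40, m=400, shift=0.25):
    """Two breeds with well-separated allele frequencies (FST ~ 0.2)."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, size=m)
    pa = np.clip(base - shift / 2, 0.02, 0.98)
    pb = np.clip(base + shift / 2, 0.02, 0.98)
    haps = np.concatenate([
        (rng.random((n, 2, m)) < pa).astype(np.int8),
        (rng.random((n, 2, m)) < pb).astype(np.int8),
    ])
    pos = np.cumsum(rng.integers(1000, 8000, size=m))
    markers = mbgp.MarkerMap(np.ones(m, int), pos, pos * 1e-6,
                             np.full(m, "A", object), np.full(m, "B", object))
    ids = np.array([f"i{k}" for k in range(2 * n)], dtype=object)
    breeds = np.array(["A"] * n + ["B"] * n, dtype=object)
    return mbgp.GenotypePanel(markers, haps, ids, breeds)


class TestPCA:
    def test_pc1_separates_divergent_breeds(self):
        panel = two_breed_panel()
        res = mbgp.pca(panel, 2)
        a = res.scores[panel.breeds == "A", 0]
        b = res.scores[panel.breeds == "B", 0]
        assert max(a.max(), b.max()) == (a.max() if a.mean() > b.mean() else b.max())
        assert min(a.min(), b.min()) < max(a.max(), b.max())
        # no overlap between breed score ranges on PC1
        assert (a.min() > b.max()) or (b.min() > a.max())

    def test_duplication_preserves_score_geometry(self):
        panel = hwe_panel(15, 200, seed=5)
        dup = mbgp.GenotypePanel(
            panel.markers,
            np.concatenate([panel.haplotypes, panel.haplotypes]),
            np.array([f"c{i}" for i in range(30)], dtype=object),
            np.array(["X"] * 30, dtype=object),
        )
        r1 = mbgp.pca(panel, 3)
        r2 = mbgp.pca(dup, 3)
        d1 = np.linalg.norm(r1.scores[:, None] - r1.scores[None], axis=-1)
        d2 = np.linalg.norm(r2.scores[:15, None] - r2.scores[None, :15], axis=-1)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_rank_one_pattern_fully_explained_by_pc1(self):
        m = 50
        haps = np.zeros((10, 2, m), dtype=np.int8)
        haps[5:, :, :] = 1  # two genotype states only
        pos = np.arange(1, m + 1) * 1000
        markers = mbgp.MarkerMap(np.ones(m, int), pos, pos * 1e-6,
                                 np.full(m, "A", object), np.full(m, "B", object))
        panel = mbgp.GenotypePanel(
            markers, haps, np.array([f"i{k}" for k in range(10)], dtype=object),
            np.array(["X"] * 10, dtype=object))
        res = mbgp.pca(panel, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        panel = hwe_panel(10, 20, seed=6)
        panel.haplotypes[:] = 1
        with pytest.raises(ValueError, match="constant"):
            mbgp.pca(panel)


class TestKMeansGroups:
    def test_recovers_configured_groups(self, tiny_founders, tiny_config):
        res = mbgp.pca(tiny_founders, 5)
        groups = mbgp.kmeans_groups(res, k=2, seed=0)
        assert groups["A"] != groups["B"]

    def test_k_equal_breeds_gives_singletons(self):
        panel = two_breed_panel()
        res = mbgp.pca(panel, 3)
        groups = mbgp.kmeans_groups(res, k=2, seed=1)
        assert groups["A"] != groups["B"]

    def test_identical_breeds_co_assigned(self):
        panel = two_breed_panel()
        # third breed duplicating breed A's genotypes exactly
        a = panel.breeds == "A"
        dup = mbgp.GenotypePanel(
            panel.markers,
            np.concatenate([panel.haplotypes, panel.haplotypes[a]]),
            np.concatenate([panel.ids,
                            np.array([f"d{i}" for i in range(a.sum())])]),
            np.concatenate([panel.breeds, np.array(["A2"] * a.sum())]),
        )
        groups = mbgp.kmeans_groups(mbgp.pca(dup, 4), k=2, seed=2)
        assert groups["A"] == groups["A2"] != groups["B"]

    def test_too_many_clusters_rejected(self):
        panel = two_breed_panel()
        with pytest.raises(ValueError, match="exceeds"):
            mbgp.kmeans_groups(mbgp.pca(panel, 2), k=3)


class TestPhasePersistence:
    def test_identity_gives_correlation_one(self, tiny_founders):
        table = mbgp.phase_persistence(tiny_founders, tiny_founders)
        populated = table.dropna(subset=["correlation"])
        assert (populated.n_pairs >= 2).all()
        assert np.allclose(populated.correlation, 1.0)

    def test_default_bins_follow_chip_conventions(self):
        edges = mbgp.default_phase_bins()
        assert edges[0] == 0 and edges[-1] == 1_000_000
        assert np.all(np.diff(edges) > 0)
        assert list(edges[:5]) == [0, 2500, 5000, 7500, 10000]
        assert 100_000 in edges and 90_000 in edges

    def test_resampled_expansion_keeps_short_range_phase(self, tiny_founders,
                                                         tiny_expanded):
        breed = tiny_founders.breed_names[0]
        table = mbgp.phase_persistence(
            tiny_founders.breed_panel(breed),
            tiny_expanded.breed_panel(breed),
            bins=np.array([0, 2500, 5000]),
        )
        assert table.correlation.iloc[0] >= 0.9

    def test_destroyed_phase_gives_near_zero_correlation(self, tiny_founders):
        rng = np.random.default_rng(0)
        shuffled = tiny_founders.haplotypes.copy()
        n = shuffled.shape[0]
        flat = shuffled.reshape(2 * n, -1)
        for j in range(flat.shape[1]):  # independent permutation per marker
            flat[:, j] = flat[rng.permutation(2 * n), j]
        destroyed = mbgp.GenotypePanel(
            tiny_founders.markers, flat.reshape(n, 2, -1),
            tiny_founders.ids, tiny_founders.breeds)
        table = mbgp.phase_persistence(tiny_founders, destroyed,
                                       bins=np.array([0, 25_000, 100_000]))
        assert (table.correlation.abs() < 0.2).all()

    def test_symmetry_in_panel_arguments(self, tiny_founders, tiny_expanded):
        bins = np.array([0, 10_000, 50_000])
        ab = mbgp.phase_persistence(tiny_founders, tiny_expanded, bins)
        ba = mbgp.phase_persistence(tiny_expanded, tiny_founders, bins)
        assert np.allclose(ab.correlation, ba.correlation, equal_nan=True)
        assert (ab.n_pairs == ba.n_pairs).all()

    def test_empty_bin_reported_missing_not_zero(self, tiny_founders):
        table = mbgp.phase_persistence(
            tiny_founders, tiny_founders, bins=np.array([0, 1, 2])
        )
        assert table.n_pairs.iloc[0] == 0
        assert np.isnan(table.correlation.iloc[0])

    def test_mismatched_maps_rejected(self, tiny_founders):
        other = tiny_founders.subset_markers(np.arange(10))
        with pytest.raises(ValueError, match="identical marker map"):
            mbgp.phase_persistence(tiny_founders, other)

    def test_dosage_method_agrees_at_short_range(self, tiny_founders,
                                                 tiny_expanded):
        breed = tiny_founders.breed_names[0]
        bins = np.array([0, 5000])
        h = mbgp.phase_persistence(tiny_founders.breed_panel(breed),
                                   tiny_expanded.breed_panel(breed),
                                   bins, method="haplotype")
        d = mbgp.phase_persistence(tiny_founders.breed_panel(breed),
                                   tiny_expanded.breed_panel(breed),
                                   bins, method="dosage")
        assert abs(h.correlation.iloc[0] - d.correlation.iloc[0]) < 0.1
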