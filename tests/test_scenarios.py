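import numpy as np
import pandas as pd
import pytest

import mbgp
from mbgp.scenarios import _breed_design_matrix


@pytest.fixture(scope="module")
def grid_panel(tiny_expanded):
    return tiny_expanded  # 2 breeds x 200 simulated individuals


@pytest.fixture(scope="module")
def grid_grm(grid_panel):
    return mbgp.compute_grm(grid_panel)


class TestMakeSplits:
    def test_single_breed_reference_and_heldout_validation(self, grid_panel):
        design = mbgp.Design("single_A", ("A",), n_reference=150, n_validation=50)
        splits = mbgp.make_splits(grid_panel, design, seed=1)
        assert len(splits.reference_idx) == 150
        assert len(splits.validation_idx["A"]) == 50
        assert len(splits.validation_idx["B"]) == 50
        assert not np.intersect1d(splits.reference_idx,
                                  splits.validation_idx["A"]).size
        assert (grid_panel.breeds[splits.reference_idx] == "A").all()

    def test_combined_design_equal_quota_per_breed(self, grid_panel):
        design = mbgp.Design("both", ("A", "B"), n_reference=200, n_validation=40)
        splits = mbgp.make_splits(grid_panel, design, seed=2)
        ref_breeds = grid_panel.breeds[splits.reference_idx]
        assert (ref_breeds == "A").sum() == 100
        assert (ref_breeds == "B").sum() == 100
        for b in ("A", "B"):
            assert not np.intersect1d(splits.reference_idx,
                                      splits.validation_idx[b]).size

    def test_uneven_quota_rejected(self):
        with pytest.raises(ValueError, match="equally"):
            mbgp.Design("bad", ("A", "B", "C"), n_reference=100)

    def test_quota_exceeding_breed_size_rejected(self, grid_panel):
        design = mbgp.Design("big", ("A",), n_reference=500)
        with pytest.raises(ValueError, match="quota"):
            mbgp.make_splits(grid_panel, design, seed=3)

    def test_standard_design_set_composition(self):
        designs = mbgp.standard_designs(mbgp.DEFAULT_GROUPS)
        assert sum(n.startswith("single_") for n in designs) == 10
        assert "group_SWC" in designs and "group_SCHC" in designs
        assert "group_NCC" not in designs  # four-breed group has no trio
        assert len(designs["combined_ten"].reference_breeds) == 10
        cross = designs["cross_group"].reference_breeds
        assert len({mbgp.DEFAULT_GROUPS[b] for b in cross}) == 3


class TestAccuracy:
    def test_perfect_and_inverted_prediction(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert mbgp.accuracy(t, t) == pytest.approx(1.0)
        assert mbgp.accuracy(-t, t) == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.1, 1.9, 3.2, 3.8])
        ca, cb = a - a.mean(), b - b.mean()
        expected = (ca @ cb) / np.sqrt((ca @ ca) * (cb @ cb))
        assert mbgp.accuracy(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.99085, abs=1e-4)

    def test_undefined_cases_return_nan(self):
        assert np.isnan(mbgp.accuracy([1.0, 2.0], [1.0, 2.0]))
        assert np.isnan(mbgp.accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestBreedDesignMatrix:
    def test_single_breed_means_intercept_only(self):
        assert _breed_design_matrix(np.array(["A", "A"], dtype=object)) is None

    def test_multi_breed_full_rank_with_intercept(self):
        x = _breed_design_matrix(np.array(["A", "B", "C", "B"], dtype=object))
        assert x.shape == (4, 3)
        assert np.linalg.matrix_rank(x) == 3
        assert (x[:, 0] == 1).all()


class TestRunGrid:
    strategies = {"I": [0.1, 0.6]}

    def designs(self):
        return {
            "single_A": mbgp.Design("single_A", ("A",), 150, 50),
            "both": mbgp.Design("both", ("A", "B"), 150, 50),
        }

    def run(self, panel, grm, seed=7, **kw):
        kw.setdefault("n_replicates", 2)
        return mbgp.run_grid(panel, grm, self.designs(), self.strategies,
                             master_seed=seed, **kw)

    def test_grid_is_complete_and_accuracies_bounded(self, grid_panel, grid_grm):
        rec = self.run(grid_panel, grid_grm)
        # 2 designs x 2 h2 x 2 reps x 2 validation breeds
        assert len(rec) == 16
        assert (rec.status == "ok").all()
        ok = rec.accuracy.dropna()
        assert ((ok >= -1) & (ok <= 1)).all()

    def test_bit_exact_reproducibility_under_master_seed(self, grid_panel,
                                                         grid_grm):
        a = self.run(grid_panel, grid_grm)
        b = self.run(grid_panel, grid_grm)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_results(self, grid_panel, grid_grm):
        a = self.run(grid_panel, grid_grm, seed=7)
        b = self.run(grid_panel, grid_grm, seed=8)
        assert not np.allclose(a.accuracy, b.accuracy)

    def test_within_breed_accuracy_increases_with_heritability(
            self, grid_panel, grid_grm):
        rec = mbgp.run_grid(
            grid_panel, grid_grm,
            {"single_A": mbgp.Design("single_A", ("A",), 150, 50)},
            {"I": [0.1, 0.3, 0.6]}, n_replicates=4, master_seed=3,
            validation_scope="own")
        means = rec.groupby("h2").accuracy.mean()
        assert means[0.1] < means[0.3] < means[0.6]

    def test_near_zero_heritability_gives_near_zero_accuracy(
            self, grid_panel, grid_grm):
        rec = mbgp.run_grid(
            grid_panel, grid_grm,
            {"single_A": mbgp.Design("single_A", ("A",), 150, 50)},
            {"I": [0.01]}, n_replicates=5, master_seed=4,
            validation_scope="own")
        assert abs(rec.accuracy.mean()) < 0.25

    def test_qtl_exclusion_matches_from_scratch_complement_grm(
            self, grid_panel):
        """The internal GRM down-date equals recomputing the GRM without the
        QTL markers, verified through identical GBLUP accuracies."""
        grm64 = mbgp.compute_grm(grid_panel, dtype=np.float64)
        design = {"single_A": mbgp.Design("single_A", ("A",), 150, 50)}
        rec_fast = mbgp.run_grid(grid_panel, grm64, design, {"I": [0.6]},
                                 n_replicates=1, master_seed=11)
        qtl = mbgp.sample_qtl(
            grid_panel, mbgp.STRATEGIES["I"],
            seed=int(np.random.SeedSequence(entropy=11, spawn_key=(0, 0, 0))
                     .generate_state(1)[0] % 2**31))
        keep = np.setdiff1d(np.arange(grid_panel.n_markers), qtl.marker_indices)
        sub = grid_panel.subset_markers(keep)
        grm_sub = mbgp.compute_grm(sub, freqs=grm64.freqs[keep],
                                   dtype=np.float64)
        full = mbgp.GRM(grm_sub.matrix, grm64.ids, grm_sub.n_markers,
                        grm_sub.freqs)
        rec_ref = mbgp.run_grid(grid_panel, full, design, {"I": [0.6]},
                                n_replicates=1, master_seed=11,
                                exclude_qtl_from_grm=False)
        merged = rec_fast.merge(rec_ref, on="validation_breed",
                                suffixes=("_fast", "_ref"))
        assert np.allclose(merged.accuracy_fast, merged.accuracy_ref, atol=5e-4)

    def test_validation_scope_filters_records(self, grid_panel, grid_grm):
        own = self.run(grid_panel, grid_grm, validation_scope="own")
        foreign = self.run(grid_panel, grid_grm, validation_scope="foreign")
        assert own.in_reference.all()
        assert not foreign.in_reference.any()

    def test_summarize_means_over_replicates(self, grid_panel, grid_grm):
        rec = self.run(grid_panel, grid_grm)
        summary = mbgp.summarize(rec)
        assert {"accuracy_mean", "accuracy_sd"} <= set(summary.columns)
        cell = summary[(summary.design == "single_A")
                       & (summary.h2 == 0.6) & summary.in_reference]
        manual = rec[(rec.design == "single_A") & (rec.h2 == 0.6)
                     & rec.in_reference].accuracy.mean()
        assert cell.accuracy_mean.iloc[0] == pytest.approx(manual)
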