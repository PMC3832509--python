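"""VEGF rank profiling and microvessel-area quantification."""
import math

import numpy as np
import pandas as pd
import pytest

import tnbcprofiler as tp

from conftest import make_matrix


class TestVegfRankScore:
    def _matrix(self, gene_values):
        genes = list(gene_values)
        vals = np.array([gene_values[g] for g in genes], dtype=float)
        return make_matrix(vals, probes=[f"pr_{g}" for g in genes],
                           genes=genes, is_log2=True)

    def test_single_gene_score_is_rank_vector(self):
        m = self._matrix({"VEGFA": [3.0, 1.0, 2.0]})
        score, used = tp.vegf_rank_score(m, ["VEGFA"])
        assert used == ["VEGFA"]
        assert list(score) == [3.0, 1.0, 2.0]

    def test_maximal_sample_scores_n_samples(self):
        m = self._matrix({"A": [1.0, 9.0], "B": [2.0, 8.0], "C": [0.0, 5.0]})
        score, _ = tp.vegf_rank_score(m, ["A", "B", "C"])
        assert score.iloc[1] == pytest.approx(2.0)  # top in every gene

    def test_hand_computed_mean_ranks_with_tie(self):
        m = self._matrix({
            "A": [1.0, 2.0, 3.0, 4.0],
            "B": [4.0, 3.0, 2.0, 1.0],
            "C": [1.0, 1.0, 2.0, 3.0],  # tie between samples 1 and 2
        })
        score, used = tp.vegf_rank_score(m, ["A", "B", "C"])
        # ranks: A=[1,2,3,4]; B=[4,3,2,1]; C=[1.5,1.5,3,4]
        expected = [(1 + 4 + 1.5) / 3, (2 + 3 + 1.5) / 3,
                    (3 + 2 + 3) / 3, (4 + 1 + 4) / 3]
        assert np.allclose(score, expected)

    def test_absent_genes_reported(self):
        m = self._matrix({"A": [1.0, 2.0], "B": [2.0, 1.0], "C": [1.0, 3.0]})
        score, used = tp.vegf_rank_score(m, ["A", "B", "C", "MISSING1",
                                             "MISSING2"])
        assert used == ["A", "B", "C"]

    def test_no_genes_errors(self):
        m = self._matrix({"A": [1.0, 2.0]})
        with pytest.raises(ValueError, match="none of the profile genes"):
            tp.vegf_rank_score(m, ["ZZZ"])


class TestPerGeneGroupTest:
    def test_identical_groups_null(self):
        vals = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (3, 1))
        m = make_matrix(vals, genes=["A", "B", "C"], is_log2=True)
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=m.sample_ids)
        out = tp.per_gene_group_test(m, ["A", "B", "C"], groups)
        assert np.allclose(out["p"], 1.0)

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(4, 10)),
                        genes=["A", "B", "C", "D"], is_log2=True)
        groups = pd.Series(["x"] * 5 + ["y"] * 5, index=m.sample_ids)
        out = tp.per_gene_group_test(m, ["A", "B", "C", "D"], groups)
        assert np.allclose(out["bonferroni_p"],
                           np.minimum(1.0, out["p"] * 4))

    def test_absent_gene_skipped_with_note(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(2, 8)), genes=["A", "B"],
                        is_log2=True)
        groups = pd.Series(["x"] * 4 + ["y"] * 4, index=m.sample_ids)
        out = tp.per_gene_group_test(m, ["A", "MISSING"], groups)
        assert "skipped" in out.loc["MISSING", "note"]

    def test_planted_subset_recovered(self):
        # 6 of 11 profile genes shifted by +2 SD in one group of 45: those
        # six and only those six should clear the Bonferroni 0.05 bar in the
        # vast majority of replicates
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            genes = [f"V{i}" for i in range(11)]
            vals = rng.normal(0, 1, size=(11, 90))
            vals[:6, :45] += 2.0
            m = make_matrix(vals, genes=genes, is_log2=True)
            groups = pd.Series(["AA"] * 45 + ["EA"] * 45, index=m.sample_ids)
            out = tp.per_gene_group_test(m, genes, groups)
            sig = set(out.index[out["bonferroni_p"] < 0.05])
            hits += sig == set(genes[:6])
        assert hits >= 0.9 * reps


class TestHistospotIO:
    def test_png_round_trip_within_quantisation(self, tmp_path):
        spot, _ = tp.simulate_histospot(96, 0.4, 0.01, n_vessels=1, seed=6,
                                        spot_id="core7")
        tp.write_histospot(spot, tmp_path)
        back = tp.read_histospot("core7", tmp_path)
        for name in ("cytokeratin", "dapi", "cd31"):
            orig = np.clip(getattr(spot, name), 0, 1)
            assert np.allclose(getattr(back, name), orig, atol=1.0 / 65535)

    def test_missing_channel_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="cytokeratin"):
            tp.read_histospot("ghost", tmp_path)


class TestMasks:
    def test_tumor_mask_recovers_fraction(self):
        spot, truth = tp.simulate_histospot(192, 0.5, 0.0, n_vessels=0, seed=0)
        spot = tp.tumor_mask(spot)
        assert not spot.excluded
        assert spot.tumor.mean() == pytest.approx(
            truth.tumor_fraction_of_spot, abs=0.05)

    def test_sparse_tumor_excluded(self):
        spot, _ = tp.simulate_histospot(192, 0.03, 0.0, n_vessels=0, seed=1)
        spot = tp.tumor_mask(spot)
        assert spot.excluded
        assert "below" in spot.exclusion_reason

    def test_blank_channel_excluded(self):
        blank = np.zeros((64, 64))
        spot = tp.Histospot("s", blank, blank, blank)
        spot = tp.tumor_mask(spot)
        assert spot.excluded
        assert spot.exclusion_reason == "no signal"

    def test_noise_only_channel_excluded(self):
        rng = np.random.default_rng(2)
        noise = np.abs(rng.normal(0.2, 0.04, size=(128, 128)))
        spot = tp.Histospot("s", noise, noise, noise)
        spot = tp.tumor_mask(spot)
        assert spot.excluded

    def test_compartments_partition_tumor(self):
        spot, _ = tp.simulate_histospot(192, 0.5, 0.0, n_vessels=0, seed=3)
        spot = tp.tumor_mask(spot)
        spot = tp.compartment_masks(spot)
        non_nuclear = spot.tumor & ~spot.nuclear
        assert not (spot.nuclear & non_nuclear).any()
        assert ((spot.nuclear | non_nuclear) == spot.tumor).all()

    def test_nuclear_fraction_recovered(self):
        spot, _ = tp.simulate_histospot(192, 0.5, 0.0, n_vessels=0, seed=4)
        spot = tp.tumor_mask(spot)
        spot = tp.compartment_masks(spot)
        frac = spot.nuclear.sum() / spot.tumor.sum()
        assert frac == pytest.approx(0.20, abs=0.05)

    def test_blank_dapi_gives_empty_nuclear(self):
        spot, _ = tp.simulate_histospot(128, 0.5, 0.0, n_vessels=0,
                                        noise_sd=0.0, seed=5)
        spot.dapi = np.zeros_like(spot.dapi)
        spot = tp.tumor_mask(spot)
        spot = tp.compartment_masks(spot)
        assert not spot.nuclear.any()


class TestMicrovesselArea:
    def test_zero_cd31(self):
        spot, truth = tp.simulate_histospot(128, 0.5, 0.0, n_vessels=0, seed=0)
        spot = tp.tumor_mask(spot)
        res = tp.microvessel_area(spot)
        assert res.mva_percent == 0.0
        assert res.high_mva is False
        assert truth.vessel_fraction_of_tumor == 0.0

    def test_planted_two_percent_recovered(self):
        spot, truth = tp.simulate_histospot(192, 0.5, 0.02, n_vessels=4,
                                            seed=1)
        spot = tp.tumor_mask(spot)
        res = tp.microvessel_area(spot)
        assert res.mva_percent == pytest.approx(
            100 * truth.vessel_fraction_of_tumor, abs=0.3)

    def test_default_threshold(self):
        import inspect
        sig = inspect.signature(tp.microvessel_area)
        assert sig.parameters["threshold_pct"].default == 0.6

    def test_excluded_spot_errors(self):
        spot, _ = tp.simulate_histospot(192, 0.03, 0.0, n_vessels=0, seed=2)
        spot = tp.tumor_mask(spot)
        with pytest.raises(ValueError, match="excluded"):
            tp.microvessel_area(spot)

    def test_scale_invariance(self):
        spot, _ = tp.simulate_histospot(192, 0.5, 0.02, n_vessels=4, seed=3)
        spot = tp.tumor_mask(spot)
        res = tp.microvessel_area(spot)
        scaled = tp.Histospot("s", spot.cytokeratin * 7.3, spot.dapi * 7.3,
                              spot.cd31 * 7.3)
        scaled = tp.tumor_mask(scaled)
        res2 = tp.microvessel_area(scaled)
        assert res2.mva_percent == pytest.approx(res.mva_percent, abs=0.05)

    def test_vessel_mask_within_tumor(self):
        spot, _ = tp.simulate_histospot(192, 0.4, 0.05, n_vessels=5, seed=4)
        spot = tp.tumor_mask(spot)
        tp.microvessel_area(spot)
        assert not (spot.vessel & ~spot.tumor).any()


class TestMvaAssociation:
    def _annotation(self, patients, nodal, stage=None):
        n = len(patients)
        return tp.validate_annotation(pd.DataFrame({
            "sample_id": patients,
            "patient_id": patients,
            "ethnicity": ["AA"] * n,
            "stage": stage or ["1"] * n,
            "nodal": nodal,
            "age": [50] * n,
            "tissue_site": ["primary"] * n,
        })).set_index("patient_id", drop=False)

    def test_perfect_separation_matches_fisher_oracle(self):
        patients = [f"p{i}" for i in range(20)]
        results = [tp.MvaResult(p, 0.5, 2.0 if i < 10 else 0.1,
                                i < 10, False)
                   for i, p in enumerate(patients)]
        ann = self._annotation(patients, ["pos"] * 10 + ["neg"] * 10)
        out = tp.mva_association(results, ann, "nodal")
        # two-sided Fisher p for the (10,0 / 0,10) table: both extreme
        # tables, each with probability 1/C(20,10)
        expected = 2 * math.comb(10, 10) ** 2 / math.comb(20, 10)
        assert out.loc["threshold_fisher", "p"] == pytest.approx(
            expected, rel=1e-9)
        assert expected < 0.001

    def test_both_tests_reported(self):
        rng = np.random.default_rng(0)
        patients = [f"p{i}" for i in range(16)]
        results = [tp.MvaResult(p, 0.5, float(rng.uniform(0, 2)), None, False)
                   for p in patients]
        for r in results:
            r.high_mva = r.mva_percent > 0.6
        ann = self._annotation(patients, ["pos", "neg"] * 8)
        out = tp.mva_association(results, ann, "nodal",
                                 strata_col="stage", n_resamples=100, seed=0)
        assert {"threshold_fisher", "numeric_welch",
                "numeric_stage_adjusted"} <= set(out.index)

    def test_excluded_spots_ignored_and_empty_patients_dropped(self):
        patients = ["p0", "p1", "p2", "p3", "p4"]
        results = [
            tp.MvaResult("p0_a", 0.5, 1.0, True, False),
            tp.MvaResult("p0_b", 0.5, 3.0, True, False),   # p0 averages 2.0
            tp.MvaResult("p1_a", 0.5, 1.5, True, False),
            tp.MvaResult("p2_a", 0.5, 0.2, False, False),
            tp.MvaResult("p3_a", 0.5, 0.3, False, False),
            tp.MvaResult("p4_a", None, None, None, True, "too sparse"),
        ]
        mapping = {r.spot_id: r.spot_id.split("_")[0] for r in results}
        ann = self._annotation(patients,
                               ["pos", "pos", "neg", "neg", "neg"])
        with pytest.warns(UserWarning, match="excluded spots"):
            out = tp.mva_association(results, ann, "nodal",
                                     spot_to_patient=mapping)
        # p4 dropped entirely; mean MVA pos = (2.0, 1.5), neg = (0.2, 0.3);
        # the t statistic compares levels in sorted order (neg minus pos)
        assert out.loc["numeric_welch", "statistic"] < 0
        assert set(out.index) == {"threshold_fisher", "numeric_welch"}

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        rej = 0
        reps = 100
        for rep in range(reps):
            patients = [f"p{i}" for i in range(30)]
            results = [tp.MvaResult(p, 0.5, float(rng.gamma(2, 0.4)), None,
                                    False) for p in patients]
            for r in results:
                r.high_mva = r.mva_percent > 0.6
            nodal = list(rng.permutation(["pos"] * 15 + ["neg"] * 15))
            ann = self._annotation(patients, nodal)
            out = tp.mva_association(results, ann, "nodal")
            rej += out.loc["numeric_welch", "p"] < 0.05
        assert rej / reps <= 0.11
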