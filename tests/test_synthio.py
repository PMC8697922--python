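import numpy as np
import pandas as pd
import pytest

from cernet import circfilter, synthio, targetlink, cernanet


SMALL = dict(
    n_features={"mRNA": 120, "lncRNA": 40, "miRNA": 30, "circRNA": 60},
    n_triplets=4,
    n_circ_candidates=60,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_samples_per_condition", 1),
        ("frac_de", 1.5),
        ("pred_sensitivity", -0.1),
        ("pred_specificity", 2.0),
        ("nb_dispersion", -1.0),
        ("corr_noise_sd", -0.5),
        ("n_triplets", -1),
        ("triplet_log2fc", 0.0),
    ])
    def test_invalid_field_rejected_by_name(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            synthio.SynthConfig(**{**SMALL, field: value})

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            synthio.SynthConfig.from_dict({"n_samplez": 3})

    def test_scalar_frac_de_broadcast(self):
        cfg = synthio.SynthConfig(**{**SMALL, "frac_de": 0.1})
        assert set(cfg.frac_de) == {"mRNA", "lncRNA", "miRNA", "circRNA"}

    def test_too_few_features_for_triplets_rejected(self):
        with pytest.raises(ValueError, match="n_features"):
            synthio.SynthConfig(
                n_features={"mRNA": 2, "lncRNA": 5, "miRNA": 10, "circRNA": 10},
                n_triplets=5,
            )


class TestGenerateCounts:
    def test_determinism_bit_identical(self):
        a, ta = synthio.generate_counts(synthio.SynthConfig(seed=1, **SMALL))
        b, tb = synthio.generate_counts(synthio.SynthConfig(seed=1, **SMALL))
        for layer in a:
            pd.testing.assert_frame_equal(a[layer].values, b[layer].values)
        assert ta.planted_de == tb.planted_de
        assert ta.planted_triplets == tb.planted_triplets

    def test_different_seed_differs(self):
        a, _ = synthio.generate_counts(synthio.SynthConfig(seed=1, **SMALL))
        b, _ = synthio.generate_counts(synthio.SynthConfig(seed=2, **SMALL))
        assert not a["mRNA"].values.equals(b["mRNA"].values)

    def test_frac_de_zero_plants_nothing(self):
        cfg = synthio.SynthConfig(seed=3, **{**SMALL, "frac_de": 0.0})
        _, truth = synthio.generate_counts(cfg)
        assert truth.planted_de == set()

    def test_non_de_features_share_condition_means(self):
        cfg = synthio.SynthConfig(seed=4, **SMALL)
        _, truth = synthio.generate_counts(cfg)
        m = cfg.n_samples_per_condition
        planted = {fid for (_, fid, _) in truth.planted_de}
        triplet_ids = {x for (ce, _, mi, mr) in truth.planted_triplets for x in (ce, mi, mr)}
        for layer, lat in truth.latent_log2_means.items():
            flat = lat.drop(index=(planted | triplet_ids) & set(lat.index))
            assert np.allclose(flat.iloc[:, :m].to_numpy(),
                               flat.iloc[:, m:].to_numpy())

    def test_planted_de_fold_change_exact_on_condition_means(self):
        cfg = synthio.SynthConfig(seed=5, **SMALL)
        _, truth = synthio.generate_counts(cfg)
        m = cfg.n_samples_per_condition
        for layer, fid, direction in truth.planted_de:
            lat = truth.latent_log2_means[layer].loc[fid].to_numpy()
            fc = np.log2(np.mean(2.0 ** lat[m:])) - np.log2(np.mean(2.0 ** lat[:m]))
            expected = cfg.log2fc_magnitude if direction == "up" else -cfg.log2fc_magnitude
            assert fc == pytest.approx(expected, abs=1e-9)

    def test_noiseless_triplet_latents_are_perfectly_coupled(self):
        cfg = synthio.SynthConfig(seed=6, corr_noise_sd=0.0, **SMALL)
        _, truth = synthio.generate_counts(cfg)
        assert truth.planted_triplets
        for (ce, cl, mi, mr) in truth.planted_triplets:
            zmi = truth.latent_log2_means["miRNA"].loc[mi].to_numpy()
            zmr = truth.latent_log2_means["mRNA"].loc[mr].to_numpy()
            zce = truth.latent_log2_means[cl].loc[ce].to_numpy()
            assert targetlink.spearman(zmi, zmr).coefficient == pytest.approx(-1.0)
            assert targetlink.spearman(zmi, zce).coefficient == pytest.approx(-1.0)
            # latent means are proportional -> PCC exactly +1
            assert cernanet.pearson(2.0**zce, 2.0**zmr).coefficient == pytest.approx(1.0)

    def test_triplet_ids_exist_in_matrices(self):
        cfg = synthio.SynthConfig(seed=7, **SMALL)
        mats, truth = synthio.generate_counts(cfg)
        for (ce, cl, mi, mr) in truth.planted_triplets:
            assert ce in mats[cl].values.index
            assert mi in mats["miRNA"].values.index
            assert mr in mats["mRNA"].values.index


class TestCircCandidates:
    def test_zero_requested_gives_empty(self):
        cfg = synthio.SynthConfig(seed=1, **{**SMALL, "n_circ_candidates": 0})
        cands, truth = synthio.generate_circ_candidates(cfg)
        assert cands == [] and truth.circ_truth == {}

    def test_determinism(self):
        cfg = synthio.SynthConfig(seed=9, **SMALL)
        a, _ = synthio.generate_circ_candidates(cfg)
        b, _ = synthio.generate_circ_candidates(cfg)
        assert [vars(x) for x in a] == [vars(y) for y in b]

    def test_truth_matches_independent_reevaluation(self):
        cfg = synthio.SynthConfig(seed=10, **SMALL)
        cands, truth = synthio.generate_circ_candidates(cfg)
        n_samples = 2 * cfg.n_samples_per_condition
        half = n_samples // 2
        for c in cands:
            v = truth.circ_truth[c.candidate_id]
            assert v["a"] == (c.breakpoint_count == 1)
            assert v["b"] == (c.anchor_overlap <= 2)
            assert v["c"] == (c.edit_distance <= 2)
            assert v["d"] == (c.n_uniq > 2)
            assert v["e"] == (c.best_qual_A > 35 or c.best_qual_B > 35)
            assert v["f"] == (c.n_uniq > half)
            assert v["g"] == (c.end - c.start < 100_000)
            assert v["overall"] == all(v[k] for k in "abcdefg")

    def test_every_criterion_exercised_both_ways(self):
        cfg = synthio.SynthConfig(seed=11, **SMALL)
        _, truth = synthio.generate_circ_candidates(cfg)
        for crit in "abcdefg":
            outcomes = {v[crit] for v in truth.circ_truth.values()}
            assert outcomes == {True, False}, crit


class TestPredictionTables:
    def _truth(self, seed=12, **over):
        cfg = synthio.SynthConfig(seed=seed, **{**SMALL, **over})
        _, truth = synthio.generate_counts(cfg)
        return cfg, truth

    def test_perfect_tables_equal_true_pairs(self):
        cfg, truth = self._truth(pred_sensitivity=1.0, pred_specificity=1.0)
        true_pairs = {(mi, mr) for (_, _, mi, mr) in truth.planted_triplets}
        for table in synthio.generate_prediction_tables(truth, cfg):
            assert set(zip(table["miRNA_id"], table["target_id"])) == true_pairs

    def test_zero_sensitivity_empties_intersection(self):
        cfg, truth = self._truth(pred_sensitivity=0.0, pred_specificity=0.5)
        tables = synthio.generate_prediction_tables(truth, cfg)
        inter = targetlink.intersect_predictions(*tables)
        true_pairs = {(mi, mr) for (_, _, mi, mr) in truth.planted_triplets}
        assert inter & true_pairs == set()

    def test_intersection_survival_matches_binomial_expectation(self):
        # each true pair survives the three-way intersection w.p. s^3
        sens = 0.8
        survived = 0
        n_seeds = 250
        for seed in range(n_seeds):
            cfg, truth = self._truth(seed=seed, pred_sensitivity=sens,
                                     pred_specificity=1.0)
            tables = synthio.generate_prediction_tables(truth, cfg)
            inter = targetlink.intersect_predictions(*tables)
            survived += len(inter)
        n_true = SMALL["n_triplets"]
        expect = n_true * sens**3
        se = np.sqrt(n_true * sens**3 * (1 - sens**3) / n_seeds)
        assert survived / n_seeds == pytest.approx(expect, abs=4 * se)


class TestDatasetWriter:
    def test_written_files_round_trip(self, tmp_path):
        cfg = synthio.SynthConfig(seed=13, **SMALL)
        mats, truth = synthio.generate_counts(cfg)
        cands, ct = synthio.generate_circ_candidates(cfg)
        truth.circ_truth = ct.circ_truth
        preds = synthio.generate_prediction_tables(truth, cfg)
        synthio.write_dataset(tmp_path, mats, truth, cands, preds)
        assert (tmp_path / "counts_mRNA.tsv").exists()
        back = pd.read_csv(tmp_path / "counts_mRNA.tsv", sep="\t", index_col="feature_id")
        pd.testing.assert_frame_equal(
            back, mats["mRNA"].values, check_dtype=False, check_names=False
        )
        trips = pd.read_csv(tmp_path / "truth_triplets.tsv", sep="\t")
        assert len(trips) == len(truth.planted_triplets)
        assert (tmp_path / "circ_candidates.tsv").exists()
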