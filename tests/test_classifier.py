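import numpy as np
import pytest
from hypothesis import given, strategies as st

from ced_tcr import (
    Cohort,
    PredictiveModel,
    apply_model,
    bootstrap_ci,
    catalog_hits,
    choose_threshold,
    classify_sample,
    evaluate,
    loocv,
    motif_matrix,
    rank_candidate_sequences,
    rank_frequencies,
    scan_thresholds,
    select_predictive,
    train_model,
)
from ced_tcr.classifier import ThresholdScan
from ced_tcr.types import EvaluationResult

from conftest import (
    make_catalog,
    make_repertoire,
    oracle_select,
    random_instance,
)


class TestRankFrequencies:
    def test_descending_counts_with_lexicographic_tie_break(self):
        rep = make_repertoire(
            [("CASSD", 10), ("CASSE", 5), ("CASSA", 5), ("CASSC", 1)]
        )
        rk = rank_frequencies(rep)
        assert rk.cdr3_r["CASSD"] == pytest.approx(0.25)
        assert rk.cdr3_r["CASSA"] == pytest.approx(0.5)
        assert rk.cdr3_r["CASSE"] == pytest.approx(0.75)
        assert rk.cdr3_r["CASSC"] == pytest.approx(1.0)

    def test_single_clone_gets_r_one(self):
        rk = rank_frequencies(make_repertoire([("CASSA", 7)]))
        assert rk.cdr3_r["CASSA"] == 1.0

    def test_top_clone_r_is_one_over_n(self):
        rep = make_repertoire([("C" + "A" * i, 100 - i) for i in range(1, 11)])
        rk = rank_frequencies(rep)
        assert min(rk.clone_r.values()) == pytest.approx(0.1)

    def test_cdr3_level_r_is_minimum_over_clones(self):
        rep = make_repertoire(
            [("CASSA", 10, "TRBV1", "TRBJ1"), ("CASSA", 1, "TRBV2", "TRBJ1"),
             ("CASSG", 5, "TRBV1", "TRBJ1")]
        )
        rk = rank_frequencies(rep)
        assert rk.cdr3_r["CASSA"] == pytest.approx(1 / 3)

    def test_empty_repertoire_warns(self, caplog):
        with caplog.at_level("WARNING"):
            rk = rank_frequencies(make_repertoire([]))
        assert rk.n_clones == 0 and rk.cdr3_r == {}

    @given(st.randoms(use_true_random=False))
    def test_bijection_and_permutation_invariance(self, pyrng):
        n = pyrng.randint(1, 20)
        seqs = ["C" + "A" * i for i in range(n)]
        records = [(s, pyrng.randint(1, 5)) for s in seqs]
        rep = make_repertoire(records)
        shuffled = records[:]
        pyrng.shuffle(shuffled)
        rk1 = rank_frequencies(rep)
        rk2 = rank_frequencies(make_repertoire(shuffled))
        assert rk1.clone_r == rk2.clone_r
        assert sorted(rk1.clone_r.values()) == pytest.approx(
            [(i + 1) / n for i in range(n)]
        )


class TestCatalogHits:
    def test_threshold_inclusion(self):
        rep = make_repertoire([("C" + "A" * i, 20 - i) for i in range(1, 11)])
        rk = rank_frequencies(rep)
        cat = make_catalog(["CAAAA"])  # r = 0.4
        assert catalog_hits(rk, cat, 0.5) == {"CAAAA"}
        assert catalog_hits(rk, cat, 0.3) == set()

    def test_threshold_one_is_presence_absence(self):
        """At t = 1 the hit set is the plain catalog-sample intersection."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            cohort, catalog = random_instance(rng)
            for rep in cohort.repertoires:
                rk = rank_frequencies(rep)
                assert catalog_hits(rk, catalog, 1.0) == (
                    set(catalog.sequences("TRB")) & rep.cdr3_set
                )


class TestSelectPredictive:
    def _cohort(self, ced_records, ctrl_records):
        return Cohort(
            name="c",
            repertoires=[
                make_repertoire(ced_records, sample_id="ced1", label="CeD"),
                make_repertoire(ctrl_records, sample_id="ctl1", label="control"),
            ],
        )

    def test_ced_hit_without_control_hit_selects(self):
        # X at r=0.2 in the CeD sample only
        cohort = self._cohort(
            [("CAAW" + "A" * i, 50 - i) for i in range(10)], [("CVVV", 1)]
        )
        cat = make_catalog(["CAAWA"])  # second-ranked, r = 0.2
        assert select_predictive(cohort, cat, 0.5, "TRB") == {"CAAWA"}

    def test_control_hit_below_threshold_disqualifies(self):
        cohort = self._cohort(
            [("CTARGET", 1)] + [("C" + "A" * i, 50 - i) for i in range(1, 10)],
            [("CTARGET", 9), ("CVVV", 1)],
        )
        # CeD r = 1.0 (last of 10), control r = 0.5: control hit at t=0.5 kills it
        assert select_predictive(cohort, make_catalog(["CTARGET"]), 0.5, "TRB") \
            == frozenset()

    def test_control_occurrence_above_threshold_tolerated(self):
        # Z ranked 0.3 in CeD, 0.8 in control; the control occurrence is above
        # the threshold and does not disqualify
        ced = [("C" + "A" * i, 50 - i) for i in range(1, 10)]
        ced.insert(2, ("CTARGET", 48))  # ties with "CAA"; lexicographic order puts it third
        ctrl = [("C" + "D" * i, 50 - i) for i in range(1, 8)] + [
            ("CTARGET", 2), ("CVV", 1), ("CWW", 1)
        ]
        cohort = self._cohort(ced, ctrl)
        cat = make_catalog(["CTARGET"])
        assert rank_frequencies(cohort.repertoires[0]).cdr3_r["CTARGET"] == \
            pytest.approx(0.3)
        assert rank_frequencies(cohort.repertoires[1]).cdr3_r["CTARGET"] == \
            pytest.approx(0.8)
        assert select_predictive(cohort, cat, 0.5, "TRB") == {"CTARGET"}
        assert oracle_select(cohort, cat, 0.5, "TRB") == {"CTARGET"}

    def test_requires_both_classes(self):
        cohort = Cohort(
            name="c",
            repertoires=[make_repertoire([("CAS", 1)], sample_id="a", label="CeD")],
        )
        with pytest.raises(ValueError):
            select_predictive(cohort, make_catalog(["CAS"]), 0.5, "TRB")

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Vectorised selection equals literal rule enumeration on random
        small cohorts with ties, shared sequences and control occurrences."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            cohort, catalog = random_instance(rng)
            t = float(rng.choice([0.2, 0.4, 0.5, 0.7, 0.9, 1.0]))
            assert select_predictive(cohort, catalog, t, "TRB") == \
                oracle_select(cohort, catalog, t, "TRB")


class TestClassifyEvaluate:
    def model(self, seqs=("CTARGET",), t=0.6, chains=("TRB",)):
        return PredictiveModel(
            chains=chains, threshold=t,
            sequences={ch: tuple(seqs) for ch in chains},
        )

    def test_hit_below_threshold_is_ced(self):
        rep = make_repertoire([("C" + "A" * i, 20 - i) for i in range(1, 5)]
                              + [("CTARGET", 19)])
        assert classify_sample(rank_frequencies(rep), self.model()) == "CeD"

    def test_absent_sequence_is_control(self):
        rep = make_repertoire([("CAAA", 5)])
        assert classify_sample(rank_frequencies(rep), self.model()) == "control"

    def test_multichain_union_rule(self):
        beta = make_repertoire([("CTARGET", 5)], chain="TRB")
        alpha = make_repertoire([("CAVAA", 5)], chain="TRA")
        model = PredictiveModel(
            chains=("TRA", "TRB"), threshold=1.0,
            sequences={"TRA": ("CAVWW",), "TRB": ("CTARGET",)},
        )
        pred = classify_sample(
            {"TRA": rank_frequencies(alpha), "TRB": rank_frequencies(beta)}, model
        )
        assert pred == "CeD"  # hit on the beta chain alone suffices

    def test_chain_mismatch_is_error(self):
        rep = make_repertoire([("CAVAA", 5)], chain="TRA")
        with pytest.raises(ValueError):
            classify_sample(rank_frequencies(rep), self.model(chains=("TRB",)))

    def test_empty_repertoire_is_control_with_warning(self, caplog):
        rep = make_repertoire([], chain="TRB")
        with caplog.at_level("WARNING"):
            assert classify_sample(rank_frequencies(rep), self.model()) == "control"

    def test_testing_cohort_arithmetic(self):
        # 9 CeD of which 6 called correctly, 6 controls all correct
        preds = ["CeD"] * 6 + ["control"] * 3 + ["control"] * 6
        truth = ["CeD"] * 9 + ["control"] * 6
        res = evaluate(preds, truth)
        assert res.sensitivity == pytest.approx(2 / 3, abs=5e-3)
        assert res.specificity == 1.0
        assert res.accuracy == pytest.approx(0.8)

    def test_all_correct(self):
        res = evaluate(["CeD", "control"], ["CeD", "control"])
        assert (res.sensitivity, res.specificity, res.accuracy,
                res.balanced_accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_absent_class_reported_missing(self):
        res = evaluate(["CeD", "CeD"], ["CeD", "CeD"])
        assert res.specificity is None
        assert res.balanced_accuracy is None
        assert res.sensitivity == 1.0

    @given(
        labels=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40
        )
    )
    def test_measure_identities(self, labels):
        preds = ["CeD" if p else "control" for p, _ in labels]
        truth = ["CeD" if t else "control" for _, t in labels]
        res = evaluate(preds, truth)
        p_n = sum(1 for t in truth if t == "CeD")
        n_n = len(truth) - p_n
        if res.sensitivity is not None and res.specificity is not None:
            assert res.accuracy == pytest.approx(
                (res.sensitivity * p_n + res.specificity * n_n) / (p_n + n_n)
            )
            assert res.balanced_accuracy == pytest.approx(
                (res.sensitivity + res.specificity) / 2
            )


class TestThresholdMachinery:
    def test_scan_on_planted_cohort_has_perfect_plateau(self, planted):
        cohort, catalog, truth = planted
        scan = scan_thresholds(cohort, catalog, chains=("TRA",))
        for t in (0.5, 0.6, 0.7):
            assert t in scan.plateau
            assert scan.results[t].accuracy == 1.0

    def test_disjoint_catalog_gives_all_control_baseline(self, planted):
        cohort, _, _ = planted
        foreign = make_catalog(["WWWWWWWW"], chain="TRA")
        scan = scan_thresholds(cohort, foreign, chains=("TRA",))
        n_ctrl = sum(1 for r in cohort.repertoires
                     if r.chain == "TRA" and r.label == "control")
        n = sum(1 for r in cohort.repertoires if r.chain == "TRA")
        for t in scan.grid:
            assert scan.results[t].sensitivity == 0.0
            assert scan.results[t].accuracy == pytest.approx(n_ctrl / n)

    def test_single_point_grid(self, planted):
        cohort, catalog, _ = planted
        scan = scan_thresholds(cohort, catalog, grid=[1.0], chains=("TRA",))
        assert scan.plateau == (1.0,)

    def _scan(self, plateau):
        grid = tuple(plateau)
        res = {t: EvaluationResult(tp=1, fn=0, tn=1, fp=0) for t in grid}
        return ThresholdScan(grid, res, grid)

    def test_choose_single_member(self):
        assert choose_threshold(self._scan([0.3]), {}) == 0.3

    def test_choose_median_on_equal_ci_widths(self):
        plateau = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        cis = {t: {"accuracy": (0.8, 1.0)} for t in plateau}
        assert choose_threshold(self._scan(plateau), cis) == 0.4

    def test_choose_narrowest_ci(self):
        cis = {0.2: {"accuracy": (0.6, 1.0)}, 0.6: {"accuracy": (0.9, 1.0)}}
        assert choose_threshold(self._scan([0.2, 0.6]), cis) == 0.6

    def test_bootstrap_separable_cohort_degenerate_ci(self, planted):
        cohort, catalog, _ = planted
        ci = bootstrap_ci(cohort, catalog, 0.6, chains=("TRA",), B=100, seed=5)
        assert ci["accuracy"] == (1.0, 1.0)

    def test_bootstrap_single_replicate_and_determinism(self, planted):
        cohort, catalog, _ = planted
        one = bootstrap_ci(cohort, catalog, 0.9, chains=("TRA",), B=1, seed=2)
        assert one["accuracy"][0] == one["accuracy"][1]
        a = bootstrap_ci(cohort, catalog, 0.9, chains=("TRA",), B=50, seed=7)
        b = bootstrap_ci(cohort, catalog, 0.9, chains=("TRA",), B=50, seed=7)
        assert a == b


class TestTrainLoocvApply:
    def test_training_recovers_planted_set(self, planted):
        cohort, catalog, truth = planted
        result = train_model(cohort, catalog, chains=("TRA",), B=50, seed=1)
        assert set(result.model.sequences["TRA"]) == set(truth.planted["TRA"])
        assert result.evaluation.accuracy == 1.0

    def test_loocv_pooled_sensitivity_on_planted_cohort(self, planted):
        cohort, catalog, truth = planted
        report = loocv(cohort, catalog, chains=("TRA",), B=30, seed=2)
        n = len(cohort.sample_ids(chains=("TRA",)))
        assert report.n_folds == n
        assert report.pooled.sensitivity == 1.0
        # core sequences shared by every CeD sample are selected in all folds
        core = set.intersection(
            *(set(s for s, _ in truth.placements[(sid, "TRA")])
              for sid in truth.labels if truth.labels[sid] == "CeD")
        )
        for seq in core:
            assert report.fold_counts["TRA"][seq] == n

    def test_loocv_cannot_use_heldout_information(self):
        # one CeD sample alone carries the only catalog sequence: its fold
        # must misclassify it
        filler = [("C" + "D" * i, 30 - i) for i in range(1, 6)]
        reps = [
            make_repertoire([("CTARGET", 40)] + filler, sample_id="ced1",
                            label="CeD"),
            make_repertoire(filler, sample_id="ced2", label="CeD"),
            make_repertoire(filler, sample_id="ced3", label="CeD"),
            make_repertoire([("CVV", 2)], sample_id="ctl1", label="control"),
            make_repertoire([("CWW", 2)], sample_id="ctl2", label="control"),
        ]
        report = loocv(Cohort(name="c", repertoires=reps),
                       make_catalog(["CTARGET"]), chains=("TRB",), B=5, seed=0)
        fold = next(f for f in report.folds if f.held_out == "ced1")
        assert fold.prediction == "control"

    def test_loocv_minimal_cohort_is_well_formed(self):
        reps = [
            make_repertoire([("CTARGET", 5), ("CAA", 1)], sample_id="ced1",
                            label="CeD"),
            make_repertoire([("CTARGET", 5), ("CDD", 1)], sample_id="ced2",
                            label="CeD"),
            make_repertoire([("CVV", 2)], sample_id="ctl1", label="control"),
        ]
        report = loocv(Cohort(name="c", repertoires=reps),
                       make_catalog(["CTARGET"]), chains=("TRB",), B=5, seed=0)
        assert len(report.folds) <= 3
        assert report.pooled.accuracy is not None

    def test_apply_empty_model_predicts_all_control(self, planted):
        cohort, _, _ = planted
        model = PredictiveModel(chains=("TRA",), threshold=0.6, sequences={})
        report = apply_model(cohort, model)
        assert set(report.predictions.values()) == {"control"}
        assert report.evaluation.sensitivity == 0.0

    def test_apply_to_planted_test_cohort_matches_design(self, planted):
        from ced_tcr.simulate import SyntheticConfig, generate_cohort
        from conftest import FAST_CFG

        cohort, catalog, truth = planted
        result = train_model(cohort, catalog, chains=("TRA",), B=50, seed=1)
        test_cfg = SyntheticConfig(**{**FAST_CFG, "seed": 101})
        test, _, test_truth = generate_cohort(test_cfg, name="test",
                                              catalog=catalog)
        report = apply_model(test, result.model)
        # every test CeD sample carries core planted sequences below the
        # ceiling, and controls only decoys above it -> perfect evaluation
        assert report.evaluation.sensitivity == 1.0
        assert report.evaluation.specificity == 1.0
        for seq, n in report.testing_counts["TRA"].items():
            planted_in = sum(
                1 for (sid, ch), pls in test_truth.placements.items()
                if ch == "TRA" and any(s == seq for s, _ in pls)
            )
            assert n == planted_in

    def test_apply_requires_model_chain(self, planted):
        cohort, _, _ = planted
        tra_only = Cohort(
            name="t",
            repertoires=[r for r in cohort.repertoires if r.chain == "TRA"],
        )
        model = PredictiveModel(chains=("TRB",), threshold=0.5, sequences={})
        with pytest.raises(ValueError, match="TRB"):
            apply_model(tra_only, model)


class TestPrioritisation:
    def test_testing_count_outranks_training_count(self):
        table = rank_candidate_sequences(
            {"AYRSEQGAQKLV": 2, "GDGGATNKL": 6},
            {"AYRSEQGAQKLV": 20, "GDGGATNKL": 19},
            {"AYRSEQGAQKLV": 3, "GDGGATNKL": 2},
        )
        assert [r.sequence for r in table.rows] == ["AYRSEQGAQKLV", "GDGGATNKL"]
        assert [r.rank_label for r in table.rows] == ["1", "2"]

    def test_ties_share_label_with_competition_ranking(self):
        train = {"A": 5, "B": 2, "C": 2, "D": 1, "E": 1}
        test = {"A": 2, "B": 1, "C": 1, "D": 1, "E": 1}
        table = rank_candidate_sequences(train, {}, test)
        labels = {r.sequence: r.rank_label for r in table.rows}
        assert labels["A"] == "1"
        assert labels["B"] == labels["C"] == "2="
        assert labels["D"] == labels["E"] == "4="

    def test_single_row(self):
        table = rank_candidate_sequences({"A": 1}, {"A": 3}, {"A": 1})
        assert table.rows[0].rank_label == "1"
        assert table.to_frame().columns[0] == "Rank"


class TestMotifMatrix:
    def test_position_frequencies(self):
        mat = motif_matrix({"AAA", "AAC"}, 3)
        assert mat.loc["A", 3] == pytest.approx(0.5)
        assert mat.loc["C", 3] == pytest.approx(0.5)
        assert np.allclose(mat.sum(axis=0), 1.0)

    def test_single_sequence(self):
        mat = motif_matrix({"ACD"}, 3)
        assert mat.loc["A", 1] == 1.0 and mat.loc["C", 2] == 1.0

    def test_no_sequences_of_length(self, caplog):
        with caplog.at_level("WARNING"):
            mat = motif_matrix({"AAAA"}, 7)
        assert mat.empty
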