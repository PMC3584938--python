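"""Scoring methods: D0 worked examples, properties, calibration, enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from gopred.annotations import AnnotationDB, CooccurrenceTable
from gopred.predictors import (
    CalibrationTable,
    PredictionSet,
    blast_baseline,
    build_calibration,
    empirical_pvalue,
    enrich_with_prior,
    esg_scores,
    gotcha_scores,
    pfp_confidence,
    pfp_parent_transfer,
    pfp_raw_scores,
    prior_prediction_set,
    prior_predictions,
    truncate_predictions,
)
from gopred.search_io import Hit, build_hit_graph
from conftest import random_instance


class TestPFPRaw:
    def test_d0_one_hit_hand_values(self, d0):
        """One hit on p2 (annots {A1, B}) at E=1e-3, b=2: the factor is 5 and
        s(A1) = 5*(P(A1|A1)+P(A1|B)) = 10, s(B) = 5*(0.5+1) = 7.5."""
        T = d0["T"]
        raw = pfp_raw_scores(
            [Hit("t", "p2", 80.0, 1e-3)], d0["db"], d0["cooc"], d0["dag"], "BP"
        )
        assert raw[T["A1"]] == pytest.approx(10.0, abs=1e-9)
        assert raw[T["B"]] == pytest.approx(7.5, abs=1e-9)
        assert T["A2"] not in raw

    def test_no_hits_gives_empty_map(self, d0):
        assert pfp_raw_scores([], d0["db"], d0["cooc"], d0["dag"], "BP") == {}

    def test_hit_at_ceiling_contributes_nothing(self, d0):
        raw = pfp_raw_scores(
            [Hit("t", "p2", 80.0, 100.0)], d0["db"], d0["cooc"], d0["dag"], "BP"
        )
        assert all(v == 0.0 for v in raw.values())

    @given(st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_adding_a_supporting_hit_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        cooc = CooccurrenceTable.build(inst.db, inst.dag, "BP")
        protein = inst.db.proteins[int(rng.integers(len(inst.db.proteins)))]
        fa = sorted(inst.protein_terms[protein])[0]
        before = pfp_raw_scores(inst.hits, inst.db, cooc, inst.dag, "BP")
        extra = Hit("T1", protein, 50.0, 1e-6)
        after = pfp_raw_scores(
            inst.hits + [extra], inst.db, cooc, inst.dag, "BP"
        )
        assert after.get(fa, 0.0) >= before.get(fa, 0.0) - 1e-12


class TestPFPTransfer:
    def test_d0_hand_ratios(self, d0):
        """s(A1)=10 transfers 10*freq(A1)/freq(A) = 20/3 to A and
        10*2/4 = 5 to the root."""
        T = d0["T"]
        out = pfp_parent_transfer({T["A1"]: 10.0}, d0["dag"], d0["stats"])
        assert out[T["A"]] == pytest.approx(10 * 2 / 3, abs=1e-9)
        assert out[T["R"]] == pytest.approx(5.0, abs=1e-9)

    def test_zero_score_transfers_zero(self, d0):
        out = pfp_parent_transfer({d0["T"]["A1"]: 0.0}, d0["dag"], d0["stats"])
        assert all(v == 0.0 for v in out.values())

    def test_root_receives_but_never_transfers(self, d0):
        T = d0["T"]
        out = pfp_parent_transfer({T["R"]: 3.0}, d0["dag"], d0["stats"])
        assert out == {T["R"]: 3.0}


class TestESG:
    def test_level1_only_hand_weights(self, d0):
        T = d0["T"]
        db = AnnotationDB({"h1": {T["A1"]: {"EXP"}}, "h2": {T["B"]: {"EXP"}}})
        g = build_hit_graph("t", [Hit("t", "h1", 80, 1e-4), Hit("t", "h2", 70, 1e-2)])
        scores = esg_scores(g, db, d0["dag"], "BP")
        assert scores[T["A1"]] == pytest.approx(4 / 6, abs=1e-9)
        assert scores[T["B"]] == pytest.approx(2 / 6, abs=1e-9)

    def test_two_level_split_hand_values(self, d0):
        T = d0["T"]
        db = AnnotationDB({
            "h1": {T["A1"]: {"EXP"}},
            "h2": {T["B"]: {"EXP"}},
            "g1": {T["A2"]: {"EXP"}},
        })
        g = build_hit_graph(
            "t",
            [Hit("t", "h1", 80, 1e-4), Hit("t", "h2", 70, 1e-2)],
            {"h1": [Hit("h1", "g1", 60, 1e-5)]},
        )
        scores = esg_scores(g, db, d0["dag"], "BP", a=0.5)
        assert scores[T["A1"]] == pytest.approx(1 / 3, abs=1e-9)
        assert scores[T["A2"]] == pytest.approx(1 / 3, abs=1e-9)
        assert scores[T["B"]] == pytest.approx(1 / 3, abs=1e-9)

    def test_single_annotated_hit_scores_one(self, d0):
        T = d0["T"]
        db = AnnotationDB({"h1": {T["A1"]: {"EXP"}}})
        g = build_hit_graph("t", [Hit("t", "h1", 80, 1e-9)])
        assert esg_scores(g, db, d0["dag"], "BP") == {T["A1"]: 1.0}

    def test_empty_graph_gives_empty_scores(self, d0):
        g = build_hit_graph("t", [])
        assert esg_scores(g, d0["db"], d0["dag"], "BP") == {}

    @given(st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_matches_two_level_enumerator_and_sum_bound(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        proteins = inst.db.proteins
        level2 = {
            h.subject: [
                Hit(h.subject, proteins[int(rng.integers(len(proteins)))],
                    50.0, float(10.0 ** rng.uniform(-8, 1)))
                for _ in range(int(rng.integers(0, 3)))
            ]
            for h in inst.hits
            if rng.random() < 0.5
        }
        g = build_hit_graph("T1", inst.hits, level2)
        scores = esg_scores(g, inst.db, inst.dag, "BP", a=0.5)
        expected = oracles.naive_esg(inst.hits, level2, inst.protein_terms, a=0.5)
        expected = {t: v for t, v in expected.items() if v > 0}
        assert set(scores) == set(expected)
        for term, value in expected.items():
            assert scores[term] == pytest.approx(value, abs=1e-12)
        if scores:
            assert all(-1e-12 <= v <= 1 + 1e-12 for v in scores.values())
            max_annot = max(len(t) for t in inst.protein_terms.values())
            assert sum(scores.values()) <= max_annot + 1e-9


class TestGOtcha:
    def test_d0_hand_i_scores(self, d0):
        T = d0["T"]
        db = AnnotationDB({"h1": {T["A1"]: {"EXP"}}, "h2": {T["B"]: {"EXP"}}})
        scores = gotcha_scores(
            [Hit("t", "h1", 80, 1e-5), Hit("t", "h2", 70, 1e-3)],
            db, d0["dag"], "BP",
        )
        assert scores[T["A1"]] == pytest.approx(0.625, abs=1e-9)
        assert scores[T["B"]] == pytest.approx(0.375, abs=1e-9)
        assert scores[T["R"]] == 1.0

    def test_weak_hits_only_gives_empty_set(self, d0):
        scores = gotcha_scores(
            [Hit("t", "p1", 80, 2.0), Hit("t", "p2", 70, 50.0)],
            d0["db"], d0["dag"], "BP",
        )
        assert scores == {}

    @given(st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_ancestors_dominate_descendants(self, seed):
        inst = random_instance(np.random.default_rng(seed))
        scores = gotcha_scores(inst.hits, inst.db, inst.dag, "BP")
        for term, value in scores.items():
            assert 0.0 <= value <= 1.0 + 1e-12
            for parent in inst.dag.parents_of(term):
                assert scores[parent] >= value - 1e-12


class TestBlastBaseline:
    def test_max_identity_wins(self, d0):
        T = d0["T"]
        scores = blast_baseline(
            [Hit("t", "p1", 80.0, 1e-5), Hit("t", "p2", 60.0, 1e-4)],
            d0["db"], d0["dag"], "BP",
        )
        assert scores[T["A1"]] == pytest.approx(0.80)
        assert scores[T["B"]] == pytest.approx(0.60)

    def test_hit_without_usable_annotation_predicts_nothing(self, d0):
        """A lone hit whose only annotation is electronically inferred (and
        therefore filtered out) yields an empty prediction set."""
        iea_only = AnnotationDB({"O26024": {"GO:0000004": {"IEA"}}}).filtered()
        assert blast_baseline(
            [Hit("t", "O26024", 95.0, 1e-30)], iea_only, d0["dag"], "BP"
        ) == {}


class TestPrior:
    def test_d0_pseudocount_scores(self, d0):
        top2 = prior_predictions(d0["stats"], d0["dag"], "BP", n_max=2)
        assert top2[0] == (d0["T"]["R"], pytest.approx(1.0, abs=1e-9))
        assert top2[1] == (d0["T"]["A"], pytest.approx(0.8, abs=1e-9))

    def test_top1_is_root(self, d0):
        assert prior_predictions(d0["stats"], d0["dag"], "BP", 1)[0][0] == d0["T"]["R"]

    def test_every_target_gets_identical_list(self, d0):
        preds = prior_prediction_set(d0["stats"], d0["dag"], "BP", ["t1", "t2"])
        assert preds["t1"] == preds["t2"]


class TestEnrichment:
    PRIOR = [("R", 1.0), ("A", 0.8), ("B", 0.4)]

    def test_pfp_mode_rescales_into_own_range(self):
        """Prior scores in [0.4, 1.0] map onto the target's [0.6, 0.9]:
        R (prior max) imports at 0.9, B (prior min) at 0.6."""
        preds = PredictionSet("pfp", {"t": [("A1", 0.9), ("A", 0.6)]})
        out = enrich_with_prior(preds, self.PRIOR, mode="pfp")
        scores = out.scores("t")
        assert scores["R"] == pytest.approx(0.9, abs=1e-12)
        assert scores["B"] == pytest.approx(0.6, abs=1e-12)
        order = [t for t, _ in out["t"]]
        assert order.index("A1") < order.index("A")
        assert set(order[:2]) == {"A1", "R"}

    def test_esg_mode_keeps_prior_scores(self):
        preds = PredictionSet("esg", {"t": [("A1", 0.9), ("A", 0.6)]})
        out = enrich_with_prior(preds, self.PRIOR, mode="esg")
        assert out.scores("t")["R"] == 1.0
        assert out.scores("t")["B"] == 0.4

    def test_prior_subset_of_predictions_is_noop(self):
        preds = PredictionSet("esg", {"t": [("R", 0.9), ("A", 0.6), ("B", 0.5)]})
        out = enrich_with_prior(preds, self.PRIOR, mode="esg")
        assert out["t"] == preds["t"]

    def test_empty_prediction_list_falls_back_to_prior(self):
        preds = PredictionSet("pfp", {"t": []})
        out = enrich_with_prior(preds, self.PRIOR, mode="pfp")
        assert out.scores("t") == dict(self.PRIOR)


class TestTruncation:
    def test_keeps_k_highest(self):
        scores = {f"GO:{i:07d}": float(i) for i in range(1, 1201)}
        preds = PredictionSet.from_scores("m", {"t": scores}, max_terms=None)
        assert len(truncate_predictions(preds, 1000)["t"]) == 1000

    def test_boundary_tie_prefers_smaller_id(self):
        preds = PredictionSet(
            "m", {"t": [("GO:0000001", 0.9), ("GO:0000002", 0.5), ("GO:0000003", 0.5)]}
        )
        kept = truncate_predictions(preds, 2)["t"]
        assert kept == [("GO:0000001", 0.9), ("GO:0000002", 0.5)]

    def test_short_list_unchanged(self):
        preds = PredictionSet("m", {"t": [("GO:0000001", 0.9)]})
        assert truncate_predictions(preds, 1000)["t"] == preds["t"]


class TestPredictionIO:
    def test_tsv_roundtrip_skips_submission_headers(self):
        import io

        preds = PredictionSet(
            "m", {"t1": [("GO:0000004", 0.9), ("GO:0000003", 0.5)]}
        )
        buffer = io.StringIO()
        buffer.write("AUTHOR team\nMODEL 1\nKEYWORDS sequence alignment.\n")
        preds.write_tsv(buffer)
        buffer.write("END\n")
        buffer.seek(0)
        loaded = PredictionSet.read_tsv(buffer)
        assert loaded.predictions == preds.predictions


class TestCalibration:
    def test_empirical_pvalue_is_inclusive(self):
        bg = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_pvalue(bg, 3.0) == pytest.approx(0.5)

    def test_score_above_background_gets_add_one_floor(self):
        bg = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_pvalue(bg, 9.0) == pytest.approx(1 / 5)

    def _calibrated(self, d0, rng):
        """Benchmark where high raw scores are mostly exact matches and low
        ones mostly wrong: confidence must decrease with the p-value."""
        T = d0["T"]
        records, truths = [], {}
        for i in range(60):
            target = f"b{i}"
            truths[target] = {T["A1"]}
            good = rng.random() < 0.5
            term = T["A1"] if good else T["B"]
            score = rng.uniform(5, 10) if good else rng.uniform(0, 5)
            records.append((target, term, float(score)))
        return records, truths

    def test_confidence_monotone_and_bounded(self, d0, rng):
        records, truths = self._calibrated(d0, rng)
        table = build_calibration(records, truths, d0["dag"])
        for k in (0, 2, 4):
            fractions = table.fractions[k]
            assert np.all(np.diff(fractions) <= 1e-12)
            assert np.all((0 <= fractions) & (fractions <= 1))
        confs = pfp_confidence({d0["T"]["A1"]: 9.0, d0["T"]["B"]: 9.0}, table, k=0)
        assert set(confs) == {d0["T"]["A1"], d0["T"]["B"]}

    def test_equal_scores_get_equal_confidence(self, d0, rng):
        records, truths = self._calibrated(d0, rng)
        table = build_calibration(records, truths, d0["dag"])
        # two novel terms fall back to the pooled background: same score,
        # same p-value, same confidence
        confs = pfp_confidence({d0["T"]["A"]: 4.0, d0["T"]["A2"]: 4.0}, table)
        assert confs[d0["T"]["A"]] == confs[d0["T"]["A2"]]

    def test_worst_bin_serves_p_equal_one(self, d0, rng):
        records, truths = self._calibrated(d0, rng)
        table = build_calibration(records, truths, d0["dag"])
        low = pfp_confidence({d0["T"]["A1"]: -1.0}, table)[d0["T"]["A1"]]
        assert low == pytest.approx(table.fractions[0][-1])

    def test_missing_calibration_directs_to_raw_ranking(self):
        with pytest.raises(ValueError, match="raw score"):
            pfp_confidence({"GO:0000004": 1.0}, None)
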