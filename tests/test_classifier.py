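import math

import pytest

from pgxtext.classifier import (
    LabeledCandidate,
    TrainedModel,
    apply_threshold,
    evaluate,
    featurize,
    filter_cancer_chemicals,
    precision_recall_at,
    score,
    train,
    train_test_split_stratified,
)
from pgxtext.corpus import EntityMention, Sentence
from pgxtext.candidates import CandidateRelation
from pgxtext.synthetic import generate_labeled_candidates
from pgxtext.variants import VariantMention


def make_candidate(text, chem_surface, var_surface, var_kind="dbsnp"):
    c_start = text.index(chem_surface)
    v_start = text.index(var_surface)
    chem = EntityMention(doc_id="d", entity_class="chemical", start=c_start,
                         end=c_start + len(chem_surface),
                         mention_text=chem_surface, normalized_id="MESH:X")
    var_base = EntityMention(doc_id="d", entity_class="variant", start=v_start,
                             end=v_start + len(var_surface),
                             mention_text=var_surface)
    rsid = var_surface if var_kind == "dbsnp" else None
    var = VariantMention(base=var_base, variant_kind=var_kind, rsid=rsid)
    sentence = Sentence(doc_id="d", start=0, end=len(text), text=text,
                        mentions=[chem, var_base])
    return CandidateRelation(sentence=sentence, chemical=chem, variant=var)


class TestFeaturize:
    def test_path_lemma_present(self):
        cand = make_candidate("rs662 modulates clopidogrel response.",
                              "clopidogrel", "rs662")
        feats = featurize(cand)
        assert feats.get("between:modulate") == 1.0
        assert feats.get("bow:response") == 1.0

    def test_identical_candidates_identical_features(self):
        a = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        b = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        assert featurize(a) == featurize(b)

    def test_different_partners_different_path_features(self):
        text = "rs1 alters warfarin but not simvastatin pharmacology."
        a = make_candidate(text, "warfarin", "rs1")
        b = make_candidate(text, "simvastatin", "rs1")
        assert featurize(a) != featurize(b)
        assert featurize(a)["between_len:1"] == 1.0


class TestTrain:
    def test_separable_data_perfect_holdout(self):
        labeled = generate_labeled_candidates(250, "group1", seed=7)
        tr, te = train_test_split_stratified(labeled, 0.2, seed=7)
        model = train(tr, "group1", seed=7)
        correct = sum((score(model, lc.candidate) >= 0.5) == lc.label for lc in te)
        assert correct == len(te)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            train([], "group1", seed=0)

    def test_single_class_error_names_missing_class(self):
        cand = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        with pytest.raises(ValueError, match="negative"):
            train([LabeledCandidate(cand, True)] * 4, "group1", seed=0)
        with pytest.raises(ValueError, match="positive"):
            train([LabeledCandidate(cand, False)] * 4, "group1", seed=0)

    def test_same_seed_identical_weights(self):
        labeled = generate_labeled_candidates(100, "group2", seed=5)
        m1 = train(labeled, "group2", seed=11)
        m2 = train(labeled, "group2", seed=11)
        assert m1.weights == m2.weights and m1.intercept == m2.intercept

    def test_json_round_trip(self, tmp_path):
        labeled = generate_labeled_candidates(80, "group1", seed=5)
        model = train(labeled, "group1", seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TrainedModel.from_json(path)
        assert back.weights == model.weights
        assert back.intercept == model.intercept
        assert score(back, labeled[0].candidate) == score(model, labeled[0].candidate)


class TestScore:
    def test_out_of_vocabulary_candidate_scores_sigmoid_intercept(self):
        model = TrainedModel(group="group1", weights={"bow:unseen-token": 2.0},
                             intercept=-0.4)
        cand = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        assert score(model, cand) == pytest.approx(1 / (1 + math.exp(0.4)))

    def test_extra_features_do_not_change_score(self):
        labeled = generate_labeled_candidates(80, "group1", seed=3)
        model = train(labeled, "group1", seed=3)
        cand = labeled[0].candidate
        base = score(model, cand)
        enlarged = TrainedModel(
            group="group1",
            weights={**model.weights, "bow:token-absent-from-sentence": 5.0},
            intercept=model.intercept,
        )
        s = score(enlarged, cand)
        assert s == pytest.approx(base)
        assert 0.0 <= s <= 1.0

    def test_group_mismatch_raises(self):
        model = TrainedModel(group="group2", weights={}, intercept=0.0)
        cand = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        with pytest.raises(ValueError, match="group"):
            score(model, cand)


class TestThreshold:
    def scored(self, scores):
        out = []
        for s in scores:
            c = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
            c.score = s
            out.append(c)
        return out

    def test_boundary_is_inclusive(self):
        assert len(apply_threshold(self.scored([0.74, 0.75, 0.76]), 0.75)) == 2

    def test_zero_accepts_all(self):
        assert len(apply_threshold(self.scored([0.1, 0.5]), 0.0)) == 2

    def test_one_accepts_none_without_perfect_scores(self):
        assert apply_threshold(self.scored([0.99, 0.5]), 1.0) == []

    def test_nesting_across_thresholds(self):
        cands = self.scored([i / 10 for i in range(11)])
        prev = None
        for t in (0.2, 0.5, 0.8):
            acc = set(id(c) for c in apply_threshold(cands, t))
            if prev is not None:
                assert acc <= prev
            prev = acc


class TestCancerFilter:
    def test_protein_variant_with_cancer_drug_removed(self):
        cand = make_candidate("T790M predicts erlotinib response.", "erlotinib",
                              "T790M", var_kind="protein_sub")
        assert filter_cancer_chemicals([cand], {"MESH:X"}) == []

    def test_group1_never_removed(self):
        cand = make_candidate("rs121434568 predicts erlotinib response.",
                              "erlotinib", "rs121434568")
        assert filter_cancer_chemicals([cand], {"MESH:X"}) == [cand]

    def test_empty_set_is_identity(self):
        cand = make_candidate("T790M predicts erlotinib response.", "erlotinib",
                              "T790M", var_kind="protein_sub")
        assert filter_cancer_chemicals([cand], set()) == [cand]


class TestEvaluate:
    def test_perfect_scores_on_separable_data(self):
        labeled = generate_labeled_candidates(200, "group1", seed=13)
        tr, te = train_test_split_stratified(labeled, 0.25, seed=13)
        model = train(tr, "group1", seed=13)
        p, r = precision_recall_at(evaluate(model, te), 0.5)
        assert p == 1.0 and r == 1.0

    def test_all_negative_predictions_reports_absent_precision(self):
        model = TrainedModel(group="group1", weights={}, intercept=-10.0)
        labeled = generate_labeled_candidates(20, "group1", seed=2)
        points = evaluate(model, labeled)
        top = max(points, key=lambda p: p.threshold)
        p, r = precision_recall_at(points, 0.99)
        assert p is None and r == 0.0

    def test_no_positives_raises(self):
        cand = make_candidate("rs1 alters warfarin dose.", "warfarin", "rs1")
        model = TrainedModel(group="group1", weights={}, intercept=0.0)
        with pytest.raises(ValueError, match="positive"):
            evaluate(model, [LabeledCandidate(cand, False)] * 3)

    def test_recall_monotone_nonincreasing_in_threshold(self):
        labeled = generate_labeled_candidates(150, "group2", seed=21)
        tr, te = train_test_split_stratified(labeled, 0.3, seed=21)
        model = train(tr, "group2", seed=21)
        points = evaluate(model, te)
        recalls = [p.recall for p in sorted(points, key=lambda p: p.threshold)]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
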