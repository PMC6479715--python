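"""Weighted voting, consistency test, similarity and CBR resolution."""

from __future__ import annotations

import numpy as np
import pytest

from embar.classifiers import LabeledDataset, fit_members
from embar.ensemble import (
    CaseLibrary,
    EnsembleModel,
    cbr_resolve,
    class_similarities,
    compute_weights,
    consistency_test,
    predict_embar,
    retain_case,
    similarity,
    weighted_vote,
)
from embar.errors import ValidationError
from embar.records import AddictionLevel

MILD, MOD, SEV = AddictionLevel.MILD, AddictionLevel.MODERATE, AddictionLevel.SEVERE


class TestComputeWeights:
    def test_equal_accuracies_symmetric(self):
        w = compute_weights([0.8, 0.8, 0.8, 0.8])
        np.testing.assert_allclose(w.weights, [0.25] * 4)

    def test_single_classifier(self):
        np.testing.assert_allclose(compute_weights([0.6]).weights, [1.0])

    def test_reported_member_accuracies_normalize(self):
        # the four published average member accuracies, normalized by hand:
        # 0.716+0.753+0.753+0.744 = 2.966
        w = compute_weights([0.716, 0.753, 0.753, 0.744])
        np.testing.assert_allclose(np.round(w.weights, 4),
                                   [0.2414, 0.2539, 0.2539, 0.2508])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [-0.1], [1.2], []])
    def test_invalid_accuracies(self, bad):
        with pytest.raises(ValidationError):
            compute_weights(bad)

    def test_conservation_property(self, rng):
        for _ in range(200):
            acc = rng.uniform(0.01, 1.0, size=rng.integers(1, 8))
            assert abs(compute_weights(acc).weights.sum() - 1.0) < 1e-9


class TestWeightedVote:
    def test_majority_weight_wins(self):
        w = compute_weights([0.3, 0.3, 0.2, 0.2])
        assert weighted_vote((MILD, MILD, MOD, MOD), w) == MILD

    def test_unanimous_ignores_weights(self):
        w = compute_weights([0.9, 0.1, 0.5, 0.5])
        assert weighted_vote((SEV,) * 4, w) == SEV

    def test_uniform_weights_plurality(self):
        w = compute_weights([0.7] * 4)
        assert weighted_vote((MILD, MOD, SEV, SEV), w) == SEV

    def test_tie_goes_to_lower_severity(self):
        w = compute_weights([0.5, 0.5])
        assert weighted_vote((SEV, MOD), w) == MOD

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            weighted_vote((MILD,), compute_weights([0.5, 0.5]))


class TestConsistencyTest:
    def test_consistent(self):
        ok, levels = consistency_test((MILD,) * 4)
        assert ok and levels == {MILD}

    def test_two_way_disagreement(self):
        ok, levels = consistency_test((MILD, MOD, MILD, MILD))
        assert not ok and levels == {MILD, MOD}

    def test_three_way_disagreement(self):
        ok, levels = consistency_test((MILD, MOD, SEV, MILD))
        assert not ok and levels == {MILD, MOD, SEV}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            consistency_test(())


class TestSimilarity:
    def test_identical_vectors(self):
        assert similarity([1, 0, 1], [1, 0, 1]) == 1.0

    def test_complementary_vectors(self):
        assert similarity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_three_quarters_agreement(self):
        assert similarity([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            similarity([1, 0], [1, 0, 1])

    def test_matches_position_count_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            a, b = rng.integers(0, 2, n), rng.integers(0, 2, n)
            agree = sum(int(x == y) for x, y in zip(a, b))
            assert similarity(a, b) == pytest.approx(agree / n)

    def test_jaccard_ignores_joint_absence(self):
        assert similarity([1, 0, 0], [1, 0, 0], kind="jaccard") == 1.0
        assert similarity([1, 1, 0], [1, 0, 0], kind="jaccard") == 0.5


class TestCbrResolve:
    def test_worked_example(self):
        lib = CaseLibrary(np.array([[1, 0, 1, 1], [0, 1, 0, 0]]),
                          np.array([1, 2]))
        x = np.array([1, 0, 1, 0])
        final, sims = cbr_resolve(x, {MILD, MOD}, lib)
        assert final == MILD
        assert sims == {MILD: 0.75, MOD: 0.25}

    def test_exact_match_retrieval(self):
        lib = CaseLibrary(np.array([[1, 1, 0], [0, 0, 1]]), np.array([1, 2]))
        final, sims = cbr_resolve([0, 0, 1], {MILD, MOD}, lib)
        assert final == MOD and sims[MOD] == 1.0

    def test_tie_falls_back_to_weighted_vote(self):
        x = np.array([1, 0, 1, 0])
        lib = CaseLibrary(np.vstack([x, x]), np.array([1, 2]))
        w = compute_weights([0.4, 0.9, 0.9, 0.4])
        final, sims = cbr_resolve(x, {MILD, MOD}, lib, weights=w,
                                  predictions=(MILD, MOD, MOD, MILD))
        assert sims[MILD] == sims[MOD] == 1.0
        assert final == MOD  # moderate voters carry more weight

    def test_tie_without_vote_context_takes_lower_severity(self):
        x = np.array([1, 0])
        lib = CaseLibrary(np.vstack([x, x]), np.array([2, 3]))
        final, _ = cbr_resolve(x, {MOD, SEV}, lib)
        assert final == MOD

    def test_candidate_without_cases_rejected(self):
        lib = CaseLibrary(np.array([[1, 0]]), np.array([1]))
        with pytest.raises(ValidationError):
            cbr_resolve([1, 0], {MILD, SEV}, lib)

    def test_matches_brute_force_over_random_libraries(self, rng):
        for _ in range(300):
            n, d = int(rng.integers(2, 9)), int(rng.integers(2, 13))
            feats = rng.integers(0, 2, size=(n, d))
            levels = rng.integers(1, 4, size=n)
            x = rng.integers(0, 2, size=d)
            present = sorted(set(levels.tolist()))
            if len(present) < 2:
                continue
            cands = {AddictionLevel(c) for c in present}
            final, sims = cbr_resolve(x, cands, CaseLibrary(feats, levels))
            # oracle: exhaustive max simple-matching per class, ties low
            oracle = {}
            for c in present:
                best = max((np.asarray(f) == x).mean()
                           for f in feats[levels == c])
                oracle[c] = best
            top = max(oracle.values())
            expect = min(c for c in present if oracle[c] == top)
            assert int(final) == expect
            for c in present:
                assert sims[AddictionLevel(c)] == pytest.approx(oracle[c])


class TestRetainCase:
    def test_retain_grows_and_is_retrievable(self):
        lib = CaseLibrary(np.array([[1, 0]]), np.array([1]),
                          retain_enabled=True)
        retain_case(lib, [0, 1], SEV)
        assert len(lib) == 2
        sims = class_similarities([0, 1], {SEV}, lib)
        assert sims[SEV] == 1.0

    def test_retention_off_by_default(self):
        lib = CaseLibrary(np.array([[1, 0]]), np.array([1]))
        for _ in range(100):
            retain_case(lib, [0, 1], SEV)
        assert len(lib) == 1


class TestCaseLibraryIO:
    def test_csv_round_trip(self, tmp_path):
        lib = CaseLibrary(np.array([[1, 0, 1], [0, 1, 1]]), np.array([1, 3]))
        path = tmp_path / "cases.csv"
        lib.save_csv(path)
        back = CaseLibrary.load_csv(path)
        np.testing.assert_array_equal(back.features, lib.features)
        np.testing.assert_array_equal(back.levels, lib.levels)


@pytest.fixture(scope="module")
def fitted(small_features):
    X, y = small_features
    data = LabeledDataset(X, y)
    members = fit_members(data)
    weights = compute_weights([m.training_accuracy(data) for m in members])
    return members, weights, CaseLibrary.from_dataset(data), X


class TestPredictEmbar:
    def test_unanimous_is_consistent_mode(self, fitted):
        members, weights, lib, X = fitted
        for x in X[:15]:
            out = predict_embar(x, members, weights, lib)
            if len(set(out.member_predictions)) == 1:
                assert out.mode == "consistent"
                assert out.final_level == out.member_predictions[0]
                return
        pytest.skip("no unanimous case found in probe set")

    def test_ensemble_only_never_uses_cbr(self, fitted):
        members, weights, lib, X = fitted
        for x in X[:20]:
            out = predict_embar(x, members, weights, lib, ensemble_only=True)
            assert out.mode == "voted"

    def test_disagreement_resolved_within_candidates(self, fitted, rng):
        members, weights, lib, X = fitted
        seen = 0
        for _ in range(300):
            x = rng.integers(0, 2, size=X.shape[1])
            out = predict_embar(x, members, weights, lib)
            if out.mode == "cbr_resolved":
                seen += 1
                cands = set(out.member_predictions)
                assert out.final_level in cands
                best = max(out.class_similarities.values())
                assert out.class_similarities[out.final_level] == \
                    pytest.approx(best)
        assert seen > 0

    def test_consistency_limit(self, fitted, rng):
        """When members agree, EMBAR = weighted vote = each member."""
        members, weights, lib, X = fitted
        checked = 0
        probes = list(X)
        for base in X[:40]:
            x = np.array(base)
            flips = rng.integers(0, X.shape[1], size=3)
            x[flips] = 1 - x[flips]
            probes.append(x)
        for x in probes:
            preds = tuple(m.predict(x) for m in members)
            if len(set(preds)) != 1:
                continue
            checked += 1
            out = predict_embar(x, members, weights, lib)
            assert out.mode == "consistent"
            assert out.final_level == preds[0]
            assert weighted_vote(preds, weights) == preds[0]
        assert checked > 0

    def test_outcome_json_export(self, fitted):
        members, weights, lib, X = fitted
        d = predict_embar(X[0], members, weights, lib).to_dict()
        assert set(d["member_predictions"]) == {"svm", "bnc", "c5", "knn"}
        assert d["mode"] in ("consistent", "voted", "cbr_resolved")


def test_ensemble_model_fit_predict(small_features):
    X, y = small_features
    model = EnsembleModel.fit(LabeledDataset(X, y), seed=1)
    preds = model.predict(X)
    assert set(preds.tolist()) <= {1, 2, 3}
    # training-set predictions should be strongly aligned with the labels
    assert (preds == y).mean() > 0.8
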