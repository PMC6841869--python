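"""Binary relevance, classifier chains and chain ensembles on
count-valued labels."""

import numpy as np
import pandas as pd
import pytest

from mricoder.labels import CodeDefinition
from mricoder.multioutput import (
    BaseClassifierSpec,
    BinaryRelevance,
    ClassifierChain,
    EnsembleOfChains,
    frame_to_labelsets,
    labelsets_to_frame,
    micro_f1_counts,
    tune,
)
from mricoder.synthetic import label_dependency_scenario

RF_FAST = BaseClassifierSpec("random_forest", {"n_estimators": 30})
NEAR_LINEAR_SVM = BaseClassifierSpec("svm_rbf", {"gamma": 5e-4, "C": 20.0})

CDEFS_AB = {"A": CodeDefinition("A", 2), "B": CodeDefinition("B", 1)}
# for the two-block fixture below, whose B label takes values {0, 2}
CDEFS_BLOCK = {"A": CodeDefinition("A", 2), "B": CodeDefinition("B", 2)}


def two_block_problem(seed, n=500):
    """Two independent labels, each readable off its own feature block."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    Y = pd.DataFrame({
        "A": (X[:, 0] > 0).astype(int),
        "B": (X[:, 2] > 0).astype(int) * 2,  # count-valued {0, 2}
    })
    return X, Y


class TestBinaryRelevance:
    def test_separable_training_data_predicted_exactly(self):
        X, Y = two_block_problem(0, n=200)
        model = BinaryRelevance(CDEFS_BLOCK, RF_FAST).fit(X, Y)
        assert (model.predict(X) == Y.to_numpy()).mean() > 0.99

    def test_constant_label_yields_constant_predictor(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        Y = pd.DataFrame({"A": np.zeros(50, dtype=int),
                          "B": (X[:, 0] > 0).astype(int)})
        model = BinaryRelevance(CDEFS_AB, RF_FAST).fit(X, Y)
        assert (model.predict(X)[:, 0] == 0).all()

    def test_disjoint_blocks_learned_independently(self):
        X, Y = two_block_problem(1)
        Xt, Yt = two_block_problem(2)
        model = BinaryRelevance(CDEFS_BLOCK, RF_FAST).fit(X, Y)
        pred = model.predict(Xt)
        assert (pred[:, 0] == Yt["A"]).mean() >= 0.95
        assert (pred[:, 1] == Yt["B"]).mean() >= 0.95

    def test_empty_training_set_is_error(self):
        with pytest.raises(ValueError):
            BinaryRelevance(CDEFS_AB, RF_FAST).fit(
                np.empty((0, 3)), pd.DataFrame({"A": [], "B": []})
            )

    def test_feature_length_mismatch_on_predict(self):
        X, Y = two_block_problem(3, n=60)
        model = BinaryRelevance(CDEFS_AB, RF_FAST).fit(X, Y)
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(X[:, :2])

    def test_predictions_respect_max_counts(self):
        # B takes value 2 in the data but its K is 1: predictions clip
        X, Y = two_block_problem(4, n=200)
        model = BinaryRelevance(CDEFS_AB, RF_FAST).fit(X, Y)
        pred = model.predict(X)
        assert pred[:, 0].max() <= 2 and pred[:, 1].max() <= 1


class TestClassifierChain:
    def test_single_label_chain_equals_binary_relevance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        Y = pd.DataFrame({"A": (X[:, 0] > 0).astype(int)})
        cdefs = {"A": CodeDefinition("A", 1)}
        br = BinaryRelevance(cdefs, RF_FAST).fit(X, Y)
        ch = ClassifierChain(cdefs, RF_FAST, label_order=["A"]).fit(X, Y)
        assert (br.predict(X) == ch.predict(X)).all()

    def test_invalid_permutation_rejected(self):
        X, Y = two_block_problem(6, n=60)
        with pytest.raises(ValueError, match="permutation"):
            ClassifierChain(CDEFS_BLOCK, RF_FAST, label_order=["A", "Z"]).fit(X, Y)

    def test_dependent_label_reached_through_chain(self):
        """B = indicator(A >= 1) has no direct feature signal for a
        near-linear learner, but the chain reaches it through A."""
        accs_chain, accs_br = [], []
        for seed in range(3):
            X, A, B = label_dependency_scenario(seed)
            Xtr, Xte = X[:500], X[500:]
            Ytr = pd.DataFrame({"A": A[:500], "B": B[:500]})
            Bte = B[500:]
            ch = ClassifierChain(CDEFS_AB, NEAR_LINEAR_SVM,
                                 label_order=["A", "B"]).fit(Xtr, Ytr)
            br = BinaryRelevance(CDEFS_AB, NEAR_LINEAR_SVM).fit(Xtr, Ytr)
            accs_chain.append((ch.predict(Xte)[:, 1] == Bte).mean())
            accs_br.append((br.predict(Xte)[:, 1] == Bte).mean())
        assert np.median(accs_chain) >= 0.95
        # binary relevance is stuck near the class prior (~0.66)
        assert np.median(accs_br) < 0.8
        assert np.median(accs_br) < np.median(accs_chain)


class TestEnsemble:
    def test_unanimous_vote_returned(self):
        X, Y = two_block_problem(7, n=200)
        ecc = EnsembleOfChains(CDEFS_BLOCK, RF_FAST, n_chains=3, seed=0).fit(X, Y)
        stack = np.stack([c.predict(X) for c in ecc.chains_])
        unanimous = (stack == stack[0]).all(axis=0)
        pred = ecc.predict(X)
        assert (pred[unanimous] == stack[0][unanimous]).all()

    def test_single_chain_ensemble_equals_its_chain(self):
        X, Y = two_block_problem(8, n=150)
        ecc = EnsembleOfChains(CDEFS_BLOCK, RF_FAST, n_chains=1, seed=3).fit(X, Y)
        assert (ecc.predict(X) == ecc.chains_[0].predict(X)).all()

    def test_majority_vote_and_smallest_count_tie_break(self):
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict(self, X):
                return np.full((len(X), 1), self.value)

        ecc = EnsembleOfChains(CDEFS_AB, RF_FAST, n_chains=3, seed=0)
        ecc.codes_ = ["A"]
        ecc.n_features_ = 2
        X = np.zeros((4, 2))
        ecc.chains_ = [Stub(1), Stub(1), Stub(2)]
        assert (ecc.predict(X) == 1).all()  # majority
        ecc.chains_ = [Stub(1), Stub(2)]
        assert (ecc.predict(X) == 1).all()  # tie -> smallest count
        ecc.chains_ = [Stub(2), Stub(0), Stub(2)]
        assert (ecc.predict(X) == 2).all()

    def test_ensemble_output_is_some_chains_value(self):
        X, Y = two_block_problem(9, n=150)
        ecc = EnsembleOfChains(CDEFS_BLOCK, RF_FAST, n_chains=5, seed=1).fit(X, Y)
        stack = np.stack([c.predict(X) for c in ecc.chains_])
        pred = ecc.predict(X)
        assert ((stack == pred[None]).any(axis=0)).all()

    def test_reproducibility_same_seed_same_predictions(self):
        X, Y = two_block_problem(10, n=200)
        p1 = EnsembleOfChains(CDEFS_BLOCK, RF_FAST, n_chains=4, seed=5).fit(X, Y).predict(X)
        p2 = EnsembleOfChains(CDEFS_BLOCK, RF_FAST, n_chains=4, seed=5).fit(X, Y).predict(X)
        assert (p1 == p2).all()

    def test_invalid_chain_count(self):
        with pytest.raises(ValueError):
            EnsembleOfChains(CDEFS_AB, RF_FAST, n_chains=0)


class TestLabelsetConversion:
    def test_round_trip(self):
        from mricoder.labels import Labelset

        lsets = [Labelset({"A": 2}), Labelset({"B": 1}), Labelset({})]
        frame = labelsets_to_frame(lsets, ["A", "B"])
        assert frame_to_labelsets(frame, ["A", "B"]) == lsets


class TestTune:
    def test_grid_of_one_returns_it(self):
        X, Y = two_block_problem(11, n=80)
        best, table = tune(X, Y, CDEFS_BLOCK, [RF_FAST], folds=4, seed=0)
        assert best is RF_FAST
        assert len(table) == 1

    def test_crippled_spec_loses_to_sound_one(self):
        X, Y = two_block_problem(12, n=300)
        crippled = BaseClassifierSpec(
            "random_forest", {"n_estimators": 1, "max_depth": 1}
        )
        best, table = tune(X, Y, CDEFS_BLOCK, [crippled, RF_FAST], folds=5, seed=0)
        assert best is RF_FAST
        assert table["mean_micro_f1"].iloc[1] > table["mean_micro_f1"].iloc[0]

    def test_same_seed_identical_cv_table(self):
        X, Y = two_block_problem(13, n=100)
        _, t1 = tune(X, Y, CDEFS_BLOCK, [RF_FAST], folds=5, seed=2)
        _, t2 = tune(X, Y, CDEFS_BLOCK, [RF_FAST], folds=5, seed=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fewer_rows_than_folds_is_error(self):
        X, Y = two_block_problem(14, n=5)
        with pytest.raises(ValueError):
            tune(X, Y, CDEFS_BLOCK, [RF_FAST], folds=10, seed=0)


def test_micro_f1_counts_partial_credit():
    Yt = np.array([[2, 0], [1, 1]])
    Yp = np.array([[1, 0], [1, 2]])
    # per-cell TP=min: 1+1+1=3; FP=excess units: 1; FN=missed units: 1
    assert micro_f1_counts(Yt, Yp) == pytest.approx(2 * 3 / (2 * 3 + 1 + 1))
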