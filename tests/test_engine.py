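import math

import numpy as np
import pytest
from sklearn.base import clone

from lysptm.engine import (
    MultiLabelKernelClassifier,
    masked_sq_distance,
    predict_labels,
    score_labels,
)
from lysptm.features import encode_dataset, fit_count_table
from lysptm.segments import Dataset

from conftest import random_labels, random_segments


def naive_scores(train_F, train_L, query, theta, engine):
    """Independent oracle: literal double loop over training records, no
    exponent shifting."""
    scores = []
    for v in range(1, 5):
        num = den = 0.0
        for i in range(len(train_F)):
            if engine == "gkpr":
                d = masked_sq_distance(query, train_F[i], v)
            else:
                d = float(np.sum((np.asarray(query) - train_F[i]) ** 2))
            w = math.exp(-d / (2 * theta**2))
            num += train_L[i][v - 1] * w
            den += w
        scores.append(num / den)
    return np.array(scores)


class TestMaskedSqDistance:
    def test_identity_is_zero(self, rng):
        x = rng.random(8)
        for v in range(1, 5):
            assert masked_sq_distance(x, x, v) == 0.0

    def test_two_block_hand_example(self):
        x = np.array([1.0, 0, 0, 0, 0, 0, 0, 0])
        y = np.zeros(8)
        assert masked_sq_distance(x, y, 1) == 1.0
        assert masked_sq_distance(x, y, 2) == 0.0

    def test_masks_partition_full_distance(self, rng):
        for _ in range(100):
            x, y = rng.random(96), rng.random(96)
            total = sum(masked_sq_distance(x, y, v) for v in range(1, 5))
            assert abs(total - np.sum((x - y) ** 2)) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            masked_sq_distance(np.zeros(8), np.zeros(12), 1)
        with pytest.raises(ValueError):
            masked_sq_distance(np.zeros(8), np.zeros(8), 5)


class TestScoreLabels:
    def test_single_record_model_reproduces_its_labels(self):
        model = MultiLabelKernelClassifier()
        model.fit(["ACKDE"], np.array([[1, -1, -1, -1]]))
        s = score_labels(model, "ACKDE")
        np.testing.assert_array_equal(s, [1, -1, -1, -1])
        np.testing.assert_array_equal(model.predict(["ACKDE"])[0], [1, -1, -1, -1])

    def test_equidistant_opposite_labels_cancel(self, rng):
        # two training rows symmetric about the query in every mask
        F = np.array([[0.2] * 8, [0.4] * 8])
        L = np.array([[1, 1, 1, 1], [-1, -1, -1, -1]])
        model = MultiLabelKernelClassifier(theta=1 / 6)
        model.train_features_ = F
        model.train_labels_ = L
        s = model.decision_function(np.array([[0.3] * 8]))[0]
        np.testing.assert_allclose(s, [0, 0, 0, 0], atol=1e-15)

    def test_two_record_closed_form(self):
        # masked distances 0 and 1 with labels +1 / -1 at theta = 1/6:
        # S = (1 - e^-18) / (1 + e^-18)
        F = np.zeros((2, 8))
        F[1, 0::4] = np.sqrt(0.5)  # distance 1 in every mask slot pair
        L = np.array([[1, 1, 1, 1], [-1, -1, -1, -1]])
        model = MultiLabelKernelClassifier(theta=1 / 6)
        model.train_features_ = F
        model.train_labels_ = L
        s = model.decision_function(np.zeros((1, 8)))[0]
        expected = (1 - math.exp(-18)) / (1 + math.exp(-18))
        assert abs(s[0] - expected) < 1e-15

    def test_scores_bounded_by_one(self, rng):
        segs = random_segments(rng, 40, 5)
        labels = random_labels(rng, 40)
        model = MultiLabelKernelClassifier().fit(segs, labels)
        s = model.decision_function(random_segments(rng, 10, 5))
        assert np.all(np.abs(s) <= 1 + 1e-12)

    @pytest.mark.parametrize("engine", ["gkpr", "gkr"])
    def test_agrees_with_naive_oracle(self, rng, engine):
        segs = random_segments(rng, 50, 5)
        labels = random_labels(rng, 50)
        model = MultiLabelKernelClassifier(theta=1 / 4, engine=engine)
        model.fit(segs, labels)
        queries = encode_dataset(model.encoder_.count_table_,
                                 random_segments(rng, 20, 5))
        got = model.decision_function(queries)
        for q, row in zip(queries, got):
            expected = naive_scores(model.train_features_, model.train_labels_,
                                    q, 1 / 4, engine)
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_duplicating_positive_record_never_lowers_score(self, rng):
        segs = random_segments(rng, 20, 4)
        labels = random_labels(rng, 20)
        labels[3, 1] = 1
        base = MultiLabelKernelClassifier().fit(segs, labels)
        # compare on fixed feature vectors so only the kernel sum changes
        # (duplication would also shift the count table otherwise)
        queries = encode_dataset(base.encoder_.count_table_,
                                 random_segments(rng, 10, 4))
        s0 = base.decision_function(queries)[:, 1]
        model2 = MultiLabelKernelClassifier(theta=base.theta)
        model2.train_features_ = np.vstack([base.train_features_,
                                            base.train_features_[3]])
        model2.train_labels_ = np.vstack([base.train_labels_, base.train_labels_[3]])
        s2 = model2.decision_function(queries)[:, 1]
        assert np.all(s2 >= s0 - 1e-12)

    def test_engines_coincide_when_other_blocks_agree(self, rng):
        # queries and training rows identical outside label 1's slots
        base = rng.random(8)
        F = np.tile(base, (3, 1))
        F[:, 0::4] = rng.random((3, 2))
        L = np.where(rng.random((3, 4)) < 0.5, 1, -1)
        q = base.copy()
        q[0::4] = rng.random(2)
        gkpr = MultiLabelKernelClassifier(theta=1 / 6, engine="gkpr")
        gkr = MultiLabelKernelClassifier(theta=1 / 6, engine="gkr")
        for m in (gkpr, gkr):
            m.train_features_ = F
            m.train_labels_ = L
        s1 = gkpr.decision_function(q[None])[0]
        s2 = gkr.decision_function(q[None])[0]
        assert abs(s1[0] - s2[0]) < 1e-12


class TestPredictLabels:
    def test_sign_rule_with_tie_positive(self):
        got = predict_labels(np.array([0.2, -0.3, 0.0, -1.0]))
        assert got.tolist() == [1, -1, 1, -1]

    def test_all_positive(self):
        assert predict_labels(np.ones(4)).tolist() == [1, 1, 1, 1]


class TestModelLifecycle:
    def test_fit_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            MultiLabelKernelClassifier().fit([], np.empty((0, 4)))
        with pytest.raises(ValueError):
            MultiLabelKernelClassifier().fit(["ACKDE"], np.array([[1, 0, 0, 0]]))
        with pytest.raises(ValueError):
            MultiLabelKernelClassifier(theta=0).fit(["ACKDE"],
                                                    np.array([[1, -1, -1, -1]]))

    def test_resubstitution_on_separated_data(self):
        from lysptm.synth import SynthSpec, generate

        ds = generate(SynthSpec(n_proteins=20, seed=5))
        model = MultiLabelKernelClassifier().fit(ds)
        pred = model.predict(ds.segments)
        absolute_true = np.all(pred == ds.labels, axis=1).mean()
        assert absolute_true >= 0.95

    def test_serialization_round_trip(self, rng, tmp_path):
        segs = random_segments(rng, 25, 4)
        labels = random_labels(rng, 25)
        model = MultiLabelKernelClassifier(theta=1 / 8).fit(segs, labels)
        path = tmp_path / "model.json"
        model.save(path)
        again = MultiLabelKernelClassifier.load(path)
        queries = random_segments(rng, 10, 4)
        np.testing.assert_array_equal(model.decision_function(queries),
                                      again.decision_function(queries))
        np.testing.assert_array_equal(model.predict(queries), again.predict(queries))

    def test_sklearn_param_protocol(self):
        model = MultiLabelKernelClassifier(theta=1 / 8, engine="gkr")
        params = model.get_params()
        assert params["theta"] == 1 / 8 and params["engine"] == "gkr"
        cloned = clone(model)
        assert cloned.get_params() == params
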