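from collections import Counter
from itertools import product

import numpy as np
import pytest

from hierbeat import predict_votes, train_ensemble
from hierbeat.ensemble import (
    CLASS_PRIORITY,
    detect_veb,
    predict_winners,
    tally_votes,
)
from hierbeat.errors import EnsembleError


def _two_cluster_groups(rng, M=3, n=40, d=5, sep=6.0):
    """M feature views of two linearly separable clusters labelled N / V."""
    labels = np.array(["N"] * (n // 2) + ["V"] * (n // 2), dtype=object)
    groups = []
    for _ in range(M):
        X = rng.standard_normal((n, d))
        X[n // 2 :, 0] += sep
        groups.append(X)
    return groups, labels


class TestTrainEnsemble:
    def test_separable_clusters_give_perfect_training_accuracy(self, rng):
        groups, labels = _two_cluster_groups(rng)
        model = train_ensemble(groups, labels, C=1.0, delta=0.5)
        for svm, G in zip(model.members, groups):
            assert (svm.predict(G) == labels).all()

    def test_single_member_ensemble_equals_its_classifier(self, rng):
        groups, labels = _two_cluster_groups(rng, M=1)
        model = train_ensemble(groups, labels)
        winners = predict_winners(model, groups)
        np.testing.assert_array_equal(winners, model.members[0].predict(groups[0]))

    def test_refit_is_deterministic(self, rng):
        groups, labels = _two_cluster_groups(rng, M=4)
        w1 = predict_winners(train_ensemble(groups, labels), groups)
        w2 = predict_winners(train_ensemble(groups, labels), groups)
        np.testing.assert_array_equal(w1, w2)

    def test_single_class_training_errors(self, rng):
        X = [rng.standard_normal((10, 3))]
        with pytest.raises(EnsembleError):
            train_ensemble(X, np.array(["N"] * 10, dtype=object))

    @pytest.mark.parametrize("C,delta", [(-1, 1), (0, 1), (1, 0), (1, -2)])
    def test_nonpositive_parameters_error(self, rng, C, delta):
        groups, labels = _two_cluster_groups(rng, M=1)
        with pytest.raises(EnsembleError):
            train_ensemble(groups, labels, C=C, delta=delta)


class TestVoting:
    def test_strict_majority_wins(self):
        row = np.array([["V"] * 9 + ["N"] * 6], dtype=object)
        (t,) = tally_votes(row)
        assert t.winner == "V" and not t.tie_flag
        assert t.counts == {"V": 9, "N": 6}

    def test_unanimity(self):
        (t,) = tally_votes(np.array([["N"] * 15], dtype=object))
        assert t.winner == "N" and not t.tie_flag and sum(t.counts.values()) == 15

    def test_tie_resolved_by_priority_and_flagged(self):
        (t,) = tally_votes(np.array([["N"] * 6 + ["S"] * 6 + ["V"] * 3], dtype=object))
        assert t.tie_flag
        assert t.winner == "S"  # S beats N in the priority order

    def test_winner_is_mode_for_exhaustive_small_ensembles(self):
        # brute-force oracle over every label assignment with M <= 5
        classes = ("N", "S", "V")
        for M in (1, 2, 3, 4, 5):
            for assignment in product(classes, repeat=M):
                row = np.array([list(assignment)], dtype=object)
                (t,) = tally_votes(row)
                counts = Counter(assignment)
                top = max(counts.values())
                modes = {c for c, v in counts.items() if v == top}
                assert t.counts == dict(counts)
                assert t.winner in modes
                assert t.tie_flag == (len(modes) > 1)
                if len(modes) == 1:
                    assert t.winner == modes.pop()
                else:
                    assert t.winner == min(modes, key=CLASS_PRIORITY.index)

    def test_random_tallies_at_m15_match_mode(self, rng):
        labels = rng.choice(np.array(list("NSVFQ"), dtype=object), size=(200, 15))
        for row, t in zip(labels, tally_votes(labels)):
            counts = Counter(row)
            top = max(counts.values())
            assert t.counts[t.winner] == top
            assert sum(t.counts.values()) == 15

    def test_member_order_does_not_change_winners(self, rng):
        labels = rng.choice(np.array(list("NSV"), dtype=object), size=(50, 6))
        base = [t.winner for t in tally_votes(labels)]
        perm = rng.permutation(6)
        shuffled = [t.winner for t in tally_votes(labels[:, perm])]
        assert base == shuffled


class TestPredictVotes:
    def test_vote_conservation_and_winner_mode(self, rng):
        groups, labels = _two_cluster_groups(rng, M=5, sep=2.0)
        model = train_ensemble(groups, labels)
        tallies = predict_votes(model, groups)
        member_preds = np.column_stack([m.predict(G) for m, G in zip(model.members, groups)])
        for i, t in enumerate(tallies):
            assert sum(t.counts.values()) == 5
            counts = Counter(member_preds[i])
            assert t.counts == dict(counts)
            assert t.counts[t.winner] == max(counts.values())

    def test_wrong_group_count_errors(self, rng):
        groups, labels = _two_cluster_groups(rng, M=3)
        model = train_ensemble(groups, labels)
        with pytest.raises(EnsembleError):
            predict_votes(model, groups[:2])

    def test_empty_test_set_gives_empty_output(self, rng):
        groups, labels = _two_cluster_groups(rng, M=2)
        model = train_ensemble(groups, labels)
        empty = [G[:0] for G in groups]
        assert predict_votes(model, empty) == []
        is_veb, winners = detect_veb(model, empty)
        assert len(is_veb) == 0 and len(winners) == 0


class TestDetectVeb:
    def test_only_v_winners_are_routed_out(self, rng):
        groups, labels = _two_cluster_groups(rng, M=3)
        model = train_ensemble(groups, labels)
        is_veb, winners = detect_veb(model, groups)
        np.testing.assert_array_equal(is_veb, winners == "V")
        # non-V stage-1 labels are not final: they remain in the output for
        # diagnostics but every one of them proceeds to stage 2
        assert set(winners[~is_veb]) <= {"N", "S", "F", "Q"}
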