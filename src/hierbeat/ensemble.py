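"""RBF-SVM ensemble with majority voting over random-projection views.

M classifiers share one (C, delta) setting; member k sees only feature
group k. The kernel parameter delta is the RBF coefficient gamma in
K(x, y) = exp(-gamma * ||x - y||^2), the convention of libsvm, so results
are interpretable either way.

A test beat receives one label from each member; the winner is the class
with the most votes. Vote ties are broken by the larger summed one-vs-one
decision margin across members (order-independent), then by the fixed
priority V > S > N > F > Q, which favours the clinically critical classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import EnsembleError
from .random_projection import RandomMatrixBank

#: Deterministic tie-break priority (most critical first).
CLASS_PRIORITY = ("V", "S", "N", "F", "Q")


@dataclass(frozen=True)
class VoteTally:
    """Vote counts for one beat, the winning class, and whether votes tied."""

    counts: Mapping[str, int]
    winner: str
    tie_flag: bool


@dataclass
class EnsembleModel:
    """M fitted SVMs sharing (C, delta), plus the bank that made their views."""

    members: list[SVC]
    C: float
    delta: float
    bank_ref: tuple[int, int, int, int]  # (seed, M, d, m)
    lead_config: str
    classes: tuple[str, ...]

    @property
    def M(self) -> int:
        return len(self.members)


def train_ensemble(
    feature_groups: Sequence[np.ndarray],
    labels: np.ndarray,
    C: float = 1.0,
    delta: float = 1.3,
    bank: RandomMatrixBank | None = None,
    lead_config: str = "A",
    class_weight: dict | str | None = None,
) -> EnsembleModel:
    """Fit one RBF SVM per feature group (one-vs-one multi-class).

    ``class_weight`` is off by default: imbalance is handled by the
    hierarchy, not by weighting; pass ``"balanced"`` or a dict to override.
    """
    if C <= 0 or delta <= 0:
        raise EnsembleError(f"C and delta must be positive, got C={C}, delta={delta}")
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise EnsembleError("training data contains a single class")
    n = len(labels)
    members = []
    for k, G in enumerate(feature_groups):
        if len(G) != n:
            raise EnsembleError(
                f"feature group {k} has {len(G)} rows for {n} labels"
            )
        svm = SVC(
            C=C,
            kernel="rbf",
            gamma=delta,
            decision_function_shape="ovo",
            class_weight=class_weight,
        )
        svm.fit(G, labels)
        members.append(svm)
    bank_ref = (bank.seed, bank.M, bank.d, bank.m) if bank is not None else (-1, len(members), -1, -1)
    return EnsembleModel(
        members=members,
        C=C,
        delta=delta,
        bank_ref=bank_ref,
        lead_config=lead_config,
        classes=classes,
    )


def _ovo_margins(svm: SVC, G: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-class summed one-vs-one decision margins for one member.

    For each class pair (ci, cj), libsvm's decision value is positive when
    the beat looks like ci; it is added to ci's margin and subtracted from
    cj's. Returns an (n, K) margin array and the member's class list.
    """
    classes = list(svm.classes_)
    dec = svm.decision_function(G)
    n = len(G)
    margins = np.zeros((n, len(classes)))
    if len(classes) == 2:
        # binary SVC returns a single column, positive for classes_[1]
        dec = np.asarray(dec).reshape(n)
        margins[:, 0] -= dec
        margins[:, 1] += dec
        return margins, classes
    for col, (i, j) in enumerate(combinations(range(len(classes)), 2)):
        margins[:, i] += dec[:, col]
        margins[:, j] -= dec[:, col]
    return margins, classes


def tally_votes(
    member_labels: np.ndarray,
    margins: np.ndarray | None = None,
    margin_classes: Sequence[str] | None = None,
) -> list[VoteTally]:
    """Combine per-member labels (n beats x M members) into one tally per beat.

    ``margins`` (n x K summed decision margins, columns ``margin_classes``)
    breaks vote ties; without margins ties fall straight to CLASS_PRIORITY.
    """
    member_labels = np.asarray(member_labels, dtype=object)
    if member_labels.ndim != 2:
        raise EnsembleError("member_labels must be (n_beats, M)")
    n, M = member_labels.shape
    tallies: list[VoteTally] = []
    for i in range(n):
        row = member_labels[i]
        counts: dict[str, int] = {}
        for lab in row:
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        tied = sorted(c for c, v in counts.items() if v == top)
        tie = len(tied) > 1
        if not tie:
            winner = tied[0]
        else:
            if margins is not None and margin_classes is not None:
                idx = {c: k for k, c in enumerate(margin_classes)}
                best = max(margins[i, idx[c]] for c in tied if c in idx)
                tied = [c for c in tied if c in idx and margins[i, idx[c]] == best]
            winner = min(tied, key=CLASS_PRIORITY.index)
        tallies.append(VoteTally(counts=counts, winner=winner, tie_flag=tie))
    return tallies


def predict_votes(
    model: EnsembleModel, feature_groups: Sequence[np.ndarray]
) -> list[VoteTally]:
    """Vote tallies for each test beat (groups must match the model's bank)."""
    if len(feature_groups) != model.M:
        raise EnsembleError(
            f"got {len(feature_groups)} feature groups for an ensemble of "
            f"{model.M} members"
        )
    n = len(feature_groups[0])
    if any(len(G) != n for G in feature_groups):
        raise EnsembleError("feature groups are not beat-aligned")
    if n == 0:
        return []
    labels = np.empty((n, model.M), dtype=object)
    margins = np.zeros((n, len(model.classes)))
    class_idx = {c: k for k, c in enumerate(model.classes)}
    for k, (svm, G) in enumerate(zip(model.members, feature_groups)):
        labels[:, k] = svm.predict(G)
        mg, mg_classes = _ovo_margins(svm, G)
        for j, c in enumerate(mg_classes):
            margins[:, class_idx[c]] += mg[:, j]
    return tally_votes(labels, margins, model.classes)


def predict_winners(
    model: EnsembleModel, feature_groups: Sequence[np.ndarray]
) -> np.ndarray:
    """Winning class label per beat."""
    return np.array([t.winner for t in predict_votes(model, feature_groups)], dtype=object)


def detect_veb(
    model: EnsembleModel, feature_groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-1 decision: ``(is_veb, winner)`` per beat.

    Only the V / non-V split feeds stage 2; non-V winners are retained for
    diagnostics but are not final labels.
    """
    winners = predict_winners(model, feature_groups)
    return winners == "V", winners
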