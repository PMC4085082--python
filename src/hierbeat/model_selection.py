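"""Leave-one-recording-out model selection for the VEB ensemble.

Each cross-validation fold holds out one complete recording, so train and
test beats never share a patient (the inter-patient guarantee, asserted per
fold). The 22 per-fold confusion matrices are summed element-wise and the
selection criterion Ave — the mean of Se and PP for classes N and V — is
computed once from the summed matrix; averaging per-fold percentages would
weight recordings unequally and is deliberately not done.

The parameter grid is C in {1, 10, 100} x delta in {0.4, 0.7, 1.0, 1.3}
(12 combinations); ties prefer smaller C, then smaller delta. Lead
configurations are compared by their best-Ave and ties resolve in the
canonical order A, B, A+B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AAMI_CLASSES
from .ensemble import predict_winners, train_ensemble
from .errors import EnsembleError
from .evaluation import ConfusionMatrix, compute_ave
from .preprocessing import BeatDataset
from .random_projection import LEAD_CONFIGS, RandomMatrixBank, featurize

__all__ = [
    "ParamGrid",
    "CVResult",
    "loro_folds",
    "cross_validate",
    "grid_search",
    "select_lead_config",
]


@dataclass(frozen=True)
class ParamGrid:
    C_values: tuple[float, ...] = (1.0, 10.0, 100.0)
    delta_values: tuple[float, ...] = (0.4, 0.7, 1.0, 1.3)

    def combinations(self) -> list[tuple[float, float]]:
        """(C, delta) pairs, ordered smaller-C-then-smaller-delta first."""
        return [
            (C, d) for C in sorted(self.C_values) for d in sorted(self.delta_values)
        ]


@dataclass
class CVResult:
    C: float
    delta: float
    lead_config: str
    summed_confusion: ConfusionMatrix
    ave: float | None
    failed: bool = False


def loro_folds(record_ids: Sequence[str]) -> list[tuple[list[str], list[str]]]:
    """One (train_records, test_records) partition per recording."""
    ids = [str(r) for r in record_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 recordings for cross-validation")
    return [([r for r in ids if r != held], [held]) for held in ids]


def cross_validate(
    beats: BeatDataset,
    feature_groups: Sequence[np.ndarray],
    C: float,
    delta: float,
    lead_config: str = "A",
) -> CVResult:
    """Run the full leave-one-recording-out CV for one (C, delta) setting.

    ``feature_groups`` are the M views of *all* beats in ``beats``; folds
    slice them by record membership, so features are computed once per bank.
    """
    records = sorted(set(beats.record_ids))
    summed: ConfusionMatrix | None = None
    for train_ids, test_ids in loro_folds(records):
        train_mask = np.isin(beats.record_ids, train_ids)
        test_mask = ~train_mask
        # inter-patient guarantee: the held-out recording contributes no
        # training beat
        assert not (set(beats.record_ids[train_mask]) & set(test_ids))
        try:
            model = train_ensemble(
                [G[train_mask] for G in feature_groups],
                beats.labels[train_mask],
                C=C,
                delta=delta,
                lead_config=lead_config,
            )
        except EnsembleError:
            return CVResult(C, delta, lead_config, _empty_cm(), None, failed=True)
        winners = predict_winners(model, [G[test_mask] for G in feature_groups])
        cm = ConfusionMatrix.from_labels(
            beats.labels[test_mask], winners, AAMI_CLASSES, AAMI_CLASSES
        )
        summed = cm if summed is None else summed + cm
    assert summed is not None and summed.grand_total == len(beats)
    return CVResult(C, delta, lead_config, summed, compute_ave(summed))


def _empty_cm() -> ConfusionMatrix:
    return ConfusionMatrix(
        np.zeros((len(AAMI_CLASSES), len(AAMI_CLASSES)), dtype=int), AAMI_CLASSES
    )


def grid_search(
    beats: BeatDataset,
    bank: RandomMatrixBank,
    grid: ParamGrid | None = None,
    lead_config: str = "A",
    mode: str = "pinv",
) -> tuple[CVResult, pd.DataFrame]:
    """Evaluate every (C, delta) by LORO CV; return the argmax-Ave result.

    The result table has one row per combination (columns C, delta,
    lead_config, ave, failed). Ties on Ave prefer smaller C, then smaller
    delta; combination order already encodes that preference.
    """
    grid = grid or ParamGrid()
    combos = grid.combinations()
    if not combos:
        raise ValueError("empty parameter grid")
    feature_groups = featurize(beats, bank, lead_config, mode)
    results = [
        cross_validate(beats, feature_groups, C, delta, lead_config)
        for C, delta in combos
    ]
    table = pd.DataFrame(
        {
            "C": [r.C for r in results],
            "delta": [r.delta for r in results],
            "lead_config": lead_config,
            "ave": [r.ave for r in results],
            "failed": [r.failed for r in results],
        }
    )
    valid = [r for r in results if not r.failed and r.ave is not None]
    if not valid:
        raise EnsembleError("every grid combination failed")
    best = max(valid, key=lambda r: r.ave)  # first max wins: smaller C, delta
    return best, table


def select_lead_config(results: dict[str, CVResult]) -> str:
    """Pick the lead configuration with the best DS1 cross-validation Ave."""
    if not results:
        raise ValueError("no lead configurations evaluated")
    order = [c for c in LEAD_CONFIGS if c in results]
    order += [c for c in results if c not in order]
    best = max(
        order,
        key=lambda c: -np.inf if results[c].ave is None else results[c].ave,
    )
    return best
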