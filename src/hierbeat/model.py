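"""Top-level modelling interface: build, fit, predict, evaluate, summarize.

:class:`HierarchicalBeatModel` holds the training beats and the design
choices (lead configuration, ensemble geometry, seed); :meth:`fit` performs
the full training procedure — optional leave-one-recording-out grid search
over (C, delta), ensemble training, and RR-ratio threshold selection on the
training beats the ensemble does not label V — and returns a
:class:`HierarchicalBeatResults` carrying everything needed to classify new
recordings and report AAMI-style tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, predict_winners, train_ensemble
from .evaluation import (
    ConfusionMatrix,
    compute_ave,
    format_report,
    per_recording_report,
)
from .io import Recording
from .model_selection import CVResult, ParamGrid, grid_search
from .preprocessing import BeatDataset, beats_from_recordings
from .random_projection import RandomMatrixBank, featurize, generate_bank
from .sveb_detector import (
    DEFAULT_THRESHOLD,
    ThresholdScan,
    detect_sveb,
    scan_thresholds,
    select_threshold,
)

__all__ = ["HierarchicalBeatModel", "HierarchicalBeatResults", "EvaluationReport"]


@dataclass
class EvaluationReport:
    """Confusion matrix + per-recording table + headline metrics."""

    confusion: ConfusionMatrix
    report: pd.DataFrame
    metrics: dict

    def formatted(self) -> pd.DataFrame:
        return format_report(self.report)


class HierarchicalBeatModel:
    """Two-stage inter-patient heartbeat classifier.

    Stage 1 detects ventricular ectopic beats with an ensemble of M
    RBF-kernel SVMs, each trained on the coefficients of the beat windows
    under one seeded Gaussian random matrix plus the preceding RR interval.
    Stage 2 labels the remaining beats supraventricular-ectopic when their
    RR ratio falls below a threshold chosen on the training set.

    Parameters
    ----------
    train_data
        Preprocessed training beats (all recordings pooled; record ids are
        retained for leave-one-recording-out model selection).
    lead_config
        ``"A"``, ``"B"`` or ``"A+B"`` (projections concatenated).
    n_matrices, projection_dim
        Ensemble size M and projection dimension d.
    seed
        Seeds the random-matrix bank; the only randomness in the model.
    mode
        ``"pinv"`` (least-squares coefficients, default) or ``"transpose"``.
    """

    def __init__(
        self,
        train_data: BeatDataset,
        lead_config: str = "A",
        n_matrices: int = 15,
        projection_dim: int = 50,
        window_len: int = 200,
        seed: int = 0,
        mode: str = "pinv",
    ) -> None:
        if len(train_data) == 0:
            raise ValueError("empty training set")
        self.train_data = train_data
        self.lead_config = lead_config
        self.n_matrices = n_matrices
        self.projection_dim = projection_dim
        self.window_len = window_len
        self.seed = seed
        self.mode = mode
        self.bank: RandomMatrixBank = generate_bank(
            M=n_matrices, d=projection_dim, m=window_len, seed=seed
        )

    @classmethod
    def from_recordings(
        cls,
        recordings: Iterable[Recording],
        config: Mapping | None = None,
        **kwargs,
    ) -> "HierarchicalBeatModel":
        return cls(beats_from_recordings(recordings, config), **kwargs)

    def fit(
        self,
        C: float = 1.0,
        delta: float = 1.3,
        do_grid_search: bool = False,
        grid: ParamGrid | None = None,
        sveb_threshold: float | None = None,
        se_target: float = 80.0,
    ) -> "HierarchicalBeatResults":
        """Train the full hierarchy on the model's training beats.

        With ``do_grid_search`` the (C, delta) arguments are ignored and the
        argmax-Ave combination from leave-one-recording-out CV is used. With
        ``sveb_threshold=None`` the threshold is scanned and selected on the
        training beats the fitted ensemble does not label V; pass a value
        (e.g. the deployment default 0.8) to skip selection.
        """
        cv_best: CVResult | None = None
        cv_table: pd.DataFrame | None = None
        if do_grid_search:
            cv_best, cv_table = grid_search(
                self.train_data, self.bank, grid, self.lead_config, self.mode
            )
            C, delta = cv_best.C, cv_best.delta

        groups = featurize(self.train_data, self.bank, self.lead_config, self.mode)
        ensemble = train_ensemble(
            groups,
            self.train_data.labels,
            C=C,
            delta=delta,
            bank=self.bank,
            lead_config=self.lead_config,
        )

        scan: ThresholdScan | None = None
        if sveb_threshold is None:
            train_winners = predict_winners(ensemble, groups)
            non_veb = train_winners != "V"
            scan = scan_thresholds(
                self.train_data.rr_ratio[non_veb],
                self.train_data.labels[non_veb],
            )
            sveb_threshold = select_threshold(scan, se_target=se_target)

        return HierarchicalBeatResults(
            model=self,
            ensemble=ensemble,
            sveb_threshold=float(sveb_threshold),
            threshold_scan=scan,
            cv_best=cv_best,
            cv_table=cv_table,
        )


class HierarchicalBeatResults:
    """Fitted hierarchy: ensemble + threshold + selection diagnostics."""

    def __init__(
        self,
        model: HierarchicalBeatModel,
        ensemble: EnsembleModel,
        sveb_threshold: float,
        threshold_scan: ThresholdScan | None = None,
        cv_best: CVResult | None = None,
        cv_table: pd.DataFrame | None = None,
    ) -> None:
        self.model = model
        self.ensemble = ensemble
        self.sveb_threshold = sveb_threshold
        self.threshold_scan = threshold_scan
        self.cv_best = cv_best
        self.cv_table = cv_table

    # -- prediction --------------------------------------------------------
    def predict_stages(self, beats: BeatDataset) -> tuple[np.ndarray, np.ndarray]:
        """(stage-1 winners, final labels) for a beat dataset.

        Final labels are V for stage-1 VEBs; among the rest, S when the RR
        ratio is strictly below the threshold, else N. Only N/S/V are ever
        emitted.
        """
        groups = featurize(
            beats, self.model.bank, self.model.lead_config, self.model.mode
        )
        winners = predict_winners(self.ensemble, groups)
        final = np.empty(len(beats), dtype=object)
        is_veb = winners == "V"
        final[is_veb] = "V"
        if (~is_veb).any():
            final[~is_veb] = detect_sveb(
                beats.rr_ratio[~is_veb], self.sveb_threshold
            )
        return winners, final

    def predict(self, beats: BeatDataset) -> np.ndarray:
        """Final N/S/V label per beat."""
        return self.predict_stages(beats)[1]

    def evaluate(self, beats: BeatDataset) -> EvaluationReport:
        """Confusion matrix, per-recording report and headline metrics."""
        final = self.predict(beats)
        cm = ConfusionMatrix.from_labels(beats.labels, final)
        report = per_recording_report(beats.labels, final, beats.record_ids)
        metrics = {
            "se_v": cm.sensitivity("V"),
            "pp_v": cm.positive_predictive_value("V"),
            "se_s": cm.sensitivity("S"),
            "pp_s": cm.positive_predictive_value("S"),
            "se_n": cm.sensitivity("N"),
            "pp_n": cm.positive_predictive_value("N"),
            "accuracy": cm.accuracy(),
            "ave": compute_ave(cm),
            "n_beats": cm.grand_total,
        }
        return EvaluationReport(confusion=cm, report=report, metrics=metrics)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Hierarchical heartbeat classifier",
            "=" * 45,
            f"training beats        {len(m.train_data)}",
            f"training recordings   {len(set(m.train_data.record_ids))}",
            f"lead configuration    {m.lead_config}",
            f"ensemble              M={m.n_matrices} RBF SVMs, d={m.projection_dim}, "
            f"mode={m.mode}",
            f"bank seed             {m.seed}",
            f"C, delta              {self.ensemble.C}, {self.ensemble.delta}",
            f"SVEB RR-ratio cutoff  {self.sveb_threshold:.2f}"
            + (" (selected on training set)" if self.threshold_scan else " (fixed)"),
        ]
        if self.cv_best is not None:
            lines.append(
                f"grid-search best Ave  {self.cv_best.ave:.1f}% "
                f"(C={self.cv_best.C}, delta={self.cv_best.delta})"
            )
        class_counts = pd.Series(m.train_data.labels).value_counts()
        lines.append(
            "class counts          "
            + ", ".join(f"{c}: {class_counts.get(c, 0)}" for c in ("N", "S", "V", "F", "Q"))
        )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Persist everything needed to reproduce predictions bit-for-bit."""
        joblib.dump(
            {
                "format": 1,
                "ensemble": self.ensemble,
                "sveb_threshold": self.sveb_threshold,
                "threshold_scan": self.threshold_scan,
                "bank_seed": self.model.seed,
                "n_matrices": self.model.n_matrices,
                "projection_dim": self.model.projection_dim,
                "window_len": self.model.window_len,
                "lead_config": self.model.lead_config,
                "mode": self.model.mode,
            },
            path,
        )

    @classmethod
    def load(cls, path, train_data: BeatDataset | None = None) -> "HierarchicalBeatResults":
        """Reload a saved fit; the bank is regenerated from its stored seed.

        ``train_data`` is optional — prediction does not need it; a
        placeholder single-beat dataset is synthesized if omitted.
        """
        payload = joblib.load(path)
        if train_data is None:
            wl = payload["window_len"]
            train_data = BeatDataset(
                record_ids=np.array(["_"], dtype=object),
                r_samples=np.array([0]),
                lead_windows={
                    lead: np.zeros((1, wl)) for lead in ("A", "B")
                },
                rr_prev_s=np.array([1.0]),
                rr_ratio=np.array([1.0]),
                labels=np.array(["N"], dtype=object),
            )
        model = HierarchicalBeatModel(
            train_data,
            lead_config=payload["lead_config"],
            n_matrices=payload["n_matrices"],
            projection_dim=payload["projection_dim"],
            window_len=payload["window_len"],
            seed=payload["bank_seed"],
            mode=payload["mode"],
        )
        return cls(
            model=model,
            ensemble=payload["ensemble"],
            sveb_threshold=payload["sveb_threshold"],
            threshold_scan=payload["threshold_scan"],
        )
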