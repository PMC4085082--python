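"""Stage-2 rule: RR-ratio thresholding for supraventricular ectopic beats.

Beats the ensemble did not label V are labelled S when their RR-interval
ratio (preceding RR over the recording-mean RR) is strictly below a
threshold, else N. The final system therefore only emits N, S or V.

The threshold is chosen on the training set by scanning 0.70..0.90 in steps
of 0.01 and taking the smallest threshold whose SVEB sensitivity reaches a
target (default 80%). Ratios are rounded to 10 decimal places before the
strict comparison so that beats sitting exactly on a grid value are never
reclassified by floating-point representation noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import threshold_grid

__all__ = [
    "DEFAULT_THRESHOLD",
    "ThresholdScan",
    "detect_sveb",
    "scan_thresholds",
    "select_threshold",
]

#: Deployment default selected on the reference training set.
DEFAULT_THRESHOLD = 0.8

_RATIO_DECIMALS = 10


@dataclass(frozen=True)
class ThresholdScan:
    """Se/PP curves over the threshold grid (percent; NaN where undefined)."""

    grid: tuple[float, ...]
    se_curve: tuple[float, ...]
    pp_curve: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.se_curve) == len(self.pp_curve)):
            raise ValueError("scan curves are not aligned with the grid")


def detect_sveb(rr_ratio: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Label each non-VEB beat: 'S' iff rr_ratio < threshold (strict), else 'N'."""
    r = np.asarray(rr_ratio, dtype=float)
    if np.isnan(r).any():
        raise ValueError("rr_ratio contains missing values")
    is_s = np.round(r, _RATIO_DECIMALS) < threshold
    return np.where(is_s, "S", "N").astype(object)


def scan_thresholds(
    rr_ratio: np.ndarray,
    reference_labels: np.ndarray,
    grid: "list[float] | None" = None,
) -> ThresholdScan:
    """SVEB Se and PP at every grid threshold, from the S-vs-not-S confusion.

    ``reference_labels`` are AAMI classes; only 'S' vs the rest matters.
    With no reference S beat the whole Se curve is undefined (NaN).
    """
    grid = list(grid) if grid is not None else threshold_grid()
    r = np.asarray(rr_ratio, dtype=float)
    ref_s = np.asarray(reference_labels, dtype=object) == "S"
    n_s = int(ref_s.sum())
    se, pp = [], []
    for t in grid:
        pred_s = np.round(r, _RATIO_DECIMALS) < t
        tp = int((pred_s & ref_s).sum())
        n_pred = int(pred_s.sum())
        se.append(100.0 * tp / n_s if n_s else np.nan)
        pp.append(100.0 * tp / n_pred if n_pred else np.nan)
    return ThresholdScan(grid=tuple(grid), se_curve=tuple(se), pp_curve=tuple(pp))


def select_threshold(scan: ThresholdScan, se_target: float = 80.0) -> float:
    """Smallest grid threshold whose sensitivity reaches ``se_target``.

    If no threshold reaches the target the grid maximum is returned with a
    warning — the rule can then only trade further sensitivity for nothing.
    """
    if not scan.grid:
        raise ValueError("empty threshold scan")
    for t, se in zip(scan.grid, scan.se_curve):
        if not np.isnan(se) and se >= se_target:
            return t
    warnings.warn(
        f"no threshold reaches Se >= {se_target}%; falling back to the grid "
        f"maximum {max(scan.grid)}",
        stacklevel=2,
    )
    return max(scan.grid)
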