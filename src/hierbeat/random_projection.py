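"""Gaussian random-matrix feature extraction.

Each of the M views projects a 200-sample beat onto the row space of a
d x m standard-Gaussian matrix A (d < m). In the default ``pinv`` mode the
feature vector is the least-squares coefficient vector

    F = X @ pinv(A),    so  F A  is the best row-space approximation of X,

the compressive-sensing reading of measuring a signal with a random sensing
matrix. ``transpose`` mode (F = X @ A.T, classical random projection) is
kept as a documented alternative; the two coincide when the rows of A are
orthonormal.

The bank of M matrices is generated once from a seed and reused everywhere
(all cross-validation folds, all parameter combinations), which both matches
the method's reuse of fixed feature groups and keeps model selection cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import BeatDataset

LEAD_CONFIGS = ("A", "B", "A+B")


@dataclass(frozen=True)
class RandomMatrixBank:
    """M seeded d x m Gaussian matrices defining the ensemble's feature views."""

    M: int
    d: int
    m: int
    seed: int
    matrices: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.matrices) != self.M:
            raise ValueError("bank size does not match M")
        for A in self.matrices:
            if A.shape != (self.d, self.m):
                raise ValueError(f"matrix shape {A.shape} != ({self.d}, {self.m})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.M, self.d, self.m)


def generate_bank(
    M: int = 15, d: int = 50, m: int = 200, seed: int = 0
) -> RandomMatrixBank:
    """Generate M i.i.d. N(0,1) matrices of shape d x m, reproducibly.

    Requires d < m (the projection must reduce dimension). Each matrix is
    checked for full row rank; a rank-deficient draw (probability ~0 for
    Gaussians) is redrawn.
    """
    if M < 1:
        raise ValueError("need at least one matrix")
    if not d < m:
        raise ValueError(f"projection dimension d={d} must be < beat length m={m}")
    rng = np.random.default_rng(seed)
    matrices = []
    while len(matrices) < M:
        A = rng.standard_normal((d, m))
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] > m * np.finfo(float).eps * s[0]:  # full row rank
            matrices.append(A)
    return RandomMatrixBank(M=M, d=d, m=m, seed=seed, matrices=tuple(matrices))


def project(X: np.ndarray, A: np.ndarray, mode: str = "pinv") -> np.ndarray:
    """Project beats (rows of X, length m) to d-dimensional features.

    ``pinv``: F = X @ pinv(A), the least-squares representation of each beat
    in the row space of A. ``transpose``: F = X @ A.T.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A, dtype=float)
    if X.shape[1] != A.shape[1]:
        raise ValueError(
            f"beat length {X.shape[1]} does not match matrix columns {A.shape[1]}"
        )
    if mode == "pinv":
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] <= max(A.shape) * np.finfo(float).eps * s[0]:
            raise ValueError("rank-deficient projection matrix")
        return X @ np.linalg.pinv(A)
    if mode == "transpose":
        return X @ A.T
    raise ValueError(f"unknown projection mode {mode!r}")


def _lead_list(lead_config: str) -> list[str]:
    if lead_config not in LEAD_CONFIGS:
        raise ValueError(f"lead_config must be one of {LEAD_CONFIGS}")
    return ["A", "B"] if lead_config == "A+B" else [lead_config]


def featurize(
    beats: BeatDataset,
    bank: RandomMatrixBank,
    lead_config: str = "A",
    mode: str = "pinv",
) -> list[np.ndarray]:
    """Build the M feature groups for a beat dataset.

    Group k has one row per beat: the d projection coefficients of each
    requested lead under matrix k (lead A then lead B for ``A+B``), followed
    by the preceding RR interval in seconds. Feature length is d+1 for a
    single lead and 2d+1 for ``A+B``. Beat order is preserved in every group.
    """
    leads = _lead_list(lead_config)
    missing = [lead for lead in leads if lead not in beats.lead_windows]
    if missing:
        raise ValueError(f"dataset lacks lead(s) {missing} for config {lead_config}")
    rr = np.asarray(beats.rr_prev_s, dtype=float).reshape(-1, 1)
    groups = []
    for A in bank.matrices:
        parts = [project(beats.lead_windows[lead], A, mode) for lead in leads]
        groups.append(np.hstack(parts + [rr]))
    return groups
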