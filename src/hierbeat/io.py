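"""Plain-text recording format: JSON header + CSV signal + CSV annotations.

A recording ``<id>`` is stored as three files in one directory:

``<id>.header.json``
    ``{"record_id", "sampling_rate", "n_samples", "leads"}``
``<id>.signal.csv``
    one column per lead (named ``A``, ``B``), one row per sample
``<id>.annotations.csv``
    columns ``sample,symbol`` — R-wave fiducial index and beat-type code

The layout mirrors the semantics of the MIT-BIH waveform/annotation triplet
(two leads, 360 Hz, R-peak sample indices with single-character beat codes)
while staying trivially diffable and hashable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RecordingError

SIGNAL_FMT = "%.6f"


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated event: R fiducial sample index plus its symbol."""

    record_id: str
    r_sample: int
    symbol: str
    sampling_rate: float = 360.0

    @property
    def time_s(self) -> float:
        return self.r_sample / self.sampling_rate


@dataclass
class Recording:
    """Two-lead (or single-lead) signal plus its ordered beat annotations."""

    record_id: str
    sampling_rate: float
    signals: dict[str, np.ndarray]
    annotations: list[BeatAnnotation] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.signals.keys())

    def __post_init__(self) -> None:
        lengths = {lead: len(sig) for lead, sig in self.signals.items()}
        if len(set(lengths.values())) > 1:
            raise RecordingError(f"lead lengths differ: {lengths}")
        samples = [a.r_sample for a in self.annotations]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise RecordingError(
                f"annotations of record {self.record_id} are not strictly increasing"
            )


def _paths(directory: str | Path, record_id: str) -> tuple[Path, Path, Path]:
    d = Path(directory)
    return (
        d / f"{record_id}.header.json",
        d / f"{record_id}.signal.csv",
        d / f"{record_id}.annotations.csv",
    )


def write_recording(recording: Recording, directory: str | Path) -> list[Path]:
    """Write the three-file triplet; returns the paths written."""
    header_p, signal_p, ann_p = _paths(directory, recording.record_id)
    header_p.parent.mkdir(parents=True, exist_ok=True)

    header = {
        "record_id": recording.record_id,
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
        "leads": list(recording.leads),
    }
    header_p.write_text(json.dumps(header, sort_keys=True, indent=1) + "\n")

    sig = pd.DataFrame({lead: recording.signals[lead] for lead in recording.leads})
    sig.to_csv(signal_p, index=False, float_format=SIGNAL_FMT)

    ann = pd.DataFrame(
        {
            "sample": [a.r_sample for a in recording.annotations],
            "symbol": [a.symbol for a in recording.annotations],
        }
    )
    ann.to_csv(ann_p, index=False)
    return [header_p, signal_p, ann_p]


def load_recording(
    directory: str | Path,
    record_id: str,
    expected_sampling_rate: float | None = None,
) -> Recording:
    """Read a recording triplet back from ``directory``.

    Annotations falling outside the signal raise a warning and are dropped;
    a sampling rate disagreeing with ``expected_sampling_rate`` is an error.
    """
    header_p, signal_p, ann_p = _paths(directory, record_id)
    for p in (header_p, signal_p, ann_p):
        if not p.exists():
            raise RecordingError(f"missing recording file: {p}")
    try:
        header = json.loads(header_p.read_text())
        sig = pd.read_csv(signal_p)
        ann = pd.read_csv(ann_p, dtype={"symbol": str}, keep_default_na=False)
    except (ValueError, OSError) as exc:
        raise RecordingError(f"corrupt recording {record_id}: {exc}") from exc

    fs = float(header["sampling_rate"])
    if expected_sampling_rate is not None and fs != float(expected_sampling_rate):
        raise RecordingError(
            f"record {record_id}: sampling rate {fs} != expected "
            f"{expected_sampling_rate}"
        )
    if list(sig.columns) != list(header["leads"]):
        raise RecordingError(
            f"record {record_id}: signal columns {list(sig.columns)} do not "
            f"match header leads {header['leads']}"
        )
    if len(sig) != int(header["n_samples"]):
        raise RecordingError(
            f"record {record_id}: header claims {header['n_samples']} samples, "
            f"signal file has {len(sig)}"
        )

    signals = {lead: sig[lead].to_numpy(dtype=float) for lead in header["leads"]}
    n = len(sig)
    annotations: list[BeatAnnotation] = []
    for sample, symbol in zip(ann["sample"], ann["symbol"]):
        sample = int(sample)
        if not 0 <= sample < n:
            warnings.warn(
                f"record {record_id}: annotation at sample {sample} outside "
                f"signal of length {n}; dropped",
                stacklevel=2,
            )
            continue
        annotations.append(
            BeatAnnotation(
                record_id=str(header["record_id"]),
                r_sample=sample,
                symbol=str(symbol),
                sampling_rate=fs,
            )
        )
    return Recording(
        record_id=str(header["record_id"]),
        sampling_rate=fs,
        signals=signals,
        annotations=annotations,
    )
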