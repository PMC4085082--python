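"""Beat segmentation, normalization, AAMI labelling and RR features.

Turns an annotated recording into a table of fixed-length, z-normalized beat
windows with per-beat RR features and AAMI class labels. Conventions:

* A beat window is 200 samples, taken ``[r-100, r+99]`` around the R
  fiducial (0.278 s either side at 360 Hz rounds to 100 samples; the window
  is symmetric to within one sample and deterministic).
* Normalization subtracts the window mean and divides by the *population*
  standard deviation (divide by n) — it is a normalization target, not an
  inference, so the convention is fixed and documented here.
* Beats whose window exits the signal, whose window is flat, or that have no
  previous RR interval (the first beat of a recording) are dropped, with
  counts reported; nothing is zero-padded, because padding distorts the
  morphology the classifier relies on.
* ``rr_ratio`` divides a beat's preceding RR interval by the mean RR
  interval of the entire recording (all annotated beats, computed once
  before any classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AAMI_CLASSES, load_config
from .errors import BeatBoundaryError, InvalidBeatError, NotABeatError
from .io import BeatAnnotation, Recording, load_recording  # noqa: F401  (re-export)

__all__ = [
    "segment_beat",
    "normalize_beat",
    "map_symbol_to_aami",
    "compute_rr_features",
    "load_recording",
    "beats_from_recording",
    "BeatDataset",
    "Heartbeat",
]


def segment_beat(
    signal: np.ndarray,
    r_sample: int,
    window_len: int = 200,
    pre_samples: int | None = None,
) -> np.ndarray:
    """Extract ``window_len`` consecutive samples around an R fiducial.

    With defaults the window is ``signal[r-100 : r+100]``. Raises
    :class:`BeatBoundaryError` if the window is not fully inside the signal.
    """
    if pre_samples is None:
        pre_samples = window_len // 2
    start = int(r_sample) - pre_samples
    stop = start + window_len
    if start < 0 or stop > len(signal):
        raise BeatBoundaryError(
            f"window [{start}, {stop}) for R at {r_sample} exceeds signal "
            f"bounds [0, {len(signal)})"
        )
    return np.asarray(signal[start:stop], dtype=float)


def normalize_beat(samples: np.ndarray) -> np.ndarray:
    """Z-normalize a beat window (population sd). Flat windows are invalid."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InvalidBeatError(f"window of length {x.size} cannot be normalized")
    sd = x.std()  # population convention (ddof=0)
    if sd == 0.0:
        raise InvalidBeatError("flat (zero-variance) beat window")
    return (x - x.mean()) / sd


def map_symbol_to_aami(
    symbol: str,
    symbol_map: Mapping[str, str] | None = None,
    non_beat_symbols: Iterable[str] | None = None,
) -> str:
    """Map a single-character beat code to its AAMI class.

    Unknown *beat* codes fall through to Q; rhythm/artifact annotation codes
    raise :class:`NotABeatError` because they do not mark a heartbeat at all.
    """
    if symbol_map is None or non_beat_symbols is None:
        cfg = load_config()
        symbol_map = symbol_map or cfg["symbol_map"]
        non_beat_symbols = non_beat_symbols or cfg["non_beat_symbols"]
    if symbol in symbol_map:
        cls = symbol_map[symbol]
        if cls not in AAMI_CLASSES:
            raise ValueError(f"symbol map sends {symbol!r} to unknown class {cls!r}")
        return cls
    if symbol in set(non_beat_symbols):
        raise NotABeatError(f"annotation code {symbol!r} is not a beat")
    return "Q"


def compute_rr_features(
    r_times_s: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Preceding RR interval and its ratio to the recording-mean RR.

    Returns ``(rr_prev_s, rr_ratio)`` aligned with the input beats; the first
    beat has no preceding interval and carries NaN in both outputs (callers
    drop it). The mean RR is taken over every successive interval of the
    recording, so ``rr_ratio`` is invariant under uniform time dilation.
    """
    t = np.asarray(r_times_s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 beats to define an RR interval")
    if np.any(np.diff(t) <= 0):
        raise ValueError("R times must be strictly increasing")
    rr = np.diff(t)
    rr_prev = np.concatenate([[np.nan], rr])
    rr_ratio = rr_prev / rr.mean()
    return rr_prev, rr_ratio


@dataclass(frozen=True)
class Heartbeat:
    """One retained beat: normalized windows per lead + RR features + label."""

    record_id: str
    r_sample: int
    samples: Mapping[str, np.ndarray]
    rr_prev_s: float
    rr_ratio: float
    aami_class: str
    symbol: str


@dataclass
class BeatDataset:
    """Column-oriented beat container: aligned arrays over n beats.

    ``lead_windows`` maps lead name to an ``(n, window_len)`` array of
    normalized windows. All arrays share beat order.
    """

    record_ids: np.ndarray
    r_samples: np.ndarray
    lead_windows: dict[str, np.ndarray]
    rr_prev_s: np.ndarray
    rr_ratio: np.ndarray
    labels: np.ndarray
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.lead_windows.keys())

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        return BeatDataset(
            record_ids=self.record_ids[mask],
            r_samples=self.r_samples[mask],
            lead_windows={k: v[mask] for k, v in self.lead_windows.items()},
            rr_prev_s=self.rr_prev_s[mask],
            rr_ratio=self.rr_ratio[mask],
            labels=self.labels[mask],
        )

    def for_records(self, record_ids: Iterable[str]) -> "BeatDataset":
        wanted = set(str(r) for r in record_ids)
        mask = np.array([r in wanted for r in self.record_ids])
        return self.subset(mask)

    @classmethod
    def concat(cls, parts: Sequence["BeatDataset"]) -> "BeatDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        leads = parts[0].leads
        if any(p.leads != leads for p in parts):
            raise ValueError("datasets have differing lead sets")
        drops: dict[str, int] = {}
        for p in parts:
            for k, v in p.drop_counts.items():
                drops[k] = drops.get(k, 0) + v
        return cls(
            record_ids=np.concatenate([p.record_ids for p in parts]),
            r_samples=np.concatenate([p.r_samples for p in parts]),
            lead_windows={
                lead: np.vstack([p.lead_windows[lead] for p in parts])
                for lead in leads
            },
            rr_prev_s=np.concatenate([p.rr_prev_s for p in parts]),
            rr_ratio=np.concatenate([p.rr_ratio for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            drop_counts=drops,
        )

    def to_table(self) -> pd.DataFrame:
        """Per-beat metadata table (no waveforms): the emitted beat CSV."""
        return pd.DataFrame(
            {
                "record_id": self.record_ids,
                "r_sample": self.r_samples,
                "aami_class": self.labels,
                "rr_prev_s": self.rr_prev_s,
                "rr_ratio": self.rr_ratio,
            }
        )


def beats_from_recording(
    recording: Recording,
    config: Mapping[str, Any] | None = None,
) -> BeatDataset:
    """Segment, normalize and label every usable beat of one recording.

    Drop accounting (``drop_counts``) satisfies
    ``annotations = retained + non_beat + first_beat + boundary + flat``.
    """
    cfg = dict(load_config())
    if config:
        cfg.update(config)
    window_len = int(cfg["window_len"])
    pre_samples = int(cfg["pre_samples"])
    symbol_map = cfg["symbol_map"]
    non_beat = set(cfg["non_beat_symbols"])

    counts = {"retained": 0, "non_beat": 0, "first_beat": 0, "boundary": 0, "flat": 0}

    beat_anns: list[BeatAnnotation] = []
    beat_classes: list[str] = []
    for ann in recording.annotations:
        try:
            cls = map_symbol_to_aami(ann.symbol, symbol_map, non_beat)
        except NotABeatError:
            counts["non_beat"] += 1
            continue
        beat_anns.append(ann)
        beat_classes.append(cls)

    if len(beat_anns) < 2:
        raise ValueError(
            f"record {recording.record_id}: need >= 2 beats, got {len(beat_anns)}"
        )

    r_times = [a.r_sample / recording.sampling_rate for a in beat_anns]
    rr_prev, rr_ratio = compute_rr_features(r_times)

    kept: list[int] = []
    windows: dict[str, list[np.ndarray]] = {lead: [] for lead in recording.leads}
    for i, ann in enumerate(beat_anns):
        if i == 0:
            counts["first_beat"] += 1  # no preceding RR interval
            continue
        try:
            beat_per_lead = {
                lead: normalize_beat(
                    segment_beat(sig, ann.r_sample, window_len, pre_samples)
                )
                for lead, sig in recording.signals.items()
            }
        except BeatBoundaryError:
            counts["boundary"] += 1
            continue
        except InvalidBeatError:
            counts["flat"] += 1
            continue
        for lead, w in beat_per_lead.items():
            windows[lead].append(w)
        kept.append(i)
        counts["retained"] += 1

    idx = np.array(kept, dtype=int)
    return BeatDataset(
        record_ids=np.array([recording.record_id] * len(idx), dtype=object),
        r_samples=np.array([beat_anns[i].r_sample for i in idx], dtype=int),
        lead_windows={
            lead: (
                np.vstack(w) if w else np.empty((0, window_len))
            )
            for lead, w in windows.items()
        },
        rr_prev_s=rr_prev[idx],
        rr_ratio=rr_ratio[idx],
        labels=np.array([beat_classes[i] for i in idx], dtype=object),
        drop_counts=counts,
    )


def beats_from_recordings(
    recordings: Iterable[Recording],
    config: Mapping[str, Any] | None = None,
) -> BeatDataset:
    """Concatenate :func:`beats_from_recording` over several recordings."""
    return BeatDataset.concat([beats_from_recording(r, config) for r in recordings])
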