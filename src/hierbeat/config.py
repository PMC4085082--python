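"""Configuration loading.

Defaults ship with the package (``defaults.yaml``); a user file given to
:func:`load_config` overrides keys shallowly. The record split and the
symbol map are configuration, not code, so alternative databases or beat
taxonomies can be used without touching the library.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

AAMI_CLASSES = ("N", "S", "V", "F", "Q")
#: Final-system output classes (stage 1 decides V, stage 2 decides S vs N).
FINAL_CLASSES = ("N", "S", "V")


def _read_defaults() -> dict[str, Any]:
    text = (
        importlib.resources.files("hierbeat").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default config, shallowly overridden by ``path`` if given."""
    cfg = _read_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg


@dataclass(frozen=True)
class DatasetSplit:
    """Inter-patient record division: DS1 trains, DS2 tests, paced excluded."""

    ds1_records: tuple[str, ...]
    ds2_records: tuple[str, ...]
    excluded_records: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.ds1_records) & set(self.ds2_records)
        if overlap:
            raise ValueError(f"DS1 and DS2 overlap: {sorted(overlap)}")
        used = set(self.ds1_records) | set(self.ds2_records)
        leaked = used & set(self.excluded_records)
        if leaked:
            raise ValueError(f"excluded records present in split: {sorted(leaked)}")

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "DatasetSplit":
        return cls(
            ds1_records=tuple(str(r) for r in cfg["ds1_records"]),
            ds2_records=tuple(str(r) for r in cfg["ds2_records"]),
            excluded_records=tuple(str(r) for r in cfg.get("excluded_records", ())),
        )


def threshold_grid(cfg: Mapping[str, Any] | None = None) -> "list[float]":
    """The RR-ratio threshold candidates (default 0.70..0.90, step 0.01)."""
    g = (cfg or _read_defaults())["threshold_grid"]
    n = int(round((g["stop"] - g["start"]) / g["step"])) + 1
    return [round(g["start"] + i * g["step"], 10) for i in range(n)]
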