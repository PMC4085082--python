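"""Seeded synthetic two-lead ECG generator for download-free testing.

Each beat is a sum of three Gaussian bumps — P wave, QRS complex, T wave —
placed on baseline noise, which is deliberately minimal but expresses the
two axes the hierarchical classifier exploits:

* **morphology** — ventricular ectopics (V) have a QRS at least twice as
  wide as normal beats and no P wave; supraventricular ectopics (S) share
  the normal morphology; fusion beats (F) mix the N and V templates 50/50;
* **rhythm** — V beats arrive early (preceding RR ratio ~0.6 of the base
  rhythm) and are followed by a compensatory pause (~1.4x); S beats arrive
  early (ratio ~0.65) with normal morphology; N and F beats keep a
  quasi-regular rhythm.

Q beats are not generated: they are vanishingly rare in the reference
corpus (15 beats in total) and carry no structure this method uses.

Lead B is the lead-A wave train under an independent amplitude scaling with
its own noise, emulating a second electrode view. All draws come from one
`numpy` generator seeded per recording, so every dataset is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import BeatAnnotation, Recording

__all__ = [
    "BeatTemplate",
    "RhythmModel",
    "default_templates",
    "simulate_recording",
    "simulate_dataset",
]

#: Minimum physiological RR interval; all draws are truncated above this.
MIN_RR_S = 0.2

#: AAMI class -> annotation symbol written to the annotation stream.
CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F"}


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-bump beat morphology: amplitudes, widths (sigma, s), centers (s)."""

    class_label: str
    p_amp: float
    p_width_s: float
    qrs_amp: float
    qrs_width_s: float
    t_amp: float
    t_width_s: float
    jitter_sd: float = 0.05  # fractional, applied per beat per parameter

    #: wave centers relative to the R fiducial (shared by all templates)
    P_OFFSET_S = -0.17
    T_OFFSET_S = 0.22


def default_templates() -> dict[str, BeatTemplate]:
    """The study conditions: N-like, wide-QRS V, N-morphology S, N/V-mix F.

    The V template's QRS width is >= 2x the N template's and its P amplitude
    is zero; S duplicates N (only rhythm distinguishes it); F parameters are
    the midpoint of N and V.
    """
    n = BeatTemplate(
        class_label="N",
        p_amp=0.15,
        p_width_s=0.02,
        qrs_amp=1.0,
        qrs_width_s=0.012,
        t_amp=0.3,
        t_width_s=0.06,
    )
    v = BeatTemplate(
        class_label="V",
        p_amp=0.0,
        p_width_s=0.02,
        qrs_amp=1.2,
        qrs_width_s=0.032,
        t_amp=-0.4,
        t_width_s=0.07,
    )
    s = replace(n, class_label="S")
    f = BeatTemplate(
        class_label="F",
        p_amp=(n.p_amp + v.p_amp) / 2,
        p_width_s=(n.p_width_s + v.p_width_s) / 2,
        qrs_amp=(n.qrs_amp + v.qrs_amp) / 2,
        qrs_width_s=(n.qrs_width_s + v.qrs_width_s) / 2,
        t_amp=(n.t_amp + v.t_amp) / 2,
        t_width_s=(n.t_width_s + v.t_width_s) / 2,
    )
    return {"N": n, "S": s, "V": v, "F": f}


@dataclass(frozen=True)
class RhythmModel:
    """RR-interval structure of a recording.

    ``sveb_ratio_mean``/``veb_ratio_mean`` set where the ectopic RR ratios
    concentrate (both well below the N mode at 1.0), with a compensatory
    pause after each V beat; this reproduces the separation the stage-2
    threshold rule relies on.
    """

    base_rr_s: float = 0.8
    rr_jitter_sd: float = 0.04
    sveb_ratio_mean: float = 0.65
    sveb_ratio_sd: float = 0.05
    veb_ratio_mean: float = 0.6
    veb_ratio_sd: float = 0.05
    compensatory_pause_factor: float = 1.4
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"N": 0.80, "S": 0.10, "V": 0.08, "F": 0.02}
    )

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mix must sum to 1, got {total}")
        unknown = set(self.class_mix) - set("NSVF")
        if unknown:
            raise ValueError(f"unknown classes in mix: {unknown}")


def _draw_rr(
    rng: np.random.Generator, rhythm: RhythmModel, cls: str, after_v: bool
) -> float:
    base = rhythm.base_rr_s
    if cls == "S":
        rr = base * rng.normal(rhythm.sveb_ratio_mean, rhythm.sveb_ratio_sd)
    elif cls == "V":
        rr = base * rng.normal(rhythm.veb_ratio_mean, rhythm.veb_ratio_sd)
    elif after_v:
        rr = base * rhythm.compensatory_pause_factor + rng.normal(
            0.0, rhythm.rr_jitter_sd
        )
    else:
        rr = rng.normal(base, rhythm.rr_jitter_sd)
    return max(rr, MIN_RR_S)


def _render_wave(
    t: np.ndarray,
    centers_s: np.ndarray,
    params: Sequence[tuple[float, float, float, float, float, float]],
    amp_scale: float,
) -> np.ndarray:
    """Sum of P/QRS/T Gaussians for every beat onto the time axis ``t``."""
    sig = np.zeros_like(t)
    for c, (pa, pw, qa, qw, ta, tw) in zip(centers_s, params):
        # restrict to a +-0.6 s neighbourhood of the beat for speed
        lo, hi = np.searchsorted(t, [c - 0.6, c + 0.6])
        win = t[lo:hi]
        sig[lo:hi] += amp_scale * (
            pa * np.exp(-0.5 * ((win - (c + BeatTemplate.P_OFFSET_S)) / pw) ** 2)
            + qa * np.exp(-0.5 * ((win - c) / qw) ** 2)
            + ta * np.exp(-0.5 * ((win - (c + BeatTemplate.T_OFFSET_S)) / tw) ** 2)
        )
    return sig


def simulate_recording(
    n_beats: int,
    record_id: str = "900",
    templates: Mapping[str, BeatTemplate] | None = None,
    rhythm: RhythmModel | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    sampling_rate: float = 360.0,
    lead_b_scale: float = 0.7,
    margin_s: float = 0.4,
) -> Recording:
    """Generate one annotated two-lead recording with known true classes.

    Beat classes are drawn i.i.d. from the rhythm model's mix; RR intervals
    follow the class-dependent rules above. R fiducials coincide with QRS
    bump centers. The annotation stream carries the MIT-BIH symbols of the
    true classes, so the recording feeds straight into preprocessing.
    """
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    templates = dict(templates or default_templates())
    rhythm = rhythm or RhythmModel()
    rng = np.random.default_rng(seed)

    mix_classes = sorted(rhythm.class_mix)
    mix_p = np.array([rhythm.class_mix[c] for c in mix_classes])
    classes = list(rng.choice(mix_classes, size=n_beats, p=mix_p))

    r_times = np.empty(n_beats)
    t_cursor = margin_s
    prev_cls = None
    for i, cls in enumerate(classes):
        if i > 0:
            t_cursor += _draw_rr(rng, rhythm, cls, after_v=(prev_cls == "V"))
        r_times[i] = t_cursor
        prev_cls = cls

    # per-beat jittered morphology parameters
    params = []
    for cls in classes:
        tpl = templates[cls]
        j = lambda x: x * (1.0 + rng.normal(0.0, tpl.jitter_sd))
        params.append(
            (
                j(tpl.p_amp),
                max(j(tpl.p_width_s), 1e-3),
                j(tpl.qrs_amp),
                max(j(tpl.qrs_width_s), 1e-3),
                j(tpl.t_amp),
                max(j(tpl.t_width_s), 1e-3),
            )
        )

    duration = r_times[-1] + margin_s
    n_samples = int(np.ceil(duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    # snap fiducials onto the sample grid so QRS centers and annotations agree
    r_samples = np.round(r_times * sampling_rate).astype(int)
    centers = r_samples / sampling_rate

    lead_a = _render_wave(t, centers, params, 1.0)
    lead_a += rng.normal(0.0, noise_sd, size=n_samples)
    lead_b = _render_wave(t, centers, params, lead_b_scale)
    lead_b += rng.normal(0.0, noise_sd, size=n_samples)

    annotations = [
        BeatAnnotation(
            record_id=str(record_id),
            r_sample=int(rs),
            symbol=CLASS_SYMBOL[cls],
            sampling_rate=sampling_rate,
        )
        for rs, cls in zip(r_samples, classes)
    ]
    return Recording(
        record_id=str(record_id),
        sampling_rate=sampling_rate,
        signals={"A": lead_a, "B": lead_b},
        annotations=annotations,
    )


def simulate_dataset(
    n_recordings: int = 6,
    n_beats: int = 500,
    seed: int = 0,
    base_rr_sd: float = 0.06,
    qrs_width_rel_sd: float = 0.10,
    amp_rel_sd: float = 0.10,
    noise_sd_range: tuple[float, float] = (0.03, 0.07),
    class_mix: Mapping[str, float] | None = None,
) -> tuple[list[Recording], list[Recording]]:
    """Generate disjoint DS1-like (train) and DS2-like (test) recording sets.

    Per-recording template and rhythm parameters are drawn from
    hyper-distributions (base heart rate, QRS widths, wave amplitudes, noise
    level, lead-B gain), so recordings behave like different patients; the
    first half of the ids forms the training set, the second half the test
    set. Fully reproducible from ``seed``.
    """
    if n_recordings < 2:
        raise ValueError("need at least 2 recordings to form a split")
    rng = np.random.default_rng(seed)
    recordings = []
    for i in range(n_recordings):
        base = default_templates()
        width_f = 1.0 + rng.normal(0.0, qrs_width_rel_sd)
        amp_f = 1.0 + rng.normal(0.0, amp_rel_sd)
        templates = {
            cls: replace(
                tpl,
                qrs_width_s=tpl.qrs_width_s * max(width_f, 0.5),
                qrs_amp=tpl.qrs_amp * max(amp_f, 0.5),
                t_amp=tpl.t_amp * max(amp_f, 0.5),
            )
            for cls, tpl in base.items()
        }
        rhythm = RhythmModel(
            base_rr_s=float(np.clip(rng.normal(0.8, base_rr_sd), 0.5, 1.2)),
            class_mix=class_mix or RhythmModel().class_mix,
        )
        recordings.append(
            simulate_recording(
                n_beats=n_beats,
                record_id=str(900 + i),
                templates=templates,
                rhythm=rhythm,
                noise_sd=float(rng.uniform(*noise_sd_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
                lead_b_scale=float(rng.uniform(0.5, 0.9)),
            )
        )
    half = n_recordings // 2
    return recordings[:half], recordings[half:]
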