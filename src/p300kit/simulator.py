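"""Synthetic P300-speller sessions with controllable ERPs and noise.

A session spells a text on the 6x6 matrix: per character, ``iterations``
pseudo-random permutations of the 12 row/column flashes at a fixed
inter-stimulus interval, with a pause between characters. Target flashes
add an N200 (negative, occipito-parietal) and a P300 (positive,
centro-parietal) template to the ongoing noise; standard flashes add
nothing. Templates are Gaussian bumps -- amplitude, latency and FWHM width
per component -- scaled by a per-sensor topography; responses of
consecutive targets sum linearly, so short-ISI interference emerges
naturally. Everything is reproducible from the seed.

``degrade`` re-creates the storage pitfalls found in public speller
datasets (overlapping or label-sorted epoch segmentation, trial
normalization, missing sensor ordering, stripped paradigm metadata) to
exercise the container importers and validators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .container import CharMarker, Recording, SensorInfo
from .paradigm import (
    Encoder,
    LogicalSymbol,
    ParadigmParams,
    StimulusEvent,
    all_logical_symbols,
    build_default_encoder,
    classify_stimulus,
)

__all__ = ["ErpTemplate", "SimConfig", "make_sequence", "synthesize", "degrade", "cut_epochs"]

#: the 8-sensor montage used throughout: midline plus parieto-occipital sites
DEFAULT_SENSORS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

FWHM_TO_SIGMA = 2.355  # full width at half maximum of a Gaussian = 2.355 sigma


@dataclass(frozen=True)
class ErpTemplate:
    """One evoked component: a Gaussian bump with a scalp topography."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float  # full width at half maximum
    topography: dict[str, float] = field(default_factory=dict)
    default_weight: float = 0.1

    def weight(self, sensor: str) -> float:
        return self.topography.get(sensor, self.default_weight)


DEFAULT_N200 = ErpTemplate(
    latency_ms=200.0,
    amplitude_uv=-5.0,
    width_ms=80.0,
    topography={"PO7": 1.0, "PO8": 0.8, "Oz": 0.5},
)
DEFAULT_P300 = ErpTemplate(
    latency_ms=300.0,
    amplitude_uv=5.0,
    width_ms=150.0,
    topography={"Cz": 1.0, "Pz": 0.9},
    default_weight=0.2,
)


@dataclass(frozen=True)
class SimConfig:
    """Session parameters. Defaults mirror a classic copy-spelling setup:

    240 Hz acquisition, 175 ms ISI, 15 iterations per character, 100 ms
    flashes, the 8-sensor montage, and 5 uV white noise around +/-5 uV
    components.
    """

    text: str
    iterations: int = 15
    isi_ms: float = 175.0
    flash_duration_ms: float = 100.0
    fs: float = 240.0
    sensors: tuple[str, ...] = DEFAULT_SENSORS
    n200: ErpTemplate = DEFAULT_N200
    p300: ErpTemplate = DEFAULT_P300
    noise_sd: float = 5.0
    noise_model: str = "white"  # or "lowpass"
    inter_char_gap_ms: float = 1000.0
    tail_ms: float = 1000.0  # silence recorded after the last flash
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("text must be non-empty")
        if self.fs <= 0 or self.isi_ms <= 0 or self.iterations < 1:
            raise ValueError("fs and isi_ms must be positive, iterations >= 1")
        if self.noise_model not in ("white", "lowpass"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def make_sequence(
    text: str,
    iterations: int,
    isi_ms: float,
    inter_char_gap_ms: float = 1000.0,
    encoder: Encoder | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[StimulusEvent]:
    """Generate the flash sequence for spelling ``text``.

    Each iteration is an independent uniform permutation of the 12 logical
    symbols; onsets are spaced ``isi_ms`` apart within a character with an
    extra ``inter_char_gap_ms`` between characters. Natures are labeled
    against the intended character.
    """
    if not text:
        raise ValueError("text must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    enc = encoder if encoder is not None else build_default_encoder()
    ls12 = all_logical_symbols()
    events: list[StimulusEvent] = []
    t = 0.0
    for ci, ss in enumerate(text):
        for _ in range(iterations):
            for j in rng.permutation(12):
                ls = ls12[j]
                events.append(StimulusEvent(t, ls, classify_stimulus(ls, ss, enc), ci))
                t += isi_ms
        t += inter_char_gap_ms
    return events


def _template_wave(tpl: ErpTemplate, onset_ms: float, times_ms: np.ndarray) -> np.ndarray:
    sigma = tpl.width_ms / FWHM_TO_SIGMA
    return tpl.amplitude_uv * np.exp(-((times_ms - onset_ms - tpl.latency_ms) ** 2) / (2 * sigma**2))


def synthesize(config: SimConfig) -> Recording:
    """Render a level-1-complete recording from a session config."""
    rng = np.random.default_rng(config.seed)
    enc = build_default_encoder()
    events = make_sequence(
        config.text,
        config.iterations,
        config.isi_ms,
        config.inter_char_gap_ms,
        encoder=enc,
        rng=rng,
    )
    n_ch = len(config.sensors)
    n_samples = int(round((events[-1].onset_ms + config.tail_ms) * config.fs / 1000.0))
    times_ms = np.arange(n_samples) * 1000.0 / config.fs

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n_ch, n_samples))
        if config.noise_model == "lowpass":
            # first-order recursive smoother, rescaled back to noise_sd
            from scipy.signal import lfilter

            a = 0.9
            noise = lfilter([1 - a], [1, -a], noise, axis=1)
            noise *= config.noise_sd / noise.std(axis=1, keepdims=True)
    else:
        noise = np.zeros((n_ch, n_samples))

    signal = noise
    for ev in events:
        if ev.nature != "target":
            continue
        # bump support: +/- 5 sigma around the later component is plenty
        lo_ms = ev.onset_ms + min(
            config.n200.latency_ms - 5 * config.n200.width_ms,
            config.p300.latency_ms - 5 * config.p300.width_ms,
        )
        hi_ms = ev.onset_ms + max(
            config.n200.latency_ms + 5 * config.n200.width_ms,
            config.p300.latency_ms + 5 * config.p300.width_ms,
        )
        lo = max(0, int(lo_ms * config.fs / 1000.0))
        hi = min(n_samples, int(hi_ms * config.fs / 1000.0) + 1)
        if lo >= hi:
            continue
        seg = times_ms[lo:hi]
        for tpl in (config.n200, config.p300):
            wave = _template_wave(tpl, ev.onset_ms, seg)
            for i, s in enumerate(config.sensors):
                signal[i, lo:hi] += tpl.weight(s) * wave

    # character markers span first flash onset to last flash onset + ISI
    markers = []
    for ci, ss in enumerate(config.text):
        evs = [ev for ev in events if ev.character_index == ci]
        begin = int(round(evs[0].onset_ms * config.fs / 1000.0))
        end = int(round((evs[-1].onset_ms + config.isi_ms) * config.fs / 1000.0))
        markers.append(CharMarker(ci, begin, end, ss))

    sensors = [
        SensorInfo(
            label=s,
            ordinal=i,
            reference_label="linked-mastoids",
            ground_label="AFz",
            technology_note="synthetic",
        )
        for i, s in enumerate(config.sensors)
    ]
    return Recording(
        signal=signal.astype(np.float32),
        fs=config.fs,
        sensors=sensors,
        events=events,
        char_markers=markers,
        paradigm=ParadigmParams(
            isi_ms=config.isi_ms,
            iterations_min=config.iterations,
            iterations_max=config.iterations,
            flash_duration_ms=config.flash_duration_ms,
        ),
        encoder=enc,
        alphabet=enc.alphabet,
        provenance=f"synthetic session, seed={config.seed}, text={config.text!r}",
    )


def cut_epochs(rec: Recording, epoch_len_ms: float) -> tuple[np.ndarray, list[str], list[float]]:
    """Slice one epoch per event from stimulus onset; drops flashes whose
    epoch would run past the end of the recording."""
    n = int(np.floor(epoch_len_ms * rec.fs / 1000.0))
    chunks, labels, onsets = [], [], []
    for ev in rec.events:
        lo = int(round(ev.onset_ms * rec.fs / 1000.0))
        if lo + n > rec.n_samples:
            continue
        chunks.append(rec.signal[:, lo : lo + n])
        labels.append(ev.nature)
        onsets.append(ev.onset_ms)
    return np.stack(chunks).astype(np.float32), labels, onsets


DIALECTS = (
    "segmented_sorted",
    "segmented_overlapping",
    "strip_sensor_order",
    "normalize_trials",
    "drop_paradigm_block",
)


def degrade(rec: Recording, dialect: str, seed: int = 0, epoch_len_ms: float = 1000.0):
    """Emulate a dataset-storage pitfall on a compliant recording.

    Returns either a degraded :class:`Recording` (metadata pitfalls) or a
    segmented-epochs payload dict suitable for
    :func:`p300kit.container.import_segmented_dialect`.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")

    if dialect == "strip_sensor_order":
        out = dataclasses.replace(rec)
        out.sensors = [dataclasses.replace(s, ordinal=None) for s in rec.sensors]
        out.provenance += " | degraded: sensor ordering stripped"
        return out

    if dialect == "drop_paradigm_block":
        out = dataclasses.replace(rec)
        out.paradigm = None
        out.encoder = None
        out.alphabet = None
        out.char_markers = []
        out.provenance += " | degraded: paradigm/encoder metadata dropped"
        return out

    epochs, labels, onsets = cut_epochs(rec, epoch_len_ms)
    isi = rec.paradigm.isi_ms if rec.paradigm is not None else None
    payload = {
        "epochs": epochs,
        "labels": labels,
        "onsets_ms": onsets,
        "fs": rec.fs,
        "epoch_len_ms": epoch_len_ms,
        "isi_ms": isi,
    }
    if dialect == "segmented_overlapping":
        return payload
    if dialect == "normalize_trials":
        flat = payload["epochs"].reshape(len(labels), -1)
        sd = flat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        payload["epochs"] = (flat / sd).reshape(payload["epochs"].shape)
        return payload
    # segmented_sorted: targets first, order within class shuffled, onsets lost
    rng = np.random.default_rng(seed)
    order = np.concatenate(
        [
            rng.permutation(np.flatnonzero([lab == "target" for lab in labels])),
            rng.permutation(np.flatnonzero([lab == "standard" for lab in labels])),
        ]
    )
    payload["epochs"] = payload["epochs"][order]
    payload["labels"] = [labels[k] for k in order]
    payload["onsets_ms"] = None
    return payload
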