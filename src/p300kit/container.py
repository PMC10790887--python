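"""Self-describing single-file format for P300-speller recordings.

A ``.p3x`` file is one UTF-8 JSON header line (schema version, acquisition
metadata, event table, paradigm block, encoder, free-text provenance,
arbitrary extension blocks) followed by a length-prefixed little-endian
float32 signal block, channel-major. The header is an ordinary JSON
document readable on its own, so any JSON tool can inspect a file without
touching the signal.

The content model has two tiers:

* level 0 -- everything acquisition: signal, sampling rate, sensor labels
  in channel order with reference/ground, and the stimulus events;
* level 1 -- everything needed to train a classifier with no side
  documents: additionally the encoder, the semantic alphabet, per-character
  stimulation-sequence markers with the intended (or inferable) symbol, and
  the stimulation parameters (ISI, iterations), stored or deducible from
  the events.

The module also imports the degraded layouts public datasets ship in
(epoch-segmented files, label-sorted trials with the original order lost,
trial-normalized amplitudes) back into the container, reporting what was
lost on the way.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .paradigm import (
    Encoder,
    LogicalSymbol,
    ParadigmParams,
    SemanticAlphabet,
    StimulusEvent,
    infer_isi,
    infer_iterations,
)

__all__ = [
    "SensorInfo",
    "CharMarker",
    "Recording",
    "ValidationReport",
    "ContainerFormatError",
    "IrrecoverableSegmentationError",
    "write_recording",
    "read_recording",
    "validate",
    "import_segmented_dialect",
    "flag_normalization",
    "recordings_equal",
    "write_events_tsv",
]

SCHEMA_VERSION = (1, 0)
MAGIC_KEY = "p3x"
#: value written into reconstructed signals where no epoch covered a sample
MISSING_VALUE = float("nan")
#: maximum disagreement (uV) tolerated between overlapping epoch samples
DEOVERLAP_TOL = 1e-5


class ContainerFormatError(ValueError):
    """The file is not a parseable container of a supported version."""


class IrrecoverableSegmentationError(ValueError):
    """Overlapping epochs disagree; the continuous signal cannot be rebuilt."""


@dataclass(frozen=True)
class SensorInfo:
    """One EEG sensor: 10-20 label, channel position, montage notes."""

    label: str
    ordinal: int | None = None
    reference_label: str | None = None
    ground_label: str | None = None
    technology_note: str = ""


@dataclass(frozen=True)
class CharMarker:
    """Begin/end (samples) of one character's stimulation sequence."""

    character_index: int
    begin_sample: int
    end_sample: int
    intended_ss: str | None = None


@dataclass
class Recording:
    """A continuous multichannel recording plus its speller metadata."""

    signal: np.ndarray  # channels x samples, microvolts
    fs: float
    sensors: list[SensorInfo] = field(default_factory=list)
    events: list[StimulusEvent] = field(default_factory=list)
    char_markers: list[CharMarker] = field(default_factory=list)
    paradigm: ParadigmParams | None = None
    encoder: Encoder | None = None
    alphabet: SemanticAlphabet | None = None
    provenance: str = ""
    extensions: dict[str, Any] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    def sensor_labels(self) -> list[str]:
        return [s.label for s in self.sensors]


@dataclass
class ValidationReport:
    level0_ok: bool
    level1_ok: bool
    findings: list[tuple[str, str, str]] = field(default_factory=list)  # severity, code, message

    def codes(self) -> set[str]:
        return {code for _, code, _ in self.findings}


# ---------------------------------------------------------------------------
# serialization


def _event_to_list(ev: StimulusEvent) -> list:
    return [ev.onset_ms, ev.ls_code, ev.nature, ev.character_index]


def _event_from_list(item: Sequence) -> StimulusEvent:
    onset, code, nature, ci = item
    ls = None if code is None else LogicalSymbol.from_code(int(code))
    return StimulusEvent(float(onset), ls, nature, None if ci is None else int(ci))


def _header_dict(rec: Recording) -> dict:
    return {
        MAGIC_KEY: True,
        "schema_version": list(SCHEMA_VERSION),
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "signal_dtype": "float32-le",
        "signal_order": "channel-major",
        "units": "microvolts",
        "missing_value": "NaN",
        "sensors": [dataclasses.asdict(s) for s in rec.sensors],
        "events": [_event_to_list(ev) for ev in rec.events],
        "char_markers": [dataclasses.asdict(m) for m in rec.char_markers],
        "paradigm": None
        if rec.paradigm is None
        else {
            "isi_ms": rec.paradigm.isi_ms,
            "iterations_min": rec.paradigm.iterations_min,
            "iterations_max": rec.paradigm.iterations_max,
            "flash_duration_ms": rec.paradigm.flash_duration_ms,
        },
        "encoder_layout": None if rec.encoder is None else list(rec.encoder.layout),
        "alphabet": None if rec.alphabet is None else "".join(rec.alphabet.symbols),
        "provenance": rec.provenance,
        "extensions": rec.extensions,
    }


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to a single ``.p3x`` file.

    Layout: one JSON header line, an 8-byte little-endian byte count, then
    the float32 signal block. Unknown extension blocks in ``rec.extensions``
    are carried verbatim.
    """
    rep = validate(rec)
    if not rep.level0_ok:
        bad = ", ".join(sorted(rep.codes()))
        raise ValueError(f"recording fails level-0 validation ({bad}); refusing to write")
    path = Path(path)
    header = json.dumps(_header_dict(rec), ensure_ascii=False, separators=(",", ":"))
    block = np.ascontiguousarray(rec.signal, dtype="<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header.encode("utf-8") + b"\n")
        fh.write(struct.pack("<Q", len(block)))
        fh.write(block)
    return path


def read_header(path: str | Path) -> dict:
    """Parse only the JSON header line of a container file."""
    with open(path, "rb") as fh:
        line = fh.readline()
    try:
        header = json.loads(line.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ContainerFormatError(f"corrupt header: {exc}") from exc
    if not isinstance(header, dict) or not header.get(MAGIC_KEY):
        raise ContainerFormatError("not a recognized container header")
    major, minor = header.get("schema_version", (0, 0))
    if (major, minor) > SCHEMA_VERSION:
        raise ContainerFormatError(
            f"schema version {major}.{minor} is newer than supported {SCHEMA_VERSION[0]}.{SCHEMA_VERSION[1]}"
        )
    return header


def read_recording(path: str | Path) -> Recording:
    """Read a ``.p3x`` file back into a :class:`Recording`."""
    path = Path(path)
    header = read_header(path)
    with open(path, "rb") as fh:
        fh.readline()
        prefix = fh.read(8)
        if len(prefix) != 8:
            raise ContainerFormatError("truncated file: missing signal length prefix")
        (nbytes,) = struct.unpack("<Q", prefix)
        block = fh.read(nbytes)
    if len(block) != nbytes:
        raise ContainerFormatError(
            f"truncated signal block: expected {nbytes} bytes, found {len(block)}"
        )
    n_ch, n_s = int(header["n_channels"]), int(header["n_samples"])
    if nbytes != n_ch * n_s * 4:
        raise ContainerFormatError("signal block size disagrees with header dimensions")
    signal = np.frombuffer(block, dtype="<f4").reshape(n_ch, n_s).astype(np.float32)

    par = header.get("paradigm")
    paradigm = (
        None
        if par is None
        else ParadigmParams(
            isi_ms=par["isi_ms"],
            iterations_min=par["iterations_min"],
            iterations_max=par["iterations_max"],
            flash_duration_ms=par.get("flash_duration_ms"),
        )
    )
    layout = header.get("encoder_layout")
    alpha = header.get("alphabet")
    return Recording(
        signal=signal,
        fs=float(header["fs_hz"]),
        sensors=[SensorInfo(**s) for s in header.get("sensors", [])],
        events=[_event_from_list(e) for e in header.get("events", [])],
        char_markers=[CharMarker(**m) for m in header.get("char_markers", [])],
        paradigm=paradigm,
        encoder=None if layout is None else Encoder(tuple(layout)),
        alphabet=None if alpha is None else SemanticAlphabet(tuple(alpha)),
        provenance=header.get("provenance", ""),
        extensions=header.get("extensions", {}),
    )


def recordings_equal(a: Recording, b: Recording) -> bool:
    """Field-by-field equality; signals compared bit-exactly (NaN == NaN)."""
    if a.signal.shape != b.signal.shape:
        return False
    if not np.array_equal(
        np.asarray(a.signal, dtype=np.float32), np.asarray(b.signal, dtype=np.float32), equal_nan=True
    ):
        return False
    return (
        a.fs == b.fs
        and a.sensors == b.sensors
        and a.events == b.events
        and a.char_markers == b.char_markers
        and a.paradigm == b.paradigm
        and a.encoder == b.encoder
        and a.alphabet == b.alphabet
        and a.provenance == b.provenance
        and a.extensions == b.extensions
    )


# ---------------------------------------------------------------------------
# validation


def validate(rec: Recording) -> ValidationReport:
    """Check the level-0 (acquisition) and level-1 (ML-ready) tiers.

    Report-only: never raises. ``level1_ok`` implies ``level0_ok``.
    """
    findings: list[tuple[str, str, str]] = []

    def err(code: str, msg: str) -> None:
        findings.append(("error", code, msg))

    def warn(code: str, msg: str) -> None:
        findings.append(("warning", code, msg))

    # --- level 0
    level0 = True
    if rec.signal is None or rec.signal.ndim != 2 or rec.signal.size == 0:
        err("NO_SIGNAL", "signal matrix missing or empty")
        level0 = False
    if not rec.fs or rec.fs <= 0:
        err("BAD_FS", "sampling rate missing or non-positive")
        level0 = False
    if not rec.sensors:
        err("NO_SENSORS", "no sensor metadata")
        level0 = False
    else:
        labels = rec.sensor_labels()
        if len(set(labels)) != len(labels):
            err("DUP_SENSOR_LABEL", "sensor labels are not unique")
            level0 = False
        if rec.signal is not None and rec.signal.ndim == 2 and len(rec.sensors) != rec.n_channels:
            err(
                "CHANNEL_MISMATCH",
                f"{len(rec.sensors)} sensors but {rec.n_channels} signal channels",
            )
            level0 = False
        ordinals = [s.ordinal for s in rec.sensors]
        if any(o is None for o in ordinals) or sorted(ordinals) != list(range(len(ordinals))):
            err(
                "SENSOR_ORDER",
                "sensor-to-channel ordering missing or inconsistent: "
                "signals cannot be matched to sensors",
            )
            level0 = False
        if any(not s.reference_label or not s.ground_label for s in rec.sensors):
            err("REF_GROUND", "reference/ground location missing for some sensors")
            level0 = False
    if not rec.events:
        err("NO_EVENTS", "no stimulus events")
        level0 = False
    else:
        dur = rec.duration_ms if rec.signal is not None and rec.signal.ndim == 2 and rec.fs else None
        if dur is not None and any(not 0 <= ev.onset_ms < dur for ev in rec.events):
            err("EVENT_RANGE", "event onsets outside the recorded signal")
            level0 = False
        onsets = [ev.onset_ms for ev in rec.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            warn("EVENT_ORDER", "event onsets are not non-decreasing (sequence may be lost)")

    # --- level 1
    level1 = level0
    if rec.encoder is None:
        err("NO_ENCODER", "encoder absent: logical symbols cannot be mapped to characters")
        level1 = False
    if rec.alphabet is None:
        err("NO_ALPHABET", "semantic alphabet absent")
        level1 = False
    if not rec.char_markers:
        err("NO_CHAR_MARKERS", "no per-character stimulation-sequence markers")
        level1 = False
    else:
        ms = sorted(rec.char_markers, key=lambda m: m.begin_sample)
        if any(a.end_sample > b.begin_sample for a, b in zip(ms, ms[1:])):
            err("CHAR_MARKER_OVERLAP", "character markers overlap")
            level1 = False
        if any(m.intended_ss is None for m in rec.char_markers):
            # the intended symbol may still be inferable from labeled events
            natures_known = bool(rec.events) and all(
                ev.nature in ("target", "standard") and ev.ls is not None for ev in rec.events
            )
            if natures_known and rec.encoder is not None:
                warn("TEXT_INFERABLE", "intended symbols absent but deducible from labeled events")
            else:
                err("UNKNOWN_TEXT", "intended symbols absent and not inferable")
                level1 = False
    if rec.events and any(ev.ls is None for ev in rec.events):
        err("NO_STIMULUS_CODES", "events lack row/column stimulus codes")
        level1 = False
    if rec.paradigm is None:
        deducible = False
        if len(rec.events) >= 2 and all(ev.character_index is not None for ev in rec.events):
            try:
                infer_isi(rec.events)
                infer_iterations(rec.events)
                deducible = True
            except ValueError:
                deducible = False
        if deducible:
            warn("PARADIGM_DEDUCED", "ISI/iterations not stored; deduced from events")
        else:
            err("NO_PARADIGM", "ISI/iteration counts neither stored nor deducible")
            level1 = False

    return ValidationReport(level0_ok=level0, level1_ok=level1 and level0, findings=findings)


# ---------------------------------------------------------------------------
# dialect import


def _default_sensors(n: int) -> list[SensorInfo]:
    return [
        SensorInfo(label=f"ch{i + 1:02d}", ordinal=i, reference_label="unknown", ground_label="unknown")
        for i in range(n)
    ]


def import_segmented_dialect(
    epochs: np.ndarray,
    labels: Sequence[str] | Sequence[int],
    fs: float,
    epoch_len_ms: float,
    isi_ms: float | None = None,
    onsets_ms: Sequence[float] | None = None,
    sensors: list[SensorInfo] | None = None,
) -> tuple[Recording, ValidationReport]:
    """Rebuild a recording from an epoch-segmented dataset.

    ``epochs`` is trials x channels x samples; ``labels`` flags each trial
    target (``"target"``/1) or standard (``"standard"``/0 or -1). When
    ``onsets_ms`` is given, the continuous signal is reconstructed by
    de-overlapping the epochs (overlapping samples must agree to
    ``DEOVERLAP_TOL``); samples no epoch covers are set to NaN. Without
    onsets the original flash order is unrecoverable: the trials are laid
    out back-to-back and the report carries a ``SEQUENCE_LOST`` finding.
    """
    epochs = np.asarray(epochs, dtype=np.float32)
    if epochs.ndim != 3:
        raise ValueError("epochs must be trials x channels x samples")
    n_trials, n_channels, n_samp = epochs.shape
    if len(labels) != n_trials:
        raise ValueError("labels length must match trial count")
    natures = ["target" if lab in ("target", 1, "1", True) else "standard" for lab in labels]

    extra: list[tuple[str, str, str]] = []
    if onsets_ms is not None:
        if len(onsets_ms) != n_trials:
            raise ValueError("onsets length must match trial count")
        onset_samples = [int(round(t * fs / 1000.0)) for t in onsets_ms]
        total = max(onset_samples) + n_samp
        signal = np.full((n_channels, total), MISSING_VALUE, dtype=np.float32)
        covered = np.zeros(total, dtype=bool)
        order = np.argsort(onset_samples)
        for k in order:
            lo, hi = onset_samples[k], onset_samples[k] + n_samp
            seen = covered[lo:hi]
            if seen.any():
                old = signal[:, lo:hi][:, seen]
                new = epochs[k][:, seen]
                if np.nanmax(np.abs(old - new), initial=0.0) > DEOVERLAP_TOL:
                    raise IrrecoverableSegmentationError(
                        f"overlapping samples of trial {k} disagree beyond {DEOVERLAP_TOL} uV"
                    )
            signal[:, lo:hi] = epochs[k]
            covered[lo:hi] = True
        events = [
            StimulusEvent(onset_samples[k] * 1000.0 / fs, None, natures[k], None)
            for k in range(n_trials)
        ]
        prov = "imported from segmented dialect with onsets; continuous signal de-overlapped"
    else:
        signal = epochs.transpose(1, 0, 2).reshape(n_channels, n_trials * n_samp)
        events = [
            StimulusEvent(k * n_samp * 1000.0 / fs, None, natures[k], None) for k in range(n_trials)
        ]
        prov = "imported from label-sorted segmented dialect; original stimulus order lost"
        extra.append(
            (
                "warning",
                "SEQUENCE_LOST",
                "trials were re-sorted by label and onsets discarded: event order is not the recording order",
            )
        )

    rec = Recording(
        signal=signal,
        fs=fs,
        sensors=sensors if sensors is not None else _default_sensors(n_channels),
        events=events,
        paradigm=None,
        provenance=prov,
        extensions={"import": {"epoch_len_ms": epoch_len_ms, "isi_ms": isi_ms}},
    )
    report = validate(rec)
    report.findings.extend(extra)
    norm = flag_normalization(epochs)
    if norm is not None:
        report.findings.append(norm)
    return rec, report


def flag_normalization(epochs_or_rec) -> tuple[str, str, str] | None:
    """Detect trial-by-trial amplitude normalization.

    When every trial has the same amplitude statistic (standard deviation
    or peak-to-peak range, constant across trials to a relative 1e-6), the
    single evoked responses no longer enter an average with their recorded
    weights, so averaging statistics are distorted. Returns a warning
    finding, or None for plausibly raw data.
    """
    epochs = getattr(epochs_or_rec, "epochs", epochs_or_rec)
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3 or epochs.shape[0] < 2:
        return None
    flat = epochs.reshape(epochs.shape[0], -1)
    for name, stat in (("std", flat.std(axis=1)), ("range", np.ptp(flat, axis=1))):
        scale = max(1.0, float(np.abs(stat).max()))
        if float(stat.max() - stat.min()) <= 1e-6 * scale:
            return (
                "warning",
                "NORMALIZED_TRIALS",
                f"per-trial {name} is constant across trials: amplitudes were "
                "normalized trial-by-trial, so averages no longer weight each "
                "evoked response equally",
            )
    return None


def write_events_tsv(rec: Recording, path: str | Path) -> Path:
    """Export the event table as tab-separated text for interoperability."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("onset_ms\tls_code\tnature\tcharacter_index\n")
        for ev in rec.events:
            code = "" if ev.ls is None else str(ev.ls.code)
            ci = "" if ev.character_index is None else str(ev.character_index)
            fh.write(f"{ev.onset_ms:.6g}\t{code}\t{ev.nature}\t{ci}\n")
    return path
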