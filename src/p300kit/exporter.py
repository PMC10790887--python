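"""ERP feature export: stimulus-locked epochs to ML-ready design matrices.

Turns a level-1 recording into the classic speller training table: an ``X``
feature matrix (one row per flash, or per row/column after within-character
averaging) with four aligned vectors -- ``Y`` (+1 target / -1 standard),
``I`` (iteration index), ``C`` (stimulus code 1-12) and ``msg`` (the
intended character). Features are the selected sensors' epoch samples
concatenated sensor-major, with optional decimation by block-averaging or
sample skipping. Tables serialize to tab-separated ASCII or Weka ARFF and
parse back losslessly at the declared float precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .container import Recording
from .paradigm import Encoder, infer_spelled_text

__all__ = [
    "EpochSet",
    "DesignMatrix",
    "segment_epochs",
    "decimate",
    "build_design",
    "write_ascii",
    "read_ascii",
    "write_arff",
    "read_arff",
    "predict_characters",
    "design_matrices_equal",
]

DEFAULT_WINDOW_MS = (0.0, 800.0)
FLOAT_FMT = "%.6g"


@dataclass
class EpochSet:
    """Stimulus-locked epochs with per-trial metadata.

    ``epochs`` is trials x channels x samples (microvolts); ``trial_meta``
    has one row per trial with columns nature, ls_code, iteration_index,
    character_index, intended_ss.
    """

    epochs: np.ndarray
    sensors: list[str]
    fs: float
    window_ms: tuple[float, float]
    sample_times_ms: np.ndarray  # per-sample time relative to flash onset
    trial_meta: pd.DataFrame
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


@dataclass
class DesignMatrix:
    """The exporter output: X with aligned Y, I, C, msg vectors."""

    X: np.ndarray  # rows x features
    Y: np.ndarray  # +1 / -1
    I: np.ndarray  # iteration index (0 in averaged mode)
    C: np.ndarray  # stimulus code 1-12
    msg: np.ndarray  # intended semantic symbol per row
    mode: Literal["single", "averaged"] = "single"
    # feature-layout metadata (sensor-major blocks of len(sample_times_ms))
    sensors: list[str] = field(default_factory=list)
    sample_times_ms: np.ndarray | None = None
    character_index: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def feature_names(self) -> list[str]:
        if self.sensors and self.sample_times_ms is not None:
            n = len(self.sample_times_ms)
            return [f"{s}.{i}" for s in self.sensors for i in range(n)]
        return [f"f{i}" for i in range(self.X.shape[1])]


def _intended_symbols(rec: Recording) -> dict[int, str]:
    """Intended SS per character: stored markers first, then inference from labels."""
    out = {m.character_index: m.intended_ss for m in rec.char_markers if m.intended_ss is not None}
    missing = {
        ev.character_index
        for ev in rec.events
        if ev.character_index is not None and ev.character_index not in out
    }
    if missing and rec.encoder is not None:
        for ci in missing:
            evs = [ev for ev in rec.events if ev.character_index == ci]
            if all(ev.nature in ("target", "standard") and ev.ls is not None for ev in evs):
                try:
                    out[ci] = infer_spelled_text(evs, rec.encoder)
                except ValueError:
                    pass
    return out


def segment_epochs(
    rec: Recording,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    sensors: Sequence[str] | None = None,
) -> EpochSet:
    """Cut one epoch per flash, time-locked to the stimulus onset.

    The epoch spans ``[onset+start, onset+end)`` with
    ``floor((end-start) * fs / 1000)`` samples. Flashes whose window falls
    outside the recording are dropped and counted in ``n_dropped``.
    """
    start_ms, end_ms = window_ms
    if end_ms <= start_ms:
        raise ValueError("window end must exceed start")
    labels = rec.sensor_labels()
    if sensors is None:
        sensors = labels
    sel = []
    for s in sensors:
        if s not in labels:
            raise KeyError(f"unknown sensor label {s!r}")
        sel.append(labels.index(s))
    if not sel:
        raise ValueError("empty sensor selection")

    n_samp = int(np.floor((end_ms - start_ms) * rec.fs / 1000.0))
    if n_samp < 1:
        raise ValueError("window shorter than one sample")
    offset = int(np.floor(start_ms * rec.fs / 1000.0))
    intended = _intended_symbols(rec)

    # iteration index: position of the flash within its character group
    counters: dict[int | None, int] = {}
    rows, slabs = [], []
    n_dropped = 0
    for ev in rec.events:
        k = counters.get(ev.character_index, 0)
        counters[ev.character_index] = k + 1
        onset = int(round(ev.onset_ms * rec.fs / 1000.0))
        lo = onset + offset
        hi = lo + n_samp
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        slabs.append(rec.signal[sel, lo:hi])
        rows.append(
            {
                "nature": ev.nature,
                "ls_code": ev.ls.code if ev.ls is not None else -1,
                "iteration_index": k // 12 + 1,
                "character_index": ev.character_index if ev.character_index is not None else -1,
                "intended_ss": intended.get(ev.character_index, "?"),
            }
        )
    epochs = (
        np.stack(slabs).astype(np.float64)
        if slabs
        else np.empty((0, len(sel), n_samp), dtype=np.float64)
    )
    times = start_ms + np.arange(n_samp) * 1000.0 / rec.fs
    meta = pd.DataFrame(rows, columns=["nature", "ls_code", "iteration_index", "character_index", "intended_ss"])
    return EpochSet(
        epochs=epochs,
        sensors=list(sensors),
        fs=rec.fs,
        window_ms=(start_ms, end_ms),
        sample_times_ms=times,
        trial_meta=meta,
        n_dropped=n_dropped,
    )


def decimate(es: EpochSet, mode: Literal["none", "average_k", "skip_k"], k: int = 1) -> EpochSet:
    """Reduce the per-epoch sample count.

    ``average_k`` replaces each run of k consecutive samples by its mean
    (a trailing partial run is averaged as-is); ``skip_k`` keeps every k-th
    sample starting at index 0. Sample times follow the same rule so that
    latency-based consumers stay consistent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode == "none":
        return replace(es)
    if k > es.n_samples:
        raise ValueError(f"k={k} exceeds epoch length {es.n_samples}")
    if mode == "average_k":
        n = es.n_samples
        edges = list(range(0, n, k)) + [n]
        blocks = [es.epochs[:, :, lo:hi].mean(axis=2) for lo, hi in zip(edges, edges[1:])]
        epochs = np.stack(blocks, axis=2)
        times = np.array(
            [es.sample_times_ms[lo:hi].mean() for lo, hi in zip(edges, edges[1:])]
        )
    elif mode == "skip_k":
        epochs = es.epochs[:, :, ::k]
        times = es.sample_times_ms[::k]
    else:
        raise ValueError(f"unknown decimation mode {mode!r}")
    return replace(es, epochs=epochs, sample_times_ms=times)


def build_design(es: EpochSet, mode: Literal["single", "averaged"] = "single") -> DesignMatrix:
    """Assemble the design matrix from an epoch set.

    ``single``: one row per flash. ``averaged``: per character one row per
    stimulus code (12 rows), the mean of that code's epochs over the
    character's iterations; the iteration vector is 0 by convention.
    """
    meta = es.trial_meta
    if (meta["nature"] == "unknown").any():
        raise ValueError("cannot label Y: some flashes have unknown nature")
    if mode == "single":
        X = es.epochs.reshape(es.n_trials, -1)
        Y = np.where(meta["nature"].to_numpy() == "target", 1, -1)
        return DesignMatrix(
            X=X,
            Y=Y,
            I=meta["iteration_index"].to_numpy().copy(),
            C=meta["ls_code"].to_numpy().copy(),
            msg=meta["intended_ss"].to_numpy(dtype=object),
            mode="single",
            sensors=list(es.sensors),
            sample_times_ms=es.sample_times_ms.copy(),
            character_index=meta["character_index"].to_numpy().copy(),
        )
    if mode != "averaged":
        raise ValueError(f"unknown mode {mode!r}")

    Xr, Yr, Cr, msgr, ci_r = [], [], [], [], []
    for ci in pd.unique(meta["character_index"]):
        sub = meta.index[meta["character_index"] == ci]
        counts = meta.loc[sub, "ls_code"].value_counts()
        if set(counts.index) != set(range(1, 13)) or counts.nunique() != 1:
            raise ValueError(
                f"character {ci}: incomplete iterations (each of the 12 codes "
                "must occur equally often) in averaged mode"
            )
        for code in range(1, 13):
            idx = sub[meta.loc[sub, "ls_code"] == code]
            Xr.append(es.epochs[idx].mean(axis=0).reshape(-1))
            Yr.append(1 if (meta.loc[idx, "nature"] == "target").all() else -1)
            Cr.append(code)
            msgr.append(meta.loc[idx, "intended_ss"].iloc[0])
            ci_r.append(ci)
    return DesignMatrix(
        X=np.stack(Xr),
        Y=np.array(Yr),
        I=np.zeros(len(Yr), dtype=int),
        C=np.array(Cr),
        msg=np.array(msgr, dtype=object),
        mode="averaged",
        sensors=list(es.sensors),
        sample_times_ms=es.sample_times_ms.copy(),
        character_index=np.array(ci_r),
    )


# ---------------------------------------------------------------------------
# text serialization


def write_ascii(dm: DesignMatrix, path: str | Path) -> Path:
    """Tab-separated table: one header line, then features + Y, I, C, msg."""
    path = Path(path)
    names = dm.feature_names() + ["Y", "I", "C", "msg"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names) + "\n")
        for r in range(dm.n_rows):
            feats = [FLOAT_FMT % v for v in dm.X[r]]
            fh.write("\t".join(feats + [str(dm.Y[r]), str(dm.I[r]), str(dm.C[r]), str(dm.msg[r])]) + "\n")
    return path


def read_ascii(path: str | Path) -> DesignMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"msg": str})
    feat_cols = [c for c in df.columns if c not in ("Y", "I", "C", "msg")]
    return DesignMatrix(
        X=df[feat_cols].to_numpy(dtype=float),
        Y=df["Y"].to_numpy(dtype=int),
        I=df["I"].to_numpy(dtype=int),
        C=df["C"].to_numpy(dtype=int),
        msg=df["msg"].to_numpy(dtype=object),
    )


def write_arff(dm: DesignMatrix, path: str | Path, relation_name: str = "p300_features") -> Path:
    """Weka ARFF: numeric features, nominal class {-1,1}, nominal/string meta.

    The class attribute always declares both labels so the schema is stable
    even when one class is absent from the data.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"% mode={dm.mode}\n")
        if dm.sample_times_ms is not None:
            fh.write(
                f"% sensors={','.join(dm.sensors)} "
                f"samples_per_sensor={len(dm.sample_times_ms)}\n"
            )
        fh.write(f"@relation {relation_name}\n\n")
        for name in dm.feature_names():
            fh.write(f"@attribute {name} numeric\n")
        fh.write("@attribute Y {-1,1}\n")
        fh.write("@attribute I string\n")
        fh.write("@attribute C {" + ",".join(str(c) for c in range(1, 13)) + "}\n")
        fh.write("@attribute msg string\n")
        fh.write("\n@data\n")
        for r in range(dm.n_rows):
            feats = [FLOAT_FMT % v for v in dm.X[r]]
            fh.write(",".join(feats + [str(dm.Y[r]), str(dm.I[r]), str(dm.C[r]), f"'{dm.msg[r]}'"]) + "\n")
    return path


_ATTR_RE = re.compile(r"@attribute\s+(\S+)\s+(.+)", re.IGNORECASE)


def read_arff(path: str | Path) -> DesignMatrix:
    names: list[str] = []
    data: list[list[str]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                data.append([tok.strip().strip("'") for tok in line.split(",")])
                continue
            low = line.lower()
            if low.startswith("@attribute"):
                m = _ATTR_RE.match(line)
                if m is None:
                    raise ValueError(f"malformed attribute line: {line}")
                names.append(m.group(1))
            elif low.startswith("@data"):
                in_data = True
    cols = {name: [row[j] for row in data] for j, name in enumerate(names)}
    feat_cols = [n for n in names if n not in ("Y", "I", "C", "msg")]
    X = np.array([[float(v) for v in cols[n]] for n in feat_cols]).T if data else np.empty((0, len(feat_cols)))
    return DesignMatrix(
        X=X,
        Y=np.array([int(v) for v in cols["Y"]]),
        I=np.array([int(v) for v in cols["I"]]),
        C=np.array([int(v) for v in cols["C"]]),
        msg=np.array(cols["msg"], dtype=object),
    )


def design_matrices_equal(a: DesignMatrix, b: DesignMatrix, rtol: float = 1e-5) -> bool:
    """Vectors exact; X to the declared text precision (6 significant digits)."""
    return (
        a.X.shape == b.X.shape
        and np.allclose(a.X, b.X, rtol=rtol, atol=1e-12)
        and np.array_equal(a.Y, b.Y)
        and np.array_equal(a.I, b.I)
        and np.array_equal(a.C, b.C)
        and list(a.msg) == list(b.msg)
    )


# ---------------------------------------------------------------------------
# demonstration decoder


def predict_characters(
    dm: DesignMatrix,
    encoder: Encoder,
    sensor: str = "Cz",
    window_ms: tuple[float, float] = (250.0, 600.0),
) -> str:
    """Decode the spelled text with a mean-amplitude score.

    Per character, each stimulus code is scored by the mean (over its
    flashes) of the mean epoch amplitude at ``sensor`` within
    ``window_ms``; the best row and best column (ties to the lower code)
    intersect at the decoded symbol. A deliberately simple decoder for
    end-to-end demonstrations, not a classifier.
    """
    if dm.mode != "single":
        raise ValueError("prediction needs a single-trial design matrix")
    if dm.character_index is None or dm.sample_times_ms is None or not dm.sensors:
        raise ValueError("design matrix lacks feature-layout metadata")
    if sensor not in dm.sensors:
        raise KeyError(f"sensor {sensor!r} not among exported sensors {dm.sensors}")
    n = len(dm.sample_times_ms)
    block = dm.sensors.index(sensor)
    in_win = (dm.sample_times_ms >= window_ms[0]) & (dm.sample_times_ms < window_ms[1])
    cols = block * n + np.flatnonzero(in_win)
    if cols.size == 0:
        raise ValueError("scoring window contains no samples")
    amp = dm.X[:, cols].mean(axis=1)

    out = []
    for ci in pd.unique(dm.character_index):
        mask = dm.character_index == ci
        scores = np.full(12, -np.inf)
        for code in range(1, 13):
            sel = mask & (dm.C == code)
            if sel.any():
                scores[code - 1] = amp[sel].mean()
        row = int(np.argmax(scores[:6])) + 1  # argmax takes the first maximum: lower code wins ties
        col = int(np.argmax(scores[6:])) + 1
        out.append(encoder.encode(row, col))
    return "".join(out)
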