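"""Grand averages, pointwise significance, component latencies, occurrences.

The target/standard contrast of the oddball paradigm is summarized by two
grand-average waveforms per channel. A pointwise Welch t-test with a
Bonferroni correction over the full channel x time family marks where the
classes differ; component latencies (N200 negative, P300 positive) are read
off the target-minus-standard difference wave at the conventional sensors
(PO7 and Cz respectively). Occurrence statistics count how often each
character -- and hence each row and column of the matrix -- is selected in
a set of spelled texts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .exporter import EpochSet
from .paradigm import Encoder

__all__ = [
    "ErpSummary",
    "ComponentLatency",
    "OccurrenceStats",
    "grand_average",
    "pointwise_test",
    "component_latency",
    "occurrence_stats",
    "export_summary_tsv",
    "export_stats_json",
]

#: default latency search windows (ms), wide enough for the usual range of
#: reported P300-speller component latencies
COMPONENT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "N200": (150.0, 300.0),
    "P300": (250.0, 550.0),
}
COMPONENT_POLARITY: dict[str, str] = {"N200": "negative", "P300": "positive"}


@dataclass
class ErpSummary:
    avg_target: np.ndarray  # channels x samples
    avg_standard: np.ndarray
    n_target: int
    n_standard: int
    sensors: list[str]
    sample_times_ms: np.ndarray
    sig_mask: np.ndarray | None = None  # channels x samples booleans
    alpha: float | None = None

    @property
    def difference(self) -> np.ndarray:
        return self.avg_target - self.avg_standard


@dataclass(frozen=True)
class ComponentLatency:
    component: Literal["N200", "P300"]
    sensor: str
    latency_ms: float
    search_window_ms: tuple[float, float]
    polarity: Literal["negative", "positive"]
    amplitude_uv: float


@dataclass
class OccurrenceStats:
    per_ss_counts: dict[str, int]
    row_shares: np.ndarray  # 6 proportions
    col_shares: np.ndarray
    total: int


def _split_classes(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    nat = es.trial_meta["nature"].to_numpy()
    tgt = es.epochs[nat == "target"]
    std = es.epochs[nat == "standard"]
    if len(tgt) == 0 or len(std) == 0:
        raise ValueError("need at least one epoch of each class")
    return tgt, std


def grand_average(es: EpochSet) -> ErpSummary:
    """Pointwise class means per channel, with the trial counts."""
    tgt, std = _split_classes(es)
    return ErpSummary(
        avg_target=tgt.mean(axis=0),
        avg_standard=std.mean(axis=0),
        n_target=len(tgt),
        n_standard=len(std),
        sensors=list(es.sensors),
        sample_times_ms=es.sample_times_ms.copy(),
    )


def pointwise_test(es: EpochSet, alpha: float = 1e-4) -> np.ndarray:
    """Bonferroni-masked pointwise Welch t-test of target vs standard.

    Each (channel, sample) point gets an unequal-variance two-sample t-test;
    the mask is true where ``p * m < alpha`` with the family size
    ``m = channels x samples``. Points where both classes are constant are
    significant iff the constants differ.
    """
    tgt, std = _split_classes(es)
    if len(tgt) < 2 or len(std) < 2:
        raise ValueError("need at least 2 trials per class")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(tgt, std, axis=0, equal_var=False)
        p = np.asarray(res.pvalue)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(tgt.mean(axis=0), std.mean(axis=0))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    m = p.size
    return p * m < alpha


def component_latency(
    summary: ErpSummary,
    component: Literal["N200", "P300"],
    sensor: str | None = None,
    window_ms: tuple[float, float] | None = None,
) -> ComponentLatency:
    """Latency of an ERP component on the target-minus-standard wave.

    The N200 is the minimum (default window 150-300 ms, read at PO7), the
    P300 the maximum (250-550 ms, at Cz). Ties go to the earliest sample.
    """
    if component not in COMPONENT_WINDOWS_MS:
        raise ValueError(f"unknown component {component!r}")
    if sensor is None:
        sensor = "PO7" if component == "N200" else "Cz"
    if sensor not in summary.sensors:
        raise KeyError(f"sensor {sensor!r} not in summary sensors {summary.sensors}")
    lo, hi = window_ms if window_ms is not None else COMPONENT_WINDOWS_MS[component]
    t = summary.sample_times_ms
    idx = np.flatnonzero((t >= lo) & (t <= hi))
    if idx.size == 0:
        raise ValueError(f"window ({lo}, {hi}) ms outside the epoch ({t[0]}, {t[-1]})")
    wave = summary.difference[summary.sensors.index(sensor), idx]
    polarity = COMPONENT_POLARITY[component]
    k = int(np.argmin(wave)) if polarity == "negative" else int(np.argmax(wave))
    return ComponentLatency(
        component=component,
        sensor=sensor,
        latency_ms=float(t[idx[k]]),
        search_window_ms=(lo, hi),
        polarity=polarity,  # type: ignore[arg-type]
        amplitude_uv=float(wave[k]),
    )


def occurrence_stats(spelled_texts: Iterable[str], enc: Encoder) -> OccurrenceStats:
    """Per-symbol selection counts and per-row/column selection shares."""
    counts: dict[str, int] = {ss: 0 for ss in "".join(enc.layout)}
    row_counts = np.zeros(6)
    col_counts = np.zeros(6)
    total = 0
    for text in spelled_texts:
        for ss in text:
            if ss not in counts:
                raise KeyError(f"character {ss!r} not in the encoder alphabet")
            counts[ss] += 1
            r, c = enc.decode(ss)
            row_counts[r - 1] += 1
            col_counts[c - 1] += 1
            total += 1
    if total == 0:
        raise ValueError("no characters to count")
    return OccurrenceStats(
        per_ss_counts=counts,
        row_shares=row_counts / total,
        col_shares=col_counts / total,
        total=total,
    )


# ---------------------------------------------------------------------------
# text export


def export_summary_tsv(summary: ErpSummary, path: str | Path) -> Path:
    """Waveform table: time, per-sensor target/standard means, mask."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["time_ms"]
        for s in summary.sensors:
            cols += [f"{s}_target", f"{s}_standard"]
            if summary.sig_mask is not None:
                cols.append(f"{s}_sig")
        fh.write("\t".join(cols) + "\n")
        for j, t in enumerate(summary.sample_times_ms):
            row = [f"{t:.6g}"]
            for i in range(len(summary.sensors)):
                row += [f"{summary.avg_target[i, j]:.6g}", f"{summary.avg_standard[i, j]:.6g}"]
                if summary.sig_mask is not None:
                    row.append("1" if summary.sig_mask[i, j] else "0")
            fh.write("\t".join(row) + "\n")
    return path


def export_stats_json(
    path: str | Path,
    summary: ErpSummary | None = None,
    latencies: Iterable[ComponentLatency] = (),
    occurrences: OccurrenceStats | None = None,
) -> Path:
    path = Path(path)
    doc: dict = {}
    if summary is not None:
        doc["grand_average"] = {
            "n_target": summary.n_target,
            "n_standard": summary.n_standard,
            "sensors": summary.sensors,
            "alpha": summary.alpha,
            "n_significant_points": None
            if summary.sig_mask is None
            else int(summary.sig_mask.sum()),
        }
    if latencies:
        doc["latencies"] = [
            {
                "component": L.component,
                "sensor": L.sensor,
                "latency_ms": L.latency_ms,
                "amplitude_uv": L.amplitude_uv,
                "window_ms": list(L.search_window_ms),
            }
            for L in latencies
        ]
    if occurrences is not None:
        doc["occurrences"] = {
            "total": occurrences.total,
            "per_symbol": occurrences.per_ss_counts,
            "row_shares": occurrences.row_shares.tolist(),
            "col_shares": occurrences.col_shares.tolist(),
        }
    path.write_text(json.dumps(doc, indent=2))
    return path
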