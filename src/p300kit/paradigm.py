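"""Core semantics of the 6x6 P300 speller.

The speller presents a 6x6 matrix of 36 *semantic symbols* (SS): letters,
digits and one filler. Stimulation flashes one of 12 *logical symbols*
(LS) at a time -- one of the 6 rows or 6 columns. The *encoder* is the
bijection between an SS and its (row, column) cell: classifying which row
and which column elicited the attended response identifies the character.

This module holds the alphabets, the encoder, stimulus labeling
(target/standard), inversion of labeled stimulus streams back into spelled
text, and the arithmetic of a speller session (flash counts, inter-stimulus
interval and iteration-count inference, epoch-overlap bookkeeping).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "SemanticAlphabet",
    "LogicalSymbol",
    "Encoder",
    "StimulusEvent",
    "ParadigmParams",
    "InconsistentLabelingError",
    "MalformedSequenceError",
    "build_default_encoder",
    "classify_stimulus",
    "infer_spelled_text",
    "infer_isi",
    "infer_iterations",
    "session_counts",
    "target_standard_split",
    "epoch_overlap",
]

N_ROWS = 6
N_COLS = 6
N_FLASHES_PER_ITERATION = N_ROWS + N_COLS  # 12

#: Canonical Farwell-Donchin row-major layout: "P" sits at row 3 / column 4,
#: column 3 holds the vowels I, O, U, digits occupy rows 5-6, and "_" fills
#: the 36th cell.
DEFAULT_LAYOUT = (
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
)


class InconsistentLabelingError(ValueError):
    """Target flashes of a character group do not name exactly one row and one column."""


class MalformedSequenceError(ValueError):
    """A character group's flash count is not a multiple of 12."""


@dataclass(frozen=True)
class SemanticAlphabet:
    """The 36 selectable characters of the matrix."""

    symbols: tuple[str, ...] = tuple("".join(DEFAULT_LAYOUT))

    def __post_init__(self) -> None:
        if len(self.symbols) != 36:
            raise ValueError(f"semantic alphabet needs exactly 36 symbols, got {len(self.symbols)}")
        if len(set(self.symbols)) != 36:
            raise ValueError("semantic alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("semantic symbols are single characters")

    def __contains__(self, ss: str) -> bool:
        return ss in self.symbols


@dataclass(frozen=True, order=True)
class LogicalSymbol:
    """One of the 12 classifier-level stimulus labels: a row or a column.

    Codes follow the convention rows 1-6, columns 7-12.
    """

    kind: Literal["row", "col"]
    index: int  # 1-6

    def __post_init__(self) -> None:
        if self.kind not in ("row", "col"):
            raise ValueError(f"kind must be 'row' or 'col', got {self.kind!r}")
        if not 1 <= self.index <= 6:
            raise ValueError(f"index must be 1-6, got {self.index}")

    @property
    def code(self) -> int:
        return self.index if self.kind == "row" else 6 + self.index

    @classmethod
    def from_code(cls, code: int) -> "LogicalSymbol":
        if not 1 <= code <= 12:
            raise ValueError(f"LS code must be 1-12, got {code}")
        return cls("row", code) if code <= 6 else cls("col", code - 6)


def all_logical_symbols() -> tuple[LogicalSymbol, ...]:
    """The 12 logical symbols in code order (rows 1-6, then columns 7-12)."""
    return tuple(LogicalSymbol.from_code(c) for c in range(1, 13))


@dataclass(frozen=True)
class Encoder:
    """Bijection between semantic symbols and (row, column) cells of the matrix.

    ``layout`` is the 6x6 grid, row-major.
    """

    layout: tuple[str, ...] = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        if len(self.layout) != 6 or any(len(r) != 6 for r in self.layout):
            raise ValueError("layout must be 6 rows of 6 symbols")
        flat = "".join(self.layout)
        if len(set(flat)) != 36:
            raise ValueError("layout symbols must be 36 unique characters")

    @property
    def alphabet(self) -> SemanticAlphabet:
        return SemanticAlphabet(tuple("".join(self.layout)))

    def encode(self, row: int, col: int) -> str:
        """The SS at 1-based (row, col)."""
        if not (1 <= row <= 6 and 1 <= col <= 6):
            raise ValueError(f"row/col must be 1-6, got ({row}, {col})")
        return self.layout[row - 1][col - 1]

    def decode(self, ss: str) -> tuple[int, int]:
        """1-based (row, col) of a semantic symbol."""
        for r, row in enumerate(self.layout, start=1):
            c = row.find(ss)
            if c >= 0:
                return r, c + 1
        raise KeyError(f"symbol {ss!r} not in the encoder layout")


@dataclass(frozen=True)
class StimulusEvent:
    """One flash: onset, the flashed row/column, and its (possibly unknown) nature."""

    onset_ms: float
    ls: LogicalSymbol | None
    nature: Literal["target", "standard", "unknown"] = "unknown"
    character_index: int | None = None

    @property
    def ls_code(self) -> int | None:
        return None if self.ls is None else self.ls.code


@dataclass(frozen=True)
class ParadigmParams:
    """Stimulation parameters: ISI and the iteration-count range."""

    isi_ms: float
    iterations_min: int
    iterations_max: int
    flash_duration_ms: float | None = None
    n_flashes_per_iteration: int = N_FLASHES_PER_ITERATION

    def __post_init__(self) -> None:
        if self.isi_ms <= 0:
            raise ValueError("isi_ms must be positive")
        if not 1 <= self.iterations_min <= self.iterations_max:
            raise ValueError("need 1 <= iterations_min <= iterations_max")


def build_default_encoder() -> Encoder:
    """The canonical alphanumeric 6x6 layout (A-Z, 1-9, filler '_')."""
    return Encoder(DEFAULT_LAYOUT)


def classify_stimulus(ls: LogicalSymbol, target_ss: str, enc: Encoder) -> str:
    """Label one flash as 'target' or 'standard' for an attended symbol.

    A flash is a target iff it names the row or the column containing
    ``target_ss``; for any symbol exactly 2 of the 12 LS are targets.
    """
    row, col = enc.decode(target_ss)
    if ls.kind == "row":
        return "target" if ls.index == row else "standard"
    return "target" if ls.index == col else "standard"


def infer_spelled_text(events: Iterable[StimulusEvent], enc: Encoder) -> str:
    """Recover the spelled text from target/standard-labeled flashes.

    Each character group's target flashes must name exactly one row and one
    column; the spelled symbol sits at their intersection.
    """
    groups: dict[int, list[StimulusEvent]] = {}
    for ev in events:
        if ev.character_index is None:
            raise ValueError("events must carry character_index")
        groups.setdefault(ev.character_index, []).append(ev)

    out = []
    for ci in sorted(groups):
        rows = {ev.ls.index for ev in groups[ci] if ev.nature == "target" and ev.ls.kind == "row"}
        cols = {ev.ls.index for ev in groups[ci] if ev.nature == "target" and ev.ls.kind == "col"}
        if len(rows) != 1 or len(cols) != 1:
            raise InconsistentLabelingError(
                f"character {ci}: target flashes name {len(rows)} rows and "
                f"{len(cols)} columns (need exactly 1 of each)"
            )
        out.append(enc.encode(rows.pop(), cols.pop()))
    return "".join(out)


def infer_isi(events: Sequence[StimulusEvent]) -> float:
    """Deduce the inter-stimulus interval from event onsets.

    Takes the mode of onset differences rounded to the millisecond, then
    discards differences more than 3x that mode (inter-character pauses)
    and returns the mode of what remains. Ties go to the smaller value.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events to infer the ISI")
    onsets = [ev.onset_ms for ev in events]
    diffs = [round(b - a) for a, b in zip(onsets, onsets[1:])]
    mode = _smallest_mode(diffs)
    kept = [d for d in diffs if d <= 3 * mode]
    return float(_smallest_mode(kept))


def _smallest_mode(values: Sequence[int]) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, n in counts.items() if n == best)


def infer_iterations(events: Iterable[StimulusEvent]) -> tuple[int, int]:
    """Per-character iteration counts (flashes / 12), as (min, max)."""
    per_char: Counter[int] = Counter()
    for ev in events:
        if ev.character_index is None:
            raise ValueError("events must carry character_index")
        per_char[ev.character_index] += 1
    if not per_char:
        raise ValueError("no events")
    for ci, n in per_char.items():
        if n % N_FLASHES_PER_ITERATION != 0:
            raise MalformedSequenceError(
                f"character {ci} has {n} flashes, not a multiple of {N_FLASHES_PER_ITERATION}"
            )
    its = [n // N_FLASHES_PER_ITERATION for n in per_char.values()]
    return min(its), max(its)


def session_counts(n_chars: int, iterations: int) -> dict[str, int]:
    """Flash/target/standard totals of a copy-spelling session.

    Every iteration delivers 12 flashes of which 2 are targets, so
    flashes = chars x iterations x 12, targets = flashes/6,
    standards = 5 x flashes / 6.
    """
    if n_chars < 0:
        raise ValueError("n_chars must be >= 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    flashes = n_chars * iterations * N_FLASHES_PER_ITERATION
    return {"flashes": flashes, "targets": flashes // 6, "standards": 5 * flashes // 6}


def target_standard_split(flashes: int) -> dict[str, int]:
    """Split a flash total into targets and standards (2 of 12 per iteration
    flash the attended cell, so 1/6 of all flashes are targets)."""
    if flashes < 0 or flashes % 6 != 0:
        raise ValueError("flash total must be a non-negative multiple of 6")
    return {"flashes": flashes, "targets": flashes // 6, "standards": 5 * flashes // 6}


def epoch_overlap(epoch_len_ms: float, isi_ms: float) -> dict[str, float]:
    """Overlap between consecutive stimulus-locked epochs.

    With epochs longer than the ISI each epoch shares ``epoch_len - isi``
    milliseconds with its neighbours; the redundancy factor is how many
    times each sample is stored.
    """
    if epoch_len_ms <= 0 or isi_ms <= 0:
        raise ValueError("epoch_len_ms and isi_ms must be positive")
    return {
        "overlap_ms": max(0.0, epoch_len_ms - isi_ms),
        "redundancy_factor": epoch_len_ms / isi_ms,
    }
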