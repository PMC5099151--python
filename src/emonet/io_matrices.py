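"""Reading, writing and validating multi-rater emotion annotation matrices.

Raters annotate perceived emotional interactions between story characters on
square matrices, one matrix per emotion.  The character roster labels both the
rows and the columns; the row is the sender ("from"), the column the receiver
("to"), so the matrix is a directed adjacency structure.  Each annotation is a
Likert value in [1, 10], and repeated annotations of the same directed pair by
the same rater *accumulate* (sum), strengthening that link.  A cell value of 0
means the rater never perceived (or never annotated) an emotional interaction
for that pair.

Two interchangeable representations are supported:

* square CSV matrices (character names in the first row and first column,
  empty cell == 0), one file per rater per emotion;
* a tidy long-format event table with columns
  ``rater_id, emotion, source, target, value, order_index``.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIKERT_MIN",
    "LIKERT_MAX",
    "DEFAULT_EMOTIONS",
    "MatrixFormatError",
    "ValidationError",
    "CharacterRoster",
    "AnnotationEvent",
    "RaterMatrix",
    "RaterMatrixSet",
    "normalize_label",
    "read_matrix_csv",
    "write_matrix_csv",
    "accumulate_events",
    "to_long_format",
    "from_long_format",
    "read_long_csv",
    "write_long_csv",
]

LIKERT_MIN = 1.0
LIKERT_MAX = 10.0

#: The four basic emotions annotated in the original movie study.
DEFAULT_EMOTIONS = ("anger", "fear", "joy", "sadness")

LONG_COLUMNS = ["rater_id", "emotion", "source", "target", "value", "order_index"]


class MatrixFormatError(ValueError):
    """Raised when a matrix file violates the square from/to layout."""


class ValidationError(ValueError):
    """Raised when data violates a domain invariant (Likert bounds, roster)."""


def normalize_label(label: str) -> str:
    """Trim surrounding whitespace and collapse internal runs to one space.

    Case is preserved: "Vincent  Vega " -> "Vincent Vega", but "vincent vega"
    stays distinct from "Vincent Vega".
    """
    return re.sub(r"\s+", " ", str(label).strip())


@dataclass(frozen=True)
class CharacterRoster:
    """Ordered, unique character labels; the order fixes matrix row/column order."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        normed = tuple(normalize_label(n) for n in self.names)
        if any(not n for n in normed):
            raise ValidationError("roster contains an empty character label")
        if len(set(normed)) != len(normed):
            dupes = sorted({n for n in normed if normed.count(n) > 1})
            raise ValidationError(f"duplicate character label(s): {dupes}")
        object.__setattr__(self, "names", normed)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return normalize_label(str(name)) in self.names

    def index(self, name: str) -> int:
        name = normalize_label(name)
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown character: {name!r}") from None


@dataclass(frozen=True)
class AnnotationEvent:
    """One Likert annotation by one rater of one directed pair, for one emotion."""

    rater_id: str
    emotion: str
    source: str
    target: str
    value: float
    order_index: int = 0

    def __post_init__(self) -> None:
        if not (LIKERT_MIN <= self.value <= LIKERT_MAX):
            raise ValidationError(
                f"annotation value {self.value} outside Likert bounds "
                f"[{LIKERT_MIN:g}, {LIKERT_MAX:g}]"
            )
        if self.order_index < 0:
            raise ValidationError("order_index must be non-negative")


@dataclass
class RaterMatrix:
    """One rater's accumulated annotation matrix for one emotion.

    ``values[i, j]`` is the accumulated Likert total sent from character ``i``
    to character ``j`` (so values may exceed 10); 0 means never annotated.
    """

    rater_id: str
    emotion: str
    roster: CharacterRoster
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roster)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match roster size {n}"
            )
        if np.any(self.values < 0):
            raise ValidationError("negative cell value")
        if np.any(np.diag(self.values) > 0):
            warnings.warn(
                f"self-loop annotation(s) in matrix ({self.rater_id}, {self.emotion}); "
                "self-directed emotion is permitted and counts toward both degrees",
                stacklevel=2,
            )

    def cell(self, source: str, target: str) -> float:
        return float(self.values[self.roster.index(source), self.roster.index(target)])

    @property
    def cells(self) -> dict[tuple[str, str], float]:
        """Mapping (source, target) -> accumulated value, zeros included."""
        names = self.roster.names
        return {
            (s, t): float(self.values[i, j])
            for i, s in enumerate(names)
            for j, t in enumerate(names)
        }


@dataclass
class RaterMatrixSet:
    """All raters' matrices for all emotions, sharing one roster.

    Every (rater, emotion) combination is present exactly once; combinations
    with no annotations hold all-zero matrices.
    """

    roster: CharacterRoster
    emotions: tuple[str, ...]
    raters: tuple[str, ...]
    matrices: dict[tuple[str, str], RaterMatrix] = field(repr=False)

    def __post_init__(self) -> None:
        expected = {(r, e) for r in self.raters for e in self.emotions}
        got = set(self.matrices)
        if expected != got:
            raise ValidationError(
                "matrix set must contain every (rater, emotion) combination "
                f"exactly once; missing {sorted(expected - got)}, "
                f"unexpected {sorted(got - expected)}"
            )
        for m in self.matrices.values():
            if m.roster != self.roster:
                raise ValidationError("all matrices must share the identical roster")

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def matrix(self, rater_id: str, emotion: str) -> RaterMatrix:
        return self.matrices[(rater_id, emotion)]

    def cell_values(self, emotion: str, source: str, target: str) -> np.ndarray:
        """Vector of the M raters' final accumulated values for one cell."""
        i = self.roster.index(source)
        j = self.roster.index(target)
        return np.array(
            [self.matrices[(r, emotion)].values[i, j] for r in self.raters]
        )

    def stacked(self, emotion: str) -> np.ndarray:
        """(M, n, n) array of all raters' matrices for one emotion."""
        return np.stack([self.matrices[(r, emotion)].values for r in self.raters])


# ---------------------------------------------------------------------------
# Square-matrix CSV I/O


def _format_cell(x: float) -> str:
    """Canonical cell rendering: 0 -> empty, integral -> int, else repr."""
    if x == 0:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def read_matrix_csv(path: str | Path, rater_id: str, emotion: str) -> RaterMatrix:
    """Read one square from/to annotation matrix.

    The first row and the first column both carry the character names, in the
    same order; cell ``[i, j]`` is the accumulated value from character ``i``
    (row, sender) to character ``j`` (column, receiver).  Empty cells map to 0.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")

    header = [normalize_label(c) for c in rows[0][1:]]
    n = len(header)
    if n == 0:
        raise MatrixFormatError(f"{path}: no character columns")
    body = rows[1:]
    if len(body) != n:
        raise MatrixFormatError(
            f"{path}: non-square layout ({len(body)} rows vs {n} columns)"
        )
    row_labels = [normalize_label(r[0]) if r else "" for r in body]
    if row_labels != header:
        raise MatrixFormatError(
            f"{path}: row labels must equal column labels in the same order; "
            f"rows={row_labels}, columns={header}"
        )
    roster = CharacterRoster(tuple(header))  # raises on duplicates/empties

    values = np.zeros((n, n))
    for i, row in enumerate(body):
        cells = row[1:]
        if len(cells) != n:
            raise MatrixFormatError(
                f"{path}: row {row_labels[i]!r} has {len(cells)} cells, expected {n}"
            )
        for j, raw in enumerate(cells):
            raw = raw.strip()
            if raw == "":
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {raw!r} at "
                    f"({row_labels[i]!r}, {header[j]!r})"
                ) from None
    return RaterMatrix(rater_id=rater_id, emotion=emotion, roster=roster, values=values)


def write_matrix_csv(matrix: RaterMatrix, path: str | Path) -> None:
    """Write a matrix in the canonical dialect: comma-delimited, UTF-8,
    ``\\n`` line endings, zeros as empty cells, integral values without a
    decimal point.  Reading then writing is byte-stable under this dialect.
    """
    names = matrix.roster.names
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["", *names])
    for i, name in enumerate(names):
        writer.writerow([name, *(_format_cell(v) for v in matrix.values[i])])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-format events


def accumulate_events(
    events: Iterable[AnnotationEvent],
    roster: CharacterRoster,
    emotions: Sequence[str] | None = None,
    raters: Sequence[str] | None = None,
) -> RaterMatrixSet:
    """Collapse an annotation event stream into accumulated matrices.

    Each cell equals the SUM of all the rater's annotation values for that
    directed pair and emotion — the additive overwriting rule.  The sum is
    order-invariant, so ``order_index`` only documents the sequence.  Raters
    and emotions are inferred from the events unless given explicitly; every
    (rater, emotion) combination is materialised, all-zero if unannotated.
    """
    events = list(events)
    for ev in events:
        if ev.source not in roster:
            raise ValidationError(f"unknown source character: {ev.source!r}")
        if ev.target not in roster:
            raise ValidationError(f"unknown target character: {ev.target!r}")

    emo_list = [normalize_label(e) for e in emotions] if emotions is not None else []
    rater_list = [str(r) for r in raters] if raters is not None else []
    for ev in events:
        e = normalize_label(ev.emotion)
        if e not in emo_list:
            emo_list.append(e)
        if ev.rater_id not in rater_list:
            rater_list.append(ev.rater_id)
    if not emo_list:
        emo_list = list(DEFAULT_EMOTIONS)
    if not rater_list:
        rater_list = ["rater_1"]

    n = len(roster)
    sums: dict[tuple[str, str], np.ndarray] = {
        (r, e): np.zeros((n, n)) for r in rater_list for e in emo_list
    }
    for ev in sorted(events, key=lambda ev: ev.order_index):
        key = (ev.rater_id, normalize_label(ev.emotion))
        sums[key][roster.index(ev.source), roster.index(ev.target)] += ev.value

    matrices = {
        (r, e): RaterMatrix(rater_id=r, emotion=e, roster=roster, values=v)
        for (r, e), v in sums.items()
    }
    return RaterMatrixSet(
        roster=roster,
        emotions=tuple(emo_list),
        raters=tuple(rater_list),
        matrices=matrices,
    )


def to_long_format(matrix_set: RaterMatrixSet) -> pd.DataFrame:
    """Export the nonzero cells as a tidy table.

    Lossless for nonzero cells: re-accumulating the table (with the same
    roster, emotions and raters) reproduces the set cell for cell.
    """
    records = []
    order = 0
    names = matrix_set.roster.names
    for rater in matrix_set.raters:
        for emotion in matrix_set.emotions:
            values = matrix_set.matrices[(rater, emotion)].values
            for i, s in enumerate(names):
                for j, t in enumerate(names):
                    v = values[i, j]
                    if v > 0:
                        records.append((rater, emotion, s, t, float(v), order))
                        order += 1
    return pd.DataFrame(records, columns=LONG_COLUMNS)


def from_long_format(
    frame: pd.DataFrame,
    roster: CharacterRoster,
    emotions: Sequence[str] | None = None,
    raters: Sequence[str] | None = None,
) -> RaterMatrixSet:
    """Rebuild a matrix set from a tidy table of (already accumulated) cells.

    Unlike :func:`accumulate_events` this accepts values above the Likert cap,
    because exported cells are sums of annotations.  Duplicate rows for one
    cell still sum.
    """
    missing = [c for c in LONG_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise MatrixFormatError(f"long-format table missing column(s): {missing}")
    emo_list = [normalize_label(e) for e in emotions] if emotions is not None else []
    rater_list = [str(r) for r in raters] if raters is not None else []
    for row in frame.itertuples(index=False):
        e = normalize_label(str(row.emotion))
        r = str(row.rater_id)
        if e not in emo_list:
            emo_list.append(e)
        if r not in rater_list:
            rater_list.append(r)
    if not emo_list:
        emo_list = list(DEFAULT_EMOTIONS)
    if not rater_list:
        rater_list = ["rater_1"]

    n = len(roster)
    sums = {(r, e): np.zeros((n, n)) for r in rater_list for e in emo_list}
    for row in frame.itertuples(index=False):
        v = float(row.value)
        if v < 0:
            raise ValidationError(f"negative cell value {v}")
        key = (str(row.rater_id), normalize_label(str(row.emotion)))
        sums[key][roster.index(str(row.source)), roster.index(str(row.target))] += v
    matrices = {
        (r, e): RaterMatrix(rater_id=r, emotion=e, roster=roster, values=v)
        for (r, e), v in sums.items()
    }
    return RaterMatrixSet(
        roster=roster,
        emotions=tuple(emo_list),
        raters=tuple(rater_list),
        matrices=matrices,
    )


def write_long_csv(matrix_set: RaterMatrixSet, path: str | Path) -> None:
    to_long_format(matrix_set).to_csv(path, index=False)


def read_long_csv(
    path: str | Path,
    roster: CharacterRoster,
    emotions: Sequence[str] | None = None,
) -> RaterMatrixSet:
    frame = pd.read_csv(path)
    return from_long_format(frame, roster, emotions=emotions)
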