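"""Annual count series: data model, derived grey sequences, CSV I/O, fixtures.

The grey model works on a short, strictly positive annual series
``x0(k), k = 1..n``.  Two derived sequences drive the parameter
estimators:

* the *mean-generated* sequence ``xm(k) = (x0(k) + x0(k-1)) / 2`` for
  ``k = 2..n`` (consecutive-pair means, which stabilise the ratio
  structure), and
* its *accumulation* ``xa(k) = sum_{m=2..k} xm(m)`` (the accumulated
  generating operation, which exposes the exponential trend).

Indexing is 1-based throughout the public API: ``k = 1`` is the first
observation, and both derived sequences start at ``k = 2``, so their
array representations have length ``n - 1`` with position ``i``
holding index ``k = i + 2``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FixtureNotFoundError, SeriesValidationError

__all__ = [
    "TimeSeries",
    "DerivedSequences",
    "read_series",
    "write_series",
    "mean_generate",
    "accumulate",
    "derived_sequences",
    "load_fixture",
    "list_fixtures",
]

MIN_LENGTH = 4

#: Registered packaged datasets: name -> CSV resource filename.
_FIXTURES = {
    "china_coal_1990_2010": "china_coal_1990_2010.csv",
}


@dataclass(frozen=True)
class TimeSeries:
    """A labelled annual count series ``x0(k)``.

    Parameters
    ----------
    labels
        Consecutive integer period identifiers (years), strictly
        increasing by one.
    values
        Strictly positive counts, one per label.
    """

    labels: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.values):
            raise SeriesValidationError(
                f"{len(self.labels)} labels but {len(self.values)} values"
            )
        if len(self.values) < MIN_LENGTH:
            raise SeriesValidationError(
                f"series has {len(self.values)} observations; at least "
                f"{MIN_LENGTH} are required"
            )
        for i, (prev, cur) in enumerate(zip(self.labels, self.labels[1:]), start=2):
            if cur == prev:
                raise SeriesValidationError(f"duplicate label {cur}", row=i)
            if cur != prev + 1:
                raise SeriesValidationError(
                    f"label {cur} follows {prev}; labels must be consecutive",
                    row=i,
                )
        for i, v in enumerate(self.values, start=1):
            if not np.isfinite(v) or v <= 0:
                raise SeriesValidationError(
                    f"value {v!r} is not a positive finite number "
                    "(the model is multiplicative)",
                    row=i,
                )

    @property
    def n(self) -> int:
        return len(self.values)

    def value_at(self, label: int) -> float:
        """Value for a given period label (year)."""
        try:
            return self.values[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label} not in series") from None

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def label_for_index(self, k: int) -> int:
        """Period label for 1-based model index ``k`` (extrapolates k > n)."""
        return self.labels[0] + (k - 1)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "TimeSeries":
        labels, values = zip(*pairs)
        return cls(tuple(int(x) for x in labels), tuple(float(v) for v in values))


@dataclass(frozen=True)
class DerivedSequences:
    """Mean-generated and accumulated sequences for indices ``k = 2..n``."""

    mean_generated: np.ndarray
    accumulated: np.ndarray

    @property
    def n(self) -> int:
        """Length of the originating series."""
        return len(self.mean_generated) + 1


def mean_generate(series: TimeSeries) -> np.ndarray:
    """Consecutive-pair means ``xm(k) = (x0(k) + x0(k-1)) / 2, k = 2..n``."""
    x = series.array()
    return (x[1:] + x[:-1]) / 2.0


def accumulate(mean_generated: Sequence[float]) -> np.ndarray:
    """Running sums of the mean-generated sequence.

    ``xa(2) = xm(2)`` and ``xa(k) - xa(k-1) = xm(k)`` exactly.
    """
    xm = np.asarray(mean_generated, dtype=float)
    if xm.size == 0:
        raise SeriesValidationError("cannot accumulate an empty sequence")
    return np.cumsum(xm)


def derived_sequences(series: TimeSeries) -> DerivedSequences:
    xm = mean_generate(series)
    return DerivedSequences(mean_generated=xm, accumulated=accumulate(xm))


def _parse_rows(rows: list[list[str]], source: str) -> TimeSeries:
    if rows and rows[0] and not _is_number(rows[0][0]):
        rows = rows[1:]  # optional header
    pairs: list[tuple[int, float]] = []
    for i, row in enumerate(rows, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise SeriesValidationError(
                f"expected two columns (label, value), got {row!r}", row=i
            )
        label_s, value_s = row[0].strip(), row[1].strip()
        if not _is_number(label_s):
            raise SeriesValidationError(
                f"non-numeric label {label_s!r} in {source}", row=i
            )
        if not _is_number(value_s):
            raise SeriesValidationError(
                f"non-numeric value {value_s!r} in {source}", row=i
            )
        pairs.append((int(float(label_s)), float(value_s)))
    if not pairs:
        raise SeriesValidationError(f"no data rows in {source}")
    return TimeSeries.from_pairs(pairs)


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_series(path: str | Path, format: str = "csv") -> TimeSeries:
    """Read a two-column (label, value) series from a CSV file.

    The canonical dialect is comma-separated UTF-8 with an optional
    ``year,deaths`` header.  Validation failures raise
    :class:`SeriesValidationError` naming the offending data row.
    """
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; supported: 'csv'")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    return _parse_rows(rows, str(path))


def read_series_text(text: str, source: str = "<string>") -> TimeSeries:
    """Parse a series from CSV text (same dialect as :func:`read_series`)."""
    return _parse_rows(list(csv.reader(io.StringIO(text))), source)


def write_series(series: TimeSeries, path: str | Path,
                 header: tuple[str, str] = ("year", "deaths")) -> None:
    """Write a series in the canonical CSV dialect (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for label, value in zip(series.labels, series.values):
            w.writerow([label, _format_value(value)])


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)


def load_fixture(name: str) -> TimeSeries:
    """Load a packaged dataset by registered name.

    ``"china_coal_1990_2010"`` is the 21-year Chinese coal-mine accident
    death toll, 1990-2010, as published by the State Administration of
    Coal Mine Safety.
    """
    try:
        filename = _FIXTURES[name]
    except KeyError:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    text = resources.files("greymarkov.data").joinpath(filename).read_text("utf-8")
    return read_series_text(text, source=f"fixture:{name}")


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)
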