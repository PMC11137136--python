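"""Reading, back-transforming and filtering per-donor expression matrices.

The screen consumes normalised microarray intensities in *linear* scale. When
the upstream normalisation emits log2 values they must be back-transformed
with :func:`delog_transform` (an explicit switch — never guessed). Transcripts
are then filtered per donor:

1. detection-flag filter — drop a transcript only if it is called Absent at
   every time point (one Present or Marginal call anywhere keeps it);
2. intensity filter — drop a transcript whose mean intensity over the series
   is below ``mean_min`` (default 50) or whose peak intensity is below
   ``peak_min`` (default 100), in the arbitrary units of the normalisation;

and finally restricted to the transcript set common to all donors, in a
canonical (lexicographic) row order shared across donors so that downstream
pairing can index rows positionally.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "ExpressionDataset",
    "FilterReport",
    "ParseError",
    "ConfigurationError",
    "read_expression_table",
    "read_flags_table",
    "delog_transform",
    "flag_filter",
    "intensity_filter",
    "intersect_donors",
]

VALID_FLAGS = frozenset("PMA")


class ParseError(ValueError):
    """Malformed input table (names the offending line)."""


class ConfigurationError(ValueError):
    """Invalid or missing configuration for a preprocessing step."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling clock shared by all series, in minutes."""

    start_min: float = 0.0
    step_min: float = 20.0
    n_points: int = 19

    def __post_init__(self) -> None:
        if self.step_min <= 0:
            raise ValueError("step_min must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")

    @property
    def times(self) -> np.ndarray:
        return self.start_min + self.step_min * np.arange(self.n_points)

    def delay_min_to_steps(self, delay_min: float) -> int:
        """Convert a delay in minutes to integer sampling steps."""
        steps = delay_min / self.step_min
        rounded = round(steps)
        if abs(steps - rounded) > 1e-9:
            raise ValueError(
                f"delay {delay_min} min is not a multiple of the {self.step_min}-min step"
            )
        return int(rounded)


@dataclass
class ExpressionDataset:
    """Transcript-by-timepoint expression matrix for one donor.

    ``values`` is a DataFrame indexed by transcript id with one column per
    time point; ``gene_symbols`` (optional) maps transcript id to annotation
    symbol (Affymetrix convention: multiple genes joined by ``///``);
    ``flags`` (optional) holds detection calls in {P, M, A} aligned with
    ``values``.
    """

    donor_id: str
    values: pd.DataFrame
    grid: TimeGrid
    gene_symbols: pd.Series | None = None
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.grid.n_points:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but grid has "
                f"{self.grid.n_points} points"
            )
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dupes}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must have the same shape as values")
            if not self.flags.index.equals(self.values.index):
                raise ValueError("flags index must match values index")
        if self.gene_symbols is not None and not self.gene_symbols.index.equals(
            self.values.index
        ):
            raise ValueError("gene_symbols index must match values index")

    @property
    def transcript_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    def subset(self, ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to ``ids`` in the given order."""
        return ExpressionDataset(
            donor_id=self.donor_id,
            values=self.values.loc[list(ids)],
            grid=self.grid,
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[list(ids)],
            flags=None if self.flags is None else self.flags.loc[list(ids)],
        )

    def series(self, transcript_id: str) -> np.ndarray:
        return self.values.loc[transcript_id].to_numpy(dtype=float)


@dataclass
class FilterReport:
    """Bookkeeping of how many transcripts each filtering rule removed."""

    n_input: int
    n_after_flag: int | None = None
    n_after_intensity: int | None = None
    removed_ids_by_rule: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [self.n_input, self.n_after_flag, self.n_after_intensity]
        present = [c for c in counts if c is not None]
        if any(b > a for a, b in zip(present, present[1:])):
            raise ValueError("filter counts must be monotone non-increasing")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @staticmethod
    def merged(flag_report: "FilterReport", intensity_report: "FilterReport") -> "FilterReport":
        removed = dict(flag_report.removed_ids_by_rule)
        removed.update(intensity_report.removed_ids_by_rule)
        return FilterReport(
            n_input=flag_report.n_input,
            n_after_flag=flag_report.n_after_flag,
            n_after_intensity=intensity_report.n_after_intensity,
            removed_ids_by_rule=removed,
        )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a delimited table; returns (header, [(line_no, cells), ...])."""
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        rows = []
        for line_no, cells in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not cells or (len(cells) == 1 and not cells[0].strip()):
                continue
            rows.append((line_no, cells))
    return header, rows


def read_expression_table(
    path: str | Path,
    donor_id: str,
    grid: TimeGrid,
) -> ExpressionDataset:
    """Read a delimited expression matrix into an :class:`ExpressionDataset`.

    Layout: one header row of time labels; one row per transcript; first
    column the transcript id; optional second column the gene symbol(s).
    Whether a symbol column is present is inferred from the header width
    (``1 + n_points`` vs ``2 + n_points`` columns). Rows keep file order.
    """
    path = Path(path)
    header, rows = _read_rows(path)
    n = grid.n_points
    if len(header) == n + 1:
        has_symbol = False
    elif len(header) == n + 2:
        has_symbol = True
    else:
        raise ParseError(
            f"{path}: header has {len(header)} columns; expected {n + 1} "
            f"(id + times) or {n + 2} (id + symbol + times) for a {n}-point grid"
        )
    expected = len(header)
    ids: list[str] = []
    symbols: list[str] = []
    data = np.empty((len(rows), n), dtype=float)
    for i, (line_no, cells) in enumerate(rows):
        if len(cells) != expected:
            raise ParseError(
                f"{path}, line {line_no}: expected {expected} columns, found {len(cells)}"
            )
        ids.append(cells[0].strip())
        offset = 1
        if has_symbol:
            symbols.append(cells[1].strip())
            offset = 2
        for j, cell in enumerate(cells[offset:]):
            try:
                data[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {line_no}: non-numeric cell {cell!r}"
                ) from exc
    index = pd.Index(ids, name="transcript_id")
    if not index.is_unique:
        dupes = sorted(set(index[index.duplicated()]))
        raise ParseError(f"{path}: duplicate transcript ids: {dupes}")
    time_labels = header[-n:]
    values = pd.DataFrame(data, index=index, columns=time_labels)
    gene_symbols = pd.Series(symbols, index=index, name="gene_symbol") if has_symbol else None
    return ExpressionDataset(
        donor_id=donor_id, values=values, grid=grid, gene_symbols=gene_symbols
    )


def read_flags_table(path: str | Path, ds: ExpressionDataset) -> ExpressionDataset:
    """Attach a companion detection-call matrix (cells in {P, M, A}) to ``ds``.

    The flags file must mirror the expression file's layout and transcript
    order; calls are accepted case-insensitively, anything else is a parse
    error.
    """
    path = Path(path)
    header, rows = _read_rows(path)
    n = ds.grid.n_points
    has_symbol = len(header) == n + 2
    expected = len(header)
    ids: list[str] = []
    calls: list[list[str]] = []
    for line_no, cells in rows:
        if len(cells) != expected:
            raise ParseError(
                f"{path}, line {line_no}: expected {expected} columns, found {len(cells)}"
            )
        ids.append(cells[0].strip())
        row_calls = []
        for cell in cells[(2 if has_symbol else 1):]:
            call = cell.strip().upper()
            if call not in VALID_FLAGS:
                raise ParseError(
                    f"{path}, line {line_no}: invalid detection call {cell!r} "
                    "(expected P, M or A)"
                )
            row_calls.append(call)
        calls.append(row_calls)
    if ids != ds.transcript_ids:
        raise ParseError(f"{path}: transcript ids do not match the expression table")
    flags = pd.DataFrame(calls, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(
        donor_id=ds.donor_id,
        values=ds.values,
        grid=ds.grid,
        gene_symbols=ds.gene_symbols,
        flags=flags,
    )


def delog_transform(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Back-transform log2-scale values to linear scale, elementwise 2**x."""
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("delog_transform requires finite input")
    out = np.exp2(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def flag_filter(ds: ExpressionDataset) -> tuple[ExpressionDataset, FilterReport]:
    """Remove transcripts called Absent at every time point.

    A transcript is kept iff at least one call anywhere in the series is
    Present or Marginal. Requires flags; when a dataset has none, this filter
    must be skipped explicitly by the caller, never silently.
    """
    if ds.flags is None:
        raise ConfigurationError(
            f"donor {ds.donor_id!r} has no detection flags; either provide a flags "
            "table or explicitly skip the flag filter (skip_flag_filter=True)"
        )
    keep = (ds.flags != "A").any(axis=1)
    removed = ds.values.index[~keep].tolist()
    kept = ds.subset(ds.values.index[keep])
    report = FilterReport(
        n_input=ds.n_transcripts,
        n_after_flag=kept.n_transcripts,
        removed_ids_by_rule={"flag_all_absent": removed},
    )
    return kept, report


def intensity_filter(
    ds: ExpressionDataset,
    mean_min: float = 50.0,
    peak_min: float = 100.0,
) -> tuple[ExpressionDataset, FilterReport]:
    """Remove weakly expressed transcripts on linear-scale intensities.

    Keeps a transcript iff its mean over all time points is at least
    ``mean_min`` and its maximum is at least ``peak_min``.
    """
    if mean_min < 0 or peak_min < 0:
        raise ConfigurationError("intensity thresholds must be non-negative")
    arr = ds.values.to_numpy()
    keep = (arr.mean(axis=1) >= mean_min) & (arr.max(axis=1) >= peak_min)
    removed = ds.values.index[~keep].tolist()
    kept = ds.subset(ds.values.index[keep])
    report = FilterReport(
        n_input=ds.n_transcripts,
        n_after_intensity=kept.n_transcripts,
        removed_ids_by_rule={"low_intensity": removed},
    )
    return kept, report


def intersect_donors(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every donor to the common transcript set, in a shared order.

    Row order after intersection is lexicographic by transcript id and
    identical across donors, which downstream pairing relies on.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two donor datasets to intersect")
    common: set[str] = set(datasets[0].transcript_ids)
    for ds in datasets[1:]:
        common &= set(ds.transcript_ids)
    if not common:
        raise ValueError("transcript-id intersection across donors is empty")
    order = sorted(common)
    return [ds.subset(order) for ds in datasets]
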