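"""Read station x taxa count tables and write per-station assessment reports.

The expected layout mirrors the calculation template: taxa in rows, sampling
stations in columns, integer read counts in the cells.  Tables arriving in
the transposed orientation are handled by an explicit ``transpose`` flag
rather than auto-detection, which misfires on square tables.

Counts must be integers: the downstream computations sum reads and count
occupied cells, so relative abundances would corrupt richness and H'.
"""

from __future__ import annotations

import io
import json
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .taxa import normalize_name

__all__ = [
    "AbundanceMatrix",
    "TableOptions",
    "AbundanceParseError",
    "read_abundance_table",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


class AbundanceParseError(ValueError):
    """A count table violated the format contract; message names the cell."""


@dataclass
class AbundanceMatrix:
    """Taxa x stations matrix of non-negative integer read counts.

    Row and column order is preserved from the input.  Taxon names are unique
    after normalization (readers merge duplicates by summation).
    """

    taxa_names: list[str]
    station_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_stations), integer dtype

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x stations array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.taxa_names), len(self.station_ids)):
            raise ValueError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.taxa_names)} taxa x {len(self.station_ids)} stations"
            )
        if len(self.station_ids) == 0:
            raise ValueError("at least one station column is required")
        keys = [normalize_name(t).casefold() for t in self.taxa_names]
        if len(set(keys)) != len(keys):
            raise ValueError("taxon names must be unique after normalization")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def station_index(self, station_id: str) -> int:
        try:
            return self.station_ids.index(station_id)
        except ValueError:
            raise KeyError(f"unknown station id {station_id!r}") from None

    def station_counts(self, station_id: str) -> np.ndarray:
        return self.counts[:, self.station_index(station_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.taxa_names, name="taxon"),
            columns=self.station_ids,
        )


@dataclass
class TableOptions:
    """Dialect controls for :func:`read_abundance_table`.

    ``delimiter``: tab or comma; sniffed from the first line when ``None``.
    ``transpose``: input arrives stations x taxa.  ``strict``: duplicate
    taxon rows abort instead of merging.
    """

    delimiter: Optional[str] = None
    transpose: bool = False
    strict: bool = False


_INT_RE = re.compile(r"^[+]?\d+$")


def _coerce_text(source: Union[str, Path, IO]) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    if isinstance(source, str):
        # a path never contains a newline; raw table content always does
        if "\n" in source:
            return source
        return Path(source).read_text(encoding="utf-8")
    data = source.read()
    return data.decode("utf-8") if isinstance(data, bytes) else data


def read_abundance_table(
    source: Union[str, Path, IO],
    options: TableOptions | None = None,
) -> AbundanceMatrix:
    """Parse a delimited count table into an :class:`AbundanceMatrix`.

    First column holds taxon names, the header row station identifiers.
    Cells must be non-negative integers (blank cells read as 0, matching
    spreadsheet conventions); fractional, negative or non-numeric values are
    rejected with the offending taxon/station named.  Duplicate taxon rows
    (same normalized name) are merged by summation with a warning, or
    rejected under ``strict``; duplicate station ids always abort.  All-zero
    rows are retained.
    """
    opts = options or TableOptions()
    text = _coerce_text(source)
    first_line = text.split("\n", 1)[0]
    delim = opts.delimiter or ("\t" if "\t" in first_line else ",")

    header = first_line.rstrip("\r").split(delim)
    ids = [h.strip() for h in header[1:]]
    dups = {s for s in ids if ids.count(s) > 1}
    if dups and not opts.transpose:
        raise AbundanceParseError(
            f"duplicate station id(s): {', '.join(sorted(dups))}"
        )

    df = pd.read_csv(io.StringIO(text), sep=delim, index_col=0, dtype=str,
                     keep_default_na=False, skip_blank_lines=True)
    if opts.transpose:
        df = df.T
        row_dups = {s for s in df.columns if list(df.columns).count(s) > 1}
        if row_dups:
            raise AbundanceParseError(
                f"duplicate station id(s): {', '.join(sorted(row_dups))}"
            )

    taxa = [str(t).strip() for t in df.index]
    stations = [str(c).strip() for c in df.columns]
    if not stations:
        raise AbundanceParseError("no station columns found")

    values = df.to_numpy(dtype=object)
    counts = np.zeros(values.shape, dtype=np.int64)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            cell = str(values[i, j]).strip()
            if cell == "":
                continue
            if _INT_RE.match(cell):
                counts[i, j] = int(cell)
                continue
            where = f"taxon {taxa[i]!r}, station {stations[j]!r}"
            try:
                x = float(cell)
            except ValueError:
                raise AbundanceParseError(
                    f"non-numeric value {cell!r} at {where}"
                ) from None
            if x < 0:
                raise AbundanceParseError(f"negative count {cell!r} at {where}")
            if not math.isclose(x, round(x), abs_tol=0.0):
                raise AbundanceParseError(
                    f"fractional read count {cell!r} at {where}; "
                    "the table must contain integer reads, not relative abundances"
                )
            raise AbundanceParseError(f"non-integer value {cell!r} at {where}")

    # merge duplicate taxon rows by normalized name, preserving first-seen order
    keys = [normalize_name(t).casefold() for t in taxa]
    if len(set(keys)) != len(keys):
        if opts.strict:
            seen: dict[str, str] = {}
            for t, k in zip(taxa, keys):
                if k in seen:
                    raise AbundanceParseError(
                        f"duplicate taxon rows {seen[k]!r} and {t!r} "
                        "(same normalized name) in strict mode"
                    )
                seen[k] = t
        order: list[str] = []
        names: dict[str, str] = {}
        sums: dict[str, np.ndarray] = {}
        merged: list[str] = []
        for t, k, row in zip(taxa, keys, counts):
            if k not in sums:
                order.append(k)
                names[k] = t
                sums[k] = row.copy()
            else:
                sums[k] += row
                merged.append(t)
        warnings.warn(
            f"merged {len(merged)} duplicate taxon row(s) by summation: "
            + ", ".join(repr(m) for m in merged[:5])
            + ("..." if len(merged) > 5 else ""),
            stacklevel=2,
        )
        taxa = [names[k] for k in order]
        counts = np.vstack([sums[k] for k in order])

    return AbundanceMatrix(taxa_names=taxa, station_ids=stations, counts=counts)


# -- assessment reports ----------------------------------------------------

#: Fixed column order of the per-station report.
REPORT_COLUMNS = [
    "station_id",
    "total_reads",
    "n_taxa",
    "shannon_h_bits",
    "reads_egi",
    "reads_egiii",
    "reads_not_assigned",
    "reads_not_in_list",
    "pct_egi",
    "pct_egiii",
    "pct_not_assigned",
    "pct_not_in_list",
    "f_egi",
    "f_egiii",
    "index_value",
    "index_display",
    "status",
    "flags",
]


def _assessment_row(a) -> dict:
    row = {c: getattr(a, c, None) for c in REPORT_COLUMNS
           if c not in ("index_display", "flags", "status")}
    row["status"] = a.status.value
    row["index_display"] = (
        None if a.index_value is None else round(a.index_value, 2)
    )
    row["flags"] = list(a.flags)
    return row


def write_report(
    assessments: Sequence,
    destination: Union[str, Path, IO],
    format: str = "tsv",
    config=None,
) -> None:
    """Write one record per station, in input order, as TSV or JSON.

    Numeric fields are emitted at full precision; ``index_display`` is the
    index rounded to two decimals for reading off.  When an
    :class:`~microgambi.index.IndexConfig` is given, its effective weights
    and class boundaries are embedded for provenance (as ``#`` comment lines
    in TSV, under a ``"config"`` key in JSON).
    """
    if len(assessments) == 0:
        raise ValueError("no assessments to write")
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")

    own = isinstance(destination, (str, Path))
    fh = open(destination, "w", encoding="utf-8") if own else destination
    try:
        rows = [_assessment_row(a) for a in assessments]
        cfg_dict = None if config is None else config.as_dict()
        if format == "json":
            payload = {"stations": rows}
            if cfg_dict is not None:
                payload = {"config": cfg_dict, **payload}
            json.dump(payload, fh, indent=2)
            fh.write("\n")
            return
        if cfg_dict is not None:
            for k, v in cfg_dict.items():
                fh.write(f"# {k} = {v}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            cells = []
            for c in REPORT_COLUMNS:
                v = row[c]
                if c == "flags":
                    cells.append(";".join(v))
                elif v is None:
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
    finally:
        if own:
            fh.close()


_INT_COLS = {"total_reads", "n_taxa", "reads_egi", "reads_egiii",
             "reads_not_assigned", "reads_not_in_list"}
_FLOAT_COLS = {"shannon_h_bits", "pct_egi", "pct_egiii", "pct_not_assigned",
               "pct_not_in_list", "f_egi", "f_egiii", "index_value",
               "index_display"}


def read_report(source: Union[str, Path, IO], format: str = "tsv") -> list[dict]:
    """Parse a report back into a list of per-station dicts (round-trip aid)."""
    text = _coerce_text(source)
    if format == "json":
        return json.load(io.StringIO(text))["stations"]
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        cells = line.split("\t")
        row: dict = {}
        for c, v in zip(header, cells):
            if c == "flags":
                row[c] = [f for f in v.split(";") if f]
            elif v == "":
                row[c] = None
            elif c in _INT_COLS:
                row[c] = int(v)
            elif c in _FLOAT_COLS:
                row[c] = float(v)
            else:
                row[c] = v
        out.append(row)
    return out
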