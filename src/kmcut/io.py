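"""Parsing, column-role recognition and validation of survival tables.

The input contract is a plain-text delimited table (tab, semicolon or
comma separated) with a header row: one sample per row, one column each
for sample id, survival time and survival event (0/1), up to three
categorical filter columns, and any number of continuous or binary
marker columns.  Limits enforced here: at most 100 columns, 8000 data
rows, 3 filters, 10 distinct values per filter; headers restricted to
English letters, digits, spaces, underscores, colons, round brackets
and exclamation marks.
"""

from __future__ import annotations

import io as _io
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataLossWarning,
    EmptyCohortError,
    RecognitionWarning,
    RoleRecognitionError,
    UnparseableTable,
    ValidationError,
)

MAX_COLUMNS = 100
MAX_ROWS = 8000
MAX_FILTERS = 3
MAX_FILTER_LEVELS = 10

HEADER_RE = re.compile(r"^[A-Za-z0-9 _:()!]+$")

_DIALECTS = {"tab": "\t", "semicolon": ";", "comma": ","}
_MISSING = {"", "na", "nan", "null", "none", "n/a"}


@dataclass
class RawTable:
    """A parsed but not yet validated table: text cells plus the dialect."""

    headers: list[str]
    rows: list[list[str]]
    dialect: str

    def __post_init__(self):
        if not self.headers:
            raise UnparseableTable("table has no header row")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.headers):
                raise UnparseableTable(
                    f"row {i} has {len(row)} cells, expected {len(self.headers)}")

    @property
    def n_columns(self) -> int:
        return len(self.headers)

    def column(self, idx: int) -> list[str]:
        return [row[idx] for row in self.rows]


@dataclass
class ColumnRoles:
    """Assignment of table columns to their analysis roles (0-based indices)."""

    sample_id: int
    time: int
    event: int
    filters: list[int] = field(default_factory=list)
    markers: list[int] = field(default_factory=list)

    def __post_init__(self):
        core = [self.sample_id, self.time, self.event]
        everything = core + list(self.filters) + list(self.markers)
        if len(set(everything)) != len(everything):
            raise ValueError("column roles must be disjoint")
        if len(self.filters) > MAX_FILTERS:
            raise ValueError(f"at most {MAX_FILTERS} filter columns allowed")


@dataclass
class SurvivalDataset:
    """A validated survival table ready for analysis.

    ``filters`` maps filter column name -> string-valued categorical array;
    ``markers`` maps marker name -> float array (NaN marks missing cells in
    columns that were demoted to unusable).
    """

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    filters: dict[str, np.ndarray]
    markers: dict[str, np.ndarray]
    id_name: str = "Sample ID"
    time_name: str = "Survival time"
    event_name: str = "Survival event"
    unusable_markers: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sample_ids)
        for arr in [self.time, self.event, *self.filters.values(),
                    *self.markers.values()]:
            if len(arr) != n:
                raise ValueError("all dataset columns must share one length")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def marker(self, name: str) -> np.ndarray:
        if name not in self.markers:
            raise KeyError(f"unknown marker {name!r}; available: "
                           f"{sorted(self.markers)}")
        return self.markers[name]

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        """Row subset preserving order; mask is boolean or index array."""
        return SurvivalDataset(
            sample_ids=self.sample_ids[mask],
            time=self.time[mask],
            event=self.event[mask],
            filters={k: v[mask] for k, v in self.filters.items()},
            markers={k: v[mask] for k, v in self.markers.items()},
            id_name=self.id_name, time_name=self.time_name,
            event_name=self.event_name,
            unusable_markers=list(self.unusable_markers),
        )

    def with_marker(self, name: str, values: np.ndarray) -> "SurvivalDataset":
        """Return a copy carrying an extra derived marker column."""
        values = np.asarray(values, dtype=float)
        if len(values) != self.n:
            raise ValueError("derived marker length mismatch")
        markers = dict(self.markers)
        markers[name] = values
        return SurvivalDataset(
            sample_ids=self.sample_ids, time=self.time, event=self.event,
            filters=self.filters, markers=markers, id_name=self.id_name,
            time_name=self.time_name, event_name=self.event_name,
            unusable_markers=list(self.unusable_markers),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.id_name: self.sample_ids,
                           self.time_name: self.time,
                           self.event_name: self.event})
        for name, col in self.filters.items():
            df[name] = col
        for name, col in self.markers.items():
            df[name] = col
        return df

    def to_tsv(self, path_or_buf=None):
        """Canonical tab-separated serialization (round-trips through parse)."""
        return self.to_frame().to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parsing

def detect_dialect(text: str) -> str:
    """Pick the delimiter (tab > semicolon > comma) giving a consistent
    column count of at least 3 over the first 10 non-empty lines."""
    if not text.strip():
        raise UnparseableTable("empty input")
    lines = [ln for ln in text.splitlines() if ln.strip()][:10]
    for name in ("tab", "semicolon", "comma"):
        sep = _DIALECTS[name]
        counts = {ln.count(sep) + 1 for ln in lines}
        if len(counts) == 1 and counts.pop() >= 3:
            return name
    raise UnparseableTable(
        "no delimiter (tab, semicolon, comma) yields a consistent column "
        "count of at least 3")


def parse_table(text: str, dialect: str | None = None) -> RawTable:
    """Split raw text into a RawTable, auto-detecting the dialect."""
    if dialect is None:
        dialect = detect_dialect(text)
    sep = _DIALECTS[dialect]
    lines = [ln for ln in text.splitlines() if ln.strip()]
    headers = [h.strip() for h in lines[0].split(sep)]
    rows = [[c.strip() for c in ln.split(sep)] for ln in lines[1:]]
    return RawTable(headers=headers, rows=rows, dialect=dialect)


def read_table(path) -> RawTable:
    with open(path, encoding="utf-8") as fh:
        return parse_table(fh.read())


# ---------------------------------------------------------------------------
# column typing helpers

def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in _MISSING


def _numeric_values(cells: list[str]) -> np.ndarray | None:
    """Parse non-missing cells as floats; None if any fails."""
    out = []
    for c in cells:
        if _is_missing(c):
            out.append(np.nan)
            continue
        try:
            out.append(float(c))
        except ValueError:
            return None
    return np.asarray(out, dtype=float)


def _column_profile(cells: list[str]) -> dict:
    vals = _numeric_values(cells)
    nonmissing = [c for c in cells if not _is_missing(c)]
    distinct = set(nonmissing)
    numeric = vals is not None and len(nonmissing) > 0
    finite = vals[np.isfinite(vals)] if numeric else np.empty(0)
    binary = numeric and len(finite) > 0 and set(np.unique(finite)) <= {0.0, 1.0}
    return {
        "numeric": numeric,
        "binary": bool(binary),
        "values": vals,
        "n_missing": len(cells) - len(nonmissing),
        "n_distinct": len(distinct),
        "complete": len(nonmissing) == len(cells),
    }


# ---------------------------------------------------------------------------
# recognition

def recognize_columns(table: RawTable) -> ColumnRoles:
    """Assign roles automatically from headers and column content.

    Rules, in order: the time column is the first fully numeric column whose
    header contains "time" (falling back to the first numeric non-binary
    column); the event column is the first 0/1 column whose header contains
    "event" or "status" (falling back to the first strictly binary column
    after the time column, with a warning); the sample id is the first
    non-numeric column (else column 0); columns whose header contains
    "filter", or text columns with 3-10 distinct values, become filters
    (first three); everything left is a marker.
    """
    profiles = [_column_profile(table.column(i)) for i in range(table.n_columns)]
    headers_lc = [h.strip().lower() for h in table.headers]
    assigned: set[int] = set()

    def header_match(pattern, idx):
        return re.search(pattern, headers_lc[idx]) is not None

    # time
    time_idx = None
    for i in range(table.n_columns):
        if profiles[i]["numeric"] and header_match(r"time", i):
            time_idx = i
            break
    if time_idx is None:
        for i in range(table.n_columns):
            if profiles[i]["numeric"] and not profiles[i]["binary"]:
                time_idx = i
                warnings.warn(
                    f"no header matched /time/; using first numeric non-binary "
                    f"column {table.headers[i]!r} as survival time",
                    RecognitionWarning, stacklevel=2)
                break
    if time_idx is None:
        raise RoleRecognitionError(
            "no candidate survival-time column (fully numeric, non-binary)",
            candidates=[h for h, p in zip(table.headers, profiles)
                        if p["numeric"]])
    assigned.add(time_idx)

    # event: a header match wins even if the values turn out non-binary —
    # validation then reports event_not_binary with coordinates
    event_idx = None
    for i in range(table.n_columns):
        if i in assigned:
            continue
        if header_match(r"event|status", i):
            event_idx = i
            break
    if event_idx is None:
        later = [i for i in range(table.n_columns)
                 if i not in assigned and profiles[i]["binary"] and i > time_idx]
        anywhere = [i for i in range(table.n_columns)
                    if i not in assigned and profiles[i]["binary"]]
        pool = later or anywhere
        if pool:
            event_idx = pool[0]
            warnings.warn(
                f"no header matched /event|status/; using first binary column "
                f"{table.headers[event_idx]!r} as survival event",
                RecognitionWarning, stacklevel=2)
    if event_idx is None:
        raise RoleRecognitionError(
            "no candidate survival-event column (values must be 0/1)",
            candidates=[h for h, p in zip(table.headers, profiles)
                        if p["binary"]])
    assigned.add(event_idx)

    # sample id
    id_idx = None
    for i in range(table.n_columns):
        if i not in assigned and not profiles[i]["numeric"]:
            id_idx = i
            break
    if id_idx is None:
        id_idx = 0 if 0 not in assigned else \
            next(i for i in range(table.n_columns) if i not in assigned)
    assigned.add(id_idx)

    # filters: explicit /filter/ headers first, then small text categoricals
    filters: list[int] = []
    for i in range(table.n_columns):
        if i in assigned or len(filters) >= MAX_FILTERS:
            continue
        if header_match(r"filter", i):
            filters.append(i)
            assigned.add(i)
    for i in range(table.n_columns):
        if i in assigned or len(filters) >= MAX_FILTERS:
            continue
        if not profiles[i]["numeric"] and 3 <= profiles[i]["n_distinct"] <= MAX_FILTER_LEVELS:
            filters.append(i)
            assigned.add(i)

    markers = [i for i in range(table.n_columns) if i not in assigned]
    return ColumnRoles(sample_id=id_idx, time=time_idx, event=event_idx,
                       filters=filters, markers=markers)


# ---------------------------------------------------------------------------
# validation

def validate(table: RawTable, roles: ColumnRoles | None = None) -> SurvivalDataset:
    """Enforce the input contract and build a SurvivalDataset.

    Raises a named :class:`ValidationError` for each class of violation;
    rows with missing time or event are dropped with a warning, and marker
    columns containing missing cells are demoted to unusable rather than
    imputed.
    """
    if table.n_columns > MAX_COLUMNS:
        raise ValidationError("too_many_columns",
                              f"{table.n_columns} columns exceed the maximum "
                              f"of {MAX_COLUMNS}")
    if len(table.rows) > MAX_ROWS:
        raise ValidationError("too_many_rows",
                              f"{len(table.rows)} rows exceed the maximum of "
                              f"{MAX_ROWS}")
    if len(table.rows) == 0:
        raise ValidationError("empty_table", "table has no data rows")

    seen = {}
    for i, h in enumerate(table.headers):
        if not HEADER_RE.match(h):
            raise ValidationError(
                "invalid_header",
                f"header {h!r} contains characters outside the allowed set "
                "(letters, digits, space, underscore, colon, round brackets, "
                "exclamation mark)", column=i)
        key = h.strip().lower()
        if key in seen:
            raise ValidationError("duplicate_header",
                                  f"duplicate header {h!r} (columns "
                                  f"{seen[key]} and {i})", column=i)
        seen[key] = i

    if roles is None:
        roles = recognize_columns(table)
    if len(roles.filters) > MAX_FILTERS:
        raise ValidationError("too_many_filters",
                              f"{len(roles.filters)} filters exceed the "
                              f"maximum of {MAX_FILTERS}")

    time_cells = table.column(roles.time)
    event_cells = table.column(roles.event)
    n_rows = len(table.rows)

    keep = np.ones(n_rows, dtype=bool)
    time = np.full(n_rows, np.nan)
    for r, cell in enumerate(time_cells):
        if _is_missing(cell):
            keep[r] = False
            continue
        try:
            t = float(cell)
        except ValueError:
            raise ValidationError("time_not_numeric",
                                  f"survival time {cell!r} is not numeric",
                                  row=r, column=roles.time) from None
        if not np.isfinite(t) or t < 0:
            raise ValidationError("time_not_nonnegative",
                                  f"survival time {cell!r} must be finite "
                                  "and nonnegative", row=r, column=roles.time)
        time[r] = t

    event = np.zeros(n_rows, dtype=int)
    for r, cell in enumerate(event_cells):
        if _is_missing(cell):
            keep[r] = False
            continue
        if cell.strip() not in {"0", "1"}:
            raise ValidationError("event_not_binary",
                                  f"survival event {cell!r} must be coded "
                                  "0 or 1", row=r, column=roles.event)
        event[r] = int(cell)

    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} row(s) with missing time/event",
                      DataLossWarning, stacklevel=2)

    ids = np.asarray([table.rows[r][roles.sample_id] for r in range(n_rows)],
                     dtype=object)[keep]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate sample IDs present", DataLossWarning,
                      stacklevel=2)

    filters: dict[str, np.ndarray] = {}
    for ci in roles.filters:
        cells = np.asarray([c.strip() for c in table.column(ci)],
                           dtype=object)[keep]
        levels = {c for c in cells if not _is_missing(c)}
        if len(levels) > MAX_FILTER_LEVELS:
            raise ValidationError(
                "filter_too_many_levels",
                f"filter {table.headers[ci]!r} has {len(levels)} distinct "
                f"values; the maximum is {MAX_FILTER_LEVELS}", column=ci)
        filters[table.headers[ci]] = cells

    markers: dict[str, np.ndarray] = {}
    unusable: list[str] = []
    for ci in roles.markers:
        name = table.headers[ci]
        prof = _column_profile(table.column(ci))
        if not prof["numeric"]:
            unusable.append(name)
            warnings.warn(f"column {name!r} is not numeric; demoted to "
                          "unusable", DataLossWarning, stacklevel=2)
            continue
        vals = prof["values"][keep]
        if np.isnan(vals).any():
            unusable.append(name)
            warnings.warn(f"marker {name!r} has missing cells; only full "
                          "columns are usable as variables", DataLossWarning,
                          stacklevel=2)
            continue
        markers[name] = vals

    return SurvivalDataset(
        sample_ids=ids, time=time[keep], event=event[keep],
        filters=filters, markers=markers,
        id_name=table.headers[roles.sample_id],
        time_name=table.headers[roles.time],
        event_name=table.headers[roles.event],
        unusable_markers=unusable,
    )


def load_dataset(path) -> SurvivalDataset:
    """Read, recognize and validate a delimited survival table in one step."""
    return validate(read_table(path))


def validation_report(text: str) -> dict:
    """Run the full validation and return a JSON-ready report instead of
    raising: ``{"valid": bool, "errors": [...], "n_samples": int, ...}``."""
    report: dict = {"valid": False, "errors": [], "warnings": []}
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = parse_table(text)
            roles = recognize_columns(table)
            ds = validate(table, roles)
        report["warnings"] = [str(w.message) for w in caught]
        report.update(valid=True, n_samples=ds.n, n_events=ds.n_events,
                      dialect=table.dialect,
                      roles={"sample_id": roles.sample_id, "time": roles.time,
                             "event": roles.event, "filters": roles.filters,
                             "markers": roles.markers},
                      filters=sorted(ds.filters),
                      markers=sorted(ds.markers),
                      unusable_markers=ds.unusable_markers)
    except ValidationError as err:
        report["errors"].append(err.to_dict())
    except (UnparseableTable, RoleRecognitionError) as err:
        report["errors"].append({"rule": type(err).__name__, "row": None,
                                 "column": None, "message": str(err)})
    return report


# ---------------------------------------------------------------------------
# filtering

def apply_filters(ds: SurvivalDataset,
                  selection: dict[str, set | list]) -> SurvivalDataset:
    """Keep rows whose value in every selected filter is among the allowed
    values (compared as strings); row order preserved."""
    if len(selection) > MAX_FILTERS:
        raise ValidationError("too_many_filters",
                              f"at most {MAX_FILTERS} filters may be selected")
    mask = np.ones(ds.n, dtype=bool)
    for name, allowed in selection.items():
        if name not in ds.filters:
            raise KeyError(f"unknown filter {name!r}; available: "
                           f"{sorted(ds.filters)}")
        allowed_str = {str(a).strip() for a in allowed}
        col = np.asarray([str(v).strip() for v in ds.filters[name]])
        mask &= np.isin(col, list(allowed_str))
    if not mask.any():
        raise EmptyCohortError(
            f"filter selection {selection!r} removed every sample")
    return ds.subset(mask)


def dataset_from_frame(df: pd.DataFrame) -> SurvivalDataset:
    """Build a dataset from an in-memory DataFrame via the same recognition
    and validation path as a file (serialize through TSV text)."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return validate(parse_table(buf.getvalue()))


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
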