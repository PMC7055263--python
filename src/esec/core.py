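"""Data model and I/O for Extended Semantic Event Chains (ESECs).

An ESEC encodes a manipulation action as an ordered sequence of *event
columns*.  Each column is the state of 30 object-pair relations at one
change-moment: the 10 unordered pairs among Hand (H), Ground (G) and the
abstract Objects O1..O3, observed through three relational channels --
touching/non-touching (TNT), static spatial relations (SSR) and dynamic
spatial relations (DSR).  Column C0 is the canonical pre-action state
(hand free and far away, no object yet in being) and is identical for
every action; every later column differs from its predecessor in at
least one cell and carries the time (seconds from action start) of the
change-moment it represents.

The SEC is the classic touching/non-touching projection: only the 10 TNT
rows are kept and columns that become identical under the projection are
merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Relation alphabet
# --------------------------------------------------------------------------

CHANNELS = ("TNT", "SSR", "DSR")

#: touching / non-touching channel
TNT_SYMBOLS = frozenset({"T", "N", "A", "U"})
#: static spatial relations (To = on-top touching, ArT = around with touch,
#: AR = around without touch, In/Sa = containment, Bw = between, O = very far)
SSR_SYMBOLS = frozenset(
    {"Ab", "Be", "R", "L", "F", "Ba", "In", "Sa", "Bw", "AR", "To", "ArT", "O", "A", "U"}
)
#: dynamic spatial relations (Q = very far)
DSR_SYMBOLS = frozenset({"MT", "HT", "FMT", "GC", "MA", "S", "Q", "A", "U"})

ALPHABET = {"TNT": TNT_SYMBOLS, "SSR": SSR_SYMBOLS, "DSR": DSR_SYMBOLS}

#: the five object roles
ROLES = ("H", "O1", "O2", "O3", "G")

#: canonical order of the 10 fundamental object pairs (rows of each sub-table)
PAIRS = (
    ("H", "O1"),
    ("H", "O2"),
    ("H", "O3"),
    ("H", "G"),
    ("O1", "O2"),
    ("O1", "O3"),
    ("O1", "G"),
    ("O2", "O3"),
    ("O2", "G"),
    ("O3", "G"),
)

PAIR_LABELS = tuple(f"{a}-{b}" for a, b in PAIRS)

N_PAIRS = len(PAIRS)
N_ROWS = N_PAIRS * len(CHANNELS)

#: canonical pre-action column: hand in the scene's far field, nothing touched,
#: no abstract object born yet.  Identical for every action.
START_COLUMN: dict[tuple[str, str], tuple[str, str, str]] = {
    pair: (("N", "O", "Q") if pair == ("H", "G") else ("U", "U", "U")) for pair in PAIRS
}


def is_valid_symbol(symbol: str, channel: str) -> bool:
    """True iff *symbol* belongs to the closed alphabet of *channel*."""
    return symbol in ALPHABET[channel]


def start_column_array() -> np.ndarray:
    """The canonical C0 as a (10, 3) array of symbols."""
    return np.array([START_COLUMN[p] for p in PAIRS], dtype=object)


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------


@dataclass
class ESECTable:
    """Symbolic event matrix of one action.

    ``cells`` has shape (10 pairs, 3 channels, K columns); ``timestamps``
    holds one change time per column, with C0 at 0.0.
    """

    cells: np.ndarray
    timestamps: np.ndarray
    action_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.cells.ndim != 3 or self.cells.shape[:2] != (N_PAIRS, len(CHANNELS)):
            raise ValueError(
                f"cells must have shape (10, 3, K); got {self.cells.shape}"
            )
        if self.timestamps.shape != (self.cells.shape[2],):
            raise ValueError("one timestamp per column required")

    # -- basic views -----------------------------------------------------

    @property
    def n_columns(self) -> int:
        return self.cells.shape[2]

    @property
    def n_events(self) -> int:
        """Number of change columns after C0."""
        return self.n_columns - 1

    def column(self, j: int) -> np.ndarray:
        """The (10, 3) symbol block of column j."""
        return self.cells[:, :, j]

    def pair_rows(self) -> np.ndarray:
        """Rows as the similarity measure sees them: (10, K) cells of
        3-symbol tuples per fundamental pair."""
        out = np.empty((N_PAIRS, self.n_columns), dtype=object)
        for i in range(N_PAIRS):
            for j in range(self.n_columns):
                out[i, j] = tuple(self.cells[i, :, j])
        return out

    def prefix(self, k: int) -> "ESECTable":
        """Table restricted to C0..Ck (k >= 0)."""
        if not 0 <= k < self.n_columns:
            raise IndexError(f"column index {k} out of range")
        return ESECTable(
            self.cells[:, :, : k + 1].copy(),
            self.timestamps[: k + 1].copy(),
            self.action_label,
            dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ESECTable):
            return NotImplemented
        return (
            self.cells.shape == other.cells.shape
            and bool(np.all(self.cells == other.cells))
            and np.allclose(self.timestamps, other.timestamps)
        )

    # -- projection ------------------------------------------------------

    def to_sec(self) -> "SECTable":
        """Project onto the touching/non-touching sub-table.

        Adjacent columns that become identical under the projection are
        merged, keeping the earlier timestamp.
        """
        tnt = self.cells[:, 0, :]
        keep = [0]
        for j in range(1, self.n_columns):
            if not np.array_equal(tnt[:, j], tnt[:, keep[-1]]):
                keep.append(j)
        return SECTable(
            tnt[:, keep].copy(),
            self.timestamps[keep].copy(),
            self.action_label,
        )


@dataclass
class SECTable:
    """Touching/non-touching projection of an ESEC: (10, K) symbol matrix."""

    cells: np.ndarray
    timestamps: np.ndarray
    action_label: str | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.cells.ndim != 2 or self.cells.shape[0] != N_PAIRS:
            raise ValueError(f"cells must have shape (10, K); got {self.cells.shape}")

    @property
    def n_columns(self) -> int:
        return self.cells.shape[1]

    def as_esec(self) -> ESECTable:
        """Lift to a degenerate ESEC whose SSR/DSR channels are constant.

        Lets the similarity measure and the predictor run unchanged in
        SEC mode: only the TNT channel can ever differ between two
        lifted tables, exactly as when "only the top sub-table is used".
        """
        cells = np.empty((N_PAIRS, len(CHANNELS), self.n_columns), dtype=object)
        cells[:, 0, :] = self.cells
        cells[:, 1, :] = "U"
        cells[:, 2, :] = "U"
        return ESECTable(cells, self.timestamps.copy(), self.action_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SECTable):
            return NotImplemented
        return (
            self.cells.shape == other.cells.shape
            and bool(np.all(self.cells == other.cells))
            and np.allclose(self.timestamps, other.timestamps)
        )


def to_sec(table: ESECTable) -> SECTable:
    """Functional form of :meth:`ESECTable.to_sec`."""
    return table.to_sec()


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule: str
    where: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.where}: {self.detail}"


def validate(table: ESECTable) -> list[Violation]:
    """Check all ESEC invariants; violations are returned, never raised."""
    out: list[Violation] = []
    # channel-valid symbols
    for i, pair in enumerate(PAIR_LABELS):
        for c, channel in enumerate(CHANNELS):
            for j in range(table.n_columns):
                sym = table.cells[i, c, j]
                if not is_valid_symbol(sym, channel):
                    out.append(
                        Violation(
                            "channel symbol",
                            f"row {pair}:{channel}, column C{j}",
                            f"symbol {sym!r} not in the {channel} alphabet",
                        )
                    )
    # canonical start column
    if table.n_columns >= 1:
        if not np.array_equal(table.column(0), start_column_array()):
            out.append(
                Violation(
                    "start column",
                    "column C0",
                    "C0 must be the canonical pre-action state",
                )
            )
    # change columns
    for j in range(1, table.n_columns):
        if np.array_equal(table.column(j), table.column(j - 1)):
            out.append(
                Violation(
                    "no-change column",
                    f"column C{j}",
                    "consecutive columns must differ in at least one cell",
                )
            )
    # timestamps
    if table.n_columns >= 1 and table.timestamps[0] != 0.0:
        out.append(Violation("timestamp origin", "column C0", "C0 must be at t=0"))
    for j in range(1, table.n_columns):
        if not table.timestamps[j] > table.timestamps[j - 1]:
            out.append(
                Violation(
                    "timestamp order",
                    f"column C{j}",
                    "timestamps must strictly increase",
                )
            )
    return out


# --------------------------------------------------------------------------
# On-disk formats
# --------------------------------------------------------------------------
#
# CSV layout (UTF-8, "." decimal separator, symbols case-sensitive):
#
#   pair,channel,C0,C1,...
#   time,,0.000000,1.150000,...
#   H-O1,TNT,U,U,...
#   ...                             (30 rows, canonical pair x channel order:
#                                    all TNT rows, then SSR, then DSR)
#
# JSON layout: {"action_label":..., "pairs":[...], "channels":[...],
#               "timestamps":[...], "columns":[[...30 symbols...], ...],
#               "meta": {...}}  -- columns in row-major canonical order.

_TS_FMT = "%.6f"


class ESECFormatError(ValueError):
    """Malformed on-disk ESEC representation."""


def _row_order() -> list[tuple[int, int]]:
    """(pair index, channel index) in on-disk row order: channel blocks."""
    return [(i, c) for c in range(len(CHANNELS)) for i in range(N_PAIRS)]


def _validate_or_raise(table: ESECTable, context: str) -> None:
    bad = [
        v
        for v in validate(table)
        if v.rule in ("channel symbol",)
    ]
    if bad:
        raise ESECFormatError(f"{context}: {bad[0]}")


def write_esec(table: ESECTable, path: str | Path, format: str = "csv") -> None:
    """Write a table; byte-stable for fixed input.

    A channel-invalid cell raises before any file is created.
    """
    _validate_or_raise(table, "refusing to write invalid table")
    path = Path(path)
    if format == "csv":
        lines = ["pair,channel," + ",".join(f"C{j}" for j in range(table.n_columns))]
        lines.append("time,," + ",".join(_TS_FMT % t for t in table.timestamps))
        for i, c in _row_order():
            syms = ",".join(table.cells[i, c, j] for j in range(table.n_columns))
            lines.append(f"{PAIR_LABELS[i]},{CHANNELS[c]},{syms}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = {
            "action_label": table.action_label,
            "pairs": list(PAIR_LABELS),
            "channels": list(CHANNELS),
            "timestamps": [float(_TS_FMT % t) for t in table.timestamps],
            "columns": [
                [table.cells[i, c, j] for c in range(len(CHANNELS)) for i in range(N_PAIRS)]
                for j in range(table.n_columns)
            ],
            "meta": table.meta,
        }
        path.write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def read_esec(path: str | Path, format: str | None = None) -> ESECTable:
    """Read a table written by :func:`write_esec` (format inferred from suffix
    when not given)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "json":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def _read_csv(path: Path) -> ESECTable:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 2 + N_ROWS:
        raise ESECFormatError(
            f"{path}: expected header + time row + {N_ROWS} relation rows, "
            f"got {len(lines)} lines"
        )
    header = lines[0].split(",")
    ncols = len(header) - 2
    if ncols < 1 or header[:2] != ["pair", "channel"]:
        raise ESECFormatError(f"{path}: malformed header row")
    time_fields = lines[1].split(",")
    if time_fields[0] != "time" or len(time_fields) != ncols + 2:
        raise ESECFormatError(f"{path}: malformed time row")
    try:
        timestamps = np.array([float(x) for x in time_fields[2:]])
    except ValueError as e:
        raise ESECFormatError(f"{path}: bad timestamp ({e})") from None

    cells = np.empty((N_PAIRS, len(CHANNELS), ncols), dtype=object)
    expected = _row_order()
    for r, (i, c) in enumerate(expected):
        fields = lines[2 + r].split(",")
        if len(fields) != ncols + 2:
            raise ESECFormatError(f"{path}: row {r + 3} has {len(fields)} fields")
        label, channel = fields[0], fields[1]
        if label != PAIR_LABELS[i] or channel != CHANNELS[c]:
            raise ESECFormatError(
                f"{path}: row {r + 3} is {label}:{channel}, expected "
                f"{PAIR_LABELS[i]}:{CHANNELS[c]} (canonical order)"
            )
        for j, sym in enumerate(fields[2:]):
            if not is_valid_symbol(sym, channel):
                raise ESECFormatError(
                    f"{path}: invalid symbol {sym!r} in cell {label}:{channel} C{j}"
                )
            cells[i, c, j] = sym
    label = path.stem
    return ESECTable(cells, timestamps, action_label=label)


def _read_json(path: Path) -> ESECTable:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ESECFormatError(f"{path}: not valid JSON ({e})") from None
    for key in ("pairs", "channels", "timestamps", "columns"):
        if key not in payload:
            raise ESECFormatError(f"{path}: missing key {key!r}")
    if list(payload["pairs"]) != list(PAIR_LABELS) or list(payload["channels"]) != list(
        CHANNELS
    ):
        raise ESECFormatError(f"{path}: non-canonical pair/channel order")
    timestamps = np.array(payload["timestamps"], dtype=float)
    columns = payload["columns"]
    if len(columns) != len(timestamps):
        raise ESECFormatError(f"{path}: column/timestamp count mismatch")
    cells = np.empty((N_PAIRS, len(CHANNELS), len(columns)), dtype=object)
    for j, col in enumerate(columns):
        if len(col) != N_ROWS:
            raise ESECFormatError(f"{path}: column {j} has {len(col)} cells")
        for r, (i, c) in enumerate(_row_order()):
            sym = col[r]
            if not is_valid_symbol(sym, CHANNELS[c]):
                raise ESECFormatError(
                    f"{path}: invalid symbol {sym!r} in cell "
                    f"{PAIR_LABELS[i]}:{CHANNELS[c]} C{j}"
                )
            cells[i, c, j] = sym
    return ESECTable(
        cells,
        timestamps,
        action_label=payload.get("action_label"),
        meta=payload.get("meta", {}),
    )


def columns_from_mapping(
    columns: Sequence[dict[tuple[str, str], tuple[str, str, str]]],
    timestamps: Iterable[float],
    action_label: str | None = None,
) -> ESECTable:
    """Build a table from per-column {pair: (tnt, ssr, dsr)} mappings."""
    cols = list(columns)
    cells = np.empty((N_PAIRS, len(CHANNELS), len(cols)), dtype=object)
    for j, mapping in enumerate(cols):
        for i, pair in enumerate(PAIRS):
            cells[i, :, j] = mapping[pair]
    return ESECTable(cells, np.fromiter(timestamps, dtype=float), action_label)
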