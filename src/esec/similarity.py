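"""Similarity measure between two ESECs.

Two actions a1 (n columns) and a2 (m columns) are compared per
fundamental object pair: each pair contributes, per column, a 3-symbol
cell (TNT, SSR, DSR).  Per channel c an indicator D^c is 0 when the
symbols agree and 1 otherwise, and the composite per-cell difference is

    diff = sqrt(D^1 + D^2 + D^3)  in {0, 1, sqrt 2, sqrt 3}.

The shorter table is padded by repeating its last column up to
p = max(n, m) -- a deliberate, comparison-independent similarity
penalty.  The total dissimilarity Dis is the grand mean of the
10 x p difference matrix and the similarity, in percent, is

    Sim = (1 - Dis) * 100.

Sim can be negative (down to (1 - sqrt 3) * 100 ~ -73.2); no clipping is
applied.  U and A are ordinary symbols: the indicators compare cells for
equality only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ALPHABET, CHANNELS, ESECTable, N_PAIRS

#: hard bounds of the measure
SIM_MAX = 100.0
SIM_MIN = (1.0 - np.sqrt(3.0)) * 100.0


@dataclass(frozen=True)
class SimilarityResult:
    sim: float
    dis: float
    difference_matrix: np.ndarray  # (10, p) of diff values
    p: int


def column_diff(cell_a, cell_b) -> float:
    """Composite difference between two 3-symbol cells of one pair."""
    for cell in (cell_a, cell_b):
        if len(cell) != len(CHANNELS):
            raise ValueError("a cell holds exactly one symbol per channel")
        for sym, channel in zip(cell, CHANNELS):
            if sym not in ALPHABET[channel]:
                raise ValueError(f"symbol {sym!r} invalid in channel {channel}")
    d = sum(int(a != b) for a, b in zip(cell_a, cell_b))
    return float(np.sqrt(d))


def _padded(cells: np.ndarray, p: int) -> np.ndarray:
    """Pad (10, 3, k) cells to (10, 3, p) by last-column repetition."""
    k = cells.shape[2]
    if k == p:
        return cells
    pad = np.repeat(cells[:, :, -1:], p - k, axis=2)
    return np.concatenate([cells, pad], axis=2)


def esec_similarity(a: ESECTable, b: ESECTable, include_start: bool = False) -> SimilarityResult:
    """Similarity of two ESECs over their post-C0 event columns.

    C0 is a pre-set column shared by all actions and is excluded by
    default; ``include_start=True`` compares the raw matrices instead.
    """
    ca, cb = a.cells, b.cells
    if not include_start:
        ca, cb = ca[:, :, 1:], cb[:, :, 1:]
    n, m = ca.shape[2], cb.shape[2]
    if n == 0 or m == 0:
        raise ValueError("cannot compare an empty table (no event columns)")
    p = max(n, m)
    ca, cb = _padded(ca, p), _padded(cb, p)
    indicators = (ca != cb).astype(float)  # (10, 3, p): D^1..D^3
    difference = np.sqrt(indicators.sum(axis=1))  # (10, p)
    dis = float(difference.mean())
    return SimilarityResult(
        sim=(1.0 - dis) * 100.0,
        dis=dis,
        difference_matrix=difference,
        p=p,
    )


def sim(a: ESECTable, b: ESECTable) -> float:
    """Shorthand: just the Sim value in percent."""
    return esec_similarity(a, b).sim


# -- integer-coded fast path -------------------------------------------------
#
# The online predictor compares on the order of a million table prefixes;
# symbol cells are therefore one-time encoded to small integers per table.
# ``sim_codes`` is numerically identical to ``esec_similarity(...).sim``.

_SYMBOLS = sorted(set().union(*ALPHABET.values()))
_CODE = {s: i for i, s in enumerate(_SYMBOLS)}


def encode_cells(table: ESECTable) -> np.ndarray:
    """(10, 3, K) int8 code array, cached on the table instance."""
    cached = table.__dict__.get("_symbol_codes")
    if cached is not None and cached.shape == table.cells.shape:
        return cached
    codes = np.empty(table.cells.shape, dtype=np.int8)
    for sym, code in _CODE.items():
        codes[table.cells == sym] = code
    table.__dict__["_symbol_codes"] = codes
    return codes


def sim_codes(ca: np.ndarray, cb: np.ndarray) -> float:
    """Sim (percent) between two integer-coded cell blocks of shape
    (10, 3, k) -- already restricted to the columns to compare."""
    n, m = ca.shape[2], cb.shape[2]
    if n == 0 or m == 0:
        raise ValueError("cannot compare an empty table (no event columns)")
    p = max(n, m)
    if n < p:
        ca = np.concatenate([ca, np.repeat(ca[:, :, -1:], p - n, axis=2)], axis=2)
    if m < p:
        cb = np.concatenate([cb, np.repeat(cb[:, :, -1:], p - m, axis=2)], axis=2)
    difference = np.sqrt((ca != cb).sum(axis=1, dtype=np.float64))
    return (1.0 - float(difference.mean())) * 100.0


def pairwise_sims(tables: list[ESECTable]) -> np.ndarray:
    """Condensed vector of Sim over all unordered pairs (scipy.pdist order)."""
    n = len(tables)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = esec_similarity(tables[i], tables[j]).sim
            k += 1
    return out
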