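"""Geometric relation predicates and trajectory -> ESEC extraction.

Objects are axis-aligned boxes moving on a tabletop world (+z up).  Three
relation channels are evaluated per fundamental object pair at every
sample:

* TNT -- touching (surface gap <= ``contact_distance``) or not.
* SSR -- static spatial relation.  Beyond ``very_far_distance`` the
  symbol is O; containment gives In/Sa; a horizontally surrounding
  footprint gives AR (ArT with touch); an on-top touch gives To;
  "between" two other role objects gives Bw; otherwise the dominant
  displacement axis yields Ab/Be/R/L/F/Ba.
* DSR -- dynamic spatial relation from finite-difference velocities.
  Beyond very-far the symbol is Q.  Pairs with the fixed Ground use
  S (still), FMT (transported horizontally) or GC/MA (vertical
  approach/recede); movable pairs use HT (both halted), MT (moving in
  lockstep), GC/MA (range-rate) or S.

Object roles follow first-contact order: Object 1 is the object first
touched by the hand; further objects come into being at their first
touch *or* un-touch transition with an already-roled entity (hand or
object, not the ground).  Before its birth an object's rows are
undefined (U) and objects that never interact keep U rows throughout,
so the start column C0 is identical for every action.

The numeric thresholds are package defaults chosen for the synthetic
block world; they are configurable and carry no claim of matching any
particular motion-capture rig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .core import CHANNELS, ESECTable, N_PAIRS, PAIRS, ROLES, start_column_array

logger = logging.getLogger(__name__)

_AXIS_SYMBOLS = {  # (axis, positive sign) -> symbol for "first relative to second"
    (2, +1): "Ab",
    (2, -1): "Be",
    (0, +1): "R",
    (0, -1): "L",
    (1, +1): "Ba",
    (1, -1): "F",
}
#: tie-break priority for the dominant displacement axis
_AXIS_PRIORITY = ("Ab", "Be", "L", "R", "F", "Ba")


@dataclass(frozen=True)
class RelationThresholds:
    """Geometric thresholds of the relation predicates (meters, m/s, s)."""

    contact_distance: float = 0.005
    very_far_distance: float = 1.0
    speed_epsilon: float = 0.01
    approach_epsilon: float = 0.02
    containment_overlap: float = 0.5
    footprint_margin: float = 0.005
    smoothing_window: float = 0.0
    #: changes within this window of a column's first change fold into
    #: that column (a change-moment, e.g. a grasp, touches several
    #: relations across neighbouring samples)
    fold_window: float = 0.15

    def __post_init__(self) -> None:
        if self.contact_distance <= 0 or self.very_far_distance <= 0:
            raise ValueError("distances must be strictly positive")
        if self.contact_distance >= self.very_far_distance:
            raise ValueError("contact_distance must be < very_far_distance")
        if self.speed_epsilon <= 0 or self.approach_epsilon <= 0:
            raise ValueError("velocity epsilons must be strictly positive")
        if not 0 < self.containment_overlap <= 1:
            raise ValueError("containment_overlap must be in (0, 1]")

    def replace(self, **kw) -> "RelationThresholds":
        return replace(self, **kw)


DEFAULT_THRESHOLDS = RelationThresholds()


@dataclass
class RelationTimeline:
    """Per pair and channel, the ordered (time, symbol) change points."""

    changes: dict[tuple[tuple[str, str], str], list[tuple[float, str]]]

    def symbol_at(self, pair: tuple[str, str], channel: str, t: float) -> str:
        run = self.changes[(pair, channel)]
        sym = run[0][1]
        for time, s in run:
            if time > t:
                break
            sym = s
        return sym


# --------------------------------------------------------------------------
# geometry helpers (vectorized over time)
# --------------------------------------------------------------------------


def _gap(pos_a, ext_a, pos_b, ext_b) -> np.ndarray:
    """Surface gap between two axis-aligned boxes, (T,) array."""
    sep = np.abs(pos_a - pos_b) - (ext_a + ext_b)
    sep = np.maximum(sep, 0.0)
    return np.sqrt((sep**2).sum(axis=-1))


def _center_distance(pos_a, pos_b) -> np.ndarray:
    return np.sqrt(((pos_a - pos_b) ** 2).sum(axis=-1))


def _overlap_fraction(pos_a, ext_a, pos_b, ext_b) -> np.ndarray:
    """Fraction of box A's volume inside box B, per sample."""
    lo = np.maximum(pos_a - ext_a, pos_b - ext_b)
    hi = np.minimum(pos_a + ext_a, pos_b + ext_b)
    inter = np.clip(hi - lo, 0.0, None).prod(axis=-1)
    vol_a = float(np.prod(2.0 * ext_a))
    return inter / vol_a


def _footprint_contains(pos_a, ext_a, pos_b, ext_b, margin) -> np.ndarray:
    """True where A's horizontal footprint contains B's with a margin."""
    ok = np.ones(pos_a.shape[0], dtype=bool)
    for ax in (0, 1):
        ok &= pos_a[:, ax] - ext_a[ax] <= pos_b[:, ax] - ext_b[ax] - margin
        ok &= pos_a[:, ax] + ext_a[ax] >= pos_b[:, ax] + ext_b[ax] + margin
    return ok


def _velocities(pos: np.ndarray, dt: float, smoothing_window: float) -> np.ndarray:
    """Forward-difference velocities, (T, 3); optional moving-average smooth."""
    v = np.empty_like(pos)
    v[:-1] = (pos[1:] - pos[:-1]) / dt
    v[-1] = v[-2]
    if smoothing_window > 0:
        w = max(1, int(round(smoothing_window / dt)))
        kernel = np.ones(w) / w
        for ax in range(3):
            v[:, ax] = np.convolve(v[:, ax], kernel, mode="same")
    return v


def _dominant_axis_symbol(delta: np.ndarray) -> str:
    """SSR symbol for the dominant displacement axis of one sample.

    Displacements are quantized to 1 um so that geometric ties are exact
    and the fixed priority order breaks them deterministically.
    """
    delta = np.round(delta, 6)
    mags = np.abs(delta)
    best = mags.max()
    candidates = []
    for (ax, sign), sym in _AXIS_SYMBOLS.items():
        if mags[ax] == best and (np.sign(delta[ax]) == sign or delta[ax] == 0):
            candidates.append(sym)
    if not candidates:  # zero displacement: fixed tie-break
        return _AXIS_PRIORITY[0]
    return min(candidates, key=_AXIS_PRIORITY.index)


# --------------------------------------------------------------------------
# role assignment
# --------------------------------------------------------------------------


def assign_roles(
    trajectory, thresholds: RelationThresholds = DEFAULT_THRESHOLDS
) -> dict[str, tuple[str, float]]:
    """Map object id -> (role, birth time) by first-contact order.

    The hand and ground are identified by their role hints.  Abstract
    roles are assigned at touch/un-touch transitions with already-roled
    non-ground entities; at most three are ever assigned and the rest of
    the scene (distractors) keeps no role.
    """
    hand = trajectory.hand_id
    ground = trajectory.ground_id
    roles: dict[str, tuple[str, float]] = {
        hand: ("H", 0.0),
        ground: ("G", 0.0),
    }
    movables = [oid for oid in trajectory.ids if oid != ground]
    touch = {}
    for a, b in combinations(movables, 2):
        touch[(a, b)] = (
            _gap(
                trajectory.positions[a],
                trajectory.extents[a],
                trajectory.positions[b],
                trajectory.extents[b],
            )
            <= thresholds.contact_distance
        )

    def _state(a, b, t_idx):
        key = (a, b) if (a, b) in touch else (b, a)
        return touch[key][t_idx]

    next_role = 1
    times = trajectory.times
    for t_idx in range(1, len(times)):
        if next_role > 3:
            break
        cast = [oid for oid, (r, _) in roles.items() if r != "G"]
        unroled = sorted(o for o in movables if o not in roles)
        for actor in cast:
            for other in unroled:
                if other in roles or next_role > 3:
                    continue
                if _state(actor, other, t_idx) != _state(actor, other, t_idx - 1):
                    # O1 must be born by the hand's first touch
                    if next_role == 1 and actor != hand:
                        continue
                    roles[other] = (f"O{next_role}", float(times[t_idx]))
                    next_role += 1
    if next_role == 1:
        logger.warning("hand never touches any object; only H and G assigned")
    return roles


# --------------------------------------------------------------------------
# per-pair symbol streams
# --------------------------------------------------------------------------


def _pair_symbols(
    trajectory,
    thresholds: RelationThresholds,
    id_a: str,
    id_b: str,
    roles: dict[str, tuple[str, float]],
) -> np.ndarray:
    """(3, T) symbol stream for the role pair carried by (id_a, id_b)."""
    times = trajectory.times
    n = len(times)
    dt = float(times[1] - times[0])
    pa, pb = trajectory.positions[id_a], trajectory.positions[id_b]
    ea, eb = trajectory.extents[id_a], trajectory.extents[id_b]
    role_a, birth_a = roles[id_a]
    role_b, birth_b = roles[id_b]
    born = times >= max(birth_a, birth_b)

    is_ground = "G" in (role_a, role_b)
    if role_b == "G":  # evaluate with the movable first
        ga, gb = pa, pb
    else:
        ga, gb = pb, pa

    gap = _gap(pa, ea, pb, eb)
    touching = gap <= thresholds.contact_distance
    if is_ground:
        far = gap > thresholds.very_far_distance
    else:
        far = _center_distance(pa, pb) > thresholds.very_far_distance

    va = _velocities(pa, dt, thresholds.smoothing_window)
    vb = _velocities(pb, dt, thresholds.smoothing_window)
    speed_a = np.sqrt((va**2).sum(axis=1))
    speed_b = np.sqrt((vb**2).sum(axis=1))
    center_dist = _center_distance(pa, pb)
    range_rate = np.empty(n)
    range_rate[:-1] = (center_dist[1:] - center_dist[:-1]) / dt
    range_rate[-1] = range_rate[-2]

    frac_a_in_b = _overlap_fraction(pa, ea, pb, eb)
    frac_b_in_a = _overlap_fraction(pb, eb, pa, ea)
    around_ab = _footprint_contains(pa, ea, pb, eb, thresholds.footprint_margin)

    # "between": the first object's center close to the segment joining two
    # other role objects
    others = [
        oid
        for oid, (r, _) in roles.items()
        if r.startswith("O") and oid not in (id_a, id_b)
    ]
    between = np.zeros(n, dtype=bool)
    if len(others) >= 2:
        tol = float(max(ea)) + thresholds.footprint_margin
        for o1, o2 in combinations(others, 2):
            q1, q2 = trajectory.positions[o1], trajectory.positions[o2]
            seg = q2 - q1
            seg_len2 = (seg**2).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = ((pa - q1) * seg).sum(axis=1) / seg_len2
            u = np.where(seg_len2 > 0, u, 0.5)
            proj = q1 + u[:, None] * seg
            ok = (u > 0.0) & (u < 1.0)
            ok &= _center_distance(pa, proj) <= tol
            between |= ok

    out = np.empty((3, n), dtype=object)
    eps_v = thresholds.speed_epsilon
    eps_a = thresholds.approach_epsilon
    dz = np.round(pa[:, 2] - pb[:, 2], 6)
    dxy = np.round(pa[:, [0, 1]] - pb[:, [0, 1]], 6)

    for t in range(n):
        if not born[t]:
            out[:, t] = ("U", "U", "U")
            continue
        # ---- TNT
        out[0, t] = "T" if touching[t] else "N"
        # ---- SSR
        if far[t]:
            out[1, t] = "O"
        elif is_ground:
            # the ground is an omnipresent support plane: anything near it
            # is either resting on top of it or above it
            out[1, t] = "To" if touching[t] else "Ab"
        elif touching[t] and around_ab[t]:
            out[1, t] = "ArT"  # e.g. a hollow cover enclosing a block
        elif frac_a_in_b[t] >= thresholds.containment_overlap:
            out[1, t] = "In"
        elif frac_b_in_a[t] >= thresholds.containment_overlap:
            out[1, t] = "Sa"
        elif around_ab[t]:
            out[1, t] = "AR"
        elif touching[t] and abs(dz[t]) >= np.abs(dxy[t]).max():
            out[1, t] = "To" if dz[t] >= 0 else "Be"
        elif between[t]:
            out[1, t] = "Bw"
        else:
            out[1, t] = _dominant_axis_symbol(pa[t] - pb[t])
        # ---- DSR
        if far[t]:
            out[2, t] = "Q"
        elif is_ground:
            vm = va[t] if role_b == "G" else vb[t]
            sp = np.sqrt((vm**2).sum())
            if sp < eps_v:
                out[2, t] = "S"
            elif vm[2] > eps_a:
                out[2, t] = "MA"
            elif vm[2] < -eps_a:
                out[2, t] = "GC"
            else:
                out[2, t] = "FMT"
        else:
            rel_speed = np.sqrt(((va[t] - vb[t]) ** 2).sum())
            if speed_a[t] < eps_v and speed_b[t] < eps_v:
                out[2, t] = "HT"
            elif rel_speed < eps_v:
                out[2, t] = "MT"
            elif range_rate[t] < -eps_a:
                out[2, t] = "GC"
            elif range_rate[t] > eps_a:
                out[2, t] = "MA"
            else:
                out[2, t] = "S"
    return out


def evaluate_relations(
    trajectory, thresholds: RelationThresholds = DEFAULT_THRESHOLDS
) -> RelationTimeline:
    """Change points of every role pair and channel."""
    streams = _role_pair_streams(trajectory, thresholds)
    changes: dict[tuple[tuple[str, str], str], list[tuple[float, str]]] = {}
    times = trajectory.times
    for pair in PAIRS:
        arr = streams[pair]  # (3, T)
        for c, channel in enumerate(CHANNELS):
            run: list[tuple[float, str]] = [(float(times[0]), arr[c, 0])]
            for t in range(1, arr.shape[1]):
                if arr[c, t] != run[-1][1]:
                    run.append((float(times[t]), arr[c, t]))
            changes[(pair, channel)] = run
    return RelationTimeline(changes)


def _role_pair_streams(trajectory, thresholds) -> dict[tuple[str, str], np.ndarray]:
    roles = assign_roles(trajectory, thresholds)
    by_role = {r: oid for oid, (r, _) in roles.items()}
    n = len(trajectory.times)
    streams: dict[tuple[str, str], np.ndarray] = {}
    for pair in PAIRS:
        ra, rb = pair
        if ra in by_role and rb in by_role:
            streams[pair] = _pair_symbols(
                trajectory, thresholds, by_role[ra], by_role[rb], roles
            )
        else:
            blank = np.empty((3, n), dtype=object)
            blank[:] = "U"
            streams[pair] = blank
    return streams


# --------------------------------------------------------------------------
# ESEC extraction
# --------------------------------------------------------------------------


def extract_esec(
    trajectory,
    thresholds: RelationThresholds = DEFAULT_THRESHOLDS,
    action_label: str | None = None,
) -> ESECTable:
    """Segment a trajectory into its event columns.

    A column opens at the first cell change after the previous column and
    absorbs every change within ``fold_window`` seconds of its opening
    (taking each cell's state at the end of that window); this folds the
    relation cascade of a single physical change-moment -- a grasp, a
    placement -- into one event.  The canonical C0 precedes all events.
    """
    times = trajectory.times
    streams = _role_pair_streams(trajectory, thresholds)
    grid = np.empty((N_PAIRS, 3, len(times)), dtype=object)
    for i, pair in enumerate(PAIRS):
        grid[i, :, :] = streams[pair]

    changed = np.zeros(len(times), dtype=bool)
    changed[1:] = (grid[:, :, 1:] != grid[:, :, :-1]).any(axis=(0, 1))
    change_idx = np.flatnonzero(changed)

    columns = [grid[:, :, 0].copy()]
    stamps = [float(times[0])]
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    window = thresholds.fold_window + 0.5 * dt  # half-sample slack: the
    # boundary decision must not depend on float rounding of the grid
    k = 0
    while k < len(change_idx):
        start = change_idx[k]
        end = start
        k += 1
        while k < len(change_idx) and times[change_idx[k]] - times[start] <= window:
            end = change_idx[k]
            k += 1
        state = grid[:, :, end].copy()
        if not np.array_equal(state, columns[-1]):
            columns.append(state)
            stamps.append(float(times[start]))

    cells = np.stack(columns, axis=2)
    t0 = stamps[0]
    table = ESECTable(
        cells,
        np.array(stamps) - t0,
        action_label=action_label or getattr(trajectory, "action_label", None),
    )
    if not np.array_equal(table.column(0), start_column_array()):
        logger.warning("trajectory does not start in the canonical pre-action state")
    return table
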