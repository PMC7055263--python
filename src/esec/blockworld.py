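"""Synthetic block-world trajectories for the ten manipulation actions.

The generator emulates tabletop manipulations demonstrated with cube-like
objects: a red hand-cube enters the scene from above, manipulates one or
two blocks (plus, for cutting, a detachable piece) and leaves again, so
every action starts and ends with the hand free.  Ten action classes are
scripted:

    Hide, Cut, Chop, Take down, Put on top, Shake, Lay, Push, Uncover, Stir

Each class comes in seeded geometric variants: the scene layout is
translated on the tabletop and oriented along one of the four compass
axes, 0-3 distractor blocks are scattered outside the workspace, and the
approach/hold/gesture phase durations are jittered around per-class means
chosen to match average human demonstration timings.  Transport phases
run at fixed speeds so that the *sequence* of relational change-moments
is a class property while their *times* vary between variants.

Trajectories are sampled on a uniform 40 Hz grid as axis-aligned boxes
(position + constant half-extents); orientation is carried along for the
on-disk format but plays no role in the relational predicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

DT = 0.025  # s, sampling interval
_ENTRY_Z = 1.55  # hand spawn height: beyond the very-far radius of the scene
_EXIT_Z = 1.45

HAND_EXTENT = np.array([0.04, 0.04, 0.04])
GROUND_EXTENT = np.array([0.75, 0.75, 0.25])
GROUND_CENTER = np.array([0.0, 0.0, -0.25])

BLOCK = np.array([0.05, 0.05, 0.05])
COVER = np.array([0.09, 0.09, 0.09])  # hollow cover box: encloses a block
BASE = np.array([0.06, 0.06, 0.05])
TALL = np.array([0.045, 0.045, 0.07])
KNIFE = np.array([0.025, 0.025, 0.06])
SLAB = np.array([0.06, 0.06, 0.04])
PIECE = np.array([0.03, 0.03, 0.04])
BOWL = np.array([0.09, 0.09, 0.06])
SPOON = np.array([0.02, 0.02, 0.06])
DISTRACTOR = np.array([0.03, 0.03, 0.03])

ACTIONS = (
    "Hide",
    "Cut",
    "Chop",
    "Take down",
    "Put on top",
    "Shake",
    "Lay",
    "Push",
    "Uncover",
    "Stir",
)

#: average human-demonstration timings (mean, std), seconds: total action
#: duration and the moments at which the full relational encoding / the
#: touch-only encoding can predict the action class
ACTION_TIMING_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "Take down": {"duration": (11.7, 2.9), "esec": (3.3, 0.7), "sec": (3.3, 0.7)},
    "Put on top": {"duration": (12.0, 2.1), "esec": (8.0, 1.9), "sec": (9.2, 1.7)},
    "Shake": {"duration": (12.5, 2.1), "esec": (6.5, 1.2), "sec": (10.8, 1.7)},
    "Push": {"duration": (12.7, 1.9), "esec": (5.0, 1.1), "sec": (10.0, 1.6)},
    "Hide": {"duration": (13.8, 2.5), "esec": (8.3, 1.6), "sec": (10.3, 1.5)},
}

#: the five actions used in the two-agent chaining game
CHAIN_ACTIONS = ("Take down", "Put on top", "Shake", "Push", "Hide")


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    id: str
    role_hint: str  # hand | ground | block | distractor
    extent: np.ndarray


@dataclass
class Trajectory:
    """Timestamped poses of all scene objects on a common uniform grid."""

    times: np.ndarray
    positions: dict[str, np.ndarray]  # id -> (T, 3)
    extents: dict[str, np.ndarray]  # id -> (3,)
    role_hints: dict[str, str]
    action_label: str | None = None
    meta: dict = field(default_factory=dict)
    hand_id: str = "hand"
    ground_id: str = "ground"

    @property
    def ids(self) -> list[str]:
        return list(self.positions)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        # tolerance matches the 6-decimal on-disk format
        return (
            self.times.shape == other.times.shape
            and np.allclose(self.times, other.times, atol=1e-6)
            and set(self.ids) == set(other.ids)
            and all(
                np.allclose(self.positions[i], other.positions[i], atol=1e-6)
                for i in self.ids
            )
            and all(np.allclose(self.extents[i], other.extents[i]) for i in self.ids)
        )

    # -- on-disk form ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: time, object, x, y, z, qw, qx, qy, qz."""
        frames = []
        for oid in self.ids:
            pos = self.positions[oid]
            df = pd.DataFrame(
                {
                    "time": np.round(self.times, 6),
                    "object": oid,
                    "x": np.round(pos[:, 0], 6),
                    "y": np.round(pos[:, 1], 6),
                    "z": np.round(pos[:, 2], 6),
                    "qw": 1.0,
                    "qx": 0.0,
                    "qy": 0.0,
                    "qz": 0.0,
                }
            )
            frames.append(df)
        pd.concat(frames).to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "action_label": self.action_label,
            "hand_id": self.hand_id,
            "ground_id": self.ground_id,
            "frame": "viewer-centric, +z up, +x right, +y back; units m, s",
            "objects": {
                oid: {
                    "role_hint": self.role_hints[oid],
                    "extent": [float(v) for v in self.extents[oid]],
                }
                for oid in self.ids
            },
            "meta": self.meta,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.manifest(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_csv(cls, csv_path: str | Path, manifest_path: str | Path) -> "Trajectory":
        manifest = json.loads(Path(manifest_path).read_text(encoding="utf-8"))
        df = pd.read_csv(csv_path)
        times = np.sort(df["time"].unique())
        positions = {}
        for oid, grp in df.groupby("object"):
            grp = grp.sort_values("time")
            positions[str(oid)] = grp[["x", "y", "z"]].to_numpy(float)
        return cls(
            times=times,
            positions=positions,
            extents={
                oid: np.asarray(spec["extent"], float)
                for oid, spec in manifest["objects"].items()
            },
            role_hints={
                oid: spec["role_hint"] for oid, spec in manifest["objects"].items()
            },
            action_label=manifest.get("action_label"),
            meta=manifest.get("meta", {}),
            hand_id=manifest.get("hand_id", "hand"),
            ground_id=manifest.get("ground_id", "ground"),
        )


@dataclass
class VariantParams:
    """Per-variant geometric configuration."""

    center: np.ndarray  # layout translation on the tabletop (2,)
    axis: np.ndarray  # layout direction: one of the four compass axes (2,)
    n_distractors: int
    distractor_xy: np.ndarray  # (n, 2)
    phase_scale: dict[str, float]  # per-phase duration multipliers

    @classmethod
    def canonical(cls) -> "VariantParams":
        return cls(
            center=np.zeros(2),
            axis=np.array([1.0, 0.0]),
            n_distractors=0,
            distractor_xy=np.zeros((0, 2)),
            phase_scale={},
        )


# --------------------------------------------------------------------------
# waypoint rig
# --------------------------------------------------------------------------


class _Rig:
    """Piecewise-linear waypoint tracks, sampled onto the uniform grid."""

    def __init__(self) -> None:
        self.tracks: dict[str, list[tuple[float, np.ndarray]]] = {}
        self.extents: dict[str, np.ndarray] = {}
        self.hints: dict[str, str] = {}

    def add(self, oid: str, hint: str, extent: np.ndarray, pos) -> None:
        self.tracks[oid] = [(0.0, np.asarray(pos, float))]
        self.extents[oid] = np.asarray(extent, float)
        self.hints[oid] = hint

    def pos(self, oid: str) -> np.ndarray:
        return self.tracks[oid][-1][1]

    def time(self, oid: str) -> float:
        return self.tracks[oid][-1][0]

    def to(self, oid: str, t: float, pos) -> None:
        last_t = self.time(oid)
        if t < last_t - 1e-9:
            raise ValueError(f"waypoint for {oid} goes backwards in time")
        self.tracks[oid].append((float(t), np.asarray(pos, float)))

    def hold(self, oid: str, t: float) -> None:
        self.to(oid, t, self.pos(oid))

    def sample(self, label: str, meta: dict | None = None) -> Trajectory:
        t_end = max(track[-1][0] for track in self.tracks.values()) + 0.3
        n = int(round(t_end / DT)) + 1
        times = np.arange(n) * DT
        positions = {}
        for oid, track in self.tracks.items():
            ts = np.array([w[0] for w in track])
            ps = np.stack([w[1] for w in track])
            pos = np.empty((n, 3))
            for ax in range(3):
                pos[:, ax] = np.interp(times, ts, ps[:, ax])
            positions[oid] = pos
        return Trajectory(
            times=times,
            positions=positions,
            extents=dict(self.extents),
            role_hints=dict(self.hints),
            action_label=label,
            meta=meta or {},
        )


def _xyz(xy, z) -> np.ndarray:
    return np.array([xy[0], xy[1], z])


class _Phases:
    """Jittered phase-duration lookup; transport phases stay fixed.

    Durations are snapped to the sampling grid so that every scripted
    keyframe falls exactly on a sample and the event-column structure
    stays a class property across variants.
    """

    def __init__(self, scale: dict[str, float]):
        self.scale = scale

    def __call__(self, name: str, canonical: float) -> float:
        dur = canonical * self.scale.get(name, 1.0)
        return max(DT, round(dur / DT) * DT)


def _setup(params: VariantParams) -> _Rig:
    rig = _Rig()
    rig.add("ground", "ground", GROUND_EXTENT, GROUND_CENTER)
    for k in range(params.n_distractors):
        xy = params.distractor_xy[k]
        rig.add(f"distractor{k + 1}", "distractor", DISTRACTOR, _xyz(xy, DISTRACTOR[2]))
    return rig


def _hand_entry(rig: _Rig, ph: _Phases, above_xy, grab_z: float) -> float:
    """Vertical hand descent onto the first object; returns grab time."""
    t_grab = ph("enter", 2.5)
    rig.add("hand", "hand", HAND_EXTENT, _xyz(above_xy, _ENTRY_Z))
    rig.to("hand", t_grab, _xyz(above_xy, grab_z))
    return t_grab


def _hand_exit(rig: _Rig, t0: float, speed: float) -> None:
    """Slow vertical drift out of the scene (same x, y)."""
    p = rig.pos("hand")
    dur = (_EXIT_Z - p[2]) / speed
    rig.to("hand", t0 + dur, _xyz(p[:2], _EXIT_Z))


def _on_top_z(lower_top: float, ext: np.ndarray) -> float:
    return lower_top + ext[2]


# --------------------------------------------------------------------------
# the ten action scripts
# --------------------------------------------------------------------------
#
# Shared choreography: the hand enters vertically above the first object,
# grasps it (a short hold), transports it (fixed-speed slant with a final
# fast vertical settle where a stacking contact must be made), rests,
# releases and drifts out vertically.  Object-specific middles -- covering,
# stacking, striking, stirring, pushing -- differ per script.


def _hide(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p2 = prm.center  # covered block
    p1 = prm.center + 0.4 * u  # cover
    rig.add("block", "block", BLOCK, _xyz(p2, BLOCK[2]))
    rig.add("cover", "block", COVER, _xyz(p1, COVER[2]))
    grab_z = 2 * COVER[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)  # grab: C2
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    # one-column ascending transport to the clearance point above the block
    z_clear = 0.27
    t3 = t2 + 1.5
    for oid, dz in (("hand", COVER[2] + HAND_EXTENT[2]), ("cover", 0.0)):
        rig.hold(oid, t2)
        rig.to(oid, t3, _xyz(p2, z_clear + dz))
    # fast settle: the hollow cover ends up around the block, resting on
    # the ground and hiding it
    t4 = t3 + 0.1
    rig.to("cover", t4, _xyz(p2, COVER[2]))
    rig.to("hand", t4, _xyz(p2, grab_z))
    t5 = t4 + ph("rest", 0.6)
    rig.hold("hand", t5)
    rig.hold("cover", t5)
    _hand_exit(rig, t5, speed=0.18)


def _put_on_top(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p2 = prm.center
    p1 = prm.center + 0.4 * u
    rig.add("base", "block", BLOCK, _xyz(p2, BLOCK[2]))
    rig.add("block", "block", BLOCK, _xyz(p1, BLOCK[2]))
    grab_z = 2 * BLOCK[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_clear = 0.26
    t3 = t2 + 1.5
    for oid, dz in (("hand", BLOCK[2] + HAND_EXTENT[2]), ("block", 0.0)):
        rig.hold(oid, t2)
        rig.to(oid, t3, _xyz(p2, z_clear + dz))
    z_on = _on_top_z(2 * BLOCK[2], BLOCK)
    t4 = t3 + 0.1
    rig.to("block", t4, _xyz(p2, z_on))
    rig.to("hand", t4, _xyz(p2, z_on + BLOCK[2] + HAND_EXTENT[2]))
    t5 = t4 + ph("rest", 0.6)
    rig.hold("hand", t5)
    rig.hold("block", t5)
    _hand_exit(rig, t5, speed=0.28)


def _take_down(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p2 = prm.center
    target = prm.center + 0.45 * u
    base_top = 2 * BASE[2]
    rig.add("base", "block", BASE, _xyz(p2, BASE[2]))
    rig.add("block", "block", BLOCK, _xyz(p2, base_top + BLOCK[2]))
    grab_z = base_top + 2 * BLOCK[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p2, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    # fast vertical lift off the base (one column), then a descending slant
    z_lift = 0.26
    t3 = t2 + 0.1
    rig.hold("block", t2)
    rig.to("block", t3, _xyz(p2, z_lift))
    rig.to("hand", t3, _xyz(p2, z_lift + BLOCK[2] + HAND_EXTENT[2]))
    t4 = t3 + 1.4
    rig.to("block", t4, _xyz(target, BLOCK[2]))
    rig.to("hand", t4, _xyz(target, 2 * BLOCK[2] + HAND_EXTENT[2]))
    t5 = t4 + ph("rest", 0.5)
    rig.hold("hand", t5)
    rig.hold("block", t5)
    _hand_exit(rig, t5, speed=0.155)


def _shake(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    p1 = prm.center
    rig.add("block", "block", BLOCK, _xyz(p1, BLOCK[2]))
    grab_z = 2 * BLOCK[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_hi, z_lo = 0.30, 0.16
    t3 = t2 + 0.5  # slow lift aloft
    rig.hold("block", t2)
    rig.to("block", t3, _xyz(p1, z_hi))
    rig.to("hand", t3, _xyz(p1, z_hi + BLOCK[2] + HAND_EXTENT[2]))
    t4 = t3 + ph("aloft", 2.3)  # halt aloft before the gesture
    rig.hold("block", t4)
    rig.hold("hand", t4)
    tt = t4
    for z in (z_lo, z_hi, z_lo, z_hi):  # two full vertical shake cycles
        tt += ph("stroke", 0.7)
        rig.to("block", tt, _xyz(p1, z))
        rig.to("hand", tt, _xyz(p1, z + BLOCK[2] + HAND_EXTENT[2]))
    t5 = tt + 0.1  # fast settle back onto the ground
    rig.to("block", t5, _xyz(p1, BLOCK[2]))
    rig.to("hand", t5, _xyz(p1, grab_z))
    t6 = t5 + ph("rest", 0.5)
    rig.hold("block", t6)
    rig.hold("hand", t6)
    _hand_exit(rig, t6, speed=0.28)


def _lay(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p1 = prm.center
    target = prm.center + 0.4 * u
    rig.add("block", "block", TALL, _xyz(p1, TALL[2]))
    grab_z = 2 * TALL[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_hi = 0.32
    t3 = t2 + 0.5
    rig.hold("block", t2)
    rig.to("block", t3, _xyz(p1, z_hi))
    rig.to("hand", t3, _xyz(p1, z_hi + TALL[2] + HAND_EXTENT[2]))
    t4 = t3 + ph("aloft", 2.3)  # same pre-gesture halt as a shake
    rig.hold("block", t4)
    rig.hold("hand", t4)
    t5 = t4 + 1.2  # descending slant: set the block down on its side
    rig.to("block", t5, _xyz(target, TALL[2]))
    rig.to("hand", t5, _xyz(target, grab_z))
    t6 = t5 + ph("rest", 0.5)
    rig.hold("block", t6)
    rig.hold("hand", t6)
    _hand_exit(rig, t6, speed=0.30)


def _push(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p1 = prm.center
    rig.add("block", "block", BLOCK, _xyz(p1, BLOCK[2]))
    side_gap = BLOCK[0] + HAND_EXTENT[0] + 0.105  # lateral stand-off
    start_xy = p1 - side_gap * u
    t = ph("enter", 5.0)
    rig.add("hand", "hand", HAND_EXTENT, _xyz(start_xy, _ENTRY_Z))
    rig.to("hand", t, _xyz(start_xy, BLOCK[2]))  # descend beside the block
    t2 = t + 0.8  # horizontal approach to contact
    contact_xy = p1 - (BLOCK[0] + HAND_EXTENT[0] + 0.004) * u
    rig.to("hand", t2, _xyz(contact_xy, BLOCK[2]))
    t3 = t2 + ph("hold", 0.3)
    rig.hold("hand", t3)
    t4 = t3 + ph("push", 1.2)  # push the block 0.35 m
    rig.hold("block", t3)
    rig.to("block", t4, _xyz(p1 + 0.35 * u, BLOCK[2]))
    rig.to("hand", t4, _xyz(contact_xy + 0.35 * u, BLOCK[2]))
    # diagonal retreat: back along the push axis while rising
    p = rig.pos("hand")
    dur = (_EXIT_Z - p[2]) / 0.20
    rig.to("hand", t4 + dur, _xyz(p[:2] - 0.24 * dur * u, _EXIT_Z))


def _cut_like(rig: _Rig, ph: _Phases, prm: VariantParams, chop: bool) -> None:
    u = prm.axis
    p2 = prm.center  # slab to be cut
    p1 = prm.center + 0.4 * u  # knife block
    slab_top = 2 * SLAB[2]
    chip_dir = -u  # the chip breaks off away from the knife's side
    rig.add("slab", "block", SLAB, _xyz(p2, SLAB[2]))
    rig.add(
        "piece", "block", PIECE, _xyz(p2 + (SLAB[0] + PIECE[0]) * chip_dir, PIECE[2])
    )
    rig.add("knife", "block", KNIFE, _xyz(p1, KNIFE[2]))
    grab_z = 2 * KNIFE[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_clear = 0.25
    t3 = t2 + 1.2  # ascending transport above the slab
    for oid, dz in (("hand", KNIFE[2] + HAND_EXTENT[2]), ("knife", 0.0)):
        rig.hold(oid, t2)
        rig.to(oid, t3, _xyz(p2, z_clear + dz))
    z_on = slab_top + KNIFE[2]

    def strike(t_start: float, split: bool) -> float:
        td = t_start + 0.1  # fast descent into contact
        rig.to("knife", td, _xyz(p2, z_on))
        rig.to("hand", td, _xyz(p2, z_on + KNIFE[2] + HAND_EXTENT[2]))
        if split:
            _slide_piece(td)
        th = td + ph("dwell", 0.3)
        rig.hold("knife", th)
        rig.hold("hand", th)
        tu = th + 0.1
        rig.to("knife", tu, _xyz(p2, z_clear))
        rig.to("hand", tu, _xyz(p2, z_clear + KNIFE[2] + HAND_EXTENT[2]))
        ta = tu + ph("aloft", 0.4)
        rig.hold("knife", ta)
        rig.hold("hand", ta)
        return ta

    def _slide_piece(t_split: float) -> None:
        xy = rig.pos("piece")[:2]
        rig.hold("piece", t_split)
        rig.to("piece", t_split + ph("slide", 0.4), _xyz(xy + 0.08 * chip_dir, PIECE[2]))

    if chop:
        t_free = strike(t3, split=False)
        t_free = strike(t_free, split=True)
    else:
        # single slow press through the slab, the piece separating midway
        td = t3 + 0.1
        rig.to("knife", td, _xyz(p2, z_on))
        rig.to("hand", td, _xyz(p2, z_on + KNIFE[2] + HAND_EXTENT[2]))
        tp = td + ph("press", 1.0)
        rig.to("knife", tp, _xyz(p2, z_on - 0.035))
        rig.to("hand", tp, _xyz(p2, z_on - 0.035 + KNIFE[2] + HAND_EXTENT[2]))
        _slide_piece(td + ph("split_delay", 0.5))
        tu = tp + 0.1
        rig.to("knife", tu, _xyz(p2, z_clear))
        rig.to("hand", tu, _xyz(p2, z_clear + KNIFE[2] + HAND_EXTENT[2]))
        t_free = tu
    # return the knife to its start position and let go
    t_back = t_free + 1.2
    rig.to("knife", t_back, _xyz(p1, KNIFE[2]))
    rig.to("hand", t_back, _xyz(p1, grab_z))
    t5 = t_back + ph("rest", 0.5)
    rig.hold("knife", t5)
    rig.hold("hand", t5)
    _hand_exit(rig, t5, speed=0.45)


def _cut(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    _cut_like(rig, ph, prm, chop=False)


def _chop(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    _cut_like(rig, ph, prm, chop=True)


def _uncover(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p2 = prm.center
    target = prm.center + 0.45 * u
    rig.add("block", "block", BLOCK, _xyz(p2, BLOCK[2]))
    rig.add("cover", "block", COVER, _xyz(p2, COVER[2]))  # hides the block
    grab_z = 2 * COVER[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p2, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_lift = 0.27
    t3 = t2 + 0.1  # fast vertical lift off the hidden block
    rig.hold("cover", t2)
    rig.to("cover", t3, _xyz(p2, z_lift))
    rig.to("hand", t3, _xyz(p2, z_lift + COVER[2] + HAND_EXTENT[2]))
    t3b = t3 + ph("reveal", 0.6)  # hold the cover aloft over the revealed block
    rig.hold("cover", t3b)
    rig.hold("hand", t3b)
    t4 = t3b + 1.4  # descending slant to the ground beside
    rig.to("cover", t4, _xyz(target, COVER[2]))
    rig.to("hand", t4, _xyz(target, 2 * COVER[2] + HAND_EXTENT[2]))
    t5 = t4 + ph("rest", 0.5)
    rig.hold("hand", t5)
    rig.hold("cover", t5)
    _hand_exit(rig, t5, speed=0.15)


def _stir(rig: _Rig, ph: _Phases, prm: VariantParams) -> None:
    u = prm.axis
    p2 = prm.center  # bowl
    p1 = prm.center + 0.4 * u  # spoon
    r = 0.02  # stirring radius
    rig.add("bowl", "block", BOWL, _xyz(p2, BOWL[2]))
    rig.add("spoon", "block", SPOON, _xyz(p1, SPOON[2]))
    grab_z = 2 * SPOON[2] + HAND_EXTENT[2]
    t = _hand_entry(rig, ph, p1, grab_z)
    t2 = t + ph("hold", 0.5)
    rig.hold("hand", t2)
    z_clear = 0.30
    entry_xy = p2 + r * u  # insertion point lies on the stirring circle
    t3 = t2 + 1.2
    for oid, dz in (("hand", SPOON[2] + HAND_EXTENT[2]), ("spoon", 0.0)):
        rig.hold(oid, t2)
        rig.to(oid, t3, _xyz(entry_xy, z_clear + dz))
    z_in = 0.10  # spoon tip inside the bowl volume
    t4 = t3 + 0.1
    rig.to("spoon", t4, _xyz(entry_xy, z_in))
    rig.to("hand", t4, _xyz(entry_xy, z_in + SPOON[2] + HAND_EXTENT[2]))
    # stirring: two revolutions around the bowl centre; waypoint steps lie
    # on the sampling grid so variant tempi keep identical event structure
    phase0 = np.arctan2(u[1], u[0])
    step_dur = max(DT, round(ph("stir", 1.5) / 12.0 / DT) * DT)
    tt = t4
    for step in range(1, 25):
        tt = t4 + step * step_dur
        ang = phase0 + 2 * np.pi * step / 12.0
        xy = p2 + r * np.array([np.cos(ang), np.sin(ang)])
        rig.to("spoon", tt, _xyz(xy, z_in))
        rig.to("hand", tt, _xyz(xy, z_in + SPOON[2] + HAND_EXTENT[2]))
    t5 = tt + 0.1  # withdraw vertically
    out_xy = rig.pos("spoon")[:2]
    rig.to("spoon", t5, _xyz(out_xy, z_clear))
    rig.to("hand", t5, _xyz(out_xy, z_clear + SPOON[2] + HAND_EXTENT[2]))
    t6 = t5 + 1.3  # descending slant back to the spoon rest
    rig.to("spoon", t6, _xyz(p1, SPOON[2]))
    rig.to("hand", t6, _xyz(p1, grab_z))
    t7 = t6 + ph("rest", 0.5)
    rig.hold("spoon", t7)
    rig.hold("hand", t7)
    _hand_exit(rig, t7, speed=0.25)


_SCRIPTS: dict[str, Callable[[_Rig, _Phases, VariantParams], None]] = {
    "Hide": _hide,
    "Put on top": _put_on_top,
    "Take down": _take_down,
    "Shake": _shake,
    "Lay": _lay,
    "Push": _push,
    "Cut": _cut,
    "Chop": _chop,
    "Uncover": _uncover,
    "Stir": _stir,
}

#: per-action entry durations tuned so the class-defining change-moment
#: falls at the human-demonstration average prediction moment
_ENTER_CANONICAL = {
    "Hide": 6.3,
    "Put on top": 6.0,
    "Take down": 3.3,
    "Shake": 2.5,
    "Lay": 2.5,
    "Push": 5.0,
    "Cut": 2.5,
    "Chop": 2.5,
    "Uncover": 2.5,
    "Stir": 2.5,
}

#: phases whose durations are jittered per variant (transport phases are
#: not: their fixed speeds make the event-column structure a class property)
_JITTERED_PHASES = (
    "enter",
    "hold",
    "rest",
    "aloft",
    "reveal",
    "stroke",
    "push",
    "stir",
)


def normalize_action(name: str) -> str:
    """Case/spacing-insensitive action-class lookup."""
    key = name.strip().lower().replace("_", " ").replace("-", " ")
    for action in ACTIONS:
        if action.lower() == key:
            return action
    raise KeyError(
        f"unknown action class {name!r}; valid classes: {', '.join(ACTIONS)}"
    )


def _variant_rng(seed: int, action: str, variant: int) -> np.random.Generator:
    """Independent per-(class, variant) stream from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(ACTIONS.index(action), variant))
    )


def sample_variant_params(
    rng: np.random.Generator, jitter: bool = True
) -> VariantParams:
    """Draw a geometric variant: layout translation and axis, distractor
    count/placement, and phase-duration jitters (a per-phase factor around
    a global tempo factor)."""
    center = rng.uniform(-0.18, 0.18, size=2)
    axis = np.asarray(
        [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)][int(rng.integers(4))]
    )
    n_d = int(rng.integers(0, 4))
    # distractors stay clear of the strip of tabletop the action uses
    seg_a, seg_b = center - 0.30 * axis, center + 0.55 * axis
    placed = []
    while len(placed) < n_d:
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.52, 0.70)
        q = np.array([rad * np.cos(ang), rad * np.sin(ang)])
        seg = seg_b - seg_a
        u_proj = np.clip(np.dot(q - seg_a, seg) / np.dot(seg, seg), 0.0, 1.0)
        if np.linalg.norm(q - (seg_a + u_proj * seg)) >= 0.24:
            placed.append(q)
    distractor_xy = np.stack(placed) if placed else np.zeros((0, 2))
    scale = {}
    if jitter:
        tempo = float(np.clip(rng.normal(1.0, 0.18), 0.7, 1.4))
        for phase in _JITTERED_PHASES:
            scale[phase] = tempo * float(rng.uniform(0.92, 1.08))
    return VariantParams(
        center=center,
        axis=np.asarray(axis, float),
        n_distractors=n_d,
        distractor_xy=distractor_xy,
        phase_scale=scale,
    )


def generate_action(
    action_class: str,
    seed: int = 0,
    variant_params: VariantParams | None = None,
    variant: int = 0,
) -> Trajectory:
    """One scripted trajectory of the given class; deterministic for a
    fixed (class, seed, variant, params) tuple."""
    action = normalize_action(action_class)
    if variant_params is None:
        variant_params = sample_variant_params(_variant_rng(seed, action, variant))
    rig = _setup(variant_params)

    class _ClassPhases(_Phases):
        # per-class entry duration; other canonical durations come from
        # the scripts themselves
        def __call__(self, name: str, canonical: float) -> float:
            if name == "enter":
                canonical = _ENTER_CANONICAL[action]
            return super().__call__(name, canonical)

    _SCRIPTS[action](rig, _ClassPhases(dict(variant_params.phase_scale)), variant_params)
    traj = rig.sample(
        action,
        meta={
            "seed": seed,
            "variant": variant,
            "axis": [float(v) for v in variant_params.axis],
            "n_distractors": variant_params.n_distractors,
        },
    )
    return traj


def generate_dataset(
    seed: int = 0, variants_per_class: int = 30, classes: tuple[str, ...] = ACTIONS
) -> list[Trajectory]:
    """The labeled action corpus: every class in ``classes`` times
    ``variants_per_class`` seeded geometric variants (10 x 30 = 300 by
    default)."""
    out = []
    for action in classes:
        for v in range(variants_per_class):
            out.append(generate_action(action, seed=seed, variant=v))
    return out


# --------------------------------------------------------------------------
# action timing distributions
# --------------------------------------------------------------------------


def sample_action_timing(
    action_class: str,
    rng: np.random.Generator | None = None,
    mode: str = "sample",
    table: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> tuple[float, float, float]:
    """(duration, full-encoding prediction moment, touch-only prediction
    moment) in seconds for one of the chain actions.

    ``mode='mean'`` returns the table averages; ``mode='sample'`` draws
    duration from its Gaussian (truncated positive) and each prediction
    moment from its Gaussian truncated to (0, duration).
    """
    table = table if table is not None else ACTION_TIMING_TABLE
    try:
        action = normalize_action(action_class)
    except KeyError:
        action = action_class
    if action not in table:
        raise KeyError(
            f"no timing distribution for {action_class!r}; available: "
            f"{', '.join(table)}"
        )
    row = table[action]
    if mode == "mean":
        return row["duration"][0], row["esec"][0], row["sec"][0]
    if mode != "sample":
        raise ValueError("mode must be 'mean' or 'sample'")
    if rng is None:
        rng = np.random.default_rng()

    def _trunc(mean: float, std: float, lo: float, hi: float) -> float:
        # rejection sampling: the bounds sit far out in the tails for the
        # tabled parameters, so the first draw is almost always accepted
        for _ in range(1000):
            x = float(rng.normal(mean, std))
            if lo < x < hi:
                return x
        return float(np.clip(mean, lo + 1e-9, hi - 1e-9))  # pragma: no cover

    mu, sd = row["duration"]
    duration = _trunc(mu, sd, 0.0, np.inf)
    esec = _trunc(*row["esec"], 0.0, duration)
    sec = _trunc(*row["sec"], 0.0, duration)
    return duration, esec, sec
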