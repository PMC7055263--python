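"""Online action prediction by cumulative class elimination.

Calibration (step 1): each action class receives an individual
self-similarity threshold Theta_i -- the average pairwise similarity of
m randomly chosen member encodings, repeated and averaged (m = 20,
20 repeats: 20 x 190 = 3800 pairwise values by default).  A single
global threshold would be wrong because classes differ in their internal
variability.

Prediction (step 2): the new action's table gamma grows column by
column.  C0 is the shared pre-set start column and is skipped.  After
each new column Ck the prefix C1..Ck is compared against equally long
prefixes of sampled members of every class still in the running; classes
whose average similarity falls below their own Theta_i are eliminated
for good.  When a single class remains the action is recognized and the
prediction moment T(gamma) is that column's timestamp; predictive power
is P = (1 - T/Tot) * 100 with Tot the total action time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ESECTable
from .similarity import encode_cells, sim_codes


@dataclass
class ClassModel:
    """A named action class: member encodings plus its threshold."""

    name: str
    members: list[ESECTable]
    threshold: float
    calibration: dict = field(default_factory=dict)


@dataclass
class PredictionResult:
    """Outcome of streaming one action against a set of class models."""

    predicted: str  # class name, "unrecognized" or "ambiguous"
    deciding_column: int | None
    prediction_moment: float | None  # T(gamma), s
    total_time: float  # Tot(gamma), s
    predictive_power: float | None  # P, percent
    survivor_trace: list[list[str]]  # surviving classes after each column
    survivors: list[str] = field(default_factory=list)

    @property
    def recognized(self) -> bool:
        return self.predicted not in ("unrecognized", "ambiguous")


def predictive_power(t_prediction: float, t_total: float) -> float:
    """P = (1 - T/Tot) * 100, the percentage of the action's duration
    still ahead when the prediction is made."""
    if t_total <= 0:
        raise ValueError("total time must be positive")
    if not 0 <= t_prediction <= t_total:
        raise ValueError("prediction moment must lie within [0, total time]")
    return (1.0 - t_prediction / t_total) * 100.0


def column_offset(observer_column: int, reference_column: int) -> int:
    """Signed event-column offset of an observer's prediction relative to
    the encoding's prediction column (0 = same event, positive = later)."""
    if observer_column < 1 or reference_column < 1:
        raise ValueError("event-column indices start at 1")
    return observer_column - reference_column


def calibrate_threshold(
    members: list[ESECTable],
    m: int = 20,
    repeats: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict]:
    """Self-similarity threshold Theta for one class.

    Each repeat draws ``min(m, len(members))`` members without
    replacement and computes all pairwise similarities; Theta is the
    grand mean over all repeats.  Returns (Theta, calibration metadata).
    """
    if len(members) < 2:
        raise ValueError("threshold calibration needs at least 2 class members")
    if rng is None:
        rng = np.random.default_rng()
    m_eff = min(m, len(members))
    codes = [encode_cells(t)[:, :, 1:] for t in members]  # C0 is pre-set
    values: list[float] = []
    for _ in range(repeats):
        idx = rng.choice(len(members), size=m_eff, replace=False)
        for a in range(m_eff):
            for b in range(a + 1, m_eff):
                values.append(sim_codes(codes[idx[a]], codes[idx[b]]))
    theta = float(np.mean(values))
    meta = {
        "m": m_eff,
        "repeats": repeats,
        "pairs_per_repeat": m_eff * (m_eff - 1) // 2,
        "n_values": len(values),
    }
    return theta, meta


def train_models(
    members_by_class: dict[str, list[ESECTable]],
    m: int = 20,
    repeats: int = 20,
    rng: np.random.Generator | None = None,
) -> dict[str, ClassModel]:
    """Calibrate a ClassModel per action class."""
    if rng is None:
        rng = np.random.default_rng()
    models = {}
    for name in sorted(members_by_class):
        members = members_by_class[name]
        if len(members) == 1:
            # a singleton class is perfectly self-similar by definition
            theta, meta = 100.0, {"m": 1, "repeats": 0, "n_values": 0}
        else:
            theta, meta = calibrate_threshold(members, m=m, repeats=repeats, rng=rng)
        models[name] = ClassModel(name, list(members), theta, meta)
    return models


def _prefix_codes(table: ESECTable, k: int) -> np.ndarray:
    """Integer codes of event columns C1..Ck, capped at the table's length
    (shorter members are later padded by the similarity rule)."""
    return encode_cells(table)[:, :, 1 : min(k, table.n_columns - 1) + 1]


def predict_online(
    gamma: ESECTable,
    models: dict[str, ClassModel] | list[ClassModel],
    comparison_count: int = 20,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    total_time: float | None = None,
) -> PredictionResult:
    """Stream ``gamma`` column by column against the class models.

    ``deterministic=True`` compares against every member instead of a
    random sample of ``comparison_count``.  ``total_time`` defaults to
    gamma's final column timestamp (the moment the hand leaves the
    scene).
    """
    if isinstance(models, list):
        models = {mdl.name: mdl for mdl in models}
    if len(models) < 2:
        raise ValueError("need at least two class models to discriminate")
    if gamma.n_columns < 2:
        raise ValueError("gamma has no event columns beyond C0")
    if rng is None:
        rng = np.random.default_rng()
    tot = float(total_time) if total_time is not None else float(gamma.timestamps[-1])

    surviving = sorted(models)
    trace: list[list[str]] = []
    for k in range(1, gamma.n_columns):
        g_pref = _prefix_codes(gamma, k)
        still = []
        for name in surviving:
            mdl = models[name]
            if deterministic or len(mdl.members) <= comparison_count:
                sample = mdl.members
            else:
                idx = rng.choice(len(mdl.members), size=comparison_count, replace=False)
                sample = [mdl.members[i] for i in idx]
            mean_sim = float(
                np.mean([sim_codes(g_pref, _prefix_codes(mem, k)) for mem in sample])
            )
            if mean_sim >= mdl.threshold - 1e-9:
                still.append(name)
        surviving = still
        trace.append(list(surviving))
        if len(surviving) == 1:
            t_pred = float(gamma.timestamps[k])
            return PredictionResult(
                predicted=surviving[0],
                deciding_column=k,
                prediction_moment=t_pred,
                total_time=tot,
                predictive_power=predictive_power(t_pred, tot) if tot > 0 else None,
                survivor_trace=trace,
                survivors=surviving,
            )
        if not surviving:
            return PredictionResult(
                predicted="unrecognized",
                deciding_column=k,
                prediction_moment=None,
                total_time=tot,
                predictive_power=None,
                survivor_trace=trace,
                survivors=[],
            )
    return PredictionResult(
        predicted="ambiguous",
        deciding_column=None,
        prediction_moment=None,
        total_time=tot,
        predictive_power=None,
        survivor_trace=trace,
        survivors=surviving,
    )
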