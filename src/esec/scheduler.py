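"""Predictive two-agent action chaining.

Two agents alternate through a fixed sequence of actions.  An agent may
start its action only once it is free *and* the predecessor action has
become predictable (its prediction moment has passed):

    start_k = max(end of the same agent's previous action,
                  start_{k-1} + prediction_moment_{k-1}),   start_1 = 0.

The interleaved completion time is compared against the sequential
baseline (the plain sum of durations); the chain-level predictive power
is the percentage of the baseline saved:

    chain_P = savings / sequential_total * 100.

A Monte-Carlo driver samples per-action (duration, prediction moment)
pairs from the timing distributions measured on human demonstrations and
accumulates the completion-time distribution over sequence orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .blockworld import CHAIN_ACTIONS, sample_action_timing


@dataclass(frozen=True)
class ActionTiming:
    """Duration and prediction moment of one action, seconds."""

    name: str
    duration: float
    prediction_moment: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"{self.name}: duration must be positive")
        if not 0 < self.prediction_moment <= self.duration:
            raise ValueError(
                f"{self.name}: prediction moment must lie in (0, duration]"
            )


@dataclass
class ScheduledAction:
    name: str
    agent: int
    start: float
    end: float
    prediction_available: float


@dataclass
class ChainSchedule:
    actions: list[ScheduledAction]
    interleaved_total: float
    sequential_total: float

    @property
    def savings(self) -> float:
        return self.sequential_total - self.interleaved_total

    @property
    def chain_p(self) -> float:
        """Chain-level predictive power, percent of the baseline saved."""
        return self.savings / self.sequential_total * 100.0


def schedule_chain(
    sequence: list[str], timings: dict[str, ActionTiming] | list[ActionTiming]
) -> ChainSchedule:
    """Timing diagram of two alternating agents over ``sequence``."""
    if isinstance(timings, list):
        timings = {t.name: t for t in timings}
    if len(sequence) < 2:
        raise ValueError("a chain needs at least two actions")
    missing = [name for name in sequence if name not in timings]
    if missing:
        raise KeyError(f"no timing for: {', '.join(missing)}")

    scheduled: list[ScheduledAction] = []
    free_at = {1: 0.0, 2: 0.0}  # when each agent finishes its previous action
    prev_pred_available = 0.0
    for k, name in enumerate(sequence):
        agent = 1 + k % 2
        timing = timings[name]
        start = max(free_at[agent], prev_pred_available)
        end = start + timing.duration
        pred = start + timing.prediction_moment
        scheduled.append(ScheduledAction(name, agent, start, end, pred))
        free_at[agent] = end
        prev_pred_available = pred
    return ChainSchedule(
        actions=scheduled,
        interleaved_total=max(a.end for a in scheduled),
        sequential_total=sum(timings[name].duration for name in sequence),
    )


def simulate_chain_distribution(
    actions: tuple[str, ...] = CHAIN_ACTIONS,
    mode: str = "esec",
    n_samples: int = 10_000,
    orderings: str = "all",
    rng: np.random.Generator | None = None,
    timing_table: dict | None = None,
) -> dict:
    """Monte-Carlo distribution of chain completion times.

    Per sample, an ordering of ``actions`` is chosen (cycling through all
    permutations for ``orderings='all'``, or keeping the given order for
    ``'fixed'``), per-action (duration, prediction moment) pairs are drawn
    from the timing distributions, and the chain is scheduled.  ``mode``
    selects the prediction moments: ``'esec'`` (full encoding), ``'sec'``
    (touch-only encoding) or ``'none'`` (no prediction: the sequential
    baseline).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("esec", "sec", "none"):
        raise ValueError("mode must be 'esec', 'sec' or 'none'")
    if orderings not in ("all", "fixed"):
        raise ValueError("orderings must be 'all' or 'fixed'")
    if rng is None:
        rng = np.random.default_rng()
    orders = (
        list(permutations(actions)) if orderings == "all" else [tuple(actions)]
    )
    totals = np.empty(n_samples)
    for i in range(n_samples):
        order = orders[i % len(orders)]
        timings = {}
        for name in order:
            duration, t_esec, t_sec = sample_action_timing(
                name, rng=rng, table=timing_table
            )
            if mode == "none":
                pred = duration
            else:
                pred = min(t_esec if mode == "esec" else t_sec, duration)
            timings[name] = ActionTiming(name, duration, pred)
        if mode == "none":
            totals[i] = sum(t.duration for t in timings.values())
        else:
            totals[i] = schedule_chain(list(order), timings).interleaved_total
    hist, edges = np.histogram(totals, bins=40)
    return {
        "mode": mode,
        "n_samples": n_samples,
        "mean": float(totals.mean()),
        "std": float(totals.std(ddof=1)) if n_samples > 1 else 0.0,
        "min": float(totals.min()),
        "max": float(totals.max()),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        "totals": totals,
    }
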