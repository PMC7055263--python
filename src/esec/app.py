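"""Configuration, packaged fixtures and the end-to-end experiment runner.

The package ships one canonical ESEC table per action class (generated
from the scripted block world at variant-free parameters; only their
structure, not any recorded human data, stands behind them) and the
average human-demonstration timing table used by the scheduler.
"""

from __future__ import annotations

import json
import logging
import sys
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__, blockworld, predictor, relations
from .core import ESECTable, read_esec

logger = logging.getLogger(__name__)

_FIXTURE_SLUGS = {a: a.lower().replace(" ", "_") for a in blockworld.ACTIONS}


@dataclass
class RunConfig:
    """Serializable configuration of one end-to-end run."""

    seed: int = 0
    variants_per_class: int = 30
    calibration_m: int = 20
    calibration_repeats: int = 20
    comparison_count: int = 20
    deterministic: bool = False
    sec_mode: bool = False
    chain_samples: int = 10_000
    thresholds: dict = field(
        default_factory=lambda: asdict(relations.DEFAULT_THRESHOLDS)
    )

    def relation_thresholds(self) -> relations.RelationThresholds:
        return relations.RelationThresholds(**self.thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def fixture_path(action: str) -> Path:
    action = blockworld.normalize_action(action)
    res = resources.files("esec").joinpath(
        f"data/fixtures/{_FIXTURE_SLUGS[action]}.json"
    )
    return Path(str(res))


def load_fixture(action: str) -> ESECTable:
    """The packaged canonical ESEC table of one action class."""
    table = read_esec(fixture_path(action), format="json")
    table.action_label = blockworld.normalize_action(action)
    return table


def load_all_fixtures() -> dict[str, ESECTable]:
    return {a: load_fixture(a) for a in blockworld.ACTIONS}


def canonical_models() -> dict[str, predictor.ClassModel]:
    """Singleton class models from the packaged canonical tables (a
    singleton class is perfectly self-similar: threshold 100)."""
    return {
        a: predictor.ClassModel(a, [t], 100.0, {"m": 1, "repeats": 0})
        for a, t in load_all_fixtures().items()
    }


def timing_table() -> dict[str, dict[str, tuple[float, float]]]:
    """The packaged per-action timing table (means and standard
    deviations of duration and prediction moments, seconds)."""
    res = resources.files("esec").joinpath("data/action_timing.yaml")
    raw = yaml.safe_load(res.read_text(encoding="utf-8"))
    return {
        name: {k: tuple(v) for k, v in row.items()} for name, row in raw.items()
    }


# --------------------------------------------------------------------------
# end-to-end experiment
# --------------------------------------------------------------------------


def run_end_to_end(config: RunConfig | None = None) -> dict:
    """Generate the synthetic corpus, extract, calibrate, classify, and
    simulate the two-agent chain distribution; reproducible from
    (config, seed)."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    thresholds = config.relation_thresholds()
    report: dict = {"version": __version__, "config": asdict(config)}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("generate+extract")
        trajs = blockworld.generate_dataset(
            seed=config.seed, variants_per_class=config.variants_per_class
        )
        tables = [
            relations.extract_esec(t, thresholds, action_label=t.action_label)
            for t in trajs
        ]
        totals = [float(t.timestamps[-1]) for t in tables]
        if config.sec_mode:
            sec_tables = []
            for t in tables:
                s = t.to_sec().as_esec()
                s.action_label = t.action_label
                sec_tables.append(s)
            tables = sec_tables
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'generate+extract' failed: {e}") from e

    try:
        _stage("calibrate")
        by_class: dict[str, list[ESECTable]] = defaultdict(list)
        for t in tables:
            by_class[t.action_label].append(t)
        models = predictor.train_models(
            by_class,
            m=config.calibration_m,
            repeats=config.calibration_repeats,
            rng=rng,
        )
        report["thresholds"] = {n: m.threshold for n, m in models.items()}
    except Exception as e:
        raise RuntimeError(f"stage 'calibrate' failed: {e}") from e

    try:
        _stage("classify")
        per_class: dict[str, dict] = {}
        n_correct = 0
        classifications = []
        for t, tot in zip(tables, totals):
            res = predictor.predict_online(
                t,
                models,
                comparison_count=config.comparison_count,
                rng=rng,
                deterministic=config.deterministic,
                total_time=tot,
            )
            correct = res.predicted == t.action_label
            n_correct += correct
            classifications.append(
                {
                    "label": t.action_label,
                    "predicted": res.predicted,
                    "column": res.deciding_column,
                    "T": res.prediction_moment,
                    "P": res.predictive_power,
                }
            )
            stats = per_class.setdefault(
                t.action_label,
                {"n": 0, "correct": 0, "unrecognized": 0, "ambiguous": 0, "P": []},
            )
            stats["n"] += 1
            if correct:
                stats["correct"] += 1
                stats["P"].append(res.predictive_power)
            elif res.predicted in ("unrecognized", "ambiguous"):
                stats[res.predicted] += 1
        for stats in per_class.values():
            ps = stats.pop("P")
            stats["mean_P"] = float(np.mean(ps)) if ps else None
        report["classification"] = {
            "n": len(tables),
            "accuracy_percent": 100.0 * n_correct / len(tables),
            "per_class": per_class,
            "items": classifications,
        }
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    try:
        _stage("chain-distribution")
        from .scheduler import simulate_chain_distribution

        chain = {}
        for mode in ("none", "esec", "sec"):
            summary = simulate_chain_distribution(
                mode=mode, n_samples=config.chain_samples, rng=rng
            )
            summary.pop("totals")
            chain[mode] = summary
        report["chain_distribution"] = chain
    except Exception as e:
        raise RuntimeError(f"stage 'chain-distribution' failed: {e}") from e

    return report


def write_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_default) + "\n",
        encoding="utf-8",
    )


def log_config(config: RunConfig, stream=sys.stderr) -> None:
    record = {"version": __version__, "config": asdict(config)}
    print(json.dumps(record, sort_keys=True), file=stream)
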