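"""Configuration files, packaged example configs, and run manifests.

Configs are YAML or JSON with four blocks: ``rounds`` (per-round arm sizes,
allocation, and borrowing sources), ``rule`` (margin, certainty), ``grid``
(control rates, differences, certainties, weights for the simulation
study), and ``sim`` (replicates, seed).  Packaged configs reproduce the
three-round design's simulation settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .bayes import BinomialOutcome, DecisionRule, WeightedOutcome
from .design import RoundDesign, Scenario, build_scenario_grid

__all__ = [
    "TrialConfig",
    "load_config",
    "packaged_config_path",
    "list_packaged_configs",
    "config_hash",
    "write_run_manifest",
]


@dataclass(frozen=True)
class TrialConfig:
    designs: tuple[RoundDesign, ...]
    rule: DecisionRule
    control_rates: tuple[float, ...]
    differences: tuple[float, ...]
    certainties: tuple[float, ...]
    weights: tuple[float, ...]
    grid_rounds: tuple[str, ...] = ()
    reps: int = 10_000
    seed: int = 0
    raw: Mapping[str, Any] = field(default_factory=dict)

    def scenario_grid(self) -> list[Scenario]:
        designs = [
            d
            for d in self.designs
            if not self.grid_rounds or d.round_id in self.grid_rounds
        ]
        return build_scenario_grid(
            control_rates=list(self.control_rates),
            differences=list(self.differences),
            certainties=list(self.certainties),
            weights=list(self.weights),
            designs=designs,
            margin=self.rule.margin,
        )


def _parse_rounds(raw_rounds: list[Mapping[str, Any]]) -> tuple[RoundDesign, ...]:
    by_id: dict[str, RoundDesign] = {}
    designs = []
    for item in raw_rounds:
        history = []
        for b in item.get("borrow", []) or []:
            src = b["from_round"]
            if src not in by_id:
                raise ValueError(
                    f"round {item['id']!r} borrows from {src!r}, which is not "
                    "an earlier round in the config"
                )
            history.append(
                WeightedOutcome(
                    BinomialOutcome(0, by_id[src].n_control), float(b["weight"])
                )
            )
        design = RoundDesign(
            round_id=str(item["id"]),
            n_control=int(item["n_control"]),
            n_experimental=int(item["n_experimental"]),
            allocation=tuple(item.get("allocation", (1, 1))),
            history=tuple(history),
        )
        by_id[design.round_id] = design
        designs.append(design)
    return tuple(designs)


def load_config(path: str | Path) -> TrialConfig:
    """Load and validate a trial config from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} does not contain a mapping")
    try:
        designs = _parse_rounds(raw["rounds"])
        rule_raw = raw.get("rule", {})
        rule = DecisionRule(
            margin=float(rule_raw.get("margin", 0.15)),
            certainty=float(rule_raw.get("certainty", 0.60)),
        )
        grid = raw.get("grid", {})
        sim = raw.get("sim", {})
        return TrialConfig(
            designs=designs,
            rule=rule,
            control_rates=tuple(float(x) for x in grid.get("control_rates", [])),
            differences=tuple(float(x) for x in grid.get("differences", [])),
            certainties=tuple(
                float(x) for x in grid.get("certainties", [rule.certainty])
            ),
            weights=tuple(float(x) for x in grid.get("weights", [1.0])),
            grid_rounds=tuple(str(x) for x in grid.get("rounds", [])),
            reps=int(sim.get("reps", 10_000)),
            seed=int(sim.get("seed", 0)),
            raw=dict(raw),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc


def list_packaged_configs() -> list[str]:
    pkg = resources.files("powerprior").joinpath("configs")
    return sorted(p.name for p in pkg.iterdir() if p.name.endswith(".yaml"))


def packaged_config_path(name: str) -> Path:
    """Filesystem path of a packaged example config (e.g. ``"r1.yaml"``)."""
    p = resources.files("powerprior").joinpath("configs", name)
    if not p.is_file():
        raise FileNotFoundError(
            f"no packaged config {name!r}; available: {list_packaged_configs()}"
        )
    return Path(str(p))


def config_hash(path: str | Path) -> str:
    """SHA-256 of the config file's bytes, for run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    config_path: str | Path | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write a machine-readable manifest describing one invocation."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "config": str(config_path) if config_path else None,
        "config_sha256": config_hash(config_path) if config_path else None,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
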