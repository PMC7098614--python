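"""Study configuration: factor levels, seeds, methods, output layout."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from . import montecarlo, sampling
from .population import PopulationParams, default_population, load_population

DEFAULT_GRID: dict[str, list] = {
    "n_per_group": list(sampling.DEFAULT_N_PER_GROUP),
    "cohens_d": list(sampling.DEFAULT_COHENS_D),
    "distribution": list(sampling.DISTRIBUTIONS),
    "variance_ratio": list(sampling.DEFAULT_VARIANCE_RATIOS),
}

SMOKE_GRID: dict[str, list] = {
    "n_per_group": [5, 10],
    "cohens_d": [0.0, 0.8],
    "distribution": ["normal"],
    "variance_ratio": [1.0],
}

_ORDINATION_DEFAULTS = {"ellipse": "chi2", "boundary_points": 720, "threshold": 0.5}


@dataclasses.dataclass
class StudyConfig:
    """Validated study configuration (YAML-serializable).

    ``population`` is either ``{"builtin": {"seed": int}}`` or
    ``{"csv": {"means": path, "variances": path, "correlation": path}}``.
    Unknown keys anywhere are rejected so typos cannot silently change a
    study.
    """

    population: dict = dataclasses.field(
        default_factory=lambda: {"builtin": {"seed": 2026}}
    )
    grid: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_GRID))
    methods: tuple[str, ...] = montecarlo.ALL_METHODS
    n_reps: int = 1000
    base_seed: int = 2026
    alpha: float = 0.05
    n_jobs: int = 1
    ordination: dict = dataclasses.field(
        default_factory=lambda: dict(_ORDINATION_DEFAULTS)
    )
    output_dir: str | None = "results"

    def __post_init__(self) -> None:
        if set(self.population) - {"builtin", "csv"} or len(self.population) != 1:
            raise ValueError(
                "population must have exactly one of the keys 'builtin' or 'csv'"
            )
        unknown = set(self.grid) - set(DEFAULT_GRID)
        if unknown:
            raise ValueError(f"unknown grid factor(s): {sorted(unknown)}")
        self.grid = {**DEFAULT_GRID, **self.grid}
        for name, levels in self.grid.items():
            if not levels:
                raise ValueError(f"grid factor {name} has no levels")
        self.methods = tuple(self.methods)
        bad = set(self.methods) - set(montecarlo.ALL_METHODS)
        if bad:
            raise ValueError(f"unknown method(s): {sorted(bad)}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.ordination) - set(_ORDINATION_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown ordination option(s): {sorted(unknown)}")
        self.ordination = {**_ORDINATION_DEFAULTS, **self.ordination}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived objects ---------------------------------------------------

    def grid_hash(self) -> str:
        payload = {
            "grid": self.grid,
            "methods": list(self.methods),
            "n_reps": self.n_reps,
            "base_seed": self.base_seed,
            "alpha": self.alpha,
            "population": self.population,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def scenarios(self) -> list[sampling.ScenarioSpec]:
        return sampling.scenario_grid(
            n_per_group=self.grid["n_per_group"],
            cohens_d=self.grid["cohens_d"],
            distributions=self.grid["distribution"],
            variance_ratios=self.grid["variance_ratio"],
        )

    def resolve_population(self) -> PopulationParams:
        if "builtin" in self.population:
            opts = dict(self.population["builtin"])
            return default_population(seed=int(opts.get("seed", 2026)))
        opts = dict(self.population["csv"])
        missing = {"means", "variances", "correlation"} - set(opts)
        if missing:
            raise ValueError(f"population.csv is missing path(s): {sorted(missing)}")
        for key in ("means", "variances", "correlation"):
            if not Path(opts[key]).exists():
                raise FileNotFoundError(
                    f"population {key} file not found: {opts[key]}"
                )
        return load_population(opts["means"], opts["variances"], opts["correlation"])
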