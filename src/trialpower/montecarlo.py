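"""Replicated simulation over the scenario grid and pooled rejection rates.

Empirical type-I error (d = 0) and power (d > 0) follow the pooled
definition: number of significant tests divided by the total number of tests,
pooling over variables/endpoints *and* replicates, with no multiplicity
correction.  Tests per replicate: 18 for the per-variable methods (ANOVA,
Welch), 6 for the per-endpoint methods (LMM, each MANOVA criterion), and the
Kaiser-retained component count for PC-score ANOVA.

Replicate r of scenario i is seeded ``base_seed + i * 10**6 + r`` so every
cell is reproducible in isolation and results are independent of worker
count.  Failed fits count as non-rejections (conservative) and are reported
in a diagnostics column.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import battery
from .battery import TestResult
from .manova import manova_endpoint
from .population import PopulationParams
from .sampling import ScenarioSpec, TrialDataset, sample_trial

logger = logging.getLogger(__name__)

MANOVA_METHODS = {
    "manova_wilks": "wilks",
    "manova_pillai": "pillai",
    "manova_hl": "hotelling_lawley",
    "manova_roy": "roy",
}
ALL_METHODS = ("anova", "welch", "lmm", "pca_anova") + tuple(MANOVA_METHODS)

_SCENARIO_SEED_STRIDE = 1_000_000


def _failed(method: str, target: str, exc: Exception) -> TestResult:
    return TestResult(
        method=method,
        statistic=float("nan"),
        df1=float("nan"),
        df2=float("nan"),
        p_value=float("nan"),
        target=target,
        note=f"error: {exc}",
    )


def evaluate_replicate(
    trial: TrialDataset,
    params: PopulationParams,
    methods: Iterable[str] = ALL_METHODS,
) -> dict[str, list[TestResult]]:
    """Run every requested method on one trial.

    Returns one TestResult list per method; a test that raises is recorded
    as a NaN result (non-significant) so a pathological replicate cannot
    abort a scenario.
    """
    methods = list(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; allowed: {ALL_METHODS}")
    out: dict[str, list[TestResult]] = {m: [] for m in methods}

    for m in ("anova", "welch"):
        if m not in methods:
            continue
        fn = battery.oneway_anova if m == "anova" else battery.welch_anova
        for j, lab in enumerate(trial.labels):
            try:
                out[m].append(fn(trial.values[:, j], trial.group, target=lab))
            except (ValueError, np.linalg.LinAlgError) as exc:
                out[m].append(_failed(m, lab, exc))

    if "lmm" in methods:
        for ep in trial.endpoints:
            try:
                out["lmm"].append(battery.lmm_main_effect(trial, ep))
            except (ValueError, np.linalg.LinAlgError) as exc:
                out["lmm"].append(_failed("lmm", ep, exc))

    if "pca_anova" in methods:
        try:
            out["pca_anova"] = battery.pca_scores_anova(trial, params)
        except (ValueError, np.linalg.LinAlgError) as exc:
            out["pca_anova"] = [_failed("pca_anova", "", exc)]

    requested_manova = [m for m in methods if m in MANOVA_METHODS]
    if requested_manova:
        for ep in trial.endpoints:
            try:
                res = manova_endpoint(trial, ep)
                for m in requested_manova:
                    out[m].append(res.tests[MANOVA_METHODS[m]])
            except (ValueError, np.linalg.LinAlgError) as exc:
                for m in requested_manova:
                    out[m].append(_failed(m, ep, exc))
    return out


@dataclasses.dataclass(frozen=True)
class RejectionSummary:
    """Pooled rejection rate of one method under one scenario."""

    scenario: ScenarioSpec
    method: str
    n_significant: int
    n_tests: int
    n_reps: int
    n_failed: int
    seed: int

    @property
    def rate(self) -> float:
        return self.n_significant / self.n_tests if self.n_tests else float("nan")

    @property
    def mc_se(self) -> float:
        if not self.n_tests:
            return float("nan")
        r = self.rate
        return float(np.sqrt(r * (1.0 - r) / self.n_tests))

    def to_record(self, scenario_id: int | None = None) -> dict:
        s = self.scenario
        rec = {
            "n_per_group": s.n_per_group,
            "cohens_d": s.cohens_d,
            "distribution": s.distribution,
            "variance_ratio": s.variance_ratio,
            "method": self.method,
            "n_significant": self.n_significant,
            "n_tests": self.n_tests,
            "rate": self.rate,
            "mc_se": self.mc_se,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }
        if scenario_id is not None:
            rec = {"scenario_id": scenario_id, **rec}
        return rec


def replicate_seed(base_seed: int, scenario_index: int, replicate: int) -> int:
    return int(base_seed) + int(scenario_index) * _SCENARIO_SEED_STRIDE + int(replicate)


def _count_one(
    scenario: ScenarioSpec,
    params: PopulationParams,
    methods: Sequence[str],
    seed: int,
    alpha: float,
) -> dict[str, tuple[int, int, int]]:
    trial = sample_trial(scenario, params, seed)
    results = evaluate_replicate(trial, params, methods)
    counts = {}
    for m, tests in results.items():
        sig = sum(1 for t in tests if t.p_value < alpha)  # NaN compares False
        fail = sum(1 for t in tests if t.note.startswith("error"))
        counts[m] = (sig, len(tests), fail)
    return counts


def run_scenario(
    scenario: ScenarioSpec,
    params: PopulationParams,
    methods: Iterable[str] = ALL_METHODS,
    n_reps: int = 1000,
    base_seed: int = 0,
    scenario_index: int = 0,
    alpha: float = battery.ALPHA_DEFAULT,
    n_jobs: int = 1,
) -> list[RejectionSummary]:
    """Pool significant-test counts for one scenario over ``n_reps`` trials.

    Deterministic given ``base_seed``/``scenario_index`` regardless of
    ``n_jobs`` (each replicate owns its seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = list(methods)
    seeds = [replicate_seed(base_seed, scenario_index, r) for r in range(n_reps)]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_rep = Parallel(n_jobs=n_jobs)(
            delayed(_count_one)(scenario, params, methods, s, alpha) for s in seeds
        )
    else:
        per_rep = [_count_one(scenario, params, methods, s, alpha) for s in seeds]

    out = []
    for m in methods:
        sig = sum(c[m][0] for c in per_rep)
        tot = sum(c[m][1] for c in per_rep)
        fail = sum(c[m][2] for c in per_rep)
        if tot == 0:
            logger.warning(
                "method %s produced no tests under scenario %s (rate missing)",
                m,
                scenario,
            )
        out.append(
            RejectionSummary(
                scenario=scenario,
                method=m,
                n_significant=sig,
                n_tests=tot,
                n_reps=n_reps,
                n_failed=fail,
                seed=replicate_seed(base_seed, scenario_index, 0),
            )
        )
    return out


def run_grid(config, params: PopulationParams | None = None) -> pd.DataFrame:
    """scenario_grid x run_scenario, streamed to disk and resumable.

    ``config`` is a :class:`trialpower.config.StudyConfig`.  Results are
    appended to ``<output_dir>/results.csv`` after each scenario; rerunning
    with the same config skips completed scenarios (the file header records
    a config hash and a rerun with a different grid refuses to resume).
    """
    from .config import StudyConfig

    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_dict(config)
    if params is None:
        params = config.resolve_population()
    scenarios = config.scenarios()
    methods = list(config.methods)
    grid_hash = config.grid_hash()

    out_path = None
    done: set[int] = set()
    rows: list[dict] = []
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "results.csv"
        if out_path.exists():
            with open(out_path) as fh:
                first = fh.readline().strip()
            if first != f"# grid_hash={grid_hash}":
                raise ValueError(
                    f"resume file {out_path} was produced under a different "
                    "configuration; move it aside or change output_dir"
                )
            existing = pd.read_csv(out_path, comment="#")
            if len(existing):
                counts = existing.groupby("scenario_id")["method"].count()
                done = set(counts[counts >= len(methods)].index)
                rows = existing.to_dict("records")
        else:
            with open(out_path, "w") as fh:
                fh.write(f"# grid_hash={grid_hash}\n")
                fh.write(",".join(_RESULT_COLUMNS) + "\n")

    for i, scenario in enumerate(scenarios):
        if i in done:
            continue
        import time

        t0 = time.perf_counter()
        summaries = run_scenario(
            scenario,
            params,
            methods=methods,
            n_reps=config.n_reps,
            base_seed=config.base_seed,
            scenario_index=i,
            alpha=config.alpha,
            n_jobs=config.n_jobs,
        )
        recs = [s.to_record(scenario_id=i) for s in summaries]
        rows.extend(recs)
        if out_path is not None:
            pd.DataFrame(recs)[_RESULT_COLUMNS].to_csv(
                out_path, mode="a", header=False, index=False
            )
        logger.info(
            "scenario %d/%d done in %.1fs (n=%d, d=%g, %s, vr=%g)",
            i + 1,
            len(scenarios),
            time.perf_counter() - t0,
            scenario.n_per_group,
            scenario.cohens_d,
            scenario.distribution,
            scenario.variance_ratio,
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["scenario_id", "method"]).reset_index(drop=True)


_RESULT_COLUMNS = [
    "scenario_id",
    "n_per_group",
    "cohens_d",
    "distribution",
    "variance_ratio",
    "method",
    "n_significant",
    "n_tests",
    "rate",
    "mc_se",
    "n_reps",
    "n_failed",
    "seed",
]


@dataclasses.dataclass
class SummaryTables:
    """Type-I-error and power pivots mirroring the 9-panel study layout."""

    type1: pd.DataFrame
    power: pd.DataFrame

    @property
    def n_panels(self) -> int:
        frames = [df for df in (self.type1, self.power) if len(df)]
        if not frames:
            return 0
        panels = set()
        for df in frames:
            panels |= {
                (d, v)
                for d, v in zip(
                    df.index.get_level_values("distribution"),
                    df.index.get_level_values("variance_ratio"),
                )
            }
        return len(panels)


def summarize(results: pd.DataFrame) -> SummaryTables:
    """Split rates into type-I (d = 0) and power (d > 0) pivot tables.

    Rates are reshaped, never aggregated: each pivot cell is exactly one
    scenario x method pooled rate.
    """
    if not len(results):
        raise ValueError("results table is empty")
    null = results[results["cohens_d"] == 0]
    alt = results[results["cohens_d"] > 0]

    def _pivot(df: pd.DataFrame, with_d: bool) -> pd.DataFrame:
        if not len(df):
            return pd.DataFrame()
        idx = ["distribution", "variance_ratio"]
        if with_d:
            idx.append("cohens_d")
        idx.append("n_per_group")
        return df.pivot_table(
            index=idx, columns="method", values="rate", aggfunc="first"
        )

    return SummaryTables(type1=_pivot(null, False), power=_pivot(alt, True))
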