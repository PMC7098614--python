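"""Simulated 4-group trials under a factorial design of study conditions.

One simulated trial has a control group plus ``n_treatment_groups`` dose
groups (default 3), each with ``n_per_group`` subjects and p correlated
variables.  Treatment effects are injected on the mean scale via Cohen's d,

    mu_treat = mu_control + sign * s * d,

where s is the control standard deviation under equal variance, or the
average of the control and treatment standard deviations when the treatment
variance is inflated by the ``variance_ratio`` factor.  Marginals can be
multivariate normal, lognormal (log-scale parameters solved in closed form so
natural-scale moments hit their targets exactly) or gamma (Gaussian copula
with moment-matched shape/rate marginals; the copula-scale correlation equals
the target R, the induced natural-scale correlation is mildly attenuated).

Reproducibility: the latent standard-normal column for variable ``label`` is
drawn from a stream keyed by ``(seed, crc32(label))`` and the correlation
transform uses the unique symmetric PSD square root, so permuting the
variables of the population permutes the sampled columns identically.
"""

from __future__ import annotations

import dataclasses
import itertools
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .population import (
    PopulationParams,
    nearest_pd_correlation,
    split_label,
)

DISTRIBUTIONS = ("normal", "lognormal", "gamma")

DEFAULT_N_PER_GROUP = (5, 10, 15, 20, 30, 40, 50)
DEFAULT_COHENS_D = (0.0, 0.2, 0.5, 0.8)
DEFAULT_VARIANCE_RATIOS = (1.0, 2.0, 5.0)


@dataclasses.dataclass(frozen=True)
class GammaParams:
    """Gamma shape/rate pair; mean = alpha/beta, variance = alpha/beta**2."""

    alpha: float | np.ndarray
    beta: float | np.ndarray


def gamma_shape_rate(mu, var) -> GammaParams:
    """Moment-match a gamma distribution: alpha = mu^2/var, beta = mu/var."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(mu <= 0):
        raise ValueError(
            "gamma scenarios require strictly positive target means; "
            "got a nonpositive mean"
        )
    if np.any(var <= 0):
        raise ValueError("gamma target variance must be strictly positive")
    alpha = mu**2 / var
    beta = mu / var
    if alpha.ndim == 0:
        return GammaParams(alpha=float(alpha), beta=float(beta))
    return GammaParams(alpha=alpha, beta=beta)


def apply_effect(mu0, s, d, sign=1):
    """Shifted treatment mean ``mu0 + sign * s * d`` (Cohen's d placement)."""
    mu0 = np.asarray(mu0, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard deviation s must be strictly positive")
    if np.any(np.asarray(d) < 0):
        raise ValueError("Cohen's d must be nonnegative (use sign for direction)")
    out = mu0 + np.asarray(sign, dtype=float) * s * np.asarray(d, dtype=float)
    return float(out) if out.ndim == 0 else out


def average_sd(s_control, variance_ratio: float):
    """s in the effect formula under unequal variance: (s_c + s_c*sqrt(v))/2."""
    if variance_ratio < 1:
        raise ValueError("variance_ratio must be >= 1")
    return np.asarray(s_control, dtype=float) * (1.0 + np.sqrt(variance_ratio)) / 2.0


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial simulation design.

    ``effect_sign`` is either None (effect with sign +1 on every variable) or
    a length-p tuple over {-1, 0, +1}; zeros mask variables that receive no
    effect (used by the practical-example workflow where only half of the
    variables carry effects).
    """

    n_per_group: int
    cohens_d: float
    distribution: str
    variance_ratio: float
    n_treatment_groups: int = 3
    effect_sign: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if int(self.n_per_group) < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.cohens_d < 0:
            raise ValueError("cohens_d must be >= 0")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"expected one of {DISTRIBUTIONS}"
            )
        if self.variance_ratio < 1:
            raise ValueError("variance_ratio must be >= 1")
        if int(self.n_treatment_groups) < 1:
            raise ValueError("n_treatment_groups must be >= 1")
        if self.effect_sign is not None:
            sign = tuple(int(s) for s in self.effect_sign)
            if any(s not in (-1, 0, 1) for s in sign):
                raise ValueError("effect_sign entries must be -1, 0 or +1")
            object.__setattr__(self, "effect_sign", sign)

    @property
    def group_names(self) -> tuple[str, ...]:
        return ("control",) + tuple(
            f"dose{k + 1}" for k in range(int(self.n_treatment_groups))
        )


@dataclasses.dataclass
class TrialDataset:
    """One simulated trial: wide (subjects x p) values plus a long view."""

    values: np.ndarray
    group: np.ndarray
    subject_id: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        self.subject_id = np.asarray(self.subject_id)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be n x len(labels)")
        if len(self.group) != n or len(self.subject_id) != n:
            raise ValueError("group/subject_id length mismatch")
        if len(set(self.subject_id)) != n:
            raise ValueError("subject_id must be unique per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial values contain non-finite entries")

    @property
    def n_total(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def endpoints(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.labels:
            e, _ = split_label(lab)
            if e not in seen:
                seen.append(e)
        return tuple(seen)

    @property
    def times(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.labels:
            _, t = split_label(lab)
            if t not in seen:
                seen.append(t)
        return tuple(seen)

    def endpoint_matrix(self, endpoint: str) -> tuple[np.ndarray, tuple[str, ...]]:
        """(n x T) matrix of one endpoint's repeated measures, plus time names."""
        cols = [
            (j, split_label(lab)[1])
            for j, lab in enumerate(self.labels)
            if split_label(lab)[0] == endpoint
        ]
        if not cols:
            raise KeyError(f"unknown endpoint {endpoint!r}")
        idx = [j for j, _ in cols]
        times = tuple(t for _, t in cols)
        return self.values[:, idx], times

    def to_wide(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "group", self.group)
        df.insert(0, "subject", self.subject_id)
        return df

    def to_long(self) -> pd.DataFrame:
        wide = self.to_wide()
        long = wide.melt(
            id_vars=["subject", "group"], var_name="variable", value_name="value"
        )
        parts = long["variable"].map(split_label)
        long["endpoint"] = [e for e, _ in parts]
        long["time"] = [t for _, t in parts]
        return long[["subject", "group", "endpoint", "time", "value"]]

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "TrialDataset":
        labels = tuple(c for c in df.columns if c not in ("subject", "group"))
        return cls(
            values=df[list(labels)].to_numpy(dtype=float),
            group=df["group"].to_numpy(),
            subject_id=df["subject"].to_numpy(),
            labels=labels,
        )


def _sqrtm_psd(A: np.ndarray) -> np.ndarray:
    """Unique symmetric PSD square root (permutation-equivariant)."""
    w, V = np.linalg.eigh((A + A.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def _latent_normals(
    seed: int, labels: Sequence[str], n_rows: int
) -> np.ndarray:
    """iid N(0,1) matrix with one label-keyed stream per column."""
    Z = np.empty((n_rows, len(labels)))
    for j, lab in enumerate(labels):
        rng = np.random.default_rng([int(seed), zlib.crc32(lab.encode())])
        Z[:, j] = rng.standard_normal(n_rows)
    return Z


def _lognormal_block(
    Z: np.ndarray, mu: np.ndarray, var: np.ndarray, R: np.ndarray
) -> np.ndarray:
    if np.any(mu <= 0):
        raise ValueError(
            "lognormal scenarios require strictly positive target means"
        )
    cv = np.sqrt(var) / mu
    sig2 = np.log1p(cv**2)
    mlog = np.log(mu) - sig2 / 2.0
    arg = 1.0 + R * np.outer(cv, cv)
    if np.any(arg <= 0):
        raise ValueError(
            "target correlation is below the lognormal attainable lower bound"
        )
    Rlog = np.log(arg) / np.sqrt(np.outer(sig2, sig2))
    np.fill_diagonal(Rlog, 1.0)
    Rlog = nearest_pd_correlation(Rlog)
    latent = (Z @ _sqrtm_psd(Rlog)) * np.sqrt(sig2) + mlog
    return np.exp(latent)


def sample_trial(
    scenario: ScenarioSpec, params: PopulationParams, seed: int
) -> TrialDataset:
    """Draw one simulated trial under a scenario.

    The control group is sampled with mean ``params.mu`` and covariance
    diag(s) R diag(s); every treatment group gets means shifted by
    ``sign * d * s_avg`` (s_avg per :func:`average_sd`) and variances
    inflated by the variance ratio, with the correlation matrix unchanged.
    Identical ``seed`` yields an identical dataset.
    """
    p = params.p
    if scenario.effect_sign is None:
        signs = np.ones(p)
    else:
        if len(scenario.effect_sign) != p:
            raise ValueError(
                f"effect_sign has length {len(scenario.effect_sign)}, expected {p}"
            )
        signs = np.asarray(scenario.effect_sign, dtype=float)

    v = float(scenario.variance_ratio)
    shift = signs * scenario.cohens_d * average_sd(params.sd, v)
    n = int(scenario.n_per_group)
    names = scenario.group_names
    n_groups = len(names)
    n_total = n_groups * n

    group_mu = [params.mu] + [params.mu + shift] * (n_groups - 1)
    group_var = [params.var] + [params.var * v] * (n_groups - 1)

    Z = _latent_normals(seed, params.labels, n_total)
    X = np.empty_like(Z)
    if scenario.distribution == "normal":
        M = _sqrtm_psd(params.corr)
        latent = Z @ M
        for g in range(n_groups):
            rows = slice(g * n, (g + 1) * n)
            X[rows] = group_mu[g] + latent[rows] * np.sqrt(group_var[g])
    elif scenario.distribution == "lognormal":
        for g in range(n_groups):
            rows = slice(g * n, (g + 1) * n)
            X[rows] = _lognormal_block(Z[rows], group_mu[g], group_var[g], params.corr)
    else:  # gamma copula
        M = _sqrtm_psd(params.corr)
        U = ndtr(Z @ M)
        for g in range(n_groups):
            rows = slice(g * n, (g + 1) * n)
            gp = gamma_shape_rate(group_mu[g], group_var[g])
            X[rows] = stats.gamma.ppf(U[rows], a=gp.alpha, scale=1.0 / gp.beta)

    group = np.repeat(names, n)
    subject_id = np.array([f"s{i + 1:04d}" for i in range(n_total)])
    return TrialDataset(values=X, group=group, subject_id=subject_id, labels=params.labels)


def scenario_grid(
    n_per_group: Sequence[int] = DEFAULT_N_PER_GROUP,
    cohens_d: Sequence[float] = DEFAULT_COHENS_D,
    distributions: Sequence[str] = DISTRIBUTIONS,
    variance_ratios: Sequence[float] = DEFAULT_VARIANCE_RATIOS,
    n_treatment_groups: int = 3,
) -> list[ScenarioSpec]:
    """Full factorial crossing, deterministic order.

    Sample size varies slowest and variance ratio fastest; the default levels
    (7 sample sizes x 4 effect sizes x 3 distributions x 3 variance ratios)
    yield 252 scenarios.
    """
    for name, levels in (
        ("n_per_group", n_per_group),
        ("cohens_d", cohens_d),
        ("distributions", distributions),
        ("variance_ratios", variance_ratios),
    ):
        if len(list(levels)) == 0:
            raise ValueError(f"factor {name} has no levels")
    return [
        ScenarioSpec(
            n_per_group=int(n),
            cohens_d=float(d),
            distribution=str(dist),
            variance_ratio=float(v),
            n_treatment_groups=n_treatment_groups,
        )
        for n, d, dist, v in itertools.product(
            n_per_group, cohens_d, distributions, variance_ratios
        )
    ]
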