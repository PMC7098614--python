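"""Control-population parameters for simulated multi-endpoint trials.

A preclinical trial is modelled as p correlated quantitative variables, one
per (endpoint, time) pair — by default 6 functional/imaging endpoints
measured on days 1, 7 and 14, hence p = 18.  The control population is fully
described by a mean vector ``mu``, a per-variable variance vector ``var`` and
a positive-definite correlation matrix ``corr``; treatment groups are derived
from these by shifting means (Cohen's d) and inflating variances (see
:mod:`trialpower.sampling`).

Parameters can be

* estimated from a small pilot trial by a row-wise nonparametric bootstrap
  (:func:`bootstrap_population_params`),
* generated by a deterministic structural emulator with strong
  within-endpoint temporal correlation and moderate cross-endpoint
  correlation (:func:`default_population`), or
* loaded from a CSV triplet of means/variances/correlations
  (:func:`load_population`), e.g. values transcribed from a published
  supplement.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_ENDPOINTS: tuple[str, ...] = (
    "neuroscore",
    "limb_placing",
    "lesion_volume",
    "edema_volume",
    "t2_lesion",
    "t2_contra",
)
DEFAULT_TIMES: tuple[str, ...] = ("day1", "day7", "day14")

#: separator between endpoint and time inside a variable label
LABEL_SEP = ":"

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def make_labels(
    endpoints: Sequence[str] = DEFAULT_ENDPOINTS,
    times: Sequence[str] = DEFAULT_TIMES,
) -> tuple[str, ...]:
    """Variable labels in endpoint-major order: ``endpoint:time``."""
    for e in endpoints:
        if LABEL_SEP in e:
            raise ValueError(f"endpoint name must not contain {LABEL_SEP!r}: {e!r}")
    return tuple(f"{e}{LABEL_SEP}{t}" for e in endpoints for t in times)


def split_label(label: str) -> tuple[str, str]:
    """Split ``endpoint:time`` back into its two parts."""
    endpoint, _, time = label.partition(LABEL_SEP)
    if not time:
        raise ValueError(f"label {label!r} does not encode an (endpoint, time) pair")
    return endpoint, time


def nearest_positive_definite(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the positive-definite cone.

    The input is symmetrised as (S + S')/2, eigendecomposed, and eigenvalues
    below ``floor = eps * lambda_max`` are clipped to the floor (an absolute
    floor of ``eps`` is used when no eigenvalue is positive, so the all-zero
    matrix maps to ``eps * I``).  Eigenvalue clipping is the Frobenius-optimal
    symmetric repair, and the operation is idempotent: a matrix that already
    satisfies the floor is returned unchanged apart from symmetrisation.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("matrix contains non-finite entries")
    A = (S + S.T) / 2.0
    w, V = np.linalg.eigh(A)
    floor = eps * w[-1] if w[-1] > 0 else eps
    if w[0] >= floor:
        return A
    w = np.maximum(w, floor)
    B = (V * w) @ V.T
    return (B + B.T) / 2.0


def nearest_pd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Positive-definite repair followed by rescaling to unit diagonal."""
    M = nearest_positive_definite(R, eps=eps)
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return M


@dataclasses.dataclass(frozen=True)
class PopulationParams:
    """Mean/variance/correlation description of the control population.

    Invariants (enforced at construction): ``var`` strictly positive,
    ``corr`` symmetric with unit diagonal and all eigenvalues > 0, and the
    three arrays share the common dimension p = ``len(labels)``.
    """

    mu: np.ndarray
    var: np.ndarray
    corr: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        var = np.atleast_1d(np.asarray(self.var, dtype=float))
        corr = np.asarray(self.corr, dtype=float)
        labels = tuple(self.labels)
        p = len(labels)
        if p < 2:
            raise ValueError("at least 2 variables are required")
        if mu.shape != (p,) or var.shape != (p,):
            raise ValueError("mu/var length does not match labels")
        if corr.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}, got {corr.shape}")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(var)) and np.all(np.isfinite(corr))):
            raise ValueError("non-finite population parameters")
        if np.any(var <= 0):
            raise ValueError("variances must be strictly positive")
        if not np.allclose(corr, corr.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.linalg.eigvalsh((corr + corr.T) / 2.0)[0] <= 0:
            raise ValueError("correlation matrix is not positive definite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "var", var)
        object.__setattr__(self, "corr", (corr + corr.T) / 2.0)
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)

    @property
    def cov(self) -> np.ndarray:
        s = self.sd
        return self.corr * np.outer(s, s)

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

    def permuted(self, order: Sequence[int]) -> "PopulationParams":
        """Same population with variables reordered (used by equivariance checks)."""
        order = np.asarray(order, dtype=int)
        return PopulationParams(
            mu=self.mu[order],
            var=self.var[order],
            corr=self.corr[np.ix_(order, order)],
            labels=tuple(self.labels[i] for i in order),
        )


@dataclasses.dataclass(frozen=True)
class PilotDataset:
    """A small pilot trial: N subjects x p variables, no missing values."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = tuple(self.labels)
        if values.ndim != 2 or values.shape[1] != len(labels):
            raise ValueError("pilot values must be N x len(labels)")
        if values.shape[0] < 2:
            raise ValueError("pilot too small: at least 2 subjects are required")
        if not np.all(np.isfinite(values)):
            raise ValueError("pilot data contain non-finite entries")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PilotDataset":
        df = pd.read_csv(path)
        return cls(values=df.to_numpy(dtype=float), labels=tuple(df.columns))


def bootstrap_population_params(
    pilot: PilotDataset, B: int = 10_000, seed: int = 0
) -> PopulationParams:
    """Bootstrap estimate of the population mean vector and covariance matrix.

    ``B`` resamples of complete subject rows (with replacement) are drawn so
    that the cross-variable covariance is preserved; the column mean vector
    and the ddof=1 covariance matrix are averaged over resamples, the average
    covariance is repaired with :func:`nearest_positive_definite` and split
    into a variance vector and a unit-diagonal correlation matrix.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = pilot.values
    N, p = X.shape
    rng = np.random.default_rng(seed)
    mean_acc = np.zeros(p)
    cov_acc = np.zeros((p, p))
    for _ in range(B):
        Xb = X[rng.integers(0, N, size=N)]
        mean_acc += Xb.mean(axis=0)
        cov_acc += np.cov(Xb, rowvar=False, ddof=1)
    mu = mean_acc / B
    S = nearest_positive_definite(cov_acc / B)
    var = np.diag(S).copy()
    sd = np.sqrt(var)
    corr = S / np.outer(sd, sd)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return PopulationParams(mu=mu, var=var, corr=corr, labels=pilot.labels)


def default_population(
    n_endpoints: int = 6,
    n_times: int = 3,
    seed: int = 2026,
    endpoints: Sequence[str] | None = None,
    times: Sequence[str] | None = None,
) -> PopulationParams:
    """Deterministic structural emulator of a plausible control population.

    Produces positive means on heterogeneous scales (per-endpoint base scale
    log-uniform over roughly 2–100, modest time drift), coefficients of
    variation U(0.2, 0.45), within-endpoint temporal correlations of 0.75
    (adjacent times) / 0.60 (two steps apart, mean ≈ 0.7 for three times),
    and cross-endpoint correlations with base U(0.3, 0.5) decaying with
    temporal distance.  The assembled matrix is repaired to a PD correlation
    matrix.  Identical arguments give identical parameters.
    """
    if n_endpoints < 1 or n_times < 1:
        raise ValueError("n_endpoints and n_times must be >= 1")
    if endpoints is None:
        endpoints = (
            DEFAULT_ENDPOINTS[:n_endpoints]
            if n_endpoints <= len(DEFAULT_ENDPOINTS)
            else tuple(f"endpoint{i + 1}" for i in range(n_endpoints))
        )
    if times is None:
        times = (
            DEFAULT_TIMES[:n_times]
            if n_times <= len(DEFAULT_TIMES)
            else tuple(f"t{i + 1}" for i in range(n_times))
        )
    if len(endpoints) != n_endpoints or len(times) != n_times:
        raise ValueError("endpoints/times lengths disagree with n_endpoints/n_times")
    labels = make_labels(endpoints, times)
    p = n_endpoints * n_times
    rng = np.random.default_rng([int(seed), 0xD06E])

    base = 10.0 ** rng.uniform(0.3, 2.0, size=n_endpoints)
    drift = rng.uniform(0.8, 1.3, size=(n_endpoints, n_times))
    mu = (base[:, None] * drift).ravel()
    cv = rng.uniform(0.2, 0.45, size=p)
    var = (cv * mu) ** 2

    R = np.eye(p)
    cross = rng.uniform(0.3, 0.5, size=(n_endpoints, n_endpoints))
    cross = (cross + cross.T) / 2.0
    for i in range(p):
        for j in range(i + 1, p):
            ei, ti = divmod(i, n_times)
            ej, tj = divmod(j, n_times)
            dt = abs(ti - tj)
            if ei == ej:
                r = 0.75 if dt == 1 else 0.60
            else:
                decay = 1.0 if dt == 0 else (0.85 if dt == 1 else 0.70)
                r = cross[ei, ej] * decay
            R[i, j] = R[j, i] = r
    R = nearest_pd_correlation(R)
    return PopulationParams(mu=mu, var=var, corr=R, labels=labels)


# ---------------------------------------------------------------------------
# CSV interchange: means.csv (label,mean), vars.csv (label,variance),
# corr.csv (p x p with label header row and index column).
# ---------------------------------------------------------------------------


def write_population(
    params: PopulationParams,
    means_path: str | Path,
    variances_path: str | Path,
    correlation_path: str | Path,
) -> None:
    labels = list(params.labels)
    pd.DataFrame({"label": labels, "mean": params.mu}).to_csv(
        means_path, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"label": labels, "variance": params.var}).to_csv(
        variances_path, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(params.corr, index=labels, columns=labels).to_csv(
        correlation_path, float_format=_FLOAT_FMT
    )


def load_population(
    means_path: str | Path,
    variances_path: str | Path,
    correlation_path: str | Path,
) -> PopulationParams:
    """Load the CSV parameter triplet, validating that all axes agree."""
    means = pd.read_csv(means_path, float_precision="round_trip")
    if list(means.columns) != ["label", "mean"]:
        raise ValueError(f"means file {means_path}: expected columns label,mean")
    variances = pd.read_csv(variances_path, float_precision="round_trip")
    if list(variances.columns) != ["label", "variance"]:
        raise ValueError(
            f"variances file {variances_path}: expected columns label,variance"
        )
    corr = pd.read_csv(correlation_path, index_col=0, float_precision="round_trip")
    labels = tuple(means["label"])
    if tuple(variances["label"]) != labels:
        raise ValueError("variances axis: labels disagree with the means file")
    if tuple(corr.index) != labels:
        raise ValueError("correlation rows: labels disagree with the means file")
    if tuple(corr.columns) != labels:
        raise ValueError("correlation columns: labels disagree with the means file")
    return PopulationParams(
        mu=means["mean"].to_numpy(dtype=float),
        var=variances["variance"].to_numpy(dtype=float),
        corr=corr.to_numpy(dtype=float),
        labels=labels,
    )
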