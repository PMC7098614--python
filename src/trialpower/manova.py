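"""Per-endpoint MANOVA with the four classical multivariate criteria.

Each endpoint's repeated measures (q = 3 time points by default) form the
dependent-variable block of a one-way MANOVA across the g = 4 trial groups.
With H the between-group and E the within-group cross-product matrices and
lambda_i the eigenvalues of E^-1 H, the criteria are

* Wilks' lambda      L = prod 1/(1 + lambda_i)   (Rao's F approximation)
* Pillai's trace     V = sum lambda_i/(1 + lambda_i)
* Lawley-Hotelling   T = sum lambda_i
* Roy's largest root theta = lambda_max, reported with the conventional
  *upper-bound* F approximation used by mainstream statistical software
  (R's ``summary.manova``, SAS, SPSS).  That approximation is deliberately
  anticonservative; its inflated type-I error under the null is one of the
  phenomena this package's Monte Carlo study measures.

For q = 1 all four criteria reduce exactly to the one-way ANOVA F test, and
for g = 2 they all reduce to Hotelling's T^2 — both reductions are exercised
as oracles in the test suite, alongside equality with statsmodels' MANOVA.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, stats

from .battery import TestResult
from .sampling import TrialDataset

CRITERIA = ("wilks", "pillai", "hotelling_lawley", "roy")


@dataclasses.dataclass
class ManovaResult:
    """All four criteria for one MANOVA, with per-criterion F tests."""

    endpoint: str
    wilks_lambda: float
    pillai_trace: float
    hotelling_lawley: float
    roy_root: float
    tests: dict[str, TestResult]

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._eigenvalues

    _eigenvalues: np.ndarray = dataclasses.field(default=None, repr=False)


def _criterion_tests(
    lam: np.ndarray, q: int, df_h: int, df_e: int, target: str
) -> dict[str, TestResult]:
    s = min(q, df_h)
    m = (abs(q - df_h) - 1) / 2.0
    n_ = (df_e - q - 1) / 2.0
    tests: dict[str, TestResult] = {}

    # Wilks / Rao
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    num = q**2 * df_h**2 - 4.0
    den = q**2 + df_h**2 - 5.0
    t = np.sqrt(num / den) if (den > 0 and num > 0) else 1.0
    wq = df_e + df_h - (q + df_h + 1) / 2.0
    df1 = q * df_h
    df2 = wq * t - (q * df_h - 2.0) / 2.0
    lam_t = wilks ** (1.0 / t) if wilks > 0 else 0.0
    F = ((1.0 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
    tests["wilks"] = TestResult(
        "manova_wilks", float(F), float(df1), float(df2),
        float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0, target,
    )

    # Pillai
    V = float(np.sum(lam / (1.0 + lam)))
    df1 = s * (2.0 * m + s + 1.0)
    df2 = s * (2.0 * n_ + s + 1.0)
    denom = s - V
    F = ((2.0 * n_ + s + 1.0) / (2.0 * m + s + 1.0)) * (V / denom) if denom > 1e-12 else np.inf
    tests["pillai"] = TestResult(
        "manova_pillai", float(F), float(df1), float(df2),
        float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0, target,
    )

    # Lawley-Hotelling (standard software approximation)
    T = float(np.sum(lam))
    df1 = s * (2.0 * m + s + 1.0)
    df2 = 2.0 * (s * n_ + 1.0)
    F = df2 * T / (s * df1)
    tests["hotelling_lawley"] = TestResult(
        "manova_hl", float(F), float(df1), float(df2),
        float(stats.f.sf(F, df1, df2)), target,
    )

    # Roy's largest root, conventional upper-bound F
    theta = float(lam[0])
    r = max(q, df_h)
    df1 = float(r)
    df2 = float(df_e - r + df_h)
    F = df2 * theta / r
    tests["roy"] = TestResult(
        "manova_roy", float(F), df1, df2, float(stats.f.sf(F, df1, df2)), target
    )
    return tests


def manova_stats(Y: np.ndarray, groups, target: str = "") -> ManovaResult:
    """One-way MANOVA of an n x q response block across groups."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    names: list = []
    for g in groups:
        if g not in names:
            names.append(g)
    if len(names) < 2:
        raise ValueError("at least 2 groups are required")
    N, q = Y.shape
    gn = len(names)
    df_h = gn - 1
    df_e = N - gn
    grand = Y.mean(axis=0)
    H = np.zeros((q, q))
    E = np.zeros((q, q))
    for nm in names:
        Yg = Y[groups == nm]
        mg = Yg.mean(axis=0)
        dev = mg - grand
        H += len(Yg) * np.outer(dev, dev)
        R = Yg - mg
        E += R.T @ R
    try:
        linalg.cholesky(E, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "insufficient error degrees of freedom: singular error matrix"
        ) from exc
    lam = linalg.eigh(H, E, eigvals_only=True)[::-1]
    lam = np.clip(lam, 0.0, None)

    tests = _criterion_tests(lam, q, df_h, df_e, target)
    res = ManovaResult(
        endpoint=target,
        wilks_lambda=float(np.prod(1.0 / (1.0 + lam))),
        pillai_trace=float(np.sum(lam / (1.0 + lam))),
        hotelling_lawley=float(np.sum(lam)),
        roy_root=float(lam[0]),
        tests=tests,
    )
    res._eigenvalues = lam
    return res


def manova_endpoint(trial: TrialDataset, endpoint: str) -> ManovaResult:
    """MANOVA with one endpoint's repeated measures as dependent variables."""
    Y, _ = trial.endpoint_matrix(endpoint)
    return manova_stats(Y, trial.group, target=endpoint)
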