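"""Hypothesis tests applied to one simulated trial.

Univariate battery: classical one-way ANOVA and Welch's heteroscedastic
ANOVA on every variable, and a linear mixed-effects omnibus test of the
treatment factor per endpoint (random intercept per subject, main effects of
treatment and time).  Multivariate battery: one-way ANOVA on Kaiser-retained
principal-component scores computed from the *population* correlation matrix
(see :func:`pca_scores_anova`); per-endpoint MANOVA lives in
:mod:`trialpower.manova`.

For the balanced, complete designs simulated here the mixed-model treatment
test has an exact closed form — the one-way ANOVA on subject means with
df (g-1, N-g) — which coincides with the Kenward-Roger F test for this
design.  That closed form is the default engine; a statsmodels ``MixedLM``
Wald test with containment df and an ML likelihood-ratio test are available
as alternative engines and serve as cross-checks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import TrialDataset

ALPHA_DEFAULT = 0.05


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Outcome of one omnibus test.

    ``p_value`` is in [0, 1] for successful fits; a failed fit is encoded as
    NaN statistics with an explanatory ``note`` (callers treating NaN as
    "not significant" get the conservative behaviour used by the Monte Carlo
    orchestration).
    """

    method: str
    statistic: float
    df1: float
    df2: float
    p_value: float
    target: str = ""
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA_DEFAULT)


def _group_arrays(y, groups) -> tuple[list[np.ndarray], list[str]]:
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.shape[0] != groups.shape[0]:
        raise ValueError("y and groups must have the same length")
    names: list[str] = []
    for g in groups:
        if g not in names:
            names.append(g)
    arrs = [y[groups == g] for g in names]
    if len(arrs) < 2:
        raise ValueError("at least 2 groups are required")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    return arrs, [str(n) for n in names]


def oneway_anova(y, groups, target: str = "") -> TestResult:
    """Classical one-way fixed-effects F test."""
    arrs, _ = _group_arrays(y, groups)
    N = sum(len(a) for a in arrs)
    g = len(arrs)
    if sum(np.sum((a - a.mean()) ** 2) for a in arrs) == 0.0:
        raise ValueError("degenerate data: zero within-group variance")
    F, p = stats.f_oneway(*arrs)
    return TestResult(
        method="anova",
        statistic=float(F),
        df1=float(g - 1),
        df2=float(N - g),
        p_value=float(p),
        target=target,
    )


def welch_anova(y, groups, target: str = "") -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (Welch 1951).

    Group weights are n_i/s_i^2; the F statistic uses the weighted grand
    mean and a Welch–Satterthwaite denominator df.
    """
    arrs, _ = _group_arrays(y, groups)
    g = len(arrs)
    n = np.array([len(a) for a in arrs], dtype=float)
    m = np.array([a.mean() for a in arrs])
    s2 = np.array([a.var(ddof=1) for a in arrs])
    if np.any(s2 <= 0):
        raise ValueError("welch_anova: a group has zero variance (weights undefined)")
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / (g - 1)
    h = (1.0 - w / W) ** 2 / (n - 1.0)
    H = h.sum()
    B = 1.0 + 2.0 * (g - 2.0) / (g**2 - 1.0) * H
    F = A / B
    df1 = g - 1.0
    df2 = (g**2 - 1.0) / (3.0 * H)
    return TestResult(
        method="welch",
        statistic=float(F),
        df1=df1,
        df2=float(df2),
        p_value=float(stats.f.sf(F, df1, df2)),
        target=target,
    )


# ---------------------------------------------------------------------------
# Linear mixed effects: treatment main effect per endpoint
# ---------------------------------------------------------------------------


def _endpoint_design(trial: TrialDataset, endpoint: str):
    Y, times = trial.endpoint_matrix(endpoint)
    if Y.shape[1] < 2:
        raise ValueError(
            f"endpoint {endpoint!r} has a single time point; use oneway_anova"
        )
    return Y, times


def lmm_main_effect(
    trial: TrialDataset, endpoint: str, df_method: str = "balanced"
) -> TestResult:
    """Omnibus treatment test from value ~ treatment + time + (1 | subject).

    Engines:

    * ``"balanced"`` (default): exact F on subject means, df (g-1, N-g) —
      identical to the mixed model's Kenward-Roger treatment test for a
      balanced complete random-intercept design, at closed-form cost.
    * ``"containment"``: REML ``MixedLM`` fit, Wald F on the treatment
      coefficients with containment denominator df N-g.
    * ``"lrt"``: ML refits with and without treatment, chi-square LRT.
    """
    Y, _ = _endpoint_design(trial, endpoint)
    groups = trial.group
    g = len(trial.group_names)
    n_subj = Y.shape[0]

    if df_method == "balanced":
        res = oneway_anova(Y.mean(axis=1), groups, target=endpoint)
        return dataclasses.replace(res, method="lmm_balanced_f")

    long = pd.DataFrame(
        {
            "value": Y.T.ravel(),
            "time": np.repeat(np.arange(Y.shape[1]), n_subj).astype(str),
            "group": np.tile(groups, Y.shape[1]),
            "subject": np.tile(trial.subject_id, Y.shape[1]),
        }
    )
    import statsmodels.formula.api as smf

    if df_method == "containment":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "value ~ C(group) + C(time)", long, groups=long["subject"]
            ).fit(reml=True)
        names = [nm for nm in fit.model.exog_names if nm.startswith("C(group)")]
        idx = [fit.model.exog_names.index(nm) for nm in names]
        beta = fit.fe_params.to_numpy()[idx]
        V = fit.cov_params().to_numpy()[np.ix_(idx, idx)]
        chi2 = float(beta @ np.linalg.solve(V, beta))
        q = len(idx)
        F = chi2 / q
        df2 = float(n_subj - g)
        note = ""
        if float(np.asarray(fit.cov_re).ravel()[0]) < 1e-8 * float(fit.scale):
            note = "boundary: between-subject variance estimated at zero"
        return TestResult(
            method="lmm_wald_containment",
            statistic=F,
            df1=float(q),
            df2=df2,
            p_value=float(stats.f.sf(F, q, df2)),
            target=endpoint,
            note=note,
        )
    if df_method == "lrt":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(
                "value ~ C(group) + C(time)", long, groups=long["subject"]
            ).fit(reml=False)
            red = smf.mixedlm(
                "value ~ C(time)", long, groups=long["subject"]
            ).fit(reml=False)
        lr = max(2.0 * (full.llf - red.llf), 0.0)
        df1 = float(g - 1)
        return TestResult(
            method="lmm_ml_lrt",
            statistic=lr,
            df1=df1,
            df2=float("inf"),
            p_value=float(stats.chi2.sf(lr, df1)),
            target=endpoint,
        )
    raise ValueError(f"unknown df_method {df_method!r}")


# ---------------------------------------------------------------------------
# ANOVA on principal-component scores (population correlation matrix)
# ---------------------------------------------------------------------------


def kaiser_components(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a correlation matrix with eigenvalue strictly > 1.

    Eigenvalues are sorted descending; each retained eigenvector is oriented
    so that its largest-magnitude loading is positive.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > 1.0
    w, V = w[keep], V[:, keep]
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return w, V


def pca_scores_anova(trial: TrialDataset, R) -> list[TestResult]:
    """One-way ANOVA on each Kaiser-retained principal-component score.

    ``R`` is the population correlation matrix (or a
    :class:`~trialpower.population.PopulationParams`); components come from
    its eigendecomposition, not from the sample.  Scores are the pooled
    standardized data matrix times the retained eigenvectors.  An empty list
    (with a warning) is returned when no eigenvalue exceeds 1, in which case
    the method contributes no tests to rejection-rate summaries.
    """
    from .population import PopulationParams

    if isinstance(R, PopulationParams):
        R = R.corr
    R = np.asarray(R, dtype=float)
    if R.shape != (trial.p, trial.p):
        raise ValueError(f"R must be {trial.p}x{trial.p}, got {R.shape}")
    w, V = kaiser_components(R)
    if V.shape[1] == 0:
        warnings.warn(
            "Kaiser criterion retained no components; no PC-score tests run",
            stacklevel=2,
        )
        return []
    X = trial.values
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    scores = Xs @ V
    out = []
    for k in range(scores.shape[1]):
        res = oneway_anova(scores[:, k], trial.group, target=f"PC{k + 1}")
        out.append(dataclasses.replace(res, method="pca_anova"))
    return out


# ---------------------------------------------------------------------------
# Interaction model + per-time post-hoc contrasts (practical example)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PosthocTable:
    """Interaction omnibus test plus per-time contrasts against control."""

    endpoint: str
    interaction: TestResult
    contrasts: pd.DataFrame

    @property
    def interaction_significant(self) -> bool:
        return self.interaction.significant


def lmm_interaction_posthoc(
    trial: TrialDataset,
    endpoint: str,
    adjust: str = "none",
    alpha: float = ALPHA_DEFAULT,
) -> PosthocTable:
    """value ~ treatment x time + (1 | subject), then dose-vs-control contrasts.

    The interaction F test and the contrasts use the exact balanced-design
    (split-plot) decomposition: interaction df ((g-1)(T-1), (N-g)(T-1));
    a contrast between two groups at one time point has variance
    2*(sigma_b^2 + sigma_e^2)/n, estimated by (MS_B + (T-1) MS_W)/T with
    Satterthwaite df.  Contrasts are computed unconditionally — the
    interaction gate is reported so callers can filter — and ``adjust``
    selects the per-(endpoint, time) multiplicity correction over the dose
    contrasts: "none" (default), "bonferroni" or "sidak".
    """
    if adjust not in ("none", "bonferroni", "sidak"):
        raise ValueError(f"unknown adjust {adjust!r}")
    Y, times = _endpoint_design(trial, endpoint)
    groups = np.asarray(trial.group)
    names = list(trial.group_names)
    g = len(names)
    T = Y.shape[1]
    counts = np.array([(groups == nm).sum() for nm in names], dtype=float)
    if len(set(counts)) != 1:
        raise ValueError("post-hoc contrasts require equal group sizes")
    n = counts[0]
    N = Y.shape[0]

    cell = np.stack([Y[groups == nm].mean(axis=0) for nm in names])  # g x T
    gmean = cell.mean(axis=1)  # per group
    tmean = Y.mean(axis=0)  # per time
    grand = Y.mean()

    subj_mean = Y.mean(axis=1)
    ss_b = T * sum(
        np.sum((subj_mean[groups == nm] - gmean[i]) ** 2) for i, nm in enumerate(names)
    )
    df_b = N - g
    resid = Y - subj_mean[:, None]
    for i, nm in enumerate(names):
        resid[groups == nm] -= cell[i] - gmean[i]
    ss_w = float(np.sum(resid**2))
    df_w = (N - g) * (T - 1)

    inter = cell - gmean[:, None] - tmean[None, :] + grand
    ss_int = float(n * np.sum(inter**2))
    df_int = (g - 1) * (T - 1)
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        raise ValueError("degenerate data: zero within-subject variance")
    F_int = (ss_int / df_int) / ms_w
    interaction = TestResult(
        method="lmm_interaction_f",
        statistic=F_int,
        df1=float(df_int),
        df2=float(df_w),
        p_value=float(stats.f.sf(F_int, df_int, df_w)),
        target=endpoint,
    )

    ms_b = ss_b / df_b
    sigma2 = (ms_b + (T - 1) * ms_w) / T  # between + within variance
    nu = sigma2**2 * T**2 / (ms_b**2 / df_b + ((T - 1) * ms_w) ** 2 / df_w)
    se = np.sqrt(2.0 * sigma2 / n)

    n_contrasts = g - 1
    rows = []
    for t_idx, time in enumerate(times):
        for k in range(1, g):
            est = cell[k, t_idx] - cell[0, t_idx]
            tval = est / se
            p = float(2.0 * stats.t.sf(abs(tval), nu))
            if adjust == "bonferroni":
                p = min(1.0, p * n_contrasts)
            elif adjust == "sidak":
                p = 1.0 - (1.0 - p) ** n_contrasts
            rows.append(
                {
                    "endpoint": endpoint,
                    "time": time,
                    "contrast": f"control_vs_{names[k]}",
                    "estimate": float(est),
                    "se": float(se),
                    "df": float(nu),
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return PosthocTable(
        endpoint=endpoint, interaction=interaction, contrasts=pd.DataFrame(rows)
    )


def results_to_frame(results) -> pd.DataFrame:
    """Flatten TestResults into the serializable TSV layout."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "target": r.target,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2,
                "p_value": r.p_value,
                "note": r.note,
            }
            for r in results
        ]
    )
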