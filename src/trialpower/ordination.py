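"""2-D ordination, 95% confidence ellipses and pattern detection.

Four ordinations of a trial's subjects into a 2-D score plane:

* **PCA** — eigendecomposition of the correlation matrix of the pooled
  standardized data (unsupervised);
* **LDA** — Fisher discriminant directions from the eigenvalues of
  W^+ B (pooled within-group scatter W, between-group scatter B).  When
  W is singular (p larger than the residual df, the small-n regime this
  package studies) the pseudo-inverse is used *without* regularisation, so
  the well-known overfitting pathology of LDA is reproduced rather than
  masked;
* **RDA** — PCA of the group-explained fitted values (projection of the
  standardized data onto group membership), with subject scores obtained by
  projecting the data onto the constrained axes (weighted-sum convention,
  so groups retain within-group scatter);
* **PLS-DA** — two-component NIPALS partial least squares of the
  standardized data against one-hot group membership (scikit-learn
  ``PLSRegression``); subject scores are the X-scores.

A group's "separation" from control is operationalised geometrically: the
95% confidence ellipse of its scores (sample covariance scaled by the
chi-square(2) 0.95 quantile by default, or a small-sample Hotelling-T2/F
scaling) must share no interior point with the control ellipse.  A
"treatment-effect pattern" is detected when the control ellipse is disjoint
from *all* treatment ellipses.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import linalg, stats

from .population import PopulationParams
from .sampling import ScenarioSpec, TrialDataset, sample_trial

logger = logging.getLogger(__name__)

ORDINATION_METHODS = ("pca", "lda", "rda", "plsda")
CHI2_95_2D = float(stats.chi2.ppf(0.95, 2))


@dataclasses.dataclass
class Ordination2D:
    """Scores on the first two multivariate dimensions of one method."""

    method: str
    scores: np.ndarray  # n x 2
    explained: np.ndarray  # fraction of variance per axis
    axis1_correlations: np.ndarray  # corr of original variables with axis 1


@dataclasses.dataclass
class Ellipse:
    """Confidence ellipse: x inside iff (x-c)' S^-1 (x-c) <= scale."""

    center: np.ndarray
    shape: np.ndarray  # 2x2 sample covariance of the group's scores
    scale: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        self._inv = np.linalg.inv(self.shape)

    def mahalanobis2(self, pts: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(pts) - self.center
        return np.einsum("ij,jk,ik->i", d, self._inv, d)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.mahalanobis2(pts) <= self.scale

    def boundary(self, k: int = 720) -> np.ndarray:
        theta = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
        circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        L = np.linalg.cholesky(self.shape)
        return self.center + np.sqrt(self.scale) * circle @ L.T


@dataclasses.dataclass
class PatternResult:
    """Ellipse-disjointness verdict: detected = AND over all dose groups."""

    method: str
    detected: bool
    per_dose: dict[str, bool]
    n_degenerate: int = 0


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a variable has zero variance; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def _one_hot(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    names: list[str] = []
    for g in groups:
        if g not in names:
            names.append(g)
    Y = np.stack([(groups == nm).astype(float) for nm in names], axis=1)
    return Y, names


def _orient(scores: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Deterministic sign convention per axis.

    The variable most correlated (in magnitude) with the axis is given a
    positive correlation; ties resolve to the lowest variable index.
    """
    scores = scores.copy()
    for a in range(scores.shape[1]):
        s = scores[:, a]
        if s.std() == 0:
            continue
        r = _safe_correlations(X, s)
        j = int(np.argmax(np.abs(r)))
        if r[j] < 0:
            scores[:, a] = -s
    return scores


def _safe_correlations(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with s; 0 for zero variance."""
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=0) * np.sum(sc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ sc / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def ordinate(trial: TrialDataset, method: str) -> Ordination2D:
    """Project a trial onto the first two dimensions of one ordination."""
    if method not in ORDINATION_METHODS:
        raise ValueError(
            f"unknown ordination method {method!r}; expected one of {ORDINATION_METHODS}"
        )
    X = trial.values
    if X.shape[1] < 2:
        raise ValueError("ordination requires p >= 2 variables")
    if X.shape[0] < 4:
        raise ValueError("ordination requires at least 4 subjects")
    Xs = _standardize(X)
    n, p = Xs.shape

    if method == "pca":
        R = np.corrcoef(X, rowvar=False)
        w, V = np.linalg.eigh(R)
        order = np.argsort(w)[::-1]
        w, V = np.clip(w[order], 0.0, None), V[:, order]
        scores = Xs @ V[:, :2]
        explained = w[:2] / w.sum()

    elif method == "lda":
        Y, names = _one_hot(np.asarray(trial.group))
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        grand = Xs.mean(axis=0)
        for k, nm in enumerate(names):
            Xg = Xs[np.asarray(trial.group) == nm]
            mg = Xg.mean(axis=0)
            W += (Xg - mg).T @ (Xg - mg)
            B += len(Xg) * np.outer(mg - grand, mg - grand)
        # pseudo-inverse on purpose: singular W (p > N - g) must run, not crash
        M = linalg.pinvh(W) @ B
        eigval, eigvec = np.linalg.eig(M)
        order = np.argsort(eigval.real)[::-1]
        eigval = np.clip(eigval.real[order], 0.0, None)
        A = eigvec.real[:, order][:, :2]
        A /= np.linalg.norm(A, axis=0)
        scores = Xs @ A
        total = eigval.sum()
        explained = eigval[:2] / total if total > 0 else np.zeros(2)

    elif method == "rda":
        Y, names = _one_hot(np.asarray(trial.group))
        # fitted values of Xs regressed on group membership = group means
        fitted = np.zeros_like(Xs)
        for nm in names:
            mask = np.asarray(trial.group) == nm
            fitted[mask] = Xs[mask].mean(axis=0)
        C = fitted.T @ fitted / (n - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = np.clip(w[order], 0.0, None), V[:, order]
        scores = Xs @ V[:, :2]  # weighted-sum site scores
        explained = w[:2] / p  # fraction of total (unit) variance per axis

    else:  # plsda
        from sklearn.cross_decomposition import PLSRegression

        Y, names = _one_hot(np.asarray(trial.group))
        pls = PLSRegression(n_components=2, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xs, Y)
        scores = np.asarray(pls.x_scores_)
        P = np.asarray(pls.x_loadings_)
        total = float(np.sum(Xs**2))
        explained = np.array(
            [
                float(np.sum(scores[:, k] ** 2) * np.sum(P[:, k] ** 2)) / total
                for k in range(2)
            ]
        )

    scores = _orient(scores, X)
    explained = np.clip(np.asarray(explained, dtype=float), 0.0, 1.0)
    return Ordination2D(
        method=method,
        scores=scores,
        explained=explained,
        axis1_correlations=_safe_correlations(X, scores[:, 0]),
    )


def confidence_ellipse_95(
    points: np.ndarray, convention: str = "chi2"
) -> Ellipse:
    """95% confidence ellipse of a 2-D point cloud.

    ``convention="chi2"`` (default) scales the sample covariance by the
    chi-square(2) 0.95 quantile (population-coverage convention, 5.9915);
    ``convention="f"`` uses the small-sample Hotelling-T2/F scaling
    2(n-1)/(n-2) * F_{0.95}(2, n-2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("degenerate ellipse: need at least 3 points")
    S = np.cov(pts, rowvar=False)
    w = np.linalg.eigvalsh(S)
    if w[0] <= 1e-12 * max(w[-1], 1.0):
        raise ValueError("degenerate ellipse: rank-deficient covariance")
    if convention == "chi2":
        scale = CHI2_95_2D
    elif convention == "f":
        scale = 2.0 * (n - 1) / (n - 2) * float(stats.f.ppf(0.95, 2, n - 2))
    else:
        raise ValueError(f"unknown ellipse convention {convention!r}")
    return Ellipse(center=pts.mean(axis=0), shape=S, scale=scale)


def ellipses_disjoint(e1: Ellipse, e2: Ellipse, k: int = 720) -> bool:
    """True iff the two ellipse interiors share no point.

    Each boundary is sampled at ``k`` points; the ellipses overlap iff either
    center lies inside the other or any boundary point of one lies inside
    the other.
    """
    if e2.contains(e1.center[None, :])[0] or e1.contains(e2.center[None, :])[0]:
        return False
    if e2.contains(e1.boundary(k)).any() or e1.contains(e2.boundary(k)).any():
        return False
    return True


def detect_pattern(
    ordination: Ordination2D,
    groups,
    control: str = "control",
    convention: str = "chi2",
    boundary_points: int = 720,
) -> PatternResult:
    """Treatment-effect pattern verdict from per-group score ellipses.

    Detected iff the control-group ellipse is disjoint from *every*
    treatment-group ellipse.  A group whose score cloud yields a degenerate
    ellipse is counted as "not separated" (flag False) and tallied in
    ``n_degenerate``.
    """
    groups = np.asarray(groups)
    names = []
    for g in groups:
        if g not in names:
            names.append(g)
    if control not in names:
        control = names[0]
    doses = [nm for nm in names if nm != control]
    scores = ordination.scores
    n_degenerate = 0
    try:
        e_control = confidence_ellipse_95(scores[groups == control], convention)
    except ValueError:
        logger.warning("degenerate control ellipse; pattern counted as not detected")
        return PatternResult(
            ordination.method, False, {d: False for d in doses}, n_degenerate=1
        )
    per_dose: dict[str, bool] = {}
    for nm in doses:
        try:
            e = confidence_ellipse_95(scores[groups == nm], convention)
            per_dose[nm] = ellipses_disjoint(e_control, e, boundary_points)
        except ValueError:
            logger.warning("degenerate ellipse for group %s; flag set to False", nm)
            per_dose[nm] = False
            n_degenerate += 1
    return PatternResult(
        method=ordination.method,
        detected=all(per_dose.values()),
        per_dose=per_dose,
        n_degenerate=n_degenerate,
    )


def loading_correlations(
    trial: TrialDataset, axis_scores: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Variable-axis Pearson correlations with small-|r| entries zeroed.

    Correlations with absolute value strictly below ``threshold`` are set to
    exactly 0 to filter out unimportant variables; all others are returned
    unchanged.  A zero-variance variable gets correlation 0 with a warning.
    """
    axis_scores = np.asarray(axis_scores, dtype=float)
    if axis_scores.shape[0] != trial.n_total:
        raise ValueError("axis_scores length must equal the number of subjects")
    sd = trial.values.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance variable: correlation set to 0", stacklevel=2)
    r = _safe_correlations(trial.values, axis_scores)
    out = np.where(np.abs(r) < threshold, 0.0, r)
    return out


def pattern_rate_study(
    scenario: ScenarioSpec,
    params: PopulationParams,
    method: str,
    n_reps: int,
    seed: int,
    convention: str = "chi2",
    boundary_points: int = 720,
) -> float:
    """Fraction of replicates in which a treatment-effect pattern is detected.

    With ``scenario.cohens_d == 0`` this is the false-pattern rate; with
    d > 0 it is the sensitivity (true-pattern rate).  Replicate r uses seed
    ``seed + r``; degenerate or failed replicates count as not detected and
    are logged, never fatal.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    detected = 0
    failures = 0
    for r in range(n_reps):
        try:
            trial = sample_trial(scenario, params, seed + r)
            ordn = ordinate(trial, method)
            res = detect_pattern(
                ordn, trial.group, convention=convention, boundary_points=boundary_points
            )
            detected += int(res.detected)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("replicate %d failed (%s); counted as not detected", r, exc)
    if failures:
        logger.warning("%d/%d replicates failed", failures, n_reps)
    return detected / n_reps
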