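"""Statistical suite for the song-feature analysis.

Log-link GLMs per feature, PCA on centered/scaled log features, linear
discriminant classification (also used as the 2-D linear partition on
PC or embedding coordinates), a UMAP contract wrapper, Procrustes
superimposition with a permutation (protest-style) significance test,
and Mantel tests of distance-matrix association.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass
class GlmFit:
    """Per-covariate estimates of one log-link GLM fit."""

    feature: str
    terms: dict[str, dict[str, float]]  # name -> {estimate, se, t, p}
    converged: bool
    family: str

    def term(self, name: str) -> dict[str, float]:
        return self.terms[name]


@dataclass
class PcaResult:
    scores: np.ndarray  # n_samples x n_components
    loadings: np.ndarray  # n_features x n_components
    var_explained: np.ndarray  # fraction per component, non-increasing
    feature_names: list[str] | None = None


@dataclass
class ProcrustesResult:
    rotation: np.ndarray  # 2x2 orthogonal
    scale: float
    translation: np.ndarray
    ss_residual: float
    correlation_stat: float  # sqrt(1 - m^2)
    p_value: float
    n_perm: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str = "spearman"


def fit_feature_glm(
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    feature_name: str = "feature",
    family: str = "gaussian_log",
) -> GlmFit:
    """Fit ``raw feature ~ scaled lon + scaled lat + species + conversion``.

    The response stays on the raw (positive) scale; the default family is
    Gaussian with a log link (a Gamma family with log link is available as
    ``family="gamma_log"``).  Longitude and latitude are standardized to
    mean 0 / SD 1 internally; species and conversion status become 0/1
    indicators (alphabetically later level = 1).
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError(f"{feature_name}: log-link GLM needs a positive response")
    required = {"longitude", "latitude", "species", "conversion_status"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"missing covariates: {sorted(missing)}")
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")

    def standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("constant covariate: singular design")
        return (x - x.mean()) / sd

    def indicator(col: pd.Series) -> np.ndarray:
        levels = sorted(col.astype(str).unique())
        if len(levels) == 1:
            raise ValueError(f"constant covariate {col.name!r}: singular design")
        if len(levels) != 2:
            raise ValueError(f"covariate {col.name!r} must be binary, got {levels}")
        return (col.astype(str) == levels[1]).to_numpy(dtype=float)

    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "longitude": standardize(covariates["longitude"].to_numpy(dtype=float)),
            "latitude": standardize(covariates["latitude"].to_numpy(dtype=float)),
            "species": indicator(covariates["species"]),
            "conversion": indicator(covariates["conversion_status"]),
        },
        index=covariates.index,
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    if family == "gaussian_log":
        fam = sm.families.Gaussian(sm.families.links.Log())
    elif family == "gamma_log":
        fam = sm.families.Gamma(sm.families.links.Log())
    else:
        raise ValueError(f"unknown family {family!r}")
    # Seed the IRLS from a log-scale OLS fit for stable convergence.
    start = np.linalg.lstsq(X.to_numpy(), np.log(y), rcond=None)[0]
    model = sm.GLM(y, X, family=fam)
    try:
        res = model.fit(start_params=start, maxiter=200)
    except Exception as exc:  # pragma: no cover - surfaced with feature name
        raise RuntimeError(f"GLM failed to converge for {feature_name}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"GLM failed to converge for {feature_name}")
    terms = {
        name: {
            "estimate": float(res.params[name]),
            "se": float(res.bse[name]),
            "t": float(res.tvalues[name]),
            "p": float(res.pvalues[name]),
        }
        for name in X.columns
    }
    return GlmFit(feature_name, terms, bool(res.converged), family)


def run_pca(table: pd.DataFrame | np.ndarray, scale: bool = True) -> PcaResult:
    """PCA of centered (and by default unit-variance scaled) columns."""
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        names = None
        X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("missing values in feature table")
    sd = X.std(axis=0, ddof=1)
    if scale and (sd == 0).any():
        bad = [names[i] if names else str(i) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # Deterministic sign: largest-magnitude loading of each component positive.
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2 / (S**2).sum()
    return PcaResult(U * S, Vt.T, var, names)


def lda_train_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    priors: tuple[float, float] = (0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher LDA with equal priors; returns (predictions, 1-D scores).

    Works on the full 16-feature table or on 2-D coordinates (PC1/PC2 or an
    embedding) as the simple linear partition classifier.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LinearDiscriminantAnalysis(priors=list(priors))
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    X_test = np.asarray(X_test, dtype=float)
    return clf.predict(X_test), clf.decision_function(X_test)


def run_umap(
    table: pd.DataFrame | np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding, deterministic under a fixed seed.

    Coordinates have no absolute meaning; only downstream linear-partition
    accuracy should be asserted.
    """
    import umap  # deferred: slow import (numba JIT)

    X = np.asarray(table, dtype=float)
    if X.shape[0] < n_neighbors:
        raise ValueError("need at least n_neighbors samples")
    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, n_components=2, random_state=seed
    )
    return np.asarray(reducer.fit_transform(X))


def _procrustes_stat(source_n: np.ndarray, target_n: np.ndarray, allow_reflection: bool) -> tuple[float, np.ndarray, float]:
    """Procrustes correlation (trace of S) for unit-norm centered configs."""
    M = source_n.T @ target_n
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        # Flip the smallest singular direction to stay in SO(2).
        U[:, -1] *= -1
        S = S.copy()
        S[-1] *= -1
        R = U @ Vt
    trace = float(S.sum())
    return trace, R, trace


def procrustes_test(
    source: np.ndarray,
    target: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    allow_reflection: bool = False,
    exhaustive: bool = False,
) -> ProcrustesResult:
    """Least-squares similarity transform of ``source`` onto ``target``.

    Translation, rotation (no reflection by default), and uniform scale are
    fitted; ``correlation_stat = sqrt(1 - m^2)`` where m^2 is the normalized
    residual sum of squares.  Significance comes from row permutations of
    the source: ``p = (1 + #{permuted stat >= observed}) / (n_perm + 1)``,
    or an exact enumeration over all n! row orders when ``exhaustive``.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("source and target must be equal-shape 2-D arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    Yc = Y - Y.mean(axis=0)
    normY = np.linalg.norm(Yc)
    if normY == 0 or np.linalg.matrix_rank(Yc) < Y.shape[1]:
        raise ValueError("degenerate target configuration")
    Xc = X - X.mean(axis=0)
    normX = np.linalg.norm(Xc)
    if normX == 0:
        raise ValueError("degenerate source configuration")
    Xn, Yn = Xc / normX, Yc / normY

    trace, R, _ = _procrustes_stat(Xn, Yn, allow_reflection)
    corr = max(0.0, min(1.0, trace))
    m2 = 1.0 - trace**2
    scale = trace * normY / normX
    translation = Y.mean(axis=0) - scale * (X.mean(axis=0) @ R)
    fitted = scale * (X @ R) + translation
    ss_residual = float(((fitted - Y) ** 2).sum())

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = 0
        for perm in _permutations(range(n)):
            t, _, _ = _procrustes_stat(Xn[list(perm)], Yn, allow_reflection)
            if t >= trace - 1e-12:
                count += 1
        p = count / factorial(n)
        n_used = factorial(n)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            t, _, _ = _procrustes_stat(Xn[idx], Yn, allow_reflection)
            if t >= trace - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return ProcrustesResult(
        rotation=R,
        scale=float(scale),
        translation=translation,
        ss_residual=ss_residual,
        correlation_stat=float(np.sqrt(max(0.0, 1.0 - m2))),
        p_value=float(p),
        n_perm=n_used,
    )


def _check_distance_matrix(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Spearman Mantel test of two distance matrices.

    r is the rank correlation of the lower-triangle entries; the null is
    built by simultaneous row/column permutation of ``d2``; the p-value is
    one-sided (upper tail) with the +1 correction, or exact under
    ``exhaustive`` enumeration of all n! permutations.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    _check_distance_matrix(d1, "d1")
    _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have equal dimensions")
    n = d1.shape[0]
    tril = np.tril_indices(n, -1)
    v1, v2 = d1[tril], d2[tril]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant distance vector: ranks undefined")

    # Joint row/column permutation preserves the multiset of off-diagonal
    # values, so rank-transform once and permute the rank matrices.
    def rank_matrix(d: np.ndarray) -> np.ndarray:
        r = np.zeros_like(d)
        r[tril] = rankdata(d[tril])
        return r + r.T

    r1m, r2m = rank_matrix(d1), rank_matrix(d2)
    a = r1m[tril]
    a = (a - a.mean()) / a.std()

    def corr_with(perm: np.ndarray) -> float:
        b = r2m[np.ix_(perm, perm)][tril]
        b = (b - b.mean()) / b.std()
        return float(np.mean(a * b))

    obs = corr_with(np.arange(n))
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = sum(
            1
            for perm in _permutations(range(n))
            if corr_with(np.array(perm)) >= obs - 1e-12
        )
        p = count / factorial(n)
        n_used = factorial(n)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if corr_with(rng.permutation(n)) >= obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=obs, p=float(p), n_perm=n_used)


def feature_distance_matrices(
    table: pd.DataFrame,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Overall Euclidean distance matrix plus per-feature |delta| matrices."""
    if table.isna().any().any():
        raise ValueError("missing values in feature table")
    X = table.to_numpy(dtype=float)
    overall = squareform(pdist(X, metric="euclidean"))
    per_feature = {
        name: np.abs(X[:, k][:, None] - X[:, k][None, :])
        for k, name in enumerate(table.columns)
    }
    return overall, per_feature
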