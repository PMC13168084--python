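"""Exploratory factor analysis: minres factoring, oblimin rotation, Horn
parallel analysis, and Ten Berge factor scores.

The 50 acoustic features are z-standardized and factored by minimum-residual
(minres) estimation: uniquenesses are chosen to minimize the off-diagonal
residuals of the correlation matrix. Loadings are rotated obliquely with
direct oblimin (gamma = 0, i.e. quartimin) via gradient projection. The
number of factors defaults to Horn's parallel analysis (95th-percentile
eigenvalues of random-normal data). Factor scores use the Ten Berge
correlation-preserving estimator, so score variances are ~1 and the score
correlations match the factor correlation matrix.

Factors are auto-labeled as composite markers (X1 dynamics .. X6 intonation)
when a majority of their salient loadings come from one construct group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize

from speechmark.features import CONSTRUCT_GROUPS, MARKER_CODES


def parallel_analysis(
    X: np.ndarray | pd.DataFrame,
    n_resamples: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis on correlation-matrix eigenvalues.

    Retains components whose observed eigenvalue exceeds the given
    percentile of eigenvalues from random standard-normal data of the same
    shape; counting stops at the first failure.
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_resamples, p))
    for b in range(n_resamples):
        Z = rng.standard_normal((n, p))
        rand[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.percentile(rand, percentile, axis=0)
    k = 0
    while k < p and obs[k] > thresh[k]:
        k += 1
    return max(k, 1)


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rs = R.copy()
    np.fill_diagonal(Rs, 1.0 - psi)
    vals, vecs = eigh(Rs)
    vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def minres_fa(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual factoring of a correlation matrix.

    Returns (unrotated loadings p x k, uniquenesses). The objective is the
    sum of squared off-diagonal residuals of R - Lambda Lambda'.
    """
    p = R.shape[0]
    off_mask = ~np.eye(p, dtype=bool)

    def objective(psi: np.ndarray) -> float:
        lam = _loadings_from_psi(R, psi, k)
        resid = R - lam @ lam.T
        return float(np.sum(resid[off_mask] ** 2))

    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        psi0 = np.clip(1.0 - smc, 0.05, 1.0)
    except np.linalg.LinAlgError:
        psi0 = np.full(p, 0.5)
    res = minimize(
        objective, psi0, method="L-BFGS-B", bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 1000},
    )
    loadings = _loadings_from_psi(R, res.x, k)
    # column sign convention: dominant loading positive
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    return loadings, res.x


def _quartimin(L: np.ndarray, gamma: float = 0.0) -> tuple[float, np.ndarray]:
    """Oblimin criterion value and gradient (gamma=0 is direct quartimin)."""
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    if gamma != 0.0:
        C = np.eye(p) - (gamma / p) * np.ones((p, p))
        X = C @ L2 @ N
    else:
        X = L2 @ N
    return float(np.sum(L2 * X) / 4.0), L * X


def oblimin_rotate(
    A: np.ndarray, gamma: float = 0.0, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation of unrotated loadings.

    Returns (pattern matrix, factor correlation matrix Phi).
    """
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L, gamma)
    G = (L.T @ Gq @ Ti).T * -1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.diag(T.T @ G))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X @ np.diag(1.0 / np.sqrt(np.diag(X.T @ X)))
            Ti2 = np.linalg.inv(X)
            L2 = A @ Ti2.T
            f2, Gq2 = _quartimin(L2, gamma)
            if f2 < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f, L, Gq, Ti = X, f2, L2, Gq2, Ti2
        G = (L.T @ Gq @ Ti).T * -1.0
    Phi = T.T @ T
    return L, Phi


def _matrix_power_sym(M: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = eigh(M)
    vals = np.clip(vals, 1e-10, None)
    return (vecs * vals**power) @ vecs.T


def ten_berge_weights(R: np.ndarray, loadings: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Ten Berge correlation-preserving factor-score weights (p x k)."""
    L = loadings @ _matrix_power_sym(Phi, 0.5)
    r_inv_sqrt = _matrix_power_sym(R, -0.5)
    inner = L.T @ np.linalg.solve(R, L)
    C = r_inv_sqrt @ L @ _matrix_power_sym(inner, -0.5)
    return r_inv_sqrt @ C @ _matrix_power_sym(Phi, 0.5)


def label_factors(
    loadings: pd.DataFrame, threshold: float = 0.4, majority: float = 0.5
) -> list[str]:
    """Assign composite-marker codes to factors by their salient loadings.

    A factor gets a construct's code (X1..X6) iff strictly more than half of
    its |loading| > threshold features belong to that one construct group
    and the code is not already taken; otherwise a generic F<i> label.
    """
    feature_to_group = {
        feat: grp for grp, feats in CONSTRUCT_GROUPS.items() for feat in feats
    }
    labels: list[str] = []
    used: set[str] = set()
    for j, col in enumerate(loadings.columns):
        salient = loadings.index[np.abs(loadings[col]) > threshold]
        label = f"F{j + 1}"
        if len(salient) > 0:
            groups = pd.Series([feature_to_group.get(f) for f in salient]).dropna()
            if len(groups) > 0:
                top = groups.value_counts()
                if top.iloc[0] / len(salient) > majority:
                    code = MARKER_CODES[top.index[0]]
                    if code not in used:
                        label = code
        used.add(label)
        labels.append(label)
    return labels


@dataclass
class FactorModel:
    """Fitted factor model: rotated loadings, factor correlations, Ten Berge
    score weights, and the column standardization constants."""

    loadings: pd.DataFrame  # p x k, oblimin-rotated pattern
    Phi: np.ndarray  # k x k factor correlations
    weights: np.ndarray  # p x k Ten Berge weights
    means: pd.Series
    sds: pd.Series
    labels: list[str]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def communalities(self) -> pd.Series:
        # h^2 = diag(Lambda Phi Lambda') for the oblique solution
        L = self.loadings.to_numpy()
        return pd.Series(np.diag(L @ self.Phi @ L.T), index=self.loadings.index)

    def to_json(self, path: str | Path) -> None:
        blob = {
            "feature_names": self.feature_names,
            "labels": self.labels,
            "loadings": self.loadings.to_numpy().tolist(),
            "Phi": self.Phi.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorModel":
        blob = json.loads(Path(path).read_text())
        names = blob["feature_names"]
        return cls(
            loadings=pd.DataFrame(blob["loadings"], index=names, columns=blob["labels"]),
            Phi=np.asarray(blob["Phi"]),
            weights=np.asarray(blob["weights"]),
            means=pd.Series(blob["means"], index=names),
            sds=pd.Series(blob["sds"], index=names),
            labels=list(blob["labels"]),
        )


def fit_factor_model(
    table: pd.DataFrame,
    k: int | None = None,
    seed: int = 0,
    n_resamples: int = 100,
    percentile: float = 95.0,
    gamma: float = 0.0,
    feature_names: list[str] | None = None,
) -> FactorModel:
    """Fit the minres/oblimin factor model to a feature table.

    ``table`` holds one row per sample; only ``feature_names`` columns are
    used (default: all columns, reordered canonically for invariance to
    input column order). ``k=None`` selects the factor count by parallel
    analysis. A singular correlation matrix is ridge-regularized with a
    warning.
    """
    cols = feature_names or sorted(table.columns)
    X = table[cols].to_numpy(dtype=np.float64)
    n, p = X.shape
    if n < p:
        warnings.warn(f"under-determined fit: {n} samples for {p} features", stacklevel=2)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        dead = [c for c, s in zip(cols, sds) if s <= 0]
        raise ValueError(f"zero-variance columns: {dead}")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    min_eig = np.linalg.eigvalsh(R)[0]
    if min_eig < 1e-8:
        warnings.warn("singular correlation matrix; applying ridge regularization",
                      stacklevel=2)
        R = (R + 1e-6 * np.eye(p)) / (1.0 + 1e-6)
    if k is None:
        k = parallel_analysis(X, n_resamples=n_resamples, percentile=percentile, seed=seed)
    loadings, _psi = minres_fa(R, k)
    rotated, Phi = oblimin_rotate(loadings, gamma=gamma)
    # order factors by explained SS loadings; orient dominant loading positive
    order = np.argsort(-np.sum(rotated**2, axis=0))
    rotated, Phi = rotated[:, order], Phi[np.ix_(order, order)]
    for j in range(k):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    ldf = pd.DataFrame(rotated, index=cols, columns=[f"F{i+1}" for i in range(k)])
    labels = label_factors(ldf)
    ldf.columns = labels
    weights = ten_berge_weights(R, rotated, Phi)
    return FactorModel(
        loadings=ldf,
        Phi=Phi,
        weights=weights,
        means=pd.Series(means, index=cols),
        sds=pd.Series(sds, index=cols),
        labels=labels,
    )


def score_markers(model: FactorModel, table: pd.DataFrame) -> pd.DataFrame:
    """Ten Berge factor scores (composite markers) for each sample."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks model columns: {missing}")
    X = table[model.feature_names].to_numpy(dtype=np.float64)
    Z = (X - model.means.to_numpy()) / model.sds.to_numpy()
    scores = Z @ model.weights
    return pd.DataFrame(scores, index=table.index, columns=model.labels)
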