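"""Clinical-utility evaluation: marker-metric regression and supervised
classification.

Regression relates the six composite markers to standardized functional
metrics (MoCA, speech intelligibility, communication efficiency) via OLS with
bidirectional stepwise selection on AIC; coefficients are reported on the
standardized scale. Classification discriminates diagnostic groups with an
RBF-kernel SVM and a random forest under stratified 5-fold cross-validation
repeated 10 times; per-fold scalers and hyperparameters are fitted on the
training split only so no information leaks across folds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedGroupKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def stepwise_regression(
    markers: pd.DataFrame,
    metric: pd.Series | np.ndarray,
    subject_ids: pd.Series | None = None,
    level: str = "sample",
) -> dict:
    """Bidirectional AIC stepwise OLS of a functional metric on the markers.

    Starts from the intercept-only model; at each step the single addition
    or removal that lowers AIC most is taken, until no move improves AIC.
    Predictors and the metric are z-standardized, so coefficients are
    standardized. ``level="participant"`` averages sentence-level rows per
    subject first (requires ``subject_ids``).
    """
    y = pd.Series(np.asarray(metric, dtype=np.float64), index=markers.index)
    data = markers.copy()
    data["_y"] = y
    data = data.dropna()
    if level == "participant":
        if subject_ids is None:
            raise ValueError("participant-level regression needs subject_ids")
        subj = pd.Series(np.asarray(subject_ids), index=markers.index)
        data["_subject"] = subj.loc[data.index]
        data = data.groupby("_subject").mean(numeric_only=True)
    if data["_y"].nunique() < 2:
        raise ValueError("metric is constant")
    yz = (data["_y"] - data["_y"].mean()) / data["_y"].std(ddof=1)
    Xz = data.drop(columns="_y")
    Xz = (Xz - Xz.mean()) / Xz.std(ddof=1)

    def fit(cols: list[str]):
        X = sm.add_constant(Xz[cols]) if cols else pd.DataFrame(
            {"const": np.ones(len(yz))}, index=yz.index
        )
        return sm.OLS(yz, X).fit()

    selected: list[str] = []
    current = fit(selected)
    while True:
        best_aic, best_move = current.aic, None
        for col in Xz.columns:
            move = (selected + [col]) if col not in selected else [c for c in selected if c != col]
            aic = fit(move).aic
            if aic < best_aic - 1e-10:
                best_aic, best_move = aic, move
        if best_move is None:
            break
        selected = best_move
        current = fit(selected)
    return {
        "selected": selected,
        "coefficients": {c: float(current.params[c]) for c in selected},
        "p_values": {c: float(current.pvalues[c]) for c in selected},
        "adjusted_r2": float(current.rsquared_adj) if selected else 0.0,
        "aic": float(current.aic),
        "n": int(len(yz)),
    }


def spearman_matrix(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p-values among functional metrics."""
    cols = list(metrics.columns)
    n = len(cols)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = metrics[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError("need at least 3 paired observations")
            r, p = spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def _make_estimator(algo: str, seed: int, rf_trees: int):
    if algo == "svm_rbf":
        grid = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.1, 1.0]}
        pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        return GridSearchCV(pipe, grid, cv=3, n_jobs=1), True
    if algo == "rf":
        return (
            Pipeline([
                ("scaler", StandardScaler()),
                ("rf", RandomForestClassifier(
                    n_estimators=rf_trees, max_features="sqrt", random_state=seed
                )),
            ]),
            False,
        )
    raise ValueError(f"unknown algorithm {algo!r}")


def _macro_rates(cm: np.ndarray) -> dict[str, float]:
    """Macro-averaged sensitivity/specificity/PPV/NPV from a confusion matrix."""
    k = cm.shape[0]
    sens, spec, ppv, npv = [], [], [], []
    total = cm.sum()
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        ppv.append(tp / (tp + fp) if tp + fp else np.nan)
        npv.append(tn / (tn + fn) if tn + fn else np.nan)
    return {
        "sensitivity": float(np.nanmean(sens)),
        "specificity": float(np.nanmean(spec)),
        "ppv": float(np.nanmean(ppv)),
        "npv": float(np.nanmean(npv)),
    }


def crossval_classify(
    markers: pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    algo: str = "rf",
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    rf_trees: int = 500,
) -> dict:
    """Repeated stratified cross-validated multiclass classification.

    Per fold, the scaler and (for the SVM) hyperparameters are fitted on the
    training split only. Multiclass AUC is macro one-vs-rest on predicted
    probabilities; sensitivity/specificity/PPV/NPV are macro-averaged.
    Pairwise AUCs restrict each test fold to the class pair. With ``groups``
    (subject ids), folds are grouped so no subject spans train and test.
    """
    X = np.asarray(markers, dtype=np.float64)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")

    if groups is None:
        splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
        split_iter = list(splitter.split(X, y_idx))
    else:
        split_iter = []
        for rep in range(repeats):
            sgk = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
            split_iter.extend(sgk.split(X, y_idx, groups=groups))

    pairs = [(i, j) for i in range(len(classes)) for j in range(i + 1, len(classes))]
    fold_auc, fold_acc, fold_rates = [], [], []
    pair_scores: dict[tuple[int, int], list[np.ndarray]] = {p: [] for p in pairs}
    pair_truth: dict[tuple[int, int], list[np.ndarray]] = {p: [] for p in pairs}
    importances = []

    for fold_i, (train, test) in enumerate(split_iter):
        est, is_grid = _make_estimator(algo, seed, rf_trees)
        est.fit(X[train], y_idx[train])
        if is_grid:  # refit best SVM with probability estimates
            best = est.best_estimator_
            best.set_params(svc__probability=True, svc__random_state=seed)
            best.fit(X[train], y_idx[train])
            model = best
        else:
            model = est
        proba = model.predict_proba(X[test])
        pred = np.argmax(proba, axis=1)
        truth = y_idx[test]
        if len(np.unique(truth)) == len(classes):
            fold_auc.append(
                roc_auc_score(truth, proba, multi_class="ovr", average="macro")
            )
        fold_acc.append(float(np.mean(pred == truth)))
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        np.add.at(cm, (truth, pred), 1)
        fold_rates.append(_macro_rates(cm))
        for a, b in pairs:
            mask = (truth == a) | (truth == b)
            if mask.sum() < 2 or len(np.unique(truth[mask])) < 2:
                continue
            score = proba[mask, b] / (proba[mask, a] + proba[mask, b] + 1e-300)
            pair_scores[(a, b)].append(score)
            pair_truth[(a, b)].append((truth[mask] == b).astype(int))
        if algo == "rf":
            importances.append(model.named_steps["rf"].feature_importances_)

    report = {
        "algorithm": algo,
        "classes": [str(c) for c in classes],
        "auc": float(np.mean(fold_auc)),
        "auc_sd": float(np.std(fold_auc)),
        "accuracy": float(np.mean(fold_acc)),
        "n_folds": len(split_iter),
    }
    for key in ("sensitivity", "specificity", "ppv", "npv"):
        report[key] = float(np.mean([r[key] for r in fold_rates]))
    pairwise = {}
    roc_points = {}
    for (a, b) in pairs:
        name = f"{classes[a]}_vs_{classes[b]}"
        scores = np.concatenate(pair_scores[(a, b)])
        truths = np.concatenate(pair_truth[(a, b)])
        pairwise[name] = float(roc_auc_score(truths, scores))
        fpr, tpr, _ = roc_curve(truths, scores)
        roc_points[name] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    report["pairwise_auc"] = pairwise
    report["roc"] = roc_points
    if importances:
        names = (
            list(markers.columns)
            if isinstance(markers, pd.DataFrame)
            else [f"f{i}" for i in range(X.shape[1])]
        )
        mean_imp = np.mean(importances, axis=0)
        report["importances"] = dict(
            sorted(zip(names, mean_imp.tolist()), key=lambda kv: -kv[1])
        )
    return report


def adjust_age_sex(
    markers: pd.DataFrame, age: np.ndarray | pd.Series, sex: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Residualize each marker on age and sex (linear model over all samples).

    Removes disease-unrelated demographic variability before clustering.
    A constant sex column is dropped with a warning. Residuals are centered
    at 0 by construction.
    """
    import warnings as _warnings

    age = np.asarray(age, dtype=np.float64)
    sex_arr = np.asarray(sex)
    design = [np.ones(len(markers)), age]
    if len(np.unique(sex_arr)) > 1:
        levels = np.unique(sex_arr)
        design.append((sex_arr == levels[-1]).astype(float))
    else:
        _warnings.warn("sex column is constant; dropping sex term", stacklevel=2)
    X = np.column_stack(design)
    out = {}
    for col in markers.columns:
        yv = markers[col].to_numpy(dtype=np.float64)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        out[col] = yv - X @ beta
    return pd.DataFrame(out, index=markers.index)
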