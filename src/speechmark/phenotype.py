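"""Unsupervised phenotyping: PAM clustering on Gower distances, cluster-count
selection by the Gap statistic, majority-rule participant subgrouping, and
subgroup speech profiles from linear mixed models.

Age/sex-adjusted composite markers (continuous) plus the clinical diagnosis
(categorical) are clustered with Partitioning Around Medoids on the Gower
dissimilarity (range-normalized Manhattan for continuous columns, simple
matching for categorical). The cluster count is chosen by the Gap statistic
against uniform reference data with the first-SE-max rule. Each participant
is assigned to the cluster holding the majority of their sentences, and each
subgroup's marker profile is contrasted against the healthy-control baseline
with a random-intercept mixed model, Cohen's d effect sizes, and
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


def gower_matrix(df: pd.DataFrame, cat_cols: list[str] | None = None) -> np.ndarray:
    """Pairwise Gower dissimilarity for mixed continuous/categorical data.

    Continuous columns contribute |x_i - x_j| / range (0 for zero-range
    columns); categorical columns contribute 1 for a mismatch. The distance
    is the unweighted mean over columns.
    """
    cat_cols = cat_cols or []
    n = len(df)
    total = np.zeros((n, n))
    for col in df.columns:
        vals = df[col].to_numpy()
        if col in cat_cols:
            total += (vals[:, None] != vals[None, :]).astype(np.float64)
        else:
            x = vals.astype(np.float64)
            rng = np.ptp(x)
            if rng > 0:
                total += np.abs(x[:, None] - x[None, :]) / rng
    return total / df.shape[1]


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    labels = np.argmin(sub, axis=1)
    return labels, float(sub[np.arange(len(D)), labels].sum())


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning Around Medoids (BUILD + SWAP) on a dissimilarity matrix.

    Deterministic: BUILD is greedy and ties break toward the lower index.
    Returns (medoid indices, labels in medoid order, total cost).
    """
    n = len(D)
    if k < 1 or k > n:
        raise ValueError("k out of range")
    if np.ptp(D) == 0 and k > 1:
        raise ValueError("all rows identical; clustering is undefined")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dmin = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        dmin = np.minimum(dmin, D[:, new])
    medoids_arr = np.array(sorted(medoids))
    _, cost = _assign(D, medoids_arr)
    # SWAP
    for _ in range(max_iter):
        sub = D[:, medoids_arr]
        part = np.partition(sub, 1, axis=1) if k > 1 else None
        nearest = np.argmin(sub, axis=1)
        d1 = sub[np.arange(n), nearest]
        d2 = part[:, 1] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        for mi in range(k):
            # distance to nearest medoid excluding medoid mi
            e = np.where(nearest == mi, d2, d1)
            cand_cost = np.minimum(D[:, non_medoids], e[:, None]).sum(axis=0)
            ci = int(np.argmin(cand_cost))
            delta = cost - float(cand_cost[ci])
            if delta > best_delta:
                best_delta, best_swap = delta, (mi, non_medoids[ci])
        if best_swap is None:
            break
        mi, h = best_swap
        medoids_arr[mi] = h
        medoids_arr = np.sort(medoids_arr)
        _, cost = _assign(D, medoids_arr)
    labels, cost = _assign(D, medoids_arr)
    return medoids_arr, labels, cost


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani W_k: sum over clusters of (sum of pairwise d) / (2 n_r)."""
    w = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            w += D[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return w


def gap_statistic(
    df: pd.DataFrame,
    cat_cols: list[str],
    k_range: range,
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap statistic for PAM/Gower over candidate cluster counts.

    Reference data draw each continuous column uniformly over its observed
    range and each categorical column uniformly over its observed levels.
    Returns a table of (k, logW, E_logW, gap, sk).
    """
    rng = np.random.default_rng(seed)
    D = gower_matrix(df, cat_cols)
    ks = list(k_range)
    logW = []
    for k in ks:
        _, labels, _ = pam(D, k)
        logW.append(np.log(max(_within_dispersion(D, labels), 1e-12)))
    ref_logW = np.zeros((B, len(ks)))
    cont_cols = [c for c in df.columns if c not in cat_cols]
    lo = df[cont_cols].min()
    hi = df[cont_cols].max()
    for b in range(B):
        ref = pd.DataFrame(index=range(len(df)))
        for c in cont_cols:
            ref[c] = rng.uniform(lo[c], hi[c], len(df))
        for c in cat_cols:
            ref[c] = rng.choice(df[c].unique(), len(df))
        Dr = gower_matrix(ref[df.columns], cat_cols)
        for j, k in enumerate(ks):
            _, labels, _ = pam(Dr, k)
            ref_logW[b, j] = np.log(max(_within_dispersion(Dr, labels), 1e-12))
    gap = ref_logW.mean(axis=0) - np.array(logW)
    sk = ref_logW.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return pd.DataFrame({"k": ks, "logW": logW, "E_logW": ref_logW.mean(axis=0),
                         "gap": gap, "sk": sk})


def select_k(gap_table: pd.DataFrame) -> int:
    """First-SE-max rule: smallest k with gap(k) >= gap(k+1) - s(k+1)."""
    gaps = gap_table["gap"].to_numpy()
    sks = gap_table["sk"].to_numpy()
    ks = gap_table["k"].to_numpy()
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return int(ks[i])
    return int(ks[np.argmax(gaps)])


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray
    labels: np.ndarray  # per-sample cluster index (0-based)
    gap_table: pd.DataFrame
    subgroups: dict = field(default_factory=dict)  # subject_id -> cluster index


def majority_subgroups(
    labels: np.ndarray, subject_ids: np.ndarray | pd.Series
) -> dict:
    """Assign each participant to the cluster holding most of their samples.

    Ties break toward the lower cluster index.
    """
    df = pd.DataFrame({"subject": np.asarray(subject_ids), "cluster": labels})
    out = {}
    for subject, grp in df.groupby("subject"):
        counts = grp["cluster"].value_counts()
        top = counts.max()
        out[subject] = int(min(c for c in counts.index if counts[c] == top))
    return out


def pam_gower(
    adjusted_markers: pd.DataFrame,
    diagnosis: pd.Series | np.ndarray,
    subject_ids: pd.Series | np.ndarray,
    k_range: range = range(1, 7),
    B: int = 100,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster disease samples on adjusted markers + diagnosis via PAM/Gower.

    The cluster count is selected by the Gap statistic (first-SE-max);
    participants are subgrouped by majority rule over their samples.
    """
    df = adjusted_markers.copy()
    df["diagnosis"] = np.asarray(diagnosis)
    gap_table = gap_statistic(df, ["diagnosis"], k_range, B=B, seed=seed)
    k = select_k(gap_table)
    D = gower_matrix(df, ["diagnosis"])
    medoids, labels, _ = pam(D, k)
    subgroups = majority_subgroups(labels, subject_ids)
    return ClusteringResult(k=k, medoids=medoids, labels=labels,
                            gap_table=gap_table, subgroups=subgroups)


def subgroup_profiles(
    adjusted_markers: pd.DataFrame,
    subgroup: pd.Series | np.ndarray,
    subject_ids: pd.Series | np.ndarray,
    baseline: str = "HC",
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Marker profiles of each subgroup vs the baseline group.

    Per marker, a linear mixed model with subgroup as fixed effect and a
    subject random intercept; the estimated marginal-mean contrast of each
    subgroup vs baseline, Cohen's d (contrast / total SD from the model),
    and BH-FDR-adjusted p-values across all subgroup x marker tests. Falls
    back to OLS with subject-cluster-robust errors when subjects lack
    repeated samples.
    """
    sub = pd.Series(np.asarray(subgroup).astype(str), name="subgroup")
    subj = pd.Series(np.asarray(subject_ids).astype(str), name="subject")
    levels = sorted(set(sub) - {baseline})
    if baseline not in set(sub):
        raise ValueError(f"baseline group {baseline!r} absent")
    if not levels:
        raise ValueError("need at least one non-baseline subgroup")
    repeated = subj.groupby(subj).size().min() >= 2
    rows = []
    for marker in adjusted_markers.columns:
        data = pd.DataFrame({
            "y": adjusted_markers[marker].to_numpy(dtype=np.float64),
            "subgroup": pd.Categorical(sub, categories=[baseline] + levels),
            "subject": subj.to_numpy(),
        })
        if repeated:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # powell is robust when the random-intercept variance sits at 0
                model = smf.mixedlm("y ~ C(subgroup)", data, groups=data["subject"]).fit(
                    reml=True, method="powell"
                )
            total_sd = float(np.sqrt(model.cov_re.iloc[0, 0] + model.scale))
            params, pvals = model.params, model.pvalues
        else:
            ols = smf.ols("y ~ C(subgroup)", data).fit(
                cov_type="cluster", cov_kwds={"groups": data["subject"]}
            )
            total_sd = float(np.sqrt(ols.mse_resid))
            params, pvals = ols.params, ols.pvalues
        for level in levels:
            term = f"C(subgroup)[T.{level}]"
            diff = float(params[term])
            rows.append({
                "marker": marker,
                "subgroup": level,
                "emm_diff": diff,
                "cohens_d": diff / total_sd if total_sd > 0 else 0.0,
                "p": float(pvals[term]),
            })
    out = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(out["p"], alpha=fdr_q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and rejection mask."""
    reject, p_adj, *_ = multipletests(np.asarray(pvalues), alpha=q, method="fdr_bh")
    return p_adj, reject
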