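"""Pipeline orchestration: extract -> factor markers -> evaluate.

``run_extract`` produces the per-sample 50-feature table (failures are
isolated per sample into an ``error`` column); ``run_full`` continues through
factor analysis, regression, classification, and phenotyping, writing all
artifacts plus the exact config and seed needed to regenerate them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from speechmark import evaluation, phenotype, temporal
from speechmark.audio import load_audio, load_manifest
from speechmark.config import DEFAULT_CONFIG, save_config
from speechmark.factors import fit_factor_model, score_markers
from speechmark.features import FEATURE_NAMES, extract_features

_META_COLS = ["sample_id", "subject_id", "group", "sex", "age", "word_count",
              "moca", "intelligibility", "efficiency"]
_METRICS = ["moca", "intelligibility", "efficiency"]


def _articulation_rates(manifest: pd.DataFrame, cfg: dict) -> pd.Series:
    p = cfg["pause"]
    rates = {}
    for _, row in manifest.iterrows():
        try:
            audio = load_audio(row["path"], row)
            seg = temporal.detect_pauses(
                audio, min_pause=p["min_pause_s"], min_speech=p["min_speech_s"],
                amp_thresh=p["amp_thresh"], env_window=p["env_window_s"],
            )
            rates[row["sample_id"]] = temporal.articulation_rate(seg, audio.word_count)
        except (ValueError, FileNotFoundError):
            rates[row["sample_id"]] = np.nan
    return pd.Series(rates)


def normative_rate(manifest: pd.DataFrame, cfg: dict) -> float:
    """The empirical articulation-rate norm: mean AR of the HC rows.

    Falls back to the overall mean (with a warning) when the manifest has no
    healthy-control rows; config ``rhythm.ar_norm`` overrides both.
    """
    override = cfg["rhythm"].get("ar_norm")
    if override:
        return float(override)
    rates = _articulation_rates(manifest, cfg)
    if "group" in manifest.columns and (manifest["group"] == "HC").any():
        hc_ids = manifest.loc[manifest["group"] == "HC", "sample_id"]
        return float(rates[hc_ids].mean())
    warnings.warn("no HC rows; using overall mean articulation rate as norm", stacklevel=2)
    return float(rates.mean())


def run_extract(
    manifest: pd.DataFrame | str | Path,
    config: dict | None = None,
    ar_norm: float | None = None,
) -> pd.DataFrame:
    """Extract the 50-feature vector for every manifest row.

    Per-sample failures are captured in the ``error`` column and do not
    abort the run. Columns: metadata, 50 features, ``unvoiced`` flag,
    ``error``.
    """
    cfg = config or DEFAULT_CONFIG
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if ar_norm is None:
        ar_norm = normative_rate(manifest, cfg)
    rows = []
    for _, mrow in manifest.iterrows():
        record = {c: mrow.get(c) for c in _META_COLS if c in manifest.columns}
        try:
            audio = load_audio(mrow["path"], mrow)
            feats, flags = extract_features(audio, ar_norm=ar_norm, config=cfg)
            record.update(feats)
            record["unvoiced"] = flags["unvoiced"]
            record["error"] = ""
        except (ValueError, FileNotFoundError, KeyError) as exc:
            record["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(record)
    out = pd.DataFrame(rows)
    out.attrs["ar_norm"] = ar_norm
    return out


def run_full(
    manifest: pd.DataFrame | str | Path,
    config: dict | None = None,
    outdir: str | Path = "speechmark_out",
) -> dict:
    """Full pipeline: features, factor model, markers, and the three
    clinical-utility analyses. Writes artifacts under ``outdir`` and returns
    them in memory."""
    cfg = config or DEFAULT_CONFIG
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    seed = int(cfg.get("seed", 0))

    table = run_extract(manifest, cfg)
    table.to_csv(outdir / "features.csv", index=False)
    ok = table[table["error"] == ""].reset_index(drop=True)
    if len(ok) < 3:
        raise ValueError("too few successfully extracted samples")

    fcfg = cfg["factor"]
    live = [c for c in FEATURE_NAMES if ok[c].std(ddof=1) > 0]
    if len(live) < len(FEATURE_NAMES):
        dead = sorted(set(FEATURE_NAMES) - set(live))
        warnings.warn(f"dropping constant feature columns before factoring: {dead}",
                      stacklevel=2)
    model = fit_factor_model(
        ok[live], k=fcfg["k"], seed=seed,
        n_resamples=fcfg["pa_resamples"], percentile=fcfg["pa_percentile"],
        gamma=fcfg["oblimin_gamma"], feature_names=live,
    )
    model.to_json(outdir / "factor_model.json")
    markers = score_markers(model, ok[live])
    markers_out = pd.concat(
        [ok[[c for c in _META_COLS if c in ok.columns]], markers], axis=1
    )
    markers_out.to_csv(outdir / "markers.csv", index=False)
    artifacts: dict = {"features": table, "model": model, "markers": markers_out}

    regression = {}
    for metric in _METRICS:
        if metric not in ok.columns or ok[metric].isna().all():
            warnings.warn(f"metric {metric} missing; regression skipped", stacklevel=2)
            continue
        regression[metric] = evaluation.stepwise_regression(
            markers, ok[metric], subject_ids=ok["subject_id"],
            level=cfg["regression"]["level"],
        )
    metrics_present = [m for m in _METRICS if m in regression]
    if len(metrics_present) >= 2:
        per_subj = ok.groupby("subject_id")[metrics_present].mean()
        rho, pval = evaluation.spearman_matrix(per_subj)
        regression["spearman"] = {"rho": rho.to_dict(), "p": pval.to_dict()}
    if regression:
        (outdir / "regression.json").write_text(json.dumps(regression, indent=1))
        artifacts["regression"] = regression

    if "group" in ok.columns and ok["group"].notna().all() and ok["group"].nunique() >= 2:
        ccfg = cfg["classify"]
        groups = ok["subject_id"].to_numpy() if ccfg["group_by_subject"] else None
        classification = {}
        roc_rows = []
        for algo in ccfg["algos"]:
            rep = evaluation.crossval_classify(
                markers, ok["group"], algo=algo, folds=ccfg["folds"],
                repeats=ccfg["repeats"], seed=seed, groups=groups,
                rf_trees=ccfg["rf_trees"],
            )
            roc = rep.pop("roc")
            for pair, pts in roc.items():
                for fpr, tpr in zip(pts["fpr"], pts["tpr"]):
                    roc_rows.append({"algorithm": algo, "pair": pair,
                                     "fpr": fpr, "tpr": tpr})
            classification[algo] = rep
        (outdir / "classification.json").write_text(json.dumps(classification, indent=1))
        pd.DataFrame(roc_rows).to_csv(outdir / "roc.csv", index=False)
        artifacts["classification"] = classification

    disease = ok[ok["group"].isin(["ALS", "PD"])] if "group" in ok.columns else ok.iloc[0:0]
    if len(disease) >= 4 and {"age", "sex"}.issubset(ok.columns):
        kcfg = cfg["cluster"]
        adjusted = evaluation.adjust_age_sex(
            markers, ok["age"].to_numpy(dtype=float), ok["sex"].to_numpy()
        )
        adj_dis = adjusted.loc[disease.index]
        result = phenotype.pam_gower(
            adj_dis, disease["group"], disease["subject_id"],
            k_range=range(kcfg["k_min"], kcfg["k_max"] + 1),
            B=kcfg["gap_B"], seed=seed,
        )
        sample_subgroup = np.where(
            ok["group"] == "HC", "HC",
            ok["subject_id"].map(result.subgroups).map(
                lambda c: f"C{int(c) + 1}" if pd.notna(c) else "NA"
            ),
        )
        keep = sample_subgroup != "NA"
        profiles = phenotype.subgroup_profiles(
            adjusted.loc[ok.index[keep]],
            pd.Series(sample_subgroup[keep]),
            ok.loc[keep, "subject_id"],
            baseline="HC",
        )
        clustering = {
            "k": int(result.k),
            "medoid_sample_ids": disease["sample_id"].to_numpy()[result.medoids].tolist(),
            "gap": result.gap_table.to_dict(orient="list"),
            "subgroups": {str(s): int(c) for s, c in result.subgroups.items()},
        }
        (outdir / "clustering.json").write_text(json.dumps(clustering, indent=1))
        profiles.to_csv(outdir / "profiles.csv", index=False)
        artifacts["clustering"] = result
        artifacts["profiles"] = profiles

    save_config({**cfg, "seed": seed}, outdir / "run_config.yaml")
    return artifacts
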