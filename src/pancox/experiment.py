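"""Pan-cancer vs single-cancer comparison harness.

Builds the feature matrix from simulated cohort tables, runs the
screening / imputation / finalization pipeline with training-only
statistics, fits CV-tuned lasso Cox models in two training scopes (pan:
pooled with cancer-type covariates; single: per cancer with its own
preprocessing statistics), and scores each cancer's held-out test set
with c-index, IBS and the median-split HR, optionally with
bias-corrected bootstrap intervals.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DataError, FitError
from .evaluate import (bc_bootstrap_ci, concordance_index, integrated_brier_score,
                       risk_stratify_and_hr)
from .features import (FeatureConfig, FeatureMatrix, finalize_matrix, make_meta,
                       screen_features, summarize_lab_series, encode_genomics,
                       zero_fill_out_of_scope)
from .impute import impute_chained, impute_knn
from .model import fit_cv_cox
from .simulate import Cohort

DEMOGRAPHIC_FEATURES = ("age", "sex", "race", "smoking", "stage", "ecog",
                        "days_dx_to_1l")
BENCHMARK_FEATURES = DEMOGRAPHIC_FEATURES + ("entry_time",)  # + cancer type in pan


@dataclass(frozen=True)
class ModelSpec:
    """A comparator model: which features, which penalties, strata or not."""

    name: str
    features: tuple[str, ...] | None = None   # None = all surviving features
    penalty_overrides: tuple[tuple[str, float], ...] = ()
    strata: bool = False


def benchmark_spec() -> ModelSpec:
    return ModelSpec("benchmark", features=BENCHMARK_FEATURES)


def ropro_like_spec(lab_stats=("mean", "min", "max", "prop_abnormal", "slope_last2"),
                    window: int = 720) -> ModelSpec:
    """Benchmark plus a configurable set of ~20 lab-summary features."""
    return ModelSpec("ropro_like", features=BENCHMARK_FEATURES
                     + (f"__lab__w{window}__" + "|".join(lab_stats),))


def full_spec() -> ModelSpec:
    return ModelSpec("full", features=None)


# ----------------------------------------------------------------------
# splitting


def stratified_split(subjects: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Per-cancer random split; test counts are round(f * n_c)."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cancer, grp in subjects.groupby("cancer_type", sort=True):
        ids = grp["subject_id"].to_numpy()
        n = len(ids)
        if n < 2:
            raise DataError(f"cancer type {cancer!r} has fewer than 2 subjects")
        n_test = int(np.clip(round(test_fraction * n), 1, n - 1))
        perm = rng.permutation(n)
        test.extend(ids[perm[:n_test]].tolist())
        train.extend(ids[perm[n_test:]].tolist())
    return sorted(train), sorted(test)


# ----------------------------------------------------------------------
# feature-matrix assembly


def build_raw_features(cohort: Cohort, feature_config: FeatureConfig | None = None,
                       mode: str = "full") -> FeatureMatrix:
    """Raw (pre-screening) matrix from the simulator tables.

    ``mode='direct'`` uses only subject-table covariates (fast, for
    large simulation studies); ``mode='full'`` adds windowed lab
    summaries and the genomic encodings.
    """
    feature_config = feature_config or FeatureConfig()
    s = cohort.subjects.set_index("subject_id")
    parts, metas = [], []

    demo = s[list(DEMOGRAPHIC_FEATURES)].copy()
    demo["ecog"] = demo["ecog"].astype(float)
    parts.append(demo)
    metas.append(make_meta(DEMOGRAPHIC_FEATURES, "demographic"))
    parts.append(s[["entry_time"]].astype(float))
    metas.append(make_meta(["entry_time"], "treatment"))

    shared = [c for c in s.columns if c.startswith(("shared_f", "noise_f"))]
    if shared:
        parts.append(s[shared].astype(float))
        metas.append(make_meta(shared, "treatment"))
    spec_cols = [c for c in s.columns if c.startswith("spec_")]
    for c in spec_cols:
        cancer = c.split("_")[1]
        parts.append(s[[c]].astype(float))
        metas.append(make_meta([c], "cancer_specific", scope=(cancer,)))

    if mode == "full":
        for w in feature_config.windows:
            lab = summarize_lab_series(cohort.labs, w, feature_config,
                                       subject_ids=list(s.index))
            parts.append(lab)
            metas.append(make_meta(lab.columns, "lab_vitals", window=w))
        gen = encode_genomics(cohort.genomics, cohort.pathways, cohort.embeddings)
        parts.append(gen.values.reindex(s.index))
        metas.append(gen.meta)
    elif mode != "direct":
        raise DataError(f"unknown feature mode {mode!r}")

    values = pd.concat(parts, axis=1)
    meta = pd.concat(metas)
    return FeatureMatrix(values, meta)


def impute_matrix(matrix: FeatureMatrix, training_ids, knn_k: int = 5,
                  chained_iterations: int = 5, seed: int = 0,
                  reference_block: pd.DataFrame | None = None) -> FeatureMatrix:
    """kNN for genomic columns, chained equations for clinical columns."""
    out = matrix.copy()
    numeric = [c for c in out.feature_names
               if pd.api.types.is_numeric_dtype(out.values[c])]
    genomic = [c for c in numeric if out.meta.loc[c, "modality"] == "genomic"
               and out.values[c].isna().any()]
    clinical = [c for c in numeric if out.meta.loc[c, "modality"] != "genomic"
                and out.values[c].isna().any()]
    if genomic:
        gcols = [c for c in numeric if out.meta.loc[c, "modality"] == "genomic"]
        ref = reference_block[gcols] if reference_block is not None else None
        out.values[gcols] = impute_knn(out.values[gcols], k=knn_k,
                                       training_ids=training_ids,
                                       reference_block=ref)
    if clinical:
        block_cols = [c for c in numeric if out.meta.loc[c, "modality"] != "genomic"]
        complete = impute_chained(out.values[block_cols], n_iterations=chained_iterations,
                                  n_datasets=1, seed=seed, training_ids=training_ids)[0]
        out.values[block_cols] = complete
    return out


def _expand_spec_features(spec: ModelSpec, fm: FeatureMatrix) -> list[str] | None:
    """Map requested base features to finalized column names."""
    if spec.features is None:
        return None
    cols = []
    names = fm.feature_names
    for f in spec.features:
        if f.startswith("__lab__"):
            # pattern: __lab__w{W}__stat1|stat2
            body = f[len("__lab__"):]
            wtag, statlist = body.split("__")
            stats = statlist.split("|")
            for c in names:
                meta = fm.meta.loc[c]
                if meta["modality"] == "lab_vitals" and f"_{wtag}_" in c and \
                        any(c.endswith("_" + st) for st in stats):
                    cols.append(c)
            continue
        hits = [c for c in names if c == f or c.startswith(f + "=")]
        if not hits:
            raise DataError(f"model spec {spec.name!r}: feature {f!r} not in matrix")
        cols.extend(hits)
    seen = set()
    return [c for c in cols if not (c in seen or seen.add(c))]


# ----------------------------------------------------------------------
# scope fitting


@dataclass
class ScopeFit:
    fit: object
    features: list[str]
    X: pd.DataFrame          # finalized matrix rows for all subjects in scope
    y: pd.DataFrame
    train_ids: list[str]
    stats_digest: str


def _response_for(subjects: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "entry": subjects["entry_time"].to_numpy(dtype=float),
        "exit": subjects["exit_time"].to_numpy(dtype=float),
        "status": subjects["event_status"].to_numpy(dtype=int),
    }, index=subjects["subject_id"])


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def fit_scope(raw_fm: FeatureMatrix, subjects: pd.DataFrame, train_ids,
              spec: ModelSpec, seed: int, feature_config: FeatureConfig | None = None,
              include_cancer_covariate: bool = True, knn_k: int = 5,
              n_lambda: int = 50, lambda_min_ratio: float = 0.05,
              n_folds: int = 5) -> ScopeFit:
    """Run screening -> imputation -> finalization -> CV lasso for one scope.

    Every fitted statistic derives from ``train_ids`` only.
    """
    feature_config = feature_config or FeatureConfig()
    s = subjects.set_index("subject_id")
    cancers = s["cancer_type"]
    raw_fm = raw_fm.select([c for c in raw_fm.feature_names])
    raw_fm = FeatureMatrix(raw_fm.values.loc[s.index], raw_fm.meta, dict(raw_fm.stats),
                           raw_fm.finalized)
    train_ids = [t for t in train_ids if t in set(s.index)]

    # structured missingness resolves to 0 before screening, so pan-scope
    # cancer-specific features are not discarded by the missingness filter
    fm = zero_fill_out_of_scope(raw_fm, cancers)
    fm = screen_features(fm, feature_config, train_ids)
    fm = impute_matrix(fm, train_ids, knn_k=knn_k, seed=seed)
    fm = finalize_matrix(fm, train_ids, config=feature_config)

    X = fm.values.copy()
    penalty = {c: 1.0 for c in X.columns}
    penalty["entry_time"] = 0.0

    if include_cancer_covariate:
        levels = cancers.loc[train_ids].value_counts()
        reference = levels.idxmax()
        for level in sorted(c for c in cancers.unique() if c != reference):
            col = f"cancer_type={level}"
            X[col] = (cancers == level).astype(float)
            penalty[col] = 0.0

    cols = _expand_spec_features(spec, fm)
    if cols is not None:
        keep = [c for c in X.columns if c in set(cols) or c.startswith("cancer_type=")
                or c == "entry_time"]
        X = X[keep]
    for name, pf in spec.penalty_overrides:
        if name in X.columns:
            penalty[name] = pf
    pf_vec = np.array([penalty[c] for c in X.columns])

    y = _response_for(subjects).loc[X.index]
    Xtr, ytr = X.loc[train_ids], y.loc[train_ids]
    strata = cancers.loc[train_ids].to_numpy() if spec.strata else None
    fold_strata = (cancers.loc[train_ids].astype(str) + "|"
                   + ytr["status"].astype(str)).to_numpy()
    fit = fit_cv_cox(Xtr, ytr, penalty_factors=pf_vec, strata=strata,
                     fold_strata=fold_strata, n_folds=n_folds, seed=seed,
                     n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    digest = _digest({
        "screen": fm.stats.get("screen_report"),
        "finalize": fm.stats.get("finalize"),
        "selected_lambda": fit.selected_lambda,
        "coefs": fit.coef().round(10).to_dict(),
    })
    return ScopeFit(fit, list(X.columns), X, y, train_ids, digest)


# ----------------------------------------------------------------------
# evaluation of one (model, cancer) cell


def _evaluate_cell(sf: ScopeFit, test_ids, cancer_label_, bootstrap_B: int,
                   bootstrap_mode: str, seed: int, compute_ibs: bool = True,
                   compute_hr: bool = True) -> dict:
    train_scores = sf.fit.predict_risk(sf.X.loc[sf.train_ids])
    lp_test = sf.fit.predict_lp(sf.X.loc[test_ids])
    y_test = sf.y.loc[test_ids]
    y_train = sf.y.loc[sf.train_ids]

    out = {"n_test": len(test_ids), "n_events": int(y_test["status"].sum())}
    try:
        c, ncomp = concordance_index(y_test["entry"], y_test["exit"],
                                     y_test["status"], lp_test)
    except FitError:
        out.update(c_index=np.nan, flag="no_comparable_pairs")
        return out
    out.update(c_index=c, n_comparable=ncomp)

    grid = None
    surv = None
    if compute_ibs:
        t_hi = float(np.quantile(y_test["exit"], 0.95))
        t_lo = float(y_test.loc[y_test["status"] == 1, "exit"].min())
        if t_hi > t_lo:
            grid = np.linspace(t_lo, t_hi, 50)
            surv = sf.fit.predict_survival(sf.X.loc[test_ids], grid)
            out["ibs"] = integrated_brier_score(y_train, y_test, surv, grid)

    if compute_hr:
        strat = risk_stratify_and_hr(train_scores, np.exp(lp_test), y_test)
        out.update(hr=strat.hr_low_vs_high, hr_lo=strat.ci[0], hr_hi=strat.ci[1],
                   hr_defined=strat.defined)

    if bootstrap_B > 0:
        test_df = pd.DataFrame({"lp": lp_test, "entry": y_test["entry"].to_numpy(),
                                "exit": y_test["exit"].to_numpy(),
                                "status": y_test["status"].to_numpy()})

        if bootstrap_mode == "refit":
            # resample training rows and refit the Cox model at the selected
            # lambda before re-evaluating (preprocessing statistics reused)
            from .model import fit_penalized_cox

            Xtr_all = sf.X.loc[sf.train_ids]
            ytr_all = sf.y.loc[sf.train_ids]
            Xte_all = sf.X.loc[test_ids]
            train_df = pd.DataFrame({"row": np.arange(len(sf.train_ids))})
            lam = sf.fit.selected_lambda

            def c_stat(tr, te):
                ridx = tr["row"].to_numpy()
                f2 = fit_penalized_cox(
                    Xtr_all.iloc[ridx], ytr_all.iloc[ridx],
                    penalty_factors=sf.fit.penalty_factors,
                    lambda_path=np.array([lam]))
                lp2 = f2.predict_lp(Xte_all.loc[te.index])
                return concordance_index(te["entry"], te["exit"], te["status"], lp2)[0]

            _, lo, hi = bc_bootstrap_ci(c_stat, train_df, test_df,
                                        B=bootstrap_B, seed=seed)
        else:
            def c_stat(_tr, te):
                return concordance_index(te["entry"], te["exit"], te["status"],
                                         te["lp"])[0]

            _, lo, hi = bc_bootstrap_ci(c_stat, None, test_df, B=bootstrap_B,
                                        seed=seed)
        out.update(c_lo=lo, c_hi=hi)
        if compute_ibs and surv is not None:
            surv_df = pd.DataFrame(surv, index=test_df.index)

            def ibs_stat(_tr, te):
                return integrated_brier_score(
                    y_train, te.rename(columns=str)[["entry", "exit", "status"]],
                    surv_df.loc[te.index].to_numpy(), grid)

            try:
                _, lo, hi = bc_bootstrap_ci(ibs_stat, None, test_df, B=bootstrap_B,
                                            seed=seed + 1)
                out.update(ibs_lo=lo, ibs_hi=hi)
            except (FitError, DataError):
                pass
    return out


def transfer_contrast(cohort: Cohort, target_cancer: str, seed: int = 0,
                      feature_mode: str = "direct", spec: ModelSpec | None = None,
                      n_lambda: int = 15, lambda_min_ratio: float = 0.08,
                      n_folds: int = 3) -> dict:
    """Pan-scope vs single-scope test c-index on one target cancer cohort.

    A light-weight probe of the transfer effect: both scopes are fit with
    their own training-only preprocessing and scored on the target
    cancer's held-out subjects.
    """
    spec = spec or full_spec()
    subjects = cohort.subjects
    train_ids, test_ids = stratified_split(subjects, 0.2, seed)
    raw_fm = build_raw_features(cohort, mode=feature_mode)
    by = subjects.set_index("subject_id")["cancer_type"]
    te_c = [t for t in test_ids if by[t] == target_cancer]

    pan = fit_scope(raw_fm, subjects, train_ids, spec, seed,
                    include_cancer_covariate=True, n_lambda=n_lambda,
                    lambda_min_ratio=lambda_min_ratio, n_folds=n_folds)
    c_pan, _ = concordance_index(
        pan.y.loc[te_c, "entry"], pan.y.loc[te_c, "exit"],
        pan.y.loc[te_c, "status"], pan.fit.predict_lp(pan.X.loc[te_c]))

    sub = subjects[subjects["cancer_type"] == target_cancer]
    tr_c = [t for t in train_ids if by[t] == target_cancer]
    single = fit_scope(raw_fm, sub, tr_c, spec, seed,
                       include_cancer_covariate=False, n_lambda=n_lambda,
                       lambda_min_ratio=lambda_min_ratio, n_folds=n_folds)
    c_single, _ = concordance_index(
        single.y.loc[te_c, "entry"], single.y.loc[te_c, "exit"],
        single.y.loc[te_c, "status"], single.fit.predict_lp(single.X.loc[te_c]))
    return {"pan_cindex": float(c_pan), "single_cindex": float(c_single),
            "n_test": len(te_c),
            "pan_selected": int((pan.fit.coef() != 0).sum()),
            "single_selected": int((single.fit.coef() != 0).sum())}


# ----------------------------------------------------------------------
# the comparison harness


def run_pan_vs_single(cohort: Cohort, model_specs=None, seed: int = 0,
                      test_fraction: float = 0.2, feature_mode: str = "full",
                      feature_config: FeatureConfig | None = None,
                      bootstrap_B: int = 0, bootstrap_mode: str = "score",
                      n_lambda: int = 50, lambda_min_ratio: float = 0.05,
                      n_folds: int = 5, compute_ibs: bool = True,
                      compute_hr: bool = True) -> pd.DataFrame:
    """Fit every model spec in pan and single scopes and score per cancer.

    Pan models are fit once on pooled training data with unpenalized
    cancer-type and entry-time covariates; single models are refit per
    cancer with that cancer's own screening/normalization statistics and
    no cancer covariate.  Both are evaluated on each cancer's held-out
    test subjects.  Returns the comparison table.
    """
    if model_specs is None:
        model_specs = [full_spec()]
    subjects = cohort.subjects
    cancers = sorted(subjects["cancer_type"].unique())
    train_ids, test_ids = stratified_split(subjects, test_fraction, seed)
    raw_fm = build_raw_features(cohort, feature_config, mode=feature_mode)
    by_cancer = subjects.set_index("subject_id")["cancer_type"]

    rows = []
    for spec in model_specs:
        pan_sf = fit_scope(raw_fm, subjects, train_ids, spec, seed,
                           feature_config, include_cancer_covariate=True,
                           n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                           n_folds=n_folds)
        n_sel = int((pan_sf.fit.coef() != 0).sum())
        pan_cells = {}
        # overall pan row
        cell = _evaluate_cell(pan_sf, test_ids, "pan", bootstrap_B, bootstrap_mode,
                              seed, compute_ibs, compute_hr)
        rows.append({"cancer_type": "pan", "model": spec.name, "scope": "pan",
                     "n_train": len(train_ids), "n_selected": n_sel, "seed": seed,
                     **cell})
        for cancer in cancers:
            ids_c = [t for t in test_ids if by_cancer[t] == cancer]
            cell = _evaluate_cell(pan_sf, ids_c, cancer, bootstrap_B, bootstrap_mode,
                                  seed, compute_ibs, compute_hr)
            rows.append({"cancer_type": cancer, "model": spec.name, "scope": "pan",
                         "n_train": len(train_ids), "n_selected": n_sel,
                         "seed": seed, **cell})

        for cancer in cancers:
            sub_c = subjects[subjects["cancer_type"] == cancer]
            tr_c = [t for t in train_ids if by_cancer[t] == cancer]
            te_c = [t for t in test_ids if by_cancer[t] == cancer]
            try:
                sf = fit_scope(raw_fm, sub_c, tr_c, spec, seed, feature_config,
                               include_cancer_covariate=False, n_lambda=n_lambda,
                               lambda_min_ratio=lambda_min_ratio, n_folds=n_folds)
            except (FitError, DataError) as exc:
                rows.append({"cancer_type": cancer, "model": spec.name,
                             "scope": "single", "n_train": len(tr_c), "seed": seed,
                             "flag": f"unfit: {exc}"})
                continue
            cell = _evaluate_cell(sf, te_c, cancer, bootstrap_B, bootstrap_mode,
                                  seed, compute_ibs, compute_hr)
            rows.append({"cancer_type": cancer, "model": spec.name, "scope": "single",
                         "n_train": len(tr_c),
                         "n_selected": int((sf.fit.coef() != 0).sum()),
                         "seed": seed, **cell})
    return pd.DataFrame(rows)
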