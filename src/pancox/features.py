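"""Clinico-genomic feature engineering.

Turns raw cohort tables into a model-ready matrix: windowed lab-series
summaries normalized to limits of normal, per-(gene, variant-class)
binary encodings with pathway flags and embedding averages, data-driven
feature screening, one-hot encoding with majority reference, z-scoring
with +/- 3-z truncation, and structured-missingness zero-filling for
cancer-specific features.  Every fitted statistic is a pure function of
the training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DataError

MODALITIES = ("demographic", "lab_vitals", "treatment", "cancer_specific", "genomic")

LAB_SUMMARY_NAMES = (
    "mean", "median", "variance", "max", "min", "apen",
    "diff_last2", "slope_last2", "n_tests", "test_rate", "prop_abnormal",
)


@dataclass(frozen=True)
class FeatureConfig:
    windows: tuple[int, ...] = (60, 720)
    apen_m: int = 2
    apen_r_factor: float = 0.2
    nzv_min_count: int = 20
    max_missing_fraction: float = 0.30
    z_truncation: float = 3.0

    def validate(self) -> None:
        if any(w <= 0 for w in self.windows):
            raise DataError("windows: must be positive day counts")
        if self.apen_m < 1:
            raise DataError("apen_m: must be >= 1")
        if self.apen_r_factor <= 0 or self.nzv_min_count <= 0:
            raise DataError("apen_r_factor and nzv_min_count must be positive")
        if not (0 < self.max_missing_fraction < 1):
            raise DataError("max_missing_fraction: must lie in (0, 1)")
        if self.z_truncation <= 0:
            raise DataError("z_truncation: must be positive")


@dataclass
class FeatureMatrix:
    """Subjects x features with per-feature metadata and fitted statistics.

    ``meta`` is indexed by feature name with columns ``modality``,
    ``window`` (nullable) and ``scope`` ('all' or a tuple of cancer
    types).  ``stats`` holds everything fitted on training rows.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    stats: dict = field(default_factory=dict)
    finalized: bool = False

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataError(f"duplicate feature name {dup!r}")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise DataError(f"features without metadata: {sorted(missing)[:5]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.meta.copy(),
                             dict(self.stats), self.finalized)

    def select(self, names) -> "FeatureMatrix":
        names = [n for n in names if n in self.values.columns]
        return FeatureMatrix(self.values[names], self.meta.loc[names],
                             dict(self.stats), self.finalized)


def make_meta(names, modality, window=None, scope="all") -> pd.DataFrame:
    return pd.DataFrame({"modality": modality, "window": window,
                         "scope": [scope] * len(names)}, index=list(names))


# ----------------------------------------------------------------------
# approximate entropy


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy with self-matches and Chebyshev distance.

    Returns NaN (missing-value sentinel) when the series is shorter than
    m + 1.  ``r`` defaults to 0.2 * SD(x); a constant series gives 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 1:
        return float("nan")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        # constant series (or degenerate tolerance): all templates match
        return 0.0

    def phi(k: int) -> float:
        count = n - k + 1
        templ = np.lib.stride_tricks.sliding_window_view(x, k)
        # Chebyshev distances between all template pairs
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        c = (d <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


# ----------------------------------------------------------------------
# lab-series window summaries


def _check_lab_table(labs: pd.DataFrame) -> None:
    required = {"subject_id", "analyte_id", "obs_time", "value", "lln", "uln"}
    missing = required - set(labs.columns)
    if missing:
        raise DataError(f"lab table is missing columns {sorted(missing)}")
    if len(labs) and np.any(labs["uln"].to_numpy() <= labs["lln"].to_numpy()):
        raise DataError("lab table has uln <= lln")
    for col in ("obs_time", "value", "lln", "uln"):
        if len(labs) and not np.all(np.isfinite(labs[col].to_numpy(dtype=float))):
            raise DataError(f"lab table has non-finite values in {col!r}")


def _summarize_one(times: np.ndarray, norm_vals: np.ndarray, abnormal: np.ndarray,
                   span_days: float, window_days: int, cfg: FeatureConfig) -> dict:
    out = dict.fromkeys(LAB_SUMMARY_NAMES, np.nan)
    n = len(norm_vals)
    out["n_tests"] = float(n)
    out["test_rate"] = float(n) / min(window_days, max(span_days, 1.0))
    if n == 0:
        return out
    out["mean"] = float(np.mean(norm_vals))
    out["median"] = float(np.median(norm_vals))
    out["max"] = float(np.max(norm_vals))
    out["min"] = float(np.min(norm_vals))
    out["prop_abnormal"] = float(np.mean(abnormal))
    if n >= 2:
        out["variance"] = float(np.var(norm_vals, ddof=1))
        out["diff_last2"] = float(norm_vals[-1] - norm_vals[-2])
        dt = times[-1] - times[-2]
        out["slope_last2"] = float((norm_vals[-1] - norm_vals[-2]) / dt) if dt > 0 else np.nan
    out["apen"] = approximate_entropy(norm_vals, m=cfg.apen_m,
                                      r=cfg.apen_r_factor * float(np.std(norm_vals)))
    return out


def summarize_lab_series(labs: pd.DataFrame, window_days: int,
                         config: FeatureConfig | None = None,
                         subject_ids=None) -> pd.DataFrame:
    """Eleven summaries per (analyte, window): wide table indexed by subject.

    Values are first mapped to (v - lln) / (uln - lln) so 0 and 1 are the
    normal-range bounds; "abnormal" means strictly outside [lln, uln].
    The window is the half-open interval [-window_days, 0) relative to
    the index date; the test_rate denominator is min(window, span of the
    subject's full lab record).
    """
    config = config or FeatureConfig()
    config.validate()
    if window_days <= 0:
        raise DataError("window_days must be positive")
    _check_lab_table(labs)

    spans = (-labs.groupby("subject_id")["obs_time"].min()).clip(lower=1.0)
    win = labs[(labs["obs_time"] >= -window_days) & (labs["obs_time"] < 0)]

    records: dict[tuple, dict] = {}
    analytes = sorted(labs["analyte_id"].unique())
    for (sid, analyte), grp in win.groupby(["subject_id", "analyte_id"], sort=True):
        grp = grp.sort_values("obs_time", kind="stable")
        t = grp["obs_time"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        lln = grp["lln"].to_numpy(dtype=float)
        uln = grp["uln"].to_numpy(dtype=float)
        norm = (v - lln) / (uln - lln)
        abnormal = (v < lln) | (v > uln)
        records[(sid, analyte)] = _summarize_one(
            t, norm, abnormal, float(spans.get(sid, 0.0)), window_days, config)

    if subject_ids is None:
        subject_ids = sorted(labs["subject_id"].unique())
    cols = {}
    for analyte in analytes:
        for stat in LAB_SUMMARY_NAMES:
            name = f"{analyte}_w{window_days}_{stat}"
            vals = []
            for sid in subject_ids:
                rec = records.get((sid, analyte))
                if rec is None:
                    if stat in ("n_tests", "test_rate"):
                        span = float(spans.get(sid, 0.0))
                        vals.append(0.0)
                    else:
                        vals.append(np.nan)
                else:
                    vals.append(rec[stat])
            cols[name] = vals
    return pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))


# ----------------------------------------------------------------------
# genomic encoding


def encode_genomics(profiles: pd.DataFrame, pathways: dict,
                    embeddings: pd.DataFrame) -> FeatureMatrix:
    """Binary (gene, class) columns, pathway-impact flags, embedding means.

    Unmeasured calls become missing (imputed downstream); a pathway is
    impacted iff any member gene has a reported alteration of any class;
    embedding features are the componentwise mean over affected genes
    (zero vector when none).
    """
    required = {"subject_id", "gene_id", "variant_class", "status"}
    if required - set(profiles.columns):
        raise DataError(f"genomic table is missing columns "
                        f"{sorted(required - set(profiles.columns))}")
    dup = profiles.duplicated(["subject_id", "gene_id", "variant_class"])
    if dup.any():
        raise DataError("duplicate (subject, gene, class) genomic records")

    status = profiles["status"].astype("Float64")
    wide = profiles.assign(status=status).pivot(
        index="subject_id", columns=["gene_id", "variant_class"], values="status")
    wide.columns = [f"{g}_{c}" for g, c in wide.columns]
    wide = wide.astype(float).sort_index(axis=1)
    subjects = wide.index

    altered = profiles[profiles["status"].astype("Float64") == 1]
    genes_by_subject = altered.groupby("subject_id")["gene_id"].agg(
        lambda s: sorted(set(s)))

    for pid, members in pathways.items():
        if not members:
            raise DataError(f"pathway {pid!r} has an empty gene set")
    path_cols = {}
    for pid, members in sorted(pathways.items()):
        member_set = set(members)
        flags = [float(bool(member_set & set(genes_by_subject.get(sid, []))))
                 for sid in subjects]
        path_cols[f"pathway_{pid}"] = flags

    d = embeddings.shape[1]
    emb = np.zeros((len(subjects), d))
    for i, sid in enumerate(subjects):
        genes = genes_by_subject.get(sid, [])
        if not genes:
            continue
        for g in genes:
            if g not in embeddings.index:
                raise DataError(f"affected gene {g!r} is absent from the embedding table")
        emb[i] = embeddings.loc[genes].to_numpy().mean(axis=0)
    emb_df = pd.DataFrame(emb, index=subjects,
                          columns=[f"embavg_{c}" for c in embeddings.columns])

    values = pd.concat([wide, pd.DataFrame(path_cols, index=subjects), emb_df], axis=1)
    meta = pd.concat([
        make_meta(wide.columns, "genomic"),
        make_meta(path_cols.keys(), "genomic"),
        make_meta(emb_df.columns, "genomic"),
    ])
    return FeatureMatrix(values, meta)


# ----------------------------------------------------------------------
# screening


def _is_dummy(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0.0, 1.0})


def screen_features(matrix: FeatureMatrix, config: FeatureConfig,
                    training_ids) -> FeatureMatrix:
    """Remove zero-variance, near-zero-variance and mostly-missing features.

    All verdicts are computed on training rows only and recorded in
    ``stats['screen_report']`` as (feature, reason, statistic) entries.
    """
    config.validate()
    training_ids = list(training_ids)
    if not training_ids:
        raise DataError("training_ids must be nonempty")
    train = matrix.values.loc[training_ids]

    report = []
    drop = []
    n_train = len(train)
    for name in matrix.feature_names:
        col = train[name]
        miss_frac = float(col.isna().mean())
        if miss_frac > config.max_missing_fraction:
            report.append({"feature": name, "reason": "missing_fraction",
                           "statistic": miss_frac})
            drop.append(name)
            continue
        obs = col.dropna()
        if obs.nunique() <= 1:
            report.append({"feature": name, "reason": "zero_variance",
                           "statistic": float(obs.nunique())})
            drop.append(name)
            continue
        if pd.api.types.is_numeric_dtype(col) and _is_dummy(col):
            pos = float((obs == 1).sum())
            if pos < config.nzv_min_count:
                report.append({"feature": name, "reason": "near_zero_variance",
                               "statistic": pos})
                drop.append(name)
    keep = [n for n in matrix.feature_names if n not in set(drop)]
    out = FeatureMatrix(matrix.values[keep], matrix.meta.loc[keep],
                        dict(matrix.stats), matrix.finalized)
    out.stats["screen_report"] = report
    out.stats["screen_training_ids"] = training_ids
    return out


# ----------------------------------------------------------------------
# structured missingness + finalization


def zero_fill_out_of_scope(matrix: FeatureMatrix, subject_cancers: pd.Series
                           ) -> FeatureMatrix:
    """Set cancer-specific features to 0 for subjects outside their scope."""
    out = matrix.copy()
    cancers = subject_cancers.reindex(out.values.index)
    for name in out.feature_names:
        scope = out.meta.loc[name, "scope"]
        if scope == "all":
            continue
        in_scope = cancers.isin(set(scope)).to_numpy()
        col = out.values[name].to_numpy(dtype=float, copy=True)
        col[~in_scope] = 0.0
        out.values[name] = col
    return out


def finalize_matrix(matrix: FeatureMatrix, training_ids,
                    subject_cancers: pd.Series | None = None,
                    config: FeatureConfig | None = None) -> FeatureMatrix:
    """One-hot encode, z-score and truncate using training statistics.

    Categoricals are expanded with the training-majority level as the
    dropped reference; continuous features are z-scored with training
    mean/SD and clipped to +/- z_truncation; dummy columns pass through
    as 0/1.  Cancer-specific features are zero-filled out of scope before
    statistics are computed.  Re-finalizing a finalized matrix is the
    identity.
    """
    config = config or FeatureConfig()
    config.validate()
    if matrix.finalized:
        return matrix.copy()
    training_ids = list(training_ids)
    if subject_cancers is not None:
        matrix = zero_fill_out_of_scope(matrix, subject_cancers)

    values = matrix.values
    train = values.loc[training_ids]

    out_cols = {}
    meta_rows = []
    fitted = {"means": {}, "sds": {}, "references": {}}
    for name in matrix.feature_names:
        col = values[name]
        meta_row = matrix.meta.loc[name]
        if not pd.api.types.is_numeric_dtype(col):
            levels = train[name].dropna().value_counts()
            if levels.empty:
                raise DataError(f"categorical {name!r} is all-missing in training")
            reference = levels.idxmax()
            fitted["references"][name] = reference
            for level in sorted(levels.index.drop(reference)):
                cname = f"{name}={level}"
                out_cols[cname] = (col == level).astype(float)
                meta_rows.append((cname, meta_row["modality"], meta_row["window"],
                                  meta_row["scope"]))
            continue
        colf = col.astype(float)
        if _is_dummy(colf):
            out_cols[name] = colf
            meta_rows.append((name, meta_row["modality"], meta_row["window"],
                              meta_row["scope"]))
            continue
        mu = float(train[name].astype(float).mean())
        sd = float(train[name].astype(float).std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"feature {name!r} has zero training SD; "
                            "screening should have removed it")
        fitted["means"][name] = mu
        fitted["sds"][name] = sd
        z = (colf - mu) / sd
        out_cols[name] = z.clip(-config.z_truncation, config.z_truncation)
        meta_rows.append((name, meta_row["modality"], meta_row["window"],
                          meta_row["scope"]))

    out_values = pd.DataFrame(out_cols, index=values.index)
    out_meta = pd.DataFrame(
        [(m, w, s) for _, m, w, s in meta_rows],
        index=[n for n, *_ in meta_rows],
        columns=["modality", "window", "scope"])
    out = FeatureMatrix(out_values, out_meta, dict(matrix.stats), finalized=True)
    out.stats["finalize"] = fitted
    out.stats["finalize_training_ids"] = training_ids
    return out
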