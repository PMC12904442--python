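"""Missing-value imputation fitted on training rows only.

Genomic blocks use deterministic k-nearest-neighbor imputation (donors =
training rows plus optional reference rows, e.g. an external panel
cohort); clinical blocks use chained equations with predictive-mean
matching for continuous columns and logistic draws for binary ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from ._exceptions import DataError


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0.0, 1.0})


# ----------------------------------------------------------------------
# kNN


def _knn_distances(target: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Euclidean over co-observed features, scaled by their count.

    d(i, j) = sqrt(mean over co-observed features of squared difference);
    infinite when nothing is co-observed.
    """
    diff = donors - target[None, :]
    co = np.isfinite(diff)
    sq = np.where(co, diff ** 2, 0.0)
    n_co = co.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=1) / n_co)
    d[n_co == 0] = np.inf
    return d


def impute_knn(block: pd.DataFrame, k: int, training_ids=None,
               reference_block: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministic kNN imputation; donors are training + reference rows.

    Each missing entry is the unweighted mean of the k nearest donors
    that observe the feature; binary features are rounded to {0, 1} at
    0.5 with ties going to 0.  Falls back to all available donors when
    fewer than k observe a feature, and to the donor column median when
    none do.  Observed values are never altered.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    out = block.copy().astype(float)
    if not out.isna().to_numpy().any():
        return out

    donors_df = out.loc[list(training_ids)] if training_ids is not None else out
    if reference_block is not None:
        missing_cols = set(block.columns) - set(reference_block.columns)
        if missing_cols:
            raise DataError(f"reference block lacks columns {sorted(missing_cols)[:5]}")
        donors_df = pd.concat([donors_df, reference_block[block.columns].astype(float)])
    donors = donors_df.to_numpy()

    arr = out.to_numpy()
    no_obs = ~np.isfinite(arr).any(axis=1)
    if no_obs.any():
        rows = list(out.index[no_obs])
        raise DataError(f"rows with no observed features: {rows[:5]}")

    binary = {j: _is_binary(block.iloc[:, j]) for j in range(block.shape[1])}
    col_median = np.nanmedian(donors, axis=0)

    for i in np.flatnonzero(~np.isfinite(arr).all(axis=1)):
        target = arr[i]
        miss_j = np.flatnonzero(~np.isfinite(target))
        d = _knn_distances(target, donors)
        order = np.argsort(d, kind="stable")
        for j in miss_j:
            avail = order[np.isfinite(donors[order, j]) & np.isfinite(d[order])]
            if len(avail) == 0:
                val = col_median[j]
            else:
                val = float(np.mean(donors[avail[:k], j]))
            if binary[j]:
                val = 1.0 if val > 0.5 else 0.0
            arr[i, j] = val
    return pd.DataFrame(arr, index=out.index, columns=out.columns)


# ----------------------------------------------------------------------
# chained equations


def _pmm_draw(y_obs: np.ndarray, pred_obs: np.ndarray, pred_mis: np.ndarray,
              rng: np.random.Generator, pool: int = 5) -> np.ndarray:
    """Predictive-mean matching: draw from the `pool` nearest observed donors."""
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pred_mis):
        idx = np.argsort(np.abs(pred_obs - p), kind="stable")[:pool]
        out[i] = y_obs[idx[rng.integers(0, len(idx))]]
    return out


def impute_chained(block: pd.DataFrame, n_iterations: int = 10,
                   n_datasets: int = 1, seed: int = 0, training_ids=None,
                   pmm_pool: int = 5) -> list[pd.DataFrame]:
    """MICE-style chained-equation imputation.

    Columns are initialized with the training median (continuous) or mode
    (binary), then cycled for ``n_iterations`` sweeps: continuous columns
    are imputed by linear predictive-mean matching (donor pool
    ``pmm_pool``), binary columns by logistic-probability draws.  Models
    are fitted on training rows and applied to all rows.  Returns
    ``n_datasets`` independently seeded completed datasets.
    """
    if n_iterations < 1 or n_datasets < 1:
        raise DataError("n_iterations and n_datasets must be >= 1")
    block = block.astype(float)
    train_idx = (block.index.isin(set(training_ids)) if training_ids is not None
                 else np.ones(len(block), dtype=bool))
    na_mask = block.isna()
    cols_with_na = [c for c in block.columns if na_mask[c].any()]
    for c in cols_with_na:
        if block.loc[train_idx, c].isna().all():
            raise DataError(f"column {c!r} entirely missing in training rows; "
                            "screening should prevent this")
    if not cols_with_na:
        return [block.copy() for _ in range(n_datasets)]

    binary = {c: _is_binary(block[c]) for c in block.columns}
    results = []
    for m in range(n_datasets):
        rng = np.random.default_rng(seed + 1000 * m)
        work = block.copy()
        for c in cols_with_na:
            tr_obs = block.loc[train_idx, c].dropna()
            fill = float(tr_obs.mode().iloc[0]) if binary[c] else float(tr_obs.median())
            work[c] = work[c].fillna(fill)

        for _ in range(n_iterations):
            for c in cols_with_na:
                others = [o for o in block.columns if o != c]
                if not others:
                    continue
                Xall = work[others].to_numpy()
                obs_tr = train_idx & ~na_mask[c].to_numpy()
                mis = na_mask[c].to_numpy()
                y_obs = block.loc[obs_tr, c].to_numpy()
                if binary[c]:
                    if len(np.unique(y_obs)) < 2:
                        work.loc[mis, c] = y_obs[0]
                        continue
                    clf = LogisticRegression(max_iter=200)
                    clf.fit(Xall[obs_tr], y_obs)
                    p = clf.predict_proba(Xall[mis])[:, 1]
                    work.loc[mis, c] = (rng.uniform(size=mis.sum()) < p).astype(float)
                else:
                    reg = LinearRegression().fit(Xall[obs_tr], y_obs)
                    pred_obs = reg.predict(Xall[obs_tr])
                    pred_mis = reg.predict(Xall[mis])
                    work.loc[mis, c] = _pmm_draw(y_obs, pred_obs, pred_mis, rng,
                                                 pool=pmm_pool)
        results.append(work)
    return results
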