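"""Synthetic clinico-genomic cohort generation.

Generates linked tables — subjects with delayed database entry (left
truncation), longitudinal lab series with limits of normal, per-gene
variant calls with unmeasured entries, a gene-embedding table, and a
pathway map — under a Weibull proportional-hazards model with shared and
cancer-specific log-hazard effects.  The hidden true linear predictor is
recorded per subject so downstream metrics can be checked against an
oracle ceiling.

All randomness flows from a single integer seed; identical configs give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, FitError

VARIANT_CLASSES = ("short_variant", "copy_number", "rearrangement")

DEFAULT_GENES = (
    "TP53", "KRAS", "EGFR", "PIK3CA", "APC", "PTEN", "BRAF", "ALK",
    "KDM6A", "FGFR4", "PAX5", "KEAP1",
)


@dataclass(frozen=True)
class LabSpec:
    """One analyte in the simulated lab catalog.

    ``prognostic_shift`` moves the per-subject mean (in units of the
    normal-range width) by ``shift * true_lp``, so higher-risk subjects
    drift toward abnormal values and window summaries become prognostic.
    """

    analyte_id: str
    lln: float
    uln: float
    rate: float = 8.0          # expected observation count over the lookback
    prognostic_shift: float = 0.0
    noise_sd: float = 0.15     # in normal-range-width units


DEFAULT_LAB_CATALOG = (
    LabSpec("albumin", 3.5, 5.5, rate=10.0, prognostic_shift=-0.15),
    LabSpec("alp", 44.0, 147.0, rate=8.0, prognostic_shift=0.20),
    LabSpec("hemoglobin", 12.0, 17.5, rate=12.0, prognostic_shift=-0.10),
    LabSpec("lymphocytes", 1.0, 4.8, rate=6.0, prognostic_shift=-0.12),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_cancers: int = 4
    cohort_sizes: tuple[int, ...] = (400, 300, 200, 100)
    n_shared_features: int = 5
    n_specific_features: int = 2
    shared_beta: tuple[float, ...] | None = None        # default zeros
    specific_beta: tuple[tuple[float, ...], ...] | None = None
    n_noise_features: int = 0
    genes: tuple[str, ...] = DEFAULT_GENES
    genomic_prevalence: object = 0.25   # scalar, (G,), or (G, K)
    cn_prevalence_scale: float = 0.5
    re_prevalence_scale: float = 0.2
    unmeasured_rate: float = 0.05
    lab_catalog: tuple[LabSpec, ...] = DEFAULT_LAB_CATALOG
    lab_lookback_days: int = 720
    weibull_shape: object = 1.2         # scalar or per-cancer
    weibull_scale: object = 700.0
    entry_mean_days: float = 60.0
    censor_rate: float = 2e-4           # per-day hazard of independent censoring
    admin_horizon_days: float = 2000.0
    embedding_dim: int = 8
    apply_truncation: bool = True
    day_resolution: bool = True
    seed: int = 0

    # ------------------------------------------------------------------
    def shared_beta_array(self) -> np.ndarray:
        if self.shared_beta is None:
            return np.zeros(self.n_shared_features)
        return np.asarray(self.shared_beta, dtype=float)

    def specific_beta_array(self, k: int) -> np.ndarray:
        if self.specific_beta is None:
            return np.zeros(self.n_specific_features)
        return np.asarray(self.specific_beta[k], dtype=float)

    def shape_for(self, k: int) -> float:
        return float(np.broadcast_to(self.weibull_shape, (self.n_cancers,))[k])

    def scale_for(self, k: int) -> float:
        return float(np.broadcast_to(self.weibull_scale, (self.n_cancers,))[k])

    def prevalence_matrix(self) -> np.ndarray:
        g, k = len(self.genes), self.n_cancers
        p = np.asarray(self.genomic_prevalence, dtype=float)
        if p.ndim == 0:
            return np.full((g, k), float(p))
        if p.ndim == 1:
            if p.shape[0] != g:
                raise ConfigError("genomic_prevalence: length must equal number of genes")
            return np.repeat(p[:, None], k, axis=1)
        if p.shape != (g, k):
            raise ConfigError("genomic_prevalence: expected shape (n_genes, n_cancers)")
        return p

    def validate(self) -> None:
        if self.n_cancers < 1:
            raise ConfigError("n_cancers: must be >= 1")
        if len(self.cohort_sizes) != self.n_cancers:
            raise ConfigError("cohort_sizes: length must equal n_cancers")
        if any(n < 2 for n in self.cohort_sizes):
            raise ConfigError("cohort_sizes: every cohort must have >= 2 subjects")
        if self.n_shared_features < 0:
            raise ConfigError("n_shared_features: must be >= 0")
        sb = self.shared_beta_array()
        if sb.shape != (self.n_shared_features,):
            raise ConfigError("shared_beta: length must equal n_shared_features")
        if self.specific_beta is not None:
            if len(self.specific_beta) != self.n_cancers:
                raise ConfigError("specific_beta: need one vector per cancer")
            for k in range(self.n_cancers):
                if len(self.specific_beta[k]) != self.n_specific_features:
                    raise ConfigError("specific_beta: vector length must equal n_specific_features")
        prev = self.prevalence_matrix()
        if np.any((prev < 0) | (prev > 1)):
            raise ConfigError("genomic_prevalence: values must lie in [0, 1]")
        if not (0 <= self.unmeasured_rate <= 1):
            raise ConfigError("unmeasured_rate: must lie in [0, 1]")
        for k in range(self.n_cancers):
            if self.shape_for(k) <= 0:
                raise ConfigError("weibull_shape: must be strictly positive")
            if self.scale_for(k) <= 0:
                raise ConfigError("weibull_scale: must be strictly positive")
        if self.entry_mean_days < 0:
            raise ConfigError("entry_mean_days: must be >= 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate: must be >= 0")
        if self.admin_horizon_days <= 0:
            raise ConfigError("admin_horizon_days: must be > 0")
        if self.embedding_dim < 1:
            raise ConfigError("embedding_dim: must be >= 1")
        for spec in self.lab_catalog:
            if spec.lln >= spec.uln:
                raise ConfigError(f"lab_catalog[{spec.analyte_id}]: lln must be < uln")
            if spec.rate < 0:
                raise ConfigError(f"lab_catalog[{spec.analyte_id}]: rate must be >= 0")


@dataclass
class Cohort:
    """Linked tables produced by :func:`simulate_cohort`."""

    subjects: pd.DataFrame
    labs: pd.DataFrame
    genomics: pd.DataFrame
    embeddings: pd.DataFrame      # index: gene_id, columns emb_0..emb_{d-1}
    pathways: dict[str, tuple[str, ...]]
    config: SimulationConfig


def cancer_label(k: int) -> str:
    return f"C{k + 1:02d}"


# ----------------------------------------------------------------------
# subject-level generation


def _draw_subject_block(cfg: SimulationConfig, k: int, n: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw n raw subjects for cancer k (pre-truncation, continuous times)."""
    shared = rng.standard_normal((n, cfg.n_shared_features))
    specific = rng.standard_normal((n, cfg.n_specific_features))
    noise = rng.standard_normal((n, cfg.n_noise_features))

    lp = shared @ cfg.shared_beta_array() + specific @ cfg.specific_beta_array(k)

    shape, scale = cfg.shape_for(k), cfg.scale_for(k)
    u = rng.uniform(size=n)
    death = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if cfg.censor_rate > 0:
        cens = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        cens = np.full(n, np.inf)
    cens = np.minimum(cens, cfg.admin_horizon_days)
    exit_raw = np.minimum(death, cens)
    status = (death <= cens).astype(int)

    if cfg.entry_mean_days > 0:
        entry = rng.exponential(cfg.entry_mean_days, size=n)
    else:
        entry = np.zeros(n)

    df = pd.DataFrame({
        "cancer_type": cancer_label(k),
        "age": np.clip(rng.normal(64.0, 10.0, size=n), 18, 85).round(1),
        "sex": rng.choice(["F", "M"], size=n),
        "race": rng.choice(["white", "nonwhite"], size=n, p=[0.73, 0.27]),
        "smoking": rng.choice(["history", "never"], size=n, p=[0.58, 0.42]),
        "stage": rng.choice(["advanced", "early"], size=n, p=[0.85, 0.15]),
        "ecog": rng.choice([0, 1, 2, 3, 4], size=n, p=[0.35, 0.4, 0.15, 0.07, 0.03]),
        "days_dx_to_1l": np.round(rng.exponential(300.0, size=n)),
        "entry_time": entry,
        "exit_time": exit_raw,
        "event_status": status,
        "true_lp": lp,
    })
    extra = {}
    for j in range(cfg.n_shared_features):
        extra[f"shared_f{j}"] = shared[:, j]
    for j in range(cfg.n_specific_features):
        extra[f"spec_{cancer_label(k)}_f{j}"] = specific[:, j]
    for j in range(cfg.n_noise_features):
        extra[f"noise_f{j}"] = noise[:, j]
    if extra:
        df = pd.concat([df, pd.DataFrame(extra, index=df.index)], axis=1)
    return df


def _round_days(df: pd.DataFrame) -> pd.DataFrame:
    """Snap times to whole days: entry floors, exit ceils (keeps exit > entry)."""
    df = df.copy()
    raw_observed = df["exit_time"].to_numpy() > df["entry_time"].to_numpy()
    df["entry_time"] = np.floor(df["entry_time"].to_numpy())
    df["exit_time"] = np.ceil(df["exit_time"].to_numpy())
    # flooring entry / ceiling exit preserves exit > entry for observed rows;
    # rows already truncated (exit <= entry) must stay truncated
    bad = raw_observed & (df["exit_time"].to_numpy() <= df["entry_time"].to_numpy())
    df.loc[bad, "exit_time"] = df.loc[bad, "entry_time"] + 1.0
    unobserved = ~raw_observed
    df.loc[unobserved, "exit_time"] = np.minimum(
        df.loc[unobserved, "exit_time"], df.loc[unobserved, "entry_time"])
    return df


def simulate_subjects(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table; post-truncation cohort sizes are exact when truncating.

    When ``cfg.apply_truncation`` is False the raw cohort (possibly with
    exit <= entry) of exactly ``cohort_sizes`` per cancer is returned.
    """
    blocks: list[pd.DataFrame] = []
    for k in range(cfg.n_cancers):
        target = cfg.cohort_sizes[k]
        if not cfg.apply_truncation:
            block = _draw_subject_block(cfg, k, target, rng)
        else:
            kept: list[pd.DataFrame] = []
            got = 0
            for _ in range(200):  # oversampling rounds; practically 1-3
                batch = _draw_subject_block(cfg, k, max(2 * target, 50), rng)
                batch = batch[batch["exit_time"] > batch["entry_time"]]
                kept.append(batch)
                got += len(batch)
                if got >= target:
                    break
            if got < target:
                raise ConfigError(
                    "entry_mean_days/cohort_sizes: truncation removes nearly all "
                    f"subjects for cancer {cancer_label(k)}; cannot reach target size")
            block = pd.concat(kept, ignore_index=True).iloc[:target]
        blocks.append(block)
    subjects = pd.concat(blocks, ignore_index=True)
    if cfg.day_resolution:
        subjects = _round_days(subjects)
    subjects.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(subjects))])
    return subjects


def apply_left_truncation(subjects: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop subjects never observed in the database (exit <= entry).

    Returns the retained table and the removed fraction.
    """
    total = len(subjects)
    if total == 0:
        return subjects.copy(), 0.0
    keep = subjects["exit_time"] > subjects["entry_time"]
    retained = subjects[keep].reset_index(drop=True)
    return retained, float((~keep).sum()) / total


# ----------------------------------------------------------------------
# linked modality tables


def simulate_labs(cfg: SimulationConfig, subjects: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    rows: dict[str, list] = {c: [] for c in
                             ("subject_id", "analyte_id", "obs_time", "value", "lln", "uln")}
    ids = subjects["subject_id"].to_numpy()
    lps = subjects["true_lp"].to_numpy()
    for spec in cfg.lab_catalog:
        width = spec.uln - spec.lln
        counts = rng.poisson(spec.rate, size=len(ids))
        for sid, lp, m in zip(ids, lps, counts):
            if m == 0:
                continue
            times = np.sort(np.floor(rng.uniform(-cfg.lab_lookback_days, 0.0, size=m)))
            center = 0.5 + spec.prognostic_shift * lp
            vals_norm = rng.normal(center, spec.noise_sd, size=m)
            vals = spec.lln + vals_norm * width
            rows["subject_id"].extend([sid] * m)
            rows["analyte_id"].extend([spec.analyte_id] * m)
            rows["obs_time"].extend(times.tolist())
            rows["value"].extend(np.round(vals, 3).tolist())
            rows["lln"].extend([spec.lln] * m)
            rows["uln"].extend([spec.uln] * m)
    labs = pd.DataFrame(rows)
    return labs.sort_values(["subject_id", "analyte_id", "obs_time"],
                            kind="stable").reset_index(drop=True)


def simulate_genomics(cfg: SimulationConfig, subjects: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    prev = cfg.prevalence_matrix()
    class_scale = {"short_variant": 1.0,
                   "copy_number": cfg.cn_prevalence_scale,
                   "rearrangement": cfg.re_prevalence_scale}
    cancer_idx = subjects["cancer_type"].map(
        {cancer_label(k): k for k in range(cfg.n_cancers)}).to_numpy()
    n = len(subjects)
    frames = []
    for gi, gene in enumerate(cfg.genes):
        p_subj = prev[gi, cancer_idx]
        for vclass in VARIANT_CLASSES:
            p = np.clip(p_subj * class_scale[vclass], 0.0, 1.0)
            status = (rng.uniform(size=n) < p).astype("float64")
            if cfg.unmeasured_rate > 0:
                status[rng.uniform(size=n) < cfg.unmeasured_rate] = np.nan
            frames.append(pd.DataFrame({
                "subject_id": subjects["subject_id"].to_numpy(),
                "gene_id": gene,
                "variant_class": vclass,
                "status": status,
            }))
    if not frames:
        return pd.DataFrame({"subject_id": pd.Series(dtype=str),
                             "gene_id": pd.Series(dtype=str),
                             "variant_class": pd.Series(dtype=str),
                             "status": pd.Series(dtype="Int64")})
    gen = pd.concat(frames, ignore_index=True)
    gen["status"] = gen["status"].astype("Float64").astype("Int64")
    return gen.sort_values(["subject_id", "gene_id", "variant_class"],
                           kind="stable").reset_index(drop=True)


def simulate_embeddings(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    vecs = rng.standard_normal((len(cfg.genes), cfg.embedding_dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return pd.DataFrame(vecs, index=pd.Index(list(cfg.genes), name="gene_id"),
                        columns=[f"emb_{i}" for i in range(cfg.embedding_dim)])


def simulate_pathways(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> dict[str, tuple[str, ...]]:
    genes = list(cfg.genes)
    rng.shuffle(genes)
    size = 4
    pathways = {}
    for i in range(0, len(genes), size):
        members = tuple(genes[i:i + size])
        if members:
            pathways[f"pathway_{len(pathways) + 1:02d}"] = members
    return pathways


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full linked cohort deterministically from ``config.seed``."""
    config.validate()
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(4)
    subjects = simulate_subjects(config, rngs[0])
    labs = simulate_labs(config, subjects, rngs[1])
    genomics = simulate_genomics(config, subjects, rngs[2])
    embeddings = simulate_embeddings(config, rngs[3])
    pathways = simulate_pathways(config, np.random.default_rng(config.seed + 1))
    return Cohort(subjects, labs, genomics, embeddings, pathways, config)


def true_model_cindex(subjects: pd.DataFrame) -> float:
    """Concordance of the hidden true linear predictor: the oracle ceiling."""
    from .evaluate import concordance_index

    if subjects["event_status"].sum() == 0:
        raise FitError("true_model_cindex: no events in subject table")
    c, _ = concordance_index(
        subjects["entry_time"].to_numpy(),
        subjects["exit_time"].to_numpy(),
        subjects["event_status"].to_numpy(),
        subjects["true_lp"].to_numpy(),
    )
    return c
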