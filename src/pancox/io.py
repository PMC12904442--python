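"""Plain-text table IO with a sidecar manifest carrying seed and version."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import DataError
from .features import FeatureMatrix
from .simulate import Cohort, LabSpec, SimulationConfig


def _config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["lab_catalog"] = [dataclasses.asdict(s) for s in cfg.lab_catalog]
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["lab_catalog"] = tuple(LabSpec(**s) for s in d.get("lab_catalog", ()))
    for key in ("cohort_sizes", "genes", "shared_beta"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("specific_beta") is not None:
        d["specific_beta"] = tuple(tuple(v) for v in d["specific_beta"])
    return SimulationConfig(**d)


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.labs.to_csv(out / "labs.csv", index=False)
    cohort.genomics.to_csv(out / "genomics.csv", index=False)
    cohort.embeddings.to_csv(out / "embeddings.csv", index_label="gene_id")
    (out / "pathways.json").write_text(
        json.dumps({k: list(v) for k, v in cohort.pathways.items()}, indent=2))
    manifest = {
        "generator": "pancox.simulate",
        "version": __version__,
        "seed": cohort.config.seed,
        "config": _config_to_dict(cohort.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg = _config_from_dict(manifest["config"])
    genomics = pd.read_csv(src / "genomics.csv")
    genomics["status"] = genomics["status"].astype("Float64").astype("Int64")
    return Cohort(
        subjects=pd.read_csv(src / "subjects.csv"),
        labs=pd.read_csv(src / "labs.csv"),
        genomics=genomics,
        embeddings=pd.read_csv(src / "embeddings.csv", index_col="gene_id"),
        pathways={k: tuple(v) for k, v in
                  json.loads((src / "pathways.json").read_text()).items()},
        config=cfg,
    )


def write_feature_matrix(fm: FeatureMatrix, out_dir, name: str = "features") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fm.values.to_csv(out / f"{name}.csv", index_label="subject_id")
    meta = fm.meta.copy()
    meta["scope"] = meta["scope"].map(
        lambda s: "all" if isinstance(s, str) else "|".join(s))
    meta.to_csv(out / f"{name}_meta.csv", index_label="feature")
    report = fm.stats.get("screen_report")
    if report is not None:
        (out / f"{name}_screening.json").write_text(json.dumps(report, indent=2))


def read_feature_matrix(in_dir, name: str = "features") -> FeatureMatrix:
    src = Path(in_dir)
    values = pd.read_csv(src / f"{name}.csv", index_col="subject_id")
    meta = pd.read_csv(src / f"{name}_meta.csv", index_col="feature")
    meta["scope"] = meta["scope"].map(
        lambda s: "all" if s == "all" else tuple(str(s).split("|")))
    return FeatureMatrix(values, meta)
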