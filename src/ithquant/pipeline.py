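"""Pipeline orchestration: simulate -> features -> score -> survival ->
report, with stage outputs on disk so each stage can be re-run from the
previous stage's artifacts.

Configuration is a YAML file with two blocks::

    synthetic:            # SyntheticParams fields (all optional)
      n_patients: 100
      seed: 1
    analysis:
      alpha: 0.05
      min_group_frac: 0.1
      endpoint: bcss      # or dmfs
      presence_threshold: 0.1

Every stage writes into the output directory; ``run_pipeline`` runs them all
and finishes with a run manifest (package version, seed, config hash) so a
bundle is traceable to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .catalogue import default_catalogue, compute_feature_matrix
from .preprocess import LabelMap, exclude_dcis
from .scoring import ITHScoreModel
from .survival import anova_across, association_table, endpoint_columns
from .synthetic import (
    REGION_CODES,
    SyntheticParams,
    simulate_patient_maps,
    simulate_survival,
    stack_from_maps,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "stage_simulate", "stage_features", "stage_score",
           "stage_survival", "run_pipeline"]

_COMPONENT_NAMES = ("tubule_forming", "mitosis_rich", "high_cellularity",
                    "discohesive")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("synthetic", {})
    cfg.setdefault("analysis", {})
    return cfg


def _config_hash(cfg: dict, seed: int | None) -> str:
    canon = yaml.safe_dump({"config": cfg, "seed": seed}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _params_from_config(cfg: dict, seed: int | None) -> SyntheticParams:
    kwargs = dict(cfg.get("synthetic", {}))
    for key in ("theta_dist", "class_props"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticParams(**kwargs)


def stage_simulate(params: SyntheticParams, out_dir: Path) -> pd.DataFrame:
    """Write per-patient base maps, nuclei point tables and the cohort CSV."""
    out_dir = Path(out_dir)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    thetas = []
    for i in range(params.n_patients):
        maps = simulate_patient_maps(params, i)
        pdir = maps_dir / maps["patient_id"]
        pdir.mkdir(exist_ok=True)
        io.write_label_map(pdir / "region.png", LabelMap(
            maps["region"], params.pixel_size_um, REGION_CODES))
        grade_codes = {1: "grade1", 2: "grade2", 3: "grade3"}
        io.write_label_map(pdir / "grade.png", LabelMap(
            maps["grade"], params.pixel_size_um, grade_codes))
        pleo_codes = {1: "pleomorphism1", 2: "pleomorphism2", 3: "pleomorphism3"}
        io.write_label_map(pdir / "pleomorphism.png", LabelMap(
            maps["pleomorphism"], params.pixel_size_um, pleo_codes))
        # four overlapping binary component layers packed as a bitmask
        bits = np.zeros_like(maps["region"], dtype=np.uint8)
        for b, name in enumerate(_COMPONENT_NAMES):
            bits |= maps["components"][name].astype(np.uint8) << b
        io.write_label_map(pdir / "components.png", LabelMap(
            bits, params.pixel_size_um,
            {k: "|".join(n for b, n in enumerate(_COMPONENT_NAMES) if k >> b & 1)
             for k in range(1, 16)}))
        io.write_label_map(pdir / "dcis.png", LabelMap(
            maps["dcis_mask"].astype(np.uint8), params.pixel_size_um,
            {1: "dcis"}))
        io.write_points(pdir / "nuclei.csv", maps["cells"], maps["patient_id"])
        thetas.append(maps["theta"])
    cohort = simulate_survival(np.asarray(thetas), params)
    io.write_cohort(out_dir / "cohort.csv", cohort)
    logger.info("simulate: wrote %d patients to %s", params.n_patients, out_dir)
    return cohort


def _load_patient_maps(pdir: Path, params: SyntheticParams) -> dict:
    region = io.read_label_map(pdir / "region.png")
    bits = io.read_label_map(pdir / "components.png").grid
    components = {name: (bits >> b & 1).astype(bool)
                  for b, name in enumerate(_COMPONENT_NAMES)}
    cells = io.read_points(
        pdir / "nuclei.csv",
        frame_shape=(region.shape[0] * 5, region.shape[1] * 5),
        frame_pixel_size_um=region.pixel_size_um / 5,
    )
    return {
        "region": region.grid,
        "grade": io.read_label_map(pdir / "grade.png").grid,
        "pleomorphism": io.read_label_map(pdir / "pleomorphism.png").grid,
        "components": components,
        "cells": cells,
        "dcis_mask": io.read_label_map(pdir / "dcis.png").grid.astype(bool),
        "patient_id": pdir.name,
    }


def stage_features(in_dir: Path, out_dir: Path, params: SyntheticParams,
                   catalogue=None) -> pd.DataFrame:
    """Assemble stacks from the simulate stage, apply DCIS exclusion and
    write the feature matrix CSV."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cat = catalogue if catalogue is not None else default_catalogue()
    stacks = []
    for pdir in sorted((in_dir / "maps").iterdir()):
        if not pdir.is_dir():
            continue
        maps = _load_patient_maps(pdir, params)
        stacks.append(exclude_dcis(stack_from_maps(maps, params)))
    fm = compute_feature_matrix(stacks, cat)
    io.write_feature_matrix(out_dir / "features.csv", fm)
    cat.to_yaml(out_dir / "catalogue.yaml")
    logger.info("features: %d patients x %d features", *fm.shape)
    return fm


def stage_score(fm: pd.DataFrame, cohort: pd.DataFrame, out_dir: Path,
                catalogue=None, alpha: float = 0.05,
                min_group_frac: float = 0.1, endpoint: str = "bcss"):
    """Fit the ITH score model; write scores, groups, family scores and the
    model JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = ITHScoreModel(fm, cohort, catalogue=catalogue, endpoint=endpoint)
    res = model.fit(alpha=alpha, min_group_frac=min_group_frac)
    scores = pd.DataFrame({
        "patient_id": res.scores.index,
        "score": res.scores.to_numpy(),
        "group": res.groups.to_numpy(),
    })
    scores.to_csv(out_dir / "scores.csv", index=False)
    res.family_scores.to_csv(out_dir / "family_scores.csv",
                             index_label="patient_id")
    res.to_json(out_dir / "ith_model.json")
    (out_dir / "summary.txt").write_text(res.summary() + "\n")
    logger.info("score: cut-off %.4g, %d/%d high-ITH", res.cutpoint.cutoff,
                int((res.groups == "high").sum()), len(res.groups))
    return res


def stage_survival(res, out_dir: Path) -> None:
    """Write KM step coordinates, the low/high log-rank and Cox tables, and
    association tables of the ITH group against cohort covariates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = res.km_curves()
    km_rows = []
    for label, c in curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            km_rows.append({"group": label, "time_months": t,
                            "survival": s, "at_risk": r})
    pd.DataFrame(km_rows).to_csv(out_dir / "km_curves.csv", index=False)

    stat, p = res.group_logrank()
    hr = res.group_hazard_ratio()
    rows = [
        {"test": "logrank_low_vs_high", "term": "group", "statistic": stat,
         "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": p},
        {"test": "cox_high_vs_low", "term": "high_ith",
         "statistic": float(hr.params.iloc[0] / hr.bse.iloc[0]),
         "estimate": float(hr.hazard_ratios.iloc[0]),
         "ci_low": float(hr.conf_int.iloc[0, 0]),
         "ci_high": float(hr.conf_int.iloc[0, 1]),
         "p": float(hr.pvalues.iloc[0])},
    ]

    cohort = res.model.cohort
    # association of the dichotomized score with cohort covariates, in the
    # style of a clinicopathologic association table
    if "theta" in cohort.columns:
        tert = pd.qcut(cohort["theta"], 3, labels=["low", "mid", "high"])
        chi, chi_p = association_table(res.groups.to_numpy(), tert)
        rows.append({"test": "chi2_group_vs_theta_tertile", "term": "theta",
                     "statistic": chi, "estimate": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": chi_p})
        f, f_p = anova_across(tert, res.scores.to_numpy())
        rows.append({"test": "anova_score_across_theta_tertiles",
                     "term": "theta", "statistic": f, "estimate": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": f_p})
    pd.DataFrame(rows).to_csv(out_dir / "survival_tables.csv", index=False)


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None):
    """Run every stage and write the report bundle plus a manifest.

    ``config`` may be a path to a YAML file or an already-loaded dict.
    Returns the fitted :class:`~ithquant.scoring.ITHScoreResults`.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = _params_from_config(config, seed)
    ana = config.get("analysis", {})
    cat = default_catalogue(
        presence_threshold=float(ana.get("presence_threshold", 0.1)))

    cohort = stage_simulate(params, out_dir)
    fm = stage_features(out_dir, out_dir, params, catalogue=cat)
    res = stage_score(
        fm, cohort, out_dir, catalogue=cat,
        alpha=float(ana.get("alpha", 0.05)),
        min_group_frac=float(ana.get("min_group_frac", 0.1)),
        endpoint=str(ana.get("endpoint", "bcss")),
    )
    stage_survival(res, out_dir)

    manifest = {
        "ithquant_version": __version__,
        "seed": params.seed,
        "config_hash": _config_hash(config, seed),
        "synthetic_params": dataclasses.asdict(params),
        "endpoint": str(ana.get("endpoint", "bcss")),
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return res
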