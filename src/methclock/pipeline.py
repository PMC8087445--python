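"""End-to-end orchestration: simulate -> preprocess -> clock -> metrics ->
covariates -> Δ_age models -> enrichment, with a manifest per run.

Each stage writes plain TSV/JSON files into the run directory and consumes
only files from prior stages; a single master seed is fanned out per stage,
so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import fit_delta_age_model
from .clock import fit_elastic_net, loocv_predict, clock_sites, write_model
from .covariates import cumulative_early_adversity, compute_dsi, fit_piecewise_bmi
from .data import filter_sites, impute_missing, sites_to_bed, write_counts
from .enrichment import derive_annotations, test_enrichment, write_bed
from .metrics import longitudinal_ordering_test, longitudinal_pairs, prediction_metrics
from .normalize import normalize_training
from .simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_grooming,
    simulate_metadata,
    simulate_methylation,
    write_grooming,
    write_metadata,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat run configuration; every field serializes to the run manifest."""

    seed: int = 1
    out_dir: str = "run"
    # simulation (None -> expects pre-existing input files in out_dir)
    simulate: bool = True
    n_individuals: int = 60
    n_sites: int = 1000
    n_age_sites: int = 120
    rank_acceleration: float = 0.1
    longitudinal_fraction: float = 0.15
    # preprocessing
    knn_k: int = 10
    # clock
    alpha: float = 0.1
    n_folds: int = 5
    # toggles
    run_enrichment: bool = True
    run_associations: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": [],
    }

    def stage(name: str, fn):
        try:
            artifacts = fn()
        except Exception as exc:  # abort with stage name and cause
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "artifacts": artifacts})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    sim = SimulationConfig(
        n_individuals=config.n_individuals,
        n_sites=config.n_sites,
        n_age_sites=config.n_age_sites,
        rank_acceleration=config.rank_acceleration,
        longitudinal_fraction=config.longitudinal_fraction,
        seed=config.seed,
    )

    state: dict = {}

    def s_simulate():
        meta = simulate_metadata(sim)
        counts, truth = simulate_methylation(meta, sim)
        grooming = simulate_grooming(meta, sim.seed)
        write_metadata(meta, out / "metadata.tsv")
        write_counts(counts, out / "methylated.tsv", out / "total.tsv")
        write_grooming(grooming, out / "grooming.tsv")
        state.update(meta=meta, counts=counts, grooming=grooming, truth=truth)
        return ["metadata.tsv", "methylated.tsv", "total.tsv", "grooming.tsv"]

    def s_preprocess():
        retained = filter_sites(state["counts"])
        ratios = impute_missing(state["counts"], retained, k=config.knn_k)
        write_bed(sites_to_bed(retained), out / "retained_sites.bed")
        ratios.ratios.to_csv(out / "ratios.tsv", sep="\t")
        state.update(ratios=ratios)
        return ["retained_sites.bed", "ratios.tsv"]

    def s_clock():
        ages = state["meta"]["age"]
        preds = loocv_predict(
            state["ratios"], ages, alpha=config.alpha, n_folds=config.n_folds, seed=config.seed
        )
        norm = normalize_training(state["ratios"].ratios)
        model = fit_elastic_net(
            norm, ages, alpha=config.alpha, n_folds=config.n_folds, seed=config.seed
        )
        write_model(model, out / "clock_model.tsv")
        preds.to_csv(out / "predictions.tsv", sep="\t")
        state.update(preds=preds, model=model)
        return ["clock_model.tsv", "predictions.tsv"]

    def s_metrics():
        m = prediction_metrics(state["preds"])
        pairs = longitudinal_pairs(state["preds"], state["meta"])
        report = asdict_metrics(m)
        if len(pairs):
            k, n, p = longitudinal_ordering_test(pairs)
            report.update(longitudinal_correct=k, longitudinal_n=n, longitudinal_p=p)
        pd.Series(report).to_csv(out / "metrics.tsv", sep="\t", header=False)
        return ["metrics.tsv"]

    def s_covariates():
        meta, preds = state["meta"], state["preds"]
        cov = preds.join(meta[["individual_id", "sex", "rank", "bmi", "collection_date"]])
        adv = cumulative_early_adversity(
            meta.groupby("individual_id").first().filter(like="adv_")
        )
        cov["cumulative_adversity"] = cov["individual_id"].map(adv)
        cov["age_adjusted_bmi"] = np.nan
        for sex in ("F", "M"):
            mask = cov["sex"] == sex
            if mask.sum() >= 6:
                pw = fit_piecewise_bmi(cov.loc[mask, "bmi"], cov.loc[mask, "age"], sex=sex)
                cov.loc[mask, "age_adjusted_bmi"] = pw.residuals
        cov["dsi"] = np.nan
        grooming = state["grooming"]
        for sid, row in cov[cov["sex"] == "F"].iterrows():
            val, _ = compute_dsi(grooming, row["individual_id"], row["collection_date"])
            cov.loc[sid, "dsi"] = val
        cov.to_csv(out / "covariates.tsv", sep="\t")
        state.update(cov=cov)
        return ["covariates.tsv"]

    def s_associations():
        rows = []
        for sex in ("F", "M"):
            try:
                res = fit_delta_age_model(state["cov"], sex)
            except ValueError:
                continue
            t = res.table.copy()
            t.insert(0, "sex", sex)
            t.insert(1, "n", res.n)
            rows.append(t)
        table = pd.concat(rows) if rows else pd.DataFrame()
        table.to_csv(out / "delta_age_models.tsv", sep="\t")
        return ["delta_age_models.tsv"]

    def s_enrichment():
        ann_raw = simulate_annotations(state["ratios"].ratios.index, sim.seed)
        annotations = derive_annotations(
            genes=ann_raw["genes"], tss=ann_raw["tss"], islands=ann_raw["cpg_islands"]
        )
        cs = clock_sites(state["model"])["all"]
        background = state["ratios"].ratios.index
        rows = []
        if len(cs):
            for name, ann in annotations.items():
                r = test_enrichment(cs, background, ann)
                rows.append(
                    (name, r.clock_in, r.clock_out, r.background_in, r.background_out,
                     r.odds_ratio, r.log2_odds_ratio, r.p, r.haldane_corrected)
                )
        pd.DataFrame(
            rows,
            columns=["annotation", "clock_in", "clock_out", "background_in",
                     "background_out", "odds_ratio", "log2_or", "p", "haldane"],
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return ["enrichment.tsv"]

    if config.simulate:
        stage("simulate", s_simulate)
    else:
        raise ValueError("run_pipeline currently requires simulate=True inputs")
    stage("preprocess", s_preprocess)
    stage("clock", s_clock)
    stage("metrics", s_metrics)
    stage("covariates", s_covariates)
    if config.run_associations:
        stage("associations", s_associations)
    if config.run_enrichment:
        stage("enrichment", s_enrichment)
    return out


def asdict_metrics(m) -> dict:
    return {
        "r": m.r, "r2": m.r2, "mad": m.mad, "mad_sd": m.mad_sd,
        "slope": m.slope, "bias": m.bias, "n": m.n,
    }
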