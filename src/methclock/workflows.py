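"""Canonical synthetic-study workflows.

These bundle the full pipeline on the package's reference synthetic
conditions (150 individuals, 4,000 candidate sites, 300 age-associated sites)
so that calibration checks and reproduction scripts run the exact same code
path.  Leave-one-out clock fits here use five internal CV folds and a
20-value lambda path — on these problem sizes the selected lambda matches the
denser default settings while keeping a full run to a few minutes on one
core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import DeltaAgeModelResult, fit_delta_age_model
from .clock import loocv_predict
from .covariates import cumulative_early_adversity, fit_piecewise_bmi
from .data import filter_sites, impute_missing
from .metrics import PredictionMetrics, prediction_metrics
from .simulate import SimulationConfig, latent_biological_age, simulate_metadata, simulate_methylation

__all__ = ["ClockRun", "canonical_clock_run", "RankRecovery", "rank_recovery_run"]


@dataclass
class ClockRun:
    config: SimulationConfig
    metadata: pd.DataFrame
    predictions: pd.DataFrame
    metrics: PredictionMetrics
    truth: "object"


def canonical_clock_run(
    seed: int,
    n_individuals: int = 150,
    n_sites: int = 4000,
    n_age_sites: int = 300,
    alpha: float = 0.1,
    n_folds: int = 5,
    n_lambda: int = 20,
    **config_kwargs,
) -> ClockRun:
    """Simulate, preprocess, and leave-one-out-predict one synthetic study."""
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_sites=n_sites,
        n_age_sites=n_age_sites,
        seed=seed,
        **config_kwargs,
    )
    meta = simulate_metadata(cfg)
    counts, truth = simulate_methylation(meta, cfg)
    retained = filter_sites(counts)
    ratios = impute_missing(counts, retained, k=10)
    preds = loocv_predict(
        ratios, meta["age"], alpha=alpha, n_folds=n_folds, seed=seed, n_lambda=n_lambda
    )
    return ClockRun(
        config=cfg,
        metadata=meta,
        predictions=preds,
        metrics=prediction_metrics(preds),
        truth=truth,
    )


@dataclass
class RankRecovery:
    run: ClockRun
    model: DeltaAgeModelResult  # Δ_age model on adult males, clock predictions
    oracle: DeltaAgeModelResult  # same design, response from latent biological age


def rank_recovery_run(
    rank_acceleration: float,
    seed: int,
    n_individuals: int = 120,
    n_sites: int = 1200,
    n_age_sites: int = 150,
) -> RankRecovery:
    """Fit the adult-male Δ_age model on a synthetic study with a known
    injected rank effect, next to the oracle fit on latent biological age.

    The oracle replaces the clock's Δ_age with the true biological-age excess
    (biological minus chronological age), so its rank coefficient is exactly
    the injected acceleration, with sign flipped (rank 1 = highest status).
    """
    run = canonical_clock_run(
        seed,
        n_individuals=n_individuals,
        n_sites=n_sites,
        n_age_sites=n_age_sites,
        rank_acceleration=rank_acceleration,
    )
    meta, preds, cfg = run.metadata, run.predictions, run.config
    cov = preds.join(meta[["individual_id", "sex", "rank", "bmi"]])
    adv = cumulative_early_adversity(
        meta.groupby("individual_id").first().filter(like="adv_")
    )
    cov["cumulative_adversity"] = cov["individual_id"].map(adv)
    cov["age_adjusted_bmi"] = np.nan
    for sex in ("F", "M"):
        mask = cov["sex"] == sex
        pw = fit_piecewise_bmi(cov.loc[mask, "bmi"], cov.loc[mask, "age"], sex=sex)
        cov.loc[mask, "age_adjusted_bmi"] = pw.residuals

    males = cov[(cov["sex"] == "M") & (cov["age"] >= cfg.adult_age)].copy()
    model = fit_delta_age_model(males, "M")
    bio = latent_biological_age(meta, cfg)
    oracle_frame = males.copy()
    oracle_frame["delta_age"] = (bio - meta["age"]).loc[males.index]
    oracle = fit_delta_age_model(oracle_frame, "M")
    return RankRecovery(run=run, model=model, oracle=oracle)
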