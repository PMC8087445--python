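"""Synthetic study generator for the wild-baboon epigenetic-clock pipeline.

Emulates the statistical structure the downstream analysis assumes: a
longitudinally monitored population with known chronological ages, sex-specific
dominance-rank dynamics (males attain their best ranks in early-to-mid
adulthood), RRBS-style binomial methylation counts with age-associated
logit-scale drift at a subset of CpG sites, extra methylation variance in older
females, a latent "biological age" for adult males that is accelerated by high
rank, sparse missingness, batch structure, and representative-sampling grooming
records between females.

Every draw flows from a single integer seed: the same configuration and seed
produce byte-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MethylationCountMatrix

__all__ = [
    "SimulationConfig",
    "TrueSimulationState",
    "simulate_metadata",
    "simulate_methylation",
    "simulate_grooming",
    "simulate_annotations",
    "write_metadata",
    "write_grooming",
]

#: calendar origin for synthetic collection dates
_STUDY_START = pd.Timestamp("2000-01-01")

ADVERSITY_COLUMNS = (
    "adv_drought",
    "adv_low_maternal_rank",
    "adv_sibling",
    "adv_large_group",
    "adv_maternal_loss",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the canonical synthetic run used throughout the test
    suite: 150 individuals, 4,000 candidate CpG sites of which 300 carry an
    age signal of ~0.05 logit units per year, ~1.4% missing entries, and a
    male rank acceleration of 0.1 apparent years per ordinal rank step.
    """

    n_individuals: int = 150
    n_sites: int = 4000
    n_age_sites: int = 300
    age_effect_scale: float = 0.05  # logit units per year at age sites
    old_female_extra_sd: float = 0.3  # added residual sd, females past 10 yr
    rank_acceleration: float = 0.1  # apparent years per rank step below alpha
    mean_coverage: float = 30.0  # reads per site-sample
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    missing_rate: float = 0.014
    n_batches: int = 2
    batch_site_fraction: float = 0.10
    batch_shift_sd: float = 0.3  # logit units
    longitudinal_fraction: float = 0.10
    max_rank: int = 20
    noise_sd: float = 0.3  # baseline residual logit sd
    adult_age: float = 8.0  # male adulthood threshold, years
    female_breakpoint: float = 10.0  # variance-inflation threshold, years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_sites <= 0 or self.n_batches <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_age_sites <= self.n_sites:
            raise ValueError("n_age_sites must lie in [0, n_sites]")
        for name in ("missing_rate", "longitudinal_fraction", "batch_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_coverage < 5:
            raise ValueError("mean_coverage must be >= 5")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one stage, fanned out from the seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class TrueSimulationState:
    """Ground truth recorded exactly as sampled, for parameter-recovery tests."""

    baseline_logit: pd.Series  # per-site intercept b0
    age_slope: pd.Series  # per-site logit slope (0 off age sites)
    biological_age: pd.Series  # per-sample latent age
    adversity: pd.DataFrame  # per-individual binary indicators

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "sites": pd.DataFrame(
                {"baseline_logit": self.baseline_logit, "age_slope": self.age_slope}
            ),
            "samples": self.biological_age.to_frame("biological_age"),
            "adversity": self.adversity,
        }


def _male_expected_rank(age: np.ndarray, max_rank: int) -> np.ndarray:
    # ordinal rank 1 = alpha; minimum of the parabola sits in the 7-12 yr window
    mu = 2.0 + 0.22 * (age - 9.5) ** 2
    return np.clip(mu, 1.0, max_rank)


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-sample metadata: one row per blood sample.

    Ages come from a half-and-half mixture of uniform(0, 8) and uniform(8, 25)
    so both the juvenile and adult regimes are populated.  Sexes are balanced.
    Male ordinal ranks concentrate their best (numerically smallest) values at
    ages 7-12; female ranks are nepotistic and stable within individuals.  BMI
    follows a continuous two-segment function of age with a breakpoint at 8
    (males) or 10 (females) plus a rank contribution and noise.  A
    ``longitudinal_fraction`` of individuals contribute a second, later sample,
    with male ranks taking a bounded random-walk step between samples.
    """
    rng = config.rng(1)
    n = config.n_individuals
    ids = [f"ind{i:04d}" for i in range(n)]
    sexes = np.array(["F", "M"] * (n // 2 + 1))[:n]
    rng.shuffle(sexes)

    young = rng.uniform(0.0, 8.0, size=n)
    old = rng.uniform(8.0, 25.0, size=n)
    ages = np.where(rng.random(n) < 0.5, young, old)

    adversity = pd.DataFrame(
        {
            "adv_drought": rng.random(n) < 0.20,
            "adv_low_maternal_rank": rng.random(n) < 0.25,
            "adv_sibling": rng.random(n) < 0.20,
            "adv_large_group": rng.random(n) < 0.25,
            "adv_maternal_loss": rng.random(n) < 0.15,
        },
        index=pd.Index(ids, name="individual_id"),
    ).astype(int)

    female_rank = rng.integers(1, config.max_rank + 1, size=n)

    def draw_rank(sex: str, age: float, ind: int) -> int:
        if sex == "F":
            return int(female_rank[ind])
        mu = _male_expected_rank(np.array([age]), config.max_rank)[0]
        r = int(np.rint(rng.normal(mu, 2.0)))
        return int(np.clip(r, 1, config.max_rank))

    rows = []
    n_long = int(np.floor(config.longitudinal_fraction * n))
    resampled = set(rng.choice(n, size=n_long, replace=False).tolist()) if n_long else set()
    batches = rng.integers(0, config.n_batches, size=n + n_long)

    k = 0
    for i, (ind, sex, age) in enumerate(zip(ids, sexes, ages)):
        rank1 = draw_rank(sex, age, i)
        date1 = _STUDY_START + pd.Timedelta(days=int(rng.integers(365, 6 * 365)))
        rows.append((f"{ind}_s1", ind, sex, float(age), rank1, int(batches[k]), date1))
        k += 1
        if i in resampled:
            gap = float(rng.uniform(1.0, 5.0))
            if sex == "M":
                step = int(np.rint(rng.normal(0.0, 4.0)))
                rank2 = int(np.clip(rank1 + step, 1, config.max_rank))
            else:
                rank2 = rank1
            date2 = date1 + pd.Timedelta(days=int(round(gap * 365)))
            rows.append((f"{ind}_s2", ind, sex, float(age + gap), rank2, int(batches[k]), date2))
            k += 1

    meta = pd.DataFrame(
        rows,
        columns=["sample_id", "individual_id", "sex", "age", "rank", "batch", "collection_date"],
    ).set_index("sample_id")

    # two-segment BMI in age, continuous at the sex-specific breakpoint
    bp = np.where(meta["sex"] == "M", 8.0, 10.0)
    a = meta["age"].to_numpy()
    bmi = 30.0 + 2.2 * np.minimum(a, bp) - 0.45 * np.maximum(a - bp, 0.0)
    bmi = bmi - 0.15 * (meta["rank"].to_numpy() - config.max_rank / 2)
    bmi = bmi + rng.normal(0.0, 1.5, size=len(meta))
    meta["bmi"] = bmi
    # crown-rump length grows and plateaus; mass back-solved so bmi = mass/crl^2
    crl = 0.35 + 0.35 * (1.0 - np.exp(-a / 4.0))
    meta["crown_rump_m"] = crl
    meta["mass_kg"] = meta["bmi"] * crl**2

    meta = meta.join(adversity, on="individual_id")
    return meta


def latent_biological_age(metadata: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Chronological age plus rank-driven acceleration for adult males.

    An adult male (age >= ``adult_age``) at ordinal rank r carries
    ``rank_acceleration * (max_rank - r)`` extra apparent years, so the alpha
    position (r = 1) accrues the largest boost.
    """
    age = metadata["age"].to_numpy(float)
    boost = np.zeros(len(metadata))
    adult_male = (metadata["sex"] == "M").to_numpy() & (age >= config.adult_age)
    boost[adult_male] = config.rank_acceleration * (
        config.max_rank - metadata.loc[adult_male, "rank"].to_numpy(float)
    )
    return pd.Series(age + boost, index=metadata.index, name="biological_age")


def simulate_methylation(
    metadata: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationCountMatrix, TrueSimulationState]:
    """Draw binomial methylation counts for every site x sample.

    Per site s and sample i the methylation probability is
    ``invlogit(b0_s + slope_s * biological_age_i + batch_s,b(i) + e_si)`` with
    ``e_si ~ N(0, sd_i)``; ``sd_i`` is ``noise_sd`` plus ``old_female_extra_sd``
    for females older than the female breakpoint.  Coverage is
    negative-binomial with mean ``mean_coverage``; methylated counts are
    binomial; a ``missing_rate`` fraction of entries is masked.
    """
    required = {"sex", "age", "rank", "batch"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata lacks columns {sorted(required - set(metadata.columns))}")
    if int(metadata["batch"].max()) >= config.n_batches:
        raise ValueError("metadata batch labels exceed config.n_batches")

    rng = config.rng(2)
    n_sites, n_samp = config.n_sites, len(metadata)

    chrom = rng.integers(1, 21, size=n_sites)
    pos = rng.integers(1, 10_000_000, size=n_sites)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    sites = pd.Index([f"chr{c}:{p}" for c, p in zip(chrom, pos)], name="site")
    if sites.has_duplicates:  # vanishingly rare; keep labels unique
        sites = pd.Index(
            [f"chr{c}:{p + i % 7}" for i, (c, p) in enumerate(zip(chrom, pos))], name="site"
        )

    b0 = rng.normal(0.0, 1.2, size=n_sites)
    slope = np.zeros(n_sites)
    age_sites = rng.choice(n_sites, size=config.n_age_sites, replace=False)
    mag = config.age_effect_scale * rng.uniform(0.5, 1.5, size=config.n_age_sites)
    sign = rng.choice([-1.0, 1.0], size=config.n_age_sites)
    slope[age_sites] = sign * mag
    # keep age-site trajectories inside the informative mid-range
    b0[age_sites] = rng.normal(0.0, 0.6, size=config.n_age_sites) - slope[age_sites] * 12.0

    bio_age = latent_biological_age(metadata, config)

    sd = np.full(n_samp, config.noise_sd)
    old_f = (metadata["sex"] == "F").to_numpy() & (
        metadata["age"].to_numpy() > config.female_breakpoint
    )
    sd[old_f] += config.old_female_extra_sd

    logit_p = b0[:, None] + slope[:, None] * bio_age.to_numpy()[None, :]

    n_batch_sites = int(round(config.batch_site_fraction * n_sites))
    batch_sites = rng.choice(n_sites, size=n_batch_sites, replace=False)
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(n_batch_sites, config.n_batches))
    shifts[:, 0] = 0.0  # batch 0 is the reference
    logit_p[batch_sites, :] += shifts[:, metadata["batch"].to_numpy(int)]

    logit_p = logit_p + rng.normal(0.0, 1.0, size=(n_sites, n_samp)) * sd[None, :]
    p = 1.0 / (1.0 + np.exp(-logit_p))

    size = config.coverage_dispersion
    cov = rng.negative_binomial(size, size / (size + config.mean_coverage), size=(n_sites, n_samp))
    meth = rng.binomial(cov, p)

    total = cov.astype(float)
    methf = meth.astype(float)
    mask = rng.random((n_sites, n_samp)) < config.missing_rate
    mask |= cov == 0
    total[mask] = np.nan
    methf[mask] = np.nan

    counts = MethylationCountMatrix(
        methylated=pd.DataFrame(methf, index=sites, columns=metadata.index),
        total=pd.DataFrame(total, index=sites, columns=metadata.index),
    )
    truth = TrueSimulationState(
        baseline_logit=pd.Series(b0, index=sites, name="baseline_logit"),
        age_slope=pd.Series(slope, index=sites, name="age_slope"),
        biological_age=bio_age,
        adversity=metadata.groupby("individual_id")[list(ADVERSITY_COLUMNS)].first(),
    )
    return counts, truth


def simulate_grooming(metadata: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Dyad-year grooming records for the females in ``metadata``.

    One record per female dyad per study year: coresidence days, focal-sample
    count, mean number of females in the group, and a grooming count drawn as
    Poisson with rate proportional to a latent dyadic affinity times observer
    effort (focal samples per coresident-day per female).
    """
    females = sorted(metadata.loc[metadata["sex"] == "F", "individual_id"].unique())
    if len(females) < 2:
        raise ValueError("grooming simulation needs at least 2 females")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    dates = pd.to_datetime(metadata["collection_date"])
    years = range(dates.min().year - 1, dates.max().year + 1)
    n_group_females = max(len(females), 2)

    rows = []
    for f1, f2 in itertools.combinations(females, 2):
        affinity = rng.lognormal(mean=0.0, sigma=0.7)
        for year in years:
            c = int(rng.integers(300, 366))
            s = int(rng.poisson(120))
            f = float(n_group_females + rng.normal(0.0, 1.0))
            f = max(f, 2.0)
            effort = s / (c * f) if s > 0 else 0.0
            lam = affinity * effort * 600.0
            g = int(rng.poisson(lam)) if lam > 0 else 0
            rows.append((f1, f2, year, c, s, f, g))
    return pd.DataFrame(
        rows,
        columns=[
            "female1",
            "female2",
            "year",
            "coresidence_days",
            "focal_samples",
            "mean_group_females",
            "grooming_count",
        ],
    )


def simulate_annotations(
    sites: pd.Index, seed: int, n_islands: int = 40, island_width: int = 1500
) -> dict[str, pd.DataFrame]:
    """Toy genomic annotation tracks (islands, genes, TSS) over the simulated
    contigs, for exercising the enrichment stage end to end."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    chroms = sorted({s.split(":")[0] for s in sites}, key=lambda c: int(c[3:]))
    islands, genes, tss = [], [], []
    for chrom in chroms:
        starts = np.sort(rng.integers(0, 10_000_000 - island_width, size=n_islands))
        for st in starts:
            islands.append((chrom, int(st), int(st + island_width)))
        for _ in range(n_islands // 2):
            g0 = int(rng.integers(0, 9_900_000))
            glen = int(rng.integers(5_000, 80_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((chrom, g0, g0 + glen, strand))
            tss.append((chrom, g0 if strand == "+" else g0 + glen, strand))
    return {
        "cpg_islands": pd.DataFrame(islands, columns=["chrom", "start", "end"]),
        "genes": pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"]),
        "tss": pd.DataFrame(tss, columns=["chrom", "tss", "strand"]),
    }


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out["collection_date"] = pd.to_datetime(out["collection_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t")


def write_grooming(grooming: pd.DataFrame, path: str | Path) -> None:
    grooming.to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
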