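"""Methylation count matrices: I/O, validation, site filtering, k-NN imputation.

RRBS processing upstream yields, per CpG site and sample, a methylated read
count and an "effective" total read count (totals may be rescaled to account
for genotype-disrupted CpGs, hence float).  This module turns those counts
into an analysis-ready ratio matrix: sites are filtered on mean methylation
level, mean coverage, and missingness, and remaining missing entries are
imputed from the nearest sites by Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationCountMatrix",
    "MethylationRatioMatrix",
    "read_counts",
    "write_counts",
    "filter_sites",
    "impute_missing",
    "sites_to_bed",
]


@dataclass
class MethylationCountMatrix:
    """Sites x samples methylated and effective-total counts; NaN = missing.

    Site labels are ``chrom:pos`` with 1-based positions.
    """

    methylated: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        m, t = self.methylated, self.total
        if not m.index.equals(t.index) or not m.columns.equals(t.columns):
            raise ValueError("methylated and total matrices have mismatched labels")
        if m.index.has_duplicates or m.columns.has_duplicates:
            raise ValueError("site and sample labels must be unique")
        mv, tv = m.to_numpy(float), t.to_numpy(float)
        obs_m, obs_t = ~np.isnan(mv), ~np.isnan(tv)
        if not (obs_m == obs_t).all():
            raise ValueError("missingness masks of methylated and total counts differ")
        if np.nanmin(mv, initial=0) < 0 or np.nanmin(tv, initial=0) < 0:
            raise ValueError("negative counts")
        with np.errstate(invalid="ignore"):
            if np.any(mv > tv):
                raise ValueError("methylated counts exceed effective total counts")

    @property
    def sites(self) -> pd.Index:
        return self.methylated.index

    @property
    def samples(self) -> pd.Index:
        return self.methylated.columns

    @property
    def observed(self) -> pd.DataFrame:
        return self.methylated.notna()

    def ratios(self) -> pd.DataFrame:
        """Raw methylation ratios (methylated / total); NaN where missing or
        where the effective total is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.methylated / self.total
        return r.where(self.total > 0)

    def subset_sites(self, sites: pd.Index) -> "MethylationCountMatrix":
        return MethylationCountMatrix(self.methylated.loc[sites], self.total.loc[sites])


@dataclass
class MethylationRatioMatrix:
    """Sites x samples ratios in [0, 1] with no missing entries post-imputation."""

    ratios: pd.DataFrame
    imputed: pd.DataFrame  # bool, True where the entry was filled in

    def __post_init__(self) -> None:
        r = self.ratios.to_numpy(float)
        if np.isnan(r).any():
            raise ValueError("ratio matrix contains missing entries")
        if r.min() < 0 or r.max() > 1:
            raise ValueError("ratios must lie in [0, 1]")
        if not self.ratios.index.equals(self.imputed.index) or not self.ratios.columns.equals(
            self.imputed.columns
        ):
            raise ValueError("provenance flags misaligned with ratios")


def read_counts(path_methylated: str | Path, path_total: str | Path) -> MethylationCountMatrix:
    """Read methylated/total TSV matrices (sites x samples, ``chrom:pos`` rows)."""
    m = pd.read_csv(path_methylated, sep="\t", index_col=0)
    t = pd.read_csv(path_total, sep="\t", index_col=0)
    return MethylationCountMatrix(m, t)


def write_counts(
    counts: MethylationCountMatrix, path_methylated: str | Path, path_total: str | Path
) -> None:
    counts.methylated.to_csv(path_methylated, sep="\t")
    counts.total.to_csv(path_total, sep="\t")


def filter_sites(
    counts: MethylationCountMatrix,
    mean_lower: float = 0.1,
    mean_upper: float = 0.9,
    min_coverage: float = 5.0,
    max_missing: float = 0.05,
) -> pd.Index:
    """Retain analyzable CpG sites, preserving input order.

    A site is kept when (1) its mean methylation ratio over observed entries is
    strictly between ``mean_lower`` and ``mean_upper`` (drops constitutively
    hypo-/hyper-methylated sites), (2) its mean effective coverage over
    observed entries is at least ``min_coverage`` (inclusive), and (3) the
    fraction of samples at which it is missing is strictly below
    ``max_missing``.
    """
    if counts.samples.size < 2:
        raise ValueError("filtering requires at least 2 samples")
    if counts.sites.size == 0:
        raise ValueError("empty matrix")
    r = counts.ratios()
    mean_ratio = r.mean(axis=1)
    mean_cov = counts.total.mean(axis=1)
    frac_missing = (~counts.observed).mean(axis=1)
    keep = (
        (mean_ratio > mean_lower)
        & (mean_ratio < mean_upper)
        & (mean_cov >= min_coverage)
        & (frac_missing < max_missing)
    )
    keep &= mean_ratio.notna()
    return counts.sites[keep.to_numpy()]


def _site_distances(values: np.ndarray) -> np.ndarray:
    """Root-mean-square distance between site rows over pairwise-complete
    samples; inf when two sites share no observed sample."""
    obs = ~np.isnan(values)
    x = np.nan_to_num(values)
    sq = x * x
    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T
    cross = (
        sq @ obs_f.T + obs_f @ sq.T - 2.0 * (x @ x.T)
    )  # sum over shared samples of (xi - xj)^2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(cross, 0.0) / shared)
    d[shared == 0] = np.inf
    np.fill_diagonal(d, np.inf)
    return d


def impute_missing(
    counts: MethylationCountMatrix, retained_sites: pd.Index | None = None, k: int = 10
) -> MethylationRatioMatrix:
    """k-nearest-neighbour imputation of missing ratios, between sites.

    Distances between site rows use root-mean-square difference over
    pairwise-complete samples.  A missing entry at (site, sample) is the mean
    ratio at that sample over the site's k nearest neighbours that are
    observed there; if no neighbour is observed at that sample the site's own
    observed mean is used.  Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = counts if retained_sites is None else counts.subset_sites(retained_sites)
    r = sub.ratios()
    values = r.to_numpy(float)
    obs = ~np.isnan(values)
    if (~obs).all(axis=1).any():
        bad = sub.sites[(~obs).all(axis=1)][0]
        raise ValueError(f"site {bad} is missing in all samples and cannot be imputed")

    filled = values.copy()
    imputed = ~obs
    if imputed.any():
        d = _site_distances(values)
        row_means = np.nanmean(values, axis=1)
        for i in np.flatnonzero(imputed.any(axis=1)):
            order = np.argsort(d[i], kind="stable")
            order = order[np.isfinite(d[i][order])]
            for j in np.flatnonzero(imputed[i]):
                neighbours = order[obs[order, j]][:k]
                if neighbours.size:
                    filled[i, j] = values[neighbours, j].mean()
                else:
                    filled[i, j] = row_means[i]
    return MethylationRatioMatrix(
        ratios=pd.DataFrame(filled, index=sub.sites, columns=sub.samples),
        imputed=pd.DataFrame(imputed, index=sub.sites, columns=sub.samples),
    )


def parse_site_label(label: str) -> tuple[str, int]:
    """``chrom:pos`` (1-based) -> (chrom, pos)."""
    chrom, pos = label.rsplit(":", 1)
    return chrom, int(pos)


def sites_to_bed(sites: pd.Index | list[str]) -> pd.DataFrame:
    """1-based point sites -> BED (0-based, half-open, one record per site)."""
    recs = [parse_site_label(s) for s in sites]
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in recs],
            "start": [p - 1 for _, p in recs],
            "end": [p for _, p in recs],
        }
    )
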