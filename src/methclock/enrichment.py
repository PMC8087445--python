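"""Genomic enrichment of clock sites in annotation classes.

Clock sites (nonzero elastic-net coefficients) are compared against the full
background of candidate CpG sites for enrichment or depletion in interval
annotations — gene bodies, exons, CpG islands, CpG shores (the 2,000 bp
flanking islands), promoters (the 2,000 bp upstream of each gene's 5'-most
TSS, strand-aware), and externally supplied BED tracks — using two-sided
Fisher's exact tests on point-overlap 2x2 tables.

Coordinates are BED-convention 0-based half-open; CpG site labels carry
1-based positions and are converted centrally in :mod:`methclock.data`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .data import parse_site_label

__all__ = [
    "GenomicIntervalSet",
    "EnrichmentResult",
    "merge_intervals",
    "derive_shores",
    "derive_promoters",
    "derive_annotations",
    "test_enrichment",
    "read_bed",
    "write_bed",
]


@dataclass
class GenomicIntervalSet:
    """A named collection of 0-based half-open genomic intervals."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end [, strand]

    def __post_init__(self) -> None:
        df = self.intervals
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError("intervals need chrom/start/end columns")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if (df["start"] < 0).any():
            raise ValueError("negative interval coordinates")

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(grp["start"].astype(int), grp["end"].astype(int))
            )
        return out

    def contains_points(self, sites: list[str] | pd.Index) -> np.ndarray:
        """Membership of 1-based ``chrom:pos`` point sites (point overlap)."""
        trees = self.trees()
        hits = np.zeros(len(sites), dtype=bool)
        for i, label in enumerate(sites):
            chrom, pos = parse_site_label(label)
            tree = trees.get(chrom)
            hits[i] = bool(tree is not None and tree.overlaps_point(pos - 1))
        return hits


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    rows = []
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(grp["start"].astype(int), grp["end"].astype(int)):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def derive_shores(islands: pd.DataFrame, flank: int = 2000) -> GenomicIntervalSet:
    """CpG shores: the ``flank`` bp on each side of every island, excluding
    island interiors (of all islands), merged."""
    raw = []
    for _, row in islands.iterrows():
        raw.append((row["chrom"], max(int(row["start"]) - flank, 0), int(row["start"])))
        raw.append((row["chrom"], int(row["end"]), int(row["end"]) + flank))
    shores = pd.DataFrame([r for r in raw if r[1] < r[2]], columns=["chrom", "start", "end"])
    shores = merge_intervals(shores)
    merged_islands = merge_intervals(islands[["chrom", "start", "end"]])
    rows = []
    for chrom, grp in shores.groupby("chrom"):
        isl = merged_islands[merged_islands["chrom"] == chrom]
        for s, e in zip(grp["start"], grp["end"]):
            pieces = [(s, e)]
            for is_, ie in zip(isl["start"], isl["end"]):
                nxt = []
                for ps, pe in pieces:
                    if ie <= ps or is_ >= pe:
                        nxt.append((ps, pe))
                    else:
                        if ps < is_:
                            nxt.append((ps, is_))
                        if ie < pe:
                            nxt.append((ie, pe))
                pieces = nxt
            rows.extend((chrom, ps, pe) for ps, pe in pieces)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return GenomicIntervalSet("cpg_shores", merge_intervals(out))


def derive_promoters(tss: pd.DataFrame, upstream: int = 2000) -> GenomicIntervalSet:
    """Promoters: ``upstream`` bp upstream of each gene's 5'-most TSS.

    ``tss`` columns: chrom, tss (0-based position), strand.  For plus-strand
    genes the promoter is [tss - upstream, tss); for minus-strand genes it is
    [tss, tss + upstream).  Intervals truncated at contig start are kept
    (flagged by their zero start); overlaps are merged.
    """
    rows = []
    for _, row in tss.iterrows():
        p = int(row["tss"])
        if row["strand"] == "+":
            rows.append((row["chrom"], max(p - upstream, 0), p))
        else:
            rows.append((row["chrom"], p, p + upstream))
    out = pd.DataFrame([r for r in rows if r[1] < r[2]], columns=["chrom", "start", "end"])
    return GenomicIntervalSet("promoters", merge_intervals(out))


def gene_tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    """5'-most TSS per gene record from a stranded gene interval table."""
    t = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    return pd.DataFrame({"chrom": genes["chrom"], "tss": t, "strand": genes["strand"]})


def derive_annotations(
    genes: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    islands: pd.DataFrame | None = None,
    extra_beds: dict[str, pd.DataFrame] | None = None,
) -> dict[str, GenomicIntervalSet]:
    """Assemble the standard annotation collection from primitive inputs."""
    out: dict[str, GenomicIntervalSet] = {}
    if genes is not None:
        out["gene_bodies"] = GenomicIntervalSet(
            "gene_bodies", merge_intervals(genes[["chrom", "start", "end"]])
        )
        if tss is None and "strand" in genes.columns:
            tss = gene_tss_table(genes)
    if islands is not None:
        out["cpg_islands"] = GenomicIntervalSet(
            "cpg_islands", merge_intervals(islands[["chrom", "start", "end"]])
        )
        out["cpg_shores"] = derive_shores(islands)
    if tss is not None:
        out["promoters"] = derive_promoters(tss)
    for name, bed in (extra_beds or {}).items():
        out[name] = GenomicIntervalSet(name, merge_intervals(bed[["chrom", "start", "end"]]))
    return out


@dataclass
class EnrichmentResult:
    """Fisher's exact test of clock-site membership in one annotation."""

    annotation: str
    clock_in: int
    clock_out: int
    background_in: int  # non-clock background sites in the annotation
    background_out: int
    odds_ratio: float
    log2_odds_ratio: float
    p: float
    haldane_corrected: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.clock_in, self.clock_out], [self.background_in, self.background_out]]
        )


def test_enrichment(
    clock_sites: pd.Index | list[str],
    background_sites: pd.Index | list[str],
    annotation: GenomicIntervalSet,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of clock sites vs. the rest of the
    background in/out of an annotation.

    The odds ratio is the sample cross-product ratio; when any cell is zero
    the Haldane 0.5 correction is applied to the OR (and noted), leaving the
    exact p untouched.  An empty annotation yields an undefined (NaN) OR.
    """
    clock = pd.Index(clock_sites)
    background = pd.Index(background_sites)
    if len(clock) == 0 or len(background) == 0:
        raise ValueError("clock and background site sets must be nonempty")
    if not clock.isin(background).all():
        raise ValueError("clock sites must be a subset of the background")
    rest = background.difference(clock)
    if len(rest) == 0:
        raise ValueError("clock sites must be a proper subset of the background")

    a = int(annotation.contains_points(clock).sum())
    b = len(clock) - a
    c = int(annotation.contains_points(rest).sum())
    d = len(rest) - c

    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if len(annotation.intervals) == 0 or (a + c) == 0:
        odds = float("nan")
        corrected = False
    elif min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    return EnrichmentResult(
        annotation=annotation.name,
        clock_in=a,
        clock_out=b,
        background_in=c,
        background_out=d,
        odds_ratio=float(odds),
        log2_odds_ratio=float(np.log2(odds)) if np.isfinite(odds) and odds > 0 else float("nan"),
        p=float(p),
        haldane_corrected=corrected,
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols) :])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
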