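"""Selection scan: windowed statistics, outlier calling, candidate regions
and per-SNP fine-mapping.

The scan contrasts a high-altitude group (QT) against a lowland group (LL)
with three windowed tests — weighted FST (upper tail), the diversity ratio
pi_LL/pi_QT (upper tail) and ZHp of the QT group (lower tail: sweeps
depress heterozygosity in the selected population).  Windows in the top
quantile of all three tests are intersected and merged into candidate
regions, annotated with overlapping genes and fine-mapped at per-SNP
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, IntervalSet, PopulationMap
from .stats import (
    pooled_heterozygosity,
    tajimas_d,
    theta_pi_ratio,
    wc_fst,
    window_pi,
    zhp_transform,
)
from .windows import Window, WindowSpec, assign_sites, make_windows

#: statistic name -> outlier tail used by the scan
SCAN_TAILS = {"fst_weighted": "upper", "ratio": "upper", "zhp": "lower"}


def compute_window_stats(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    spec: WindowSpec | None = None,
    contig_lengths: dict[str, int] | None = None,
    zhp_group: str = "QT",
) -> tuple[pd.DataFrame, list[Window]]:
    """Windowed statistics table for the QT-vs-LL contrast.

    Columns: chrom, start, end (1-based inclusive), n_snps, insufficient,
    pi_QT, pi_LL, ratio (pi_LL/pi_QT), hp, zhp, fst_weighted, tajd_QT,
    tajd_LL.  ZHp is standardised across the windows of all contigs
    jointly, for the ``zhp_group`` samples (default the high-altitude
    group).  Contig lengths default to the last observed position.
    """
    if spec is None:
        spec = WindowSpec()
    popmap.check_samples(matrix.sample_ids)
    qt = matrix.sample_indices(
        [s for s in popmap.group_samples("QT") if s in matrix.sample_ids]
    )
    ll = matrix.sample_indices(
        [s for s in popmap.group_samples("LL") if s in matrix.sample_ids]
    )
    if len(qt) == 0 or len(ll) == 0:
        raise ValueError("both QT and LL groups must have samples in the matrix")
    zidx = qt if zhp_group == "QT" else ll

    all_windows: list[Window] = []
    rows = []
    for chrom in pd.unique(matrix.chrom):
        cmask = np.flatnonzero(matrix.chrom == chrom)
        sub = matrix.take_sites(cmask)
        length = (
            contig_lengths.get(str(chrom), int(sub.positions[-1]))
            if contig_lengths
            else int(sub.positions[-1])
        )
        wins = assign_sites(
            make_windows(length, spec, chrom=str(chrom)), sub, spec.min_snps
        )
        for w in wins:
            pi_qt = window_pi(sub, w, qt)
            pi_ll = window_pi(sub, w, ll)
            _, fst_w = wc_fst(sub, w, qt, ll)
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": w.start,
                    "end": w.end,
                    "n_snps": w.n_snps,
                    "insufficient": w.insufficient,
                    "pi_QT": pi_qt,
                    "pi_LL": pi_ll,
                    "ratio": theta_pi_ratio(pi_ll, pi_qt),
                    "hp": pooled_heterozygosity(sub, w, zidx),
                    "fst_weighted": fst_w,
                    "tajd_QT": tajimas_d(sub, w, qt) if w.n_snps else np.nan,
                    "tajd_LL": tajimas_d(sub, w, ll) if w.n_snps else np.nan,
                }
            )
        all_windows.extend(wins)
    df = pd.DataFrame(rows)
    if len(df):
        df["zhp"] = zhp_transform(df["hp"].to_numpy())
    else:
        df["zhp"] = pd.Series(dtype=float)
    cols = [
        "chrom", "start", "end", "n_snps", "insufficient",
        "pi_QT", "pi_LL", "ratio", "hp", "zhp",
        "fst_weighted", "tajd_QT", "tajd_LL",
    ]
    return df[cols], all_windows


def call_outliers(
    stats: pd.DataFrame,
    statistic: str,
    quantile: float = 0.05,
    tail: str = "upper",
) -> pd.DataFrame:
    """Flag windows in the selected tail's top ``quantile`` fraction.

    Eligible windows have enough SNPs and a defined statistic.  With
    k = floor(quantile * n_eligible), a window is flagged iff its value
    lies strictly beyond the (k+1)-th extreme order statistic — exactly k
    windows when boundary values are distinct, none when all values tie.
    Returns a copy of ``stats`` with columns value, eligible, flagged,
    rank_q (fractional tail rank among eligible windows) and tail.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    values = stats[statistic].to_numpy(dtype=float)
    eligible = ~stats["insufficient"].to_numpy(dtype=bool) & ~np.isnan(values)
    n = int(eligible.sum())
    if 0 < n < 20:
        warnings.warn(
            f"only {n} eligible windows; the {quantile:.0%} quantile is unstable",
            stacklevel=2,
        )
    flagged = np.zeros(len(values), dtype=bool)
    rank_q = np.full(len(values), np.nan)
    if n:
        v = values[eligible]
        signed = v if tail == "upper" else -v
        order = np.argsort(-signed, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        rank_q[eligible] = ranks / n
        k = int(np.floor(quantile * n))
        if 0 < k < n:
            boundary = np.sort(signed)[::-1][k]
            flagged[eligible] = signed > boundary
        elif k >= n:
            flagged[eligible] = True
    out = stats.copy()
    out["statistic"] = statistic
    out["value"] = values
    out["eligible"] = eligible
    out["flagged"] = flagged
    out["rank_q"] = rank_q
    out["tail"] = tail
    return out


@dataclass
class CandidateRegion:
    """Maximal merged run of windows flagged by all three tests."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    window_rows: list[int]
    genes: list[str] = field(default_factory=list)
    summary: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def intersect_and_merge(
    calls_fst: pd.DataFrame,
    calls_ratio: pd.DataFrame,
    calls_zhp: pd.DataFrame,
) -> list[CandidateRegion]:
    """Windows flagged in all three tests, merged over overlapping or
    bookended spans into maximal non-overlapping candidate regions."""
    key_cols = ["chrom", "start", "end"]
    for other in (calls_ratio, calls_zhp):
        if not calls_fst[key_cols].equals(other[key_cols]):
            raise ValueError("outlier calls computed on different window sets")
    joint = (
        calls_fst["flagged"].to_numpy()
        & calls_ratio["flagged"].to_numpy()
        & calls_zhp["flagged"].to_numpy()
    )
    hits = calls_fst.loc[joint, key_cols].reset_index()
    regions: list[CandidateRegion] = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur: CandidateRegion | None = None
        for _, row in grp.iterrows():
            if cur is not None and row["start"] <= cur.end + 1:
                cur.end = max(cur.end, int(row["end"]))
                cur.window_rows.append(int(row["index"]))
            else:
                cur = CandidateRegion(
                    str(chrom), int(row["start"]), int(row["end"]), [int(row["index"])]
                )
                regions.append(cur)
    for r in regions:
        member = calls_fst.loc[r.window_rows]
        r.summary = {
            "n_windows": float(len(r.window_rows)),
            "max_fst": float(member["fst_weighted"].max()),
            "max_ratio": float(member["ratio"].max()),
            "min_zhp": float(member["zhp"].min()),
        }
    return regions


def annotate_genes(
    regions: list[CandidateRegion], genes: IntervalSet
) -> list[CandidateRegion]:
    """Attach names of genes overlapping each region by >= 1 bp.

    Regions are 1-based inclusive; the interval set is 0-based half-open,
    so region [start, end] is compared as [start-1, end)."""
    for r in regions:
        r.genes = genes.overlapping(r.chrom, r.start - 1, r.end)
    return regions


@dataclass
class FineMapResult:
    """Per-SNP and 20 kb-window tracks across a candidate region + flanks."""

    region: CandidateRegion
    lo: int
    hi: int
    snp_table: pd.DataFrame      # chrom, pos, fst, highlighted
    window_table: pd.DataFrame   # chrom, start, end, n_snps, ratio, tajd_QT, tajd_LL
    top_snps: list[int]          # positions sharing the maximal per-SNP FST
    fst_threshold: float

    @property
    def highlighted(self) -> list[int]:
        return self.snp_table.loc[self.snp_table["highlighted"], "pos"].tolist()


def fine_map_region(
    matrix: GenotypeMatrix,
    region: CandidateRegion,
    popmap: PopulationMap,
    flank: int = 500_000,
    fst_threshold: float = 0.3,
    window_size: int = 20_000,
) -> FineMapResult:
    """Per-SNP FST plus 20 kb pi-ratio and Tajima's D tracks around a
    candidate region.

    SNPs with per-site FST strictly above ``fst_threshold`` are
    highlighted across the whole scanned span (the region extended by
    ``flank`` bp on each side, clipped at 1); ``top_snps`` lists the
    position(s) attaining the maximal per-SNP FST within the candidate
    region itself — the flanks only provide context tracks.
    """
    cmask = np.flatnonzero(matrix.chrom == region.chrom)
    if len(cmask) == 0:
        raise ValueError(f"no sites on {region.chrom}")
    sub = matrix.take_sites(cmask)
    qt = sub.sample_indices(
        [s for s in popmap.group_samples("QT") if s in sub.sample_ids]
    )
    ll = sub.sample_indices(
        [s for s in popmap.group_samples("LL") if s in sub.sample_ids]
    )
    lo = max(1, region.start - flank)
    hi = region.end + flank
    span = Window(region.chrom, lo, hi)
    assign_sites([span], sub, min_snps=1)
    if span.n_snps == 0:
        raise ValueError("region (with flanks) contains no SNPs")
    theta, _ = wc_fst(sub, span, qt, ll)
    pos = sub.positions[span.site_idx]
    with np.errstate(invalid="ignore"):
        highlighted = theta > fst_threshold
    snp_table = pd.DataFrame(
        {
            "chrom": region.chrom,
            "pos": pos,
            "fst": theta,
            "highlighted": highlighted,
        }
    )
    in_region = (pos >= region.start) & (pos <= region.end)
    finite = ~np.isnan(theta) & in_region
    if not finite.any():
        finite = ~np.isnan(theta)
    top: list[int] = []
    if finite.any():
        best = theta[finite].max()
        top = [int(p) for p in pos[finite & (theta == best)]]

    first_tile = (lo - 1) // window_size
    last_tile = (hi - 1) // window_size
    wrows = []
    for k in range(first_tile, last_tile + 1):
        w = Window(region.chrom, 1 + k * window_size, (k + 1) * window_size)
        assign_sites([w], sub, min_snps=1)
        pi_qt = window_pi(sub, w, qt)
        pi_ll = window_pi(sub, w, ll)
        wrows.append(
            {
                "chrom": region.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "pi_QT": pi_qt,
                "pi_LL": pi_ll,
                "ratio": theta_pi_ratio(pi_ll, pi_qt),
                "tajd_QT": tajimas_d(sub, w, qt) if w.n_snps else np.nan,
                "tajd_LL": tajimas_d(sub, w, ll) if w.n_snps else np.nan,
            }
        )
    return FineMapResult(
        region=region,
        lo=lo,
        hi=hi,
        snp_table=snp_table,
        window_table=pd.DataFrame(wrows),
        top_snps=top,
        fst_threshold=fst_threshold,
    )
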