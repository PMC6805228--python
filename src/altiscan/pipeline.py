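"""End-to-end orchestration: filter -> windows -> statistics -> outliers ->
candidate regions -> fine-mapping -> association, plus a replicate
simulation-study driver.

``run_full_scan`` is deterministic: identical inputs and configuration give
byte-identical output tables.  Every emitted table carries a header comment
declaring its coordinate convention (1-based inclusive).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .assoc import associate_snp, results_table
from .filters import SiteFilterConfig, apply_site_filters
from .matrix import GenotypeMatrix, PopulationMap
from .scan import (
    SCAN_TAILS,
    CandidateRegion,
    FineMapResult,
    annotate_genes,
    call_outliers,
    compute_window_stats,
    fine_map_region,
    intersect_and_merge,
)
from .sim import DEMES, SimConfig, simulate_demography
from .stats import patterson_d
from .windows import WindowSpec

log = logging.getLogger("altiscan")

_COORD_COMMENT = "# coordinates: 1-based inclusive\n"


@dataclass
class RunConfig:
    """Paths and parameters of one full scan run."""

    vcf: str
    popmap: str
    outdir: str
    genes: str | None = None
    phenotypes: str | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    site_filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    filter_on_missing: str = "fail"
    quantile: float = 0.05
    zhp_tail: str = "lower"
    focal_snps: list[str] = field(default_factory=list)
    flank: int = 500_000
    fst_threshold: float = 0.3
    finemap_window: int = 20_000
    contig_lengths: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quantile <= 0.5:
            raise ValueError("quantile must lie in (0, 0.5]")

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScanResult:
    windows: pd.DataFrame
    calls: dict[str, pd.DataFrame]
    candidates: list[CandidateRegion]
    finemaps: list[FineMapResult]
    association: pd.DataFrame | None
    report: object
    manifest: dict


def _write_table(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def scan_matrix(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    window: WindowSpec | None = None,
    quantile: float = 0.05,
    zhp_tail: str = "lower",
    contig_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[CandidateRegion]]:
    """The in-memory core of the scan: windowed stats, three outlier calls
    (FST upper, pi-ratio upper, ZHp ``zhp_tail``), intersected candidates."""
    stats, _ = compute_window_stats(
        matrix, popmap, spec=window, contig_lengths=contig_lengths
    )
    tails = dict(SCAN_TAILS)
    tails["zhp"] = zhp_tail
    calls = {
        name: call_outliers(stats, name, quantile=quantile, tail=tails[name])
        for name in ("fst_weighted", "ratio", "zhp")
    }
    candidates = intersect_and_merge(
        calls["fst_weighted"], calls["ratio"], calls["zhp"]
    )
    return stats, calls, candidates


def run_full_scan(cfg: RunConfig) -> ScanResult:
    """Execute the full pipeline from files and write the result bundle.

    Outputs under ``cfg.outdir``: windows.tsv, candidates.tsv,
    candidates.bed, finemap_<k>.tsv per region, association.tsv (when
    phenotypes are given) and manifest.json with the config hash and
    per-stage counts.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    matrix = gio.read_vcf(cfg.vcf)
    popmap = gio.read_population_map(cfg.popmap)
    popmap.check_samples(matrix.sample_ids)
    filtered, report = apply_site_filters(
        matrix, cfg.site_filters, on_missing=cfg.filter_on_missing
    )
    log.info("site filters: %d -> %d sites (%s)",
             report.n_input, report.n_passed, report.removed)
    if filtered.n_sites == 0:
        raise ValueError(
            f"no sites after filtering (removed per rule: {report.removed})"
        )
    stats, calls, candidates = scan_matrix(
        filtered,
        popmap,
        window=cfg.window,
        quantile=cfg.quantile,
        zhp_tail=cfg.zhp_tail,
        contig_lengths=cfg.contig_lengths,
    )
    if cfg.genes:
        annotate_genes(candidates, gio.read_intervals(cfg.genes))
    finemaps = [
        fine_map_region(
            filtered, region, popmap,
            flank=cfg.flank,
            fst_threshold=cfg.fst_threshold,
            window_size=cfg.finemap_window,
        )
        for region in candidates
    ]

    association = None
    if cfg.phenotypes:
        phenos = gio.read_phenotypes(cfg.phenotypes)
        focal = list(cfg.focal_snps)
        if not focal:
            focal = [
                f"{fm.region.chrom}:{fm.top_snps[0]}"
                for fm in finemaps
                if fm.top_snps
            ]
        association = _associate(filtered, popmap, phenos, focal)

    _write_table(stats, os.path.join(cfg.outdir, "windows.tsv"))
    cand_df = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "n_windows": int(r.summary.get("n_windows", 0)),
                "genes": ",".join(r.genes) or ".",
                "max_fst": r.summary.get("max_fst", np.nan),
                "max_ratio": r.summary.get("max_ratio", np.nan),
                "min_zhp": r.summary.get("min_zhp", np.nan),
            }
            for r in candidates
        ],
        columns=["chrom", "start", "end", "n_windows", "genes",
                 "max_fst", "max_ratio", "min_zhp"],
    )
    _write_table(cand_df, os.path.join(cfg.outdir, "candidates.tsv"))
    with open(os.path.join(cfg.outdir, "candidates.bed"), "w") as fh:
        for r in candidates:  # BED is 0-based half-open
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{','.join(r.genes) or '.'}\n")
    for k, fm in enumerate(finemaps):
        _write_table(
            fm.snp_table, os.path.join(cfg.outdir, f"finemap_{k}_snps.tsv")
        )
        _write_table(
            fm.window_table, os.path.join(cfg.outdir, f"finemap_{k}_windows.tsv")
        )
    if association is not None:
        _write_table(association, os.path.join(cfg.outdir, "association.tsv"))

    manifest = {
        "config_hash": cfg.config_hash(),
        "config": cfg.canonical(),
        "counts": {
            "input_sites": report.n_input,
            "filtered_sites": report.n_passed,
            "removed_per_rule": report.removed,
            "windows": int(len(stats)),
            "eligible_windows": int((~stats["insufficient"]).sum()),
            "flagged_fst": int(calls["fst_weighted"]["flagged"].sum()),
            "flagged_ratio": int(calls["ratio"]["flagged"].sum()),
            "flagged_zhp": int(calls["zhp"]["flagged"].sum()),
            "candidate_regions": len(candidates),
        },
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return ScanResult(stats, calls, candidates, finemaps, association, report, manifest)


def _associate(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    phenos: pd.DataFrame,
    focal_snps: list[str],
) -> pd.DataFrame:
    results = []
    pheno_cols = [c for c in phenos.columns if c != "sex"]
    common = [s for s in matrix.sample_ids if s in phenos.index]
    col_idx = matrix.sample_indices(common)
    sex = phenos.loc[common, "sex"].to_numpy(dtype=float)
    pops = popmap.populations
    alts = np.array([popmap.altitude_of(p) for p in pops])
    for snp in focal_snps:
        chrom, _, p = snp.partition(":")
        row = np.flatnonzero((matrix.chrom == chrom) & (matrix.positions == int(p)))
        if len(row) == 0:
            log.warning("focal SNP %s not in matrix; skipped", snp)
            continue
        i = int(row[0])
        dos = matrix.dosages[i, col_idx]
        pop_freqs = np.array(
            [
                matrix.alt_freq(matrix.sample_indices(
                    [s for s in popmap.population_samples(pop)
                     if s in matrix.sample_ids]
                ))[i]
                for pop in pops
            ]
        )
        for pc in pheno_cols:
            y = phenos.loc[common, pc].to_numpy(dtype=float)
            res = associate_snp(
                f"{snp}:{pc}", dos, y, sex,
                pop_freqs=pop_freqs, pop_altitudes=alts,
            )
            results.append(res)
    return results_table(results)


def run_simulation_study(
    n_seeds: int,
    sim_cfg: SimConfig | None = None,
    master_seed: int = 0,
    quantile: float = 0.05,
    window: WindowSpec | None = None,
    flank: int = 100_000,
    d_block_snps: int = 200,
) -> pd.DataFrame:
    """Replicate sweep-recovery study: per-seed candidate hit/miss, top
    fine-map SNP distance to the true selected site, and a Patterson's D
    (NC, SW; QT, ancestor) calibration using the known ancestral alleles
    as the outgroup.

    Seeds fan out as ``master_seed + i``.  ``d_block_snps`` (default 200)
    sizes the jackknife blocks to roughly a dozen blocks on the default
    1 Mb desk-scale chromosome, and the default fine-mapping ``flank`` of
    100 kb keeps the fine-mapped span a small fraction of the simulated
    chromosome, as it is of a real genome.  Returns one row per seed.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if sim_cfg is None:
        sim_cfg = SimConfig()
    rows = []
    for i in range(n_seeds):
        cfg = dataclasses.replace(sim_cfg, seed=master_seed + i)
        result = simulate_demography(cfg)
        matrix = result.to_genotype_matrix()
        popmap = _sim_popmap(cfg)
        stats, calls, candidates = scan_matrix(
            matrix, popmap,
            window=window,
            quantile=quantile,
            contig_lengths={cfg.chrom_name: cfg.chrom_length},
        )
        sel = result.truth.selected_pos
        hit_region = next(
            (r for r in candidates if r.contains(cfg.chrom_name, sel)), None
        )
        top_dist = np.nan
        if hit_region is not None:
            fm = fine_map_region(matrix, hit_region, popmap, flank=flank)
            if fm.top_snps:
                top_dist = min(abs(p - sel) for p in fm.top_snps)
        freqs = {
            deme: matrix.alt_freq(matrix.sample_indices(
                popmap.group_samples("QT") if deme == "QT"
                else popmap.population_samples(deme)
            ))
            for deme in DEMES
        }
        dres = patterson_d(
            freqs["NC"], freqs["SW"], freqs["QT"],
            np.zeros(matrix.n_sites),
            block_size_snps=d_block_snps,
            labels=("NC", "SW", "QT", "ancestor"),
        )
        rows.append(
            {
                "seed": cfg.seed,
                "n_snps": matrix.n_sites,
                "n_candidates": len(candidates),
                "hit": hit_region is not None,
                "top_snp_dist": top_dist,
                "final_freq_qt": result.truth.final_freqs["QT"],
                "lost": result.truth.lost,
                "d_stat": dres.d,
                "d_z": dres.z,
            }
        )
    return pd.DataFrame(rows)


def _sim_popmap(cfg: SimConfig) -> PopulationMap:
    rows = []
    for i, deme in enumerate(DEMES):
        group = "QT" if deme == "QT" else "LL"
        for j in range(cfg.sample_sizes[i]):
            rows.append((f"{deme}{j + 1:03d}", deme, group, cfg.altitudes[i]))
    df = pd.DataFrame(rows, columns=["sample", "population", "group", "altitude"])
    return PopulationMap(df.set_index("sample"))
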