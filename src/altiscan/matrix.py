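"""Core in-memory containers for genotype and annotation data.

The central object is :class:`GenotypeMatrix`: a biallelic sites x samples
matrix of ALT-allele dosages (0, 1, 2, or missing), together with positions,
allele labels and optional per-site quality annotations.  All statistics in
this package are frequency/dosage based, so phase is deliberately discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage.
MISSING = np.int8(-1)


class GenotypeMatrixError(ValueError):
    """Raised when a GenotypeMatrix invariant is violated."""


@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples ALT-allele dosage matrix.

    Parameters
    ----------
    chrom
        Per-site contig label, shape ``(n_sites,)``.
    positions
        1-based chromosomal coordinates, strictly increasing within each
        contig, shape ``(n_sites,)``.
    sample_ids
        Ordered unique sample labels.
    dosages
        ``int8`` array of shape ``(n_sites, n_samples)`` with values in
        ``{0, 1, 2}`` or :data:`MISSING`.
    ref, alt
        Per-site REF/ALT allele strings.  For sites flagged non-biallelic,
        ``alt`` holds the first ALT allele.
    qual
        Optional per-site QUAL scores (NaN when absent).
    info
        Optional per-site INFO annotations, keyed by VCF tag (e.g. ``QD``,
        ``FS``, ``ReadPosRankSum``); NaN when absent at a site.
    is_biallelic
        Per-site flag; multi-allelic input sites are flagged, not dropped.
    """

    chrom: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    dosages: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray | None = None
    info: dict[str, np.ndarray] = field(default_factory=dict)
    is_biallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(len(self.positions), dtype=bool)
        else:
            self.is_biallelic = np.asarray(self.is_biallelic, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_sites
        if self.dosages.shape != (n, self.n_samples):
            raise GenotypeMatrixError(
                f"dosages shape {self.dosages.shape} != ({n}, {self.n_samples})"
            )
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise GenotypeMatrixError("duplicate sample ids")
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise GenotypeMatrixError("dosage values outside {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            p = self.positions[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise GenotypeMatrixError(
                    f"positions not strictly increasing on {c}"
                )

    # -- basic accessors ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        """Column indices for the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row-subset preserving all annotations."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            sample_ids=list(self.sample_ids),
            dosages=self.dosages[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=None if self.qual is None else self.qual[idx],
            info={k: v[idx] for k, v in self.info.items()},
            is_biallelic=self.is_biallelic[idx],
        )

    # -- allele counting ----------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site (n_ref, n_alt) allele counts over non-missing calls.

        Returns two float arrays of shape ``(n_sites,)``.
        """
        d = self.dosages if sample_idx is None else self.dosages[:, sample_idx]
        present = d != MISSING
        n_called = present.sum(axis=1)
        alt = np.where(present, d, 0).sum(axis=1).astype(float)
        return 2.0 * n_called - alt, alt

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site ALT allele frequency (NaN where no calls)."""
        n_ref, n_alt = self.allele_counts(sample_idx)
        tot = n_ref + n_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, n_alt / np.maximum(tot, 1), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site minor allele frequency (NaN where no calls)."""
        f = self.alt_freq(sample_idx)
        return np.minimum(f, 1.0 - f)

    def het_counts(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site count of heterozygous (dosage 1) individuals."""
        d = self.dosages if sample_idx is None else self.dosages[:, sample_idx]
        return (d == 1).sum(axis=1)

    def __eq__(self, other: object) -> bool:  # matrix equality, not identity
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        qual_eq = (self.qual is None) == (other.qual is None)
        if qual_eq and self.qual is not None:
            qual_eq = np.allclose(self.qual, other.qual, equal_nan=True)
        info_eq = set(self.info) == set(other.info) and all(
            np.allclose(self.info[k], other.info[k], equal_nan=True)
            for k in self.info
        )
        return bool(
            (self.chrom == other.chrom).all()
            and np.array_equal(self.positions, other.positions)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.dosages, other.dosages)
            and (self.ref == other.ref).all()
            and (self.alt == other.alt).all()
            and np.array_equal(self.is_biallelic, other.is_biallelic)
            and qual_eq
            and info_eq
        )


@dataclass
class PopulationMap:
    """sample_id -> (population, group, altitude) assignment.

    ``group`` is the analysis contrast: ``QT`` (high altitude), ``LL``
    (lowland) or ``other`` (excluded from the scan but kept for admixture
    statistics).  Altitudes are metres above sea level.
    """

    table: pd.DataFrame  # index: sample; columns: population, group, altitude

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in population map: {dups}")
        if (self.table["altitude"] < 0).any():
            raise ValueError("negative altitude in population map")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def population_samples(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population"]))

    def altitude_of(self, population: str) -> float:
        alts = self.table.loc[self.table["population"] == population, "altitude"]
        return float(alts.iloc[0])

    def check_samples(self, sample_ids: list[str]) -> None:
        """Raise if any scanned sample is absent from the map."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")


@dataclass
class IntervalSet:
    """Gene/feature intervals, stored 0-based half-open."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for chrom, start, end, name in self.intervals:
            if not start < end:
                raise ValueError(f"empty interval {name}: {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Names of intervals overlapping [start, end) on chrom by >= 1 bp."""
        return [
            name
            for c, s, e, name in self.intervals
            if c == chrom and s < end and start < e
        ]
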