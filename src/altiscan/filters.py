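"""Site filtering and LD pruning.

The site filters mirror hard-filter practice for short-read genotype calls:
variant confidence (QD), strand bias (FS), read-position bias rank-sum,
per-site QUAL above the run mean, biallelic-only and a minor-allele-frequency
floor.  All thresholds are inclusive (>= / <=).  LD pruning follows the
PLINK ``--indep-pairwise`` scheme: sliding blocks of variants, greedy removal
while any retained pair exceeds the r-squared ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix


class MissingAnnotationError(ValueError):
    """A filter is enabled but its annotation is absent at some site."""


@dataclass
class SiteFilterConfig:
    """Thresholds for site-level hard filters; ``None`` disables a rule.

    Defaults: QD >= 20, FS <= 10, ReadPosRankSum >= -8, MAF >= 0.05,
    biallelic only, QUAL strictly greater than the mean QUAL of sites
    surviving the other filters.
    """

    min_qd: float | None = 20.0
    max_fs: float | None = 10.0
    min_ranksum: float | None = -8.0
    min_maf: float | None = 0.05
    require_biallelic: bool = True
    require_qual_above_mean: bool = True

    def __post_init__(self) -> None:
        if self.min_maf is not None and not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")


@dataclass
class FilterReport:
    """Per-rule removal counts (each removed site charged to its first
    failing rule, in the order the rules are listed)."""

    n_input: int
    n_passed: int
    removed: dict[str, int] = field(default_factory=dict)
    mean_qual: float | None = None

    def __post_init__(self) -> None:
        assert self.n_input == self.n_passed + sum(self.removed.values())


def _annotation(matrix: GenotypeMatrix, tag: str, on_missing: str) -> np.ndarray:
    vals = matrix.info.get(tag)
    if vals is None:
        vals = np.full(matrix.n_sites, np.nan)
    absent = np.isnan(vals)
    if absent.any() and on_missing == "fail":
        raise MissingAnnotationError(
            f"{tag} absent at {int(absent.sum())} site(s); "
            "disable the rule or pass on_missing='skip'"
        )
    return vals


def apply_site_filters(
    matrix: GenotypeMatrix,
    cfg: SiteFilterConfig | None = None,
    on_missing: str = "fail",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Return the sites passing all enabled rules, plus a removal report.

    ``on_missing`` controls sites lacking an annotation an enabled rule
    needs: ``"fail"`` raises, ``"skip"`` lets the rule pass there.
    MAF is computed over non-missing alleles across all samples.
    """
    if cfg is None:
        cfg = SiteFilterConfig()
    if on_missing not in ("fail", "skip"):
        raise ValueError("on_missing must be 'fail' or 'skip'")
    n = matrix.n_sites
    true = np.ones(n, dtype=bool)

    def rule_pass(vals: np.ndarray, ok: np.ndarray) -> np.ndarray:
        # NaN comparisons are False; under 'skip' missing values pass
        return np.where(np.isnan(vals), True, ok) if on_missing == "skip" else ok

    checks: list[tuple[str, np.ndarray]] = []
    if cfg.require_biallelic:
        checks.append(("biallelic", matrix.is_biallelic.copy()))
    if cfg.min_qd is not None:
        v = _annotation(matrix, "QD", on_missing)
        with np.errstate(invalid="ignore"):
            checks.append(("qd", rule_pass(v, v >= cfg.min_qd)))
    if cfg.max_fs is not None:
        v = _annotation(matrix, "FS", on_missing)
        with np.errstate(invalid="ignore"):
            checks.append(("fs", rule_pass(v, v <= cfg.max_fs)))
    if cfg.min_ranksum is not None:
        v = _annotation(matrix, "ReadPosRankSum", on_missing)
        with np.errstate(invalid="ignore"):
            checks.append(("ranksum", rule_pass(v, v >= cfg.min_ranksum)))
    if cfg.min_maf is not None:
        maf = matrix.maf()
        with np.errstate(invalid="ignore"):
            checks.append(("maf", rule_pass(maf, maf >= cfg.min_maf)))

    pass_other = true
    for _, ok in checks:
        pass_other = pass_other & ok

    mean_qual = None
    if cfg.require_qual_above_mean:
        qual = matrix.qual
        if qual is None:
            qual = np.full(n, np.nan)
        absent = np.isnan(qual)
        if absent.any() and on_missing == "fail":
            raise MissingAnnotationError(
                f"QUAL absent at {int(absent.sum())} site(s)"
            )
        if pass_other.any() and not np.isnan(qual[pass_other]).all():
            mean_qual = float(np.nanmean(qual[pass_other]))
            with np.errstate(invalid="ignore"):
                ok = qual > mean_qual
            checks.append(("qual_above_mean", rule_pass(qual, ok)))

    passed = true
    removed: dict[str, int] = {}
    for name, ok in checks:
        removed[name] = int((passed & ~ok).sum())
        passed = passed & ok
    report = FilterReport(
        n_input=n,
        n_passed=int(passed.sum()),
        removed=removed,
        mean_qual=mean_qual,
    )
    return matrix.take_sites(np.flatnonzero(passed)), report


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation of dosage rows (sites x samples)
    over pairwise-complete samples.  NaN where undefined."""
    m = (d != MISSING).astype(float)
    x = np.where(d == MISSING, 0, d).astype(float)
    x2 = x * x
    n = m @ m.T
    sx = x @ m.T          # sum of x over samples present in both i and j
    sxx = x2 @ m.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
        r2 = np.where((n >= 2) & (varx > 0) & (varx.T > 0), r2, np.nan)
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window_snps: int = 1000,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> GenotypeMatrix:
    """Thin variants so no retained pair within a block has r^2 > ``r2_max``.

    Blocks of ``window_snps`` variants advance by ``step_snps``.  Within a
    block, while any retained pair exceeds the ceiling, the pair with the
    lowest indices is resolved by dropping its lower-MAF member (tie: the
    later position).  Deterministic; missing dosages are excluded pairwise.
    """
    n = matrix.n_sites
    if n < 2:
        return matrix
    maf = matrix.maf()
    keep = np.ones(n, dtype=bool)
    starts = range(0, max(n - 1, 1), step_snps)
    for s in starts:
        e = min(s + window_snps, n)
        if e - s < 2:
            continue
        idx = np.arange(s, e)
        r2 = _pairwise_r2(matrix.dosages[idx])
        np.fill_diagonal(r2, np.nan)
        while True:
            active = keep[idx]
            with np.errstate(invalid="ignore"):
                offend = (r2 > r2_max) & active[:, None] & active[None, :]
            if not offend.any():
                break
            i, j = np.argwhere(offend)[0]  # lexicographically first pair
            a, b = idx[i], idx[j]
            if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                keep[a] = False
            else:
                keep[b] = False
        if e == n:
            break
    return matrix.take_sites(np.flatnonzero(keep))
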