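"""Population-genetic statistics.

Implements the full statistic set of the selection scan and admixture
analysis: nucleotide diversity pi and its between-group ratio, pooled
heterozygosity Hp and its Z-transform ZHp, the Weir & Cockerham (1984)
two-population FST estimator (per site and windowed as a ratio of summed
variance components), Tajima's D, Patterson's ABBA-BABA D statistic, the
three-population f3 test, a delete-one block jackknife, and genotype
r-squared.  All estimators work on unphased allele dosages and handle
missing genotypes by per-site non-missing allele counts (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix
from .windows import Window

# ---------------------------------------------------------------------------
# diversity


def site_pi(n_ref: np.ndarray, n_alt: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2*n_ref*n_alt / (n*(n-1))."""
    n = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def window_pi(
    matrix: GenotypeMatrix, window: Window, sample_idx: np.ndarray
) -> float:
    """Per-bp nucleotide diversity of a window for the given samples.

    Sites with fewer than two non-missing alleles are skipped; the sum of
    per-site pi is divided by the window span in bp.
    """
    if window.span <= 0:
        raise ValueError("zero-span window")
    sub = matrix.take_sites(window.site_idx) if window.n_snps else None
    if sub is None:
        return 0.0
    n_ref, n_alt = sub.allele_counts(sample_idx)
    pi = site_pi(n_ref, n_alt)
    return float(np.nansum(pi)) / window.span


def theta_pi_ratio(pi_ll: float, pi_qt: float) -> float:
    """Lowland/high-altitude diversity ratio; NaN (excluded) when the
    denominator is zero."""
    if pi_qt == 0 or np.isnan(pi_qt) or np.isnan(pi_ll):
        return float("nan")
    return pi_ll / pi_qt


def pooled_heterozygosity(
    matrix: GenotypeMatrix, window: Window, sample_idx: np.ndarray
) -> float:
    """Window pooled heterozygosity Hp = 2*SumMAJ*SumMIN/(SumMAJ+SumMIN)^2.

    Major/minor orientation is per site within the analysed group; sums run
    over the window's SNPs.  NaN when the window has no sites with data.
    """
    if window.n_snps == 0:
        return float("nan")
    sub = matrix.take_sites(window.site_idx)
    n_ref, n_alt = sub.allele_counts(sample_idx)
    ok = (n_ref + n_alt) > 0
    if not ok.any():
        return float("nan")
    n_maj = np.maximum(n_ref[ok], n_alt[ok]).sum()
    n_min = np.minimum(n_ref[ok], n_alt[ok]).sum()
    return float(2.0 * n_maj * n_min / (n_maj + n_min) ** 2)


def zhp_transform(hp: np.ndarray) -> np.ndarray:
    """Z-standardise window Hp values across all windows of a group.

    Uses the sample standard deviation (n-1); NaN entries (undefined Hp)
    are ignored for the mean/sd and propagated in the output.
    """
    hp = np.asarray(hp, dtype=float)
    ok = ~np.isnan(hp)
    if ok.sum() < 2:
        raise ValueError("need >= 2 windows with defined Hp")
    mu = hp[ok].mean()
    sd = hp[ok].std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("all Hp values identical; ZHp undefined")
    return (hp - mu) / sd


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


def wc_fst_components(
    matrix: GenotypeMatrix,
    site_idx: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    a: among populations; b: among individuals within populations;
    c: within individuals.  Computed from per-site non-missing sample
    sizes, allele frequencies and observed heterozygote proportions of the
    two populations.  Sites monomorphic across both populations, or with
    fewer than one called individual in either, yield NaN components.
    """
    sub = matrix.take_sites(site_idx)
    comps = []
    for idx in (idx1, idx2):
        d = sub.dosages[:, idx]
        called = (d != MISSING).sum(axis=1).astype(float)
        alt = np.where(d != MISSING, d, 0).sum(axis=1).astype(float)
        het = (d == 1).sum(axis=1).astype(float)
        comps.append((called, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / (2 * n1)
        p2 = alt2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1) & (pbar > 0) & (pbar < 1)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_fst(
    matrix: GenotypeMatrix,
    window: Window,
    idx1: np.ndarray,
    idx2: np.ndarray,
):
    """Per-site theta and the windowed weighted theta of a window.

    The window value is sum(a)/sum(a+b+c) over usable sites — the
    "weighted" Weir & Cockerham combination.  Negative per-site estimates
    are retained.  Returns ``(per_site_theta, weighted_theta)``; the
    window value is NaN when no site contributes.
    """
    if window.n_snps == 0:
        return np.empty(0), float("nan")
    a, b, c = wc_fst_components(matrix, window.site_idx, idx1, idx2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    sum_d = np.nansum(denom)
    if not np.any(~np.isnan(denom)) or sum_d == 0:
        return theta, float("nan")
    return theta, float(np.nansum(a) / sum_d)


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants a1..e2 of Tajima (1989) for n haplotypes."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    matrix: GenotypeMatrix,
    window: Window,
    sample_idx: np.ndarray,
    n_mode: str = "modal",
) -> float:
    """Tajima's D over the window's sites for the given samples.

    With missing data the haplotype count varies by site; by default
    (``n_mode="modal"``) the per-window modal non-missing allele count n
    is used and sites with a different count are dropped.
    ``n_mode="mean"`` instead keeps every segregating site and evaluates
    the constants at the rounded mean per-site count (an approximation).
    Returns NaN when no segregating site remains.
    """
    if len(sample_idx) < 1:
        raise ValueError("no samples")
    if window.n_snps == 0:
        return float("nan")
    sub = matrix.take_sites(window.site_idx)
    n_ref, n_alt = sub.allele_counts(sample_idx)
    n_site = (n_ref + n_alt).astype(int)
    usable = n_site >= 2
    if not usable.any():
        if n_site.max(initial=0) < 2:
            raise ValueError("fewer than 2 non-missing haplotypes at all sites")
        return float("nan")
    if n_mode == "modal":
        vals, counts = np.unique(n_site[usable], return_counts=True)
        n = int(vals[np.argmax(counts)])
        keep = usable & (n_site == n)
    elif n_mode == "mean":
        n = int(round(n_site[usable].mean()))
        keep = usable
    else:
        raise ValueError("n_mode must be 'modal' or 'mean'")
    if n < 2:
        raise ValueError("modal haplotype count below 2")
    seg = keep & (n_alt > 0) & (n_ref > 0)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_hat = float(np.nansum(site_pi(n_ref[seg], n_alt[seg])))
    k = tajima_constants(n)
    num = pi_hat - S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var == 0:  # n = 2: the numerator is identically zero as well
        return 0.0 if abs(num) < 1e-9 else float("nan")
    return num / np.sqrt(var)


# ---------------------------------------------------------------------------
# admixture statistics


@dataclass
class FourPopResult:
    """Patterson's D with block-jackknife uncertainty."""

    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    labels: tuple[str, str, str, str] = ("P1", "P2", "P3", "P4")


@dataclass
class ThreePopResult:
    """Three-population f3 test with block-jackknife uncertainty."""

    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    labels: tuple[str, str, str] = ("C", "A", "B")


def block_jackknife(components: np.ndarray, combine) -> tuple[float, float, float]:
    """Delete-one-block jackknife for a statistic built from additive
    per-block components.

    ``components`` has shape (n_blocks, k); ``combine`` maps a length-k
    vector of summed components to the statistic.  Returns (estimate, SE,
    Z) with SE^2 = ((B-1)/B) * sum((theta_j - mean theta_j)^2) and
    Z = estimate/SE; SE and Z are NaN when fewer than two blocks or SE = 0.
    """
    components = np.atleast_2d(np.asarray(components, dtype=float))
    B = components.shape[0]
    total = components.sum(axis=0)
    est = float(combine(total))
    if B < 2:
        return est, float("nan"), float("nan")
    theta = np.array([combine(total - components[j]) for j in range(B)])
    se = float(np.sqrt((B - 1.0) / B * ((theta - theta.mean()) ** 2).sum()))
    z = est / se if se > 0 else float("nan")
    return est, se, z


def _abba_baba(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba - baba, abba + baba


def patterson_d(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    block_size_snps: int = 1000,
    labels: tuple[str, str, str, str] = ("P1", "P2", "P3", "P4"),
) -> FourPopResult:
    """ABBA-BABA D over four allele-frequency tracks (P4 = outgroup).

    D = sum(ABBA - BABA)/sum(ABBA + BABA) with ABBA = (1-p1)p2p3(1-p4)
    and BABA = p1(1-p2)p3(1-p4); Z from a delete-one jackknife over
    contiguous blocks of ``block_size_snps`` sites.  Sites with any
    missing frequency are dropped.
    """
    tracks = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    ok = ~np.any([np.isnan(t) for t in tracks], axis=0)
    p1, p2, p3, p4 = (t[ok] for t in tracks)
    num, den = _abba_baba(p1, p2, p3, p4)
    n = len(num)
    if n == 0 or den.sum() == 0:
        return FourPopResult(float("nan"), float("nan"), float("nan"), 0, n, labels)
    bounds = np.arange(0, n, block_size_snps)
    comps = np.array(
        [
            [num[s : s + block_size_snps].sum(), den[s : s + block_size_snps].sum()]
            for s in bounds
        ]
    )

    def combine(v):
        return v[0] / v[1] if v[1] != 0 else float("nan")

    est, se, z = block_jackknife(comps, combine)
    return FourPopResult(est, se, z, len(bounds), n, labels)


def f3_statistic(
    pc: np.ndarray,
    pa: np.ndarray,
    pb: np.ndarray,
    nc_alleles: np.ndarray | None = None,
    correction: bool = True,
    block_size_snps: int = 1000,
    labels: tuple[str, str, str] = ("C", "A", "B"),
) -> ThreePopResult:
    """Three-population test f3(C; A, B): mean of (pC-pA)(pC-pB).

    With ``correction`` on (default), the finite-sample bias of the target
    population's frequency estimate is removed by subtracting h_C/n_C per
    site, where h_C = n_C/(n_C-1) * pC(1-pC) is the unbiased within-C
    heterozygosity and n_C the per-site non-missing allele count
    (``nc_alleles``, required for the correction).  Significantly negative
    f3 indicates C is admixed between sources related to A and B.
    """
    pc, pa, pb = (np.asarray(p, dtype=float) for p in (pc, pa, pb))
    if correction:
        if nc_alleles is None:
            raise ValueError("correction requires nc_alleles")
        nc = np.asarray(nc_alleles, dtype=float)
    else:
        nc = np.full(len(pc), np.nan)
    ok = ~(np.isnan(pc) | np.isnan(pa) | np.isnan(pb))
    if correction:
        ok &= ~np.isnan(nc) & (nc >= 2)
    pc, pa, pb, nc = pc[ok], pa[ok], pb[ok], nc[ok]
    terms = (pc - pa) * (pc - pb)
    if correction:
        terms = terms - pc * (1 - pc) / (nc - 1.0)
    n = len(terms)
    if n == 0:
        return ThreePopResult(float("nan"), float("nan"), float("nan"), 0, 0, labels)
    bounds = np.arange(0, n, block_size_snps)
    comps = np.array(
        [
            [terms[s : s + block_size_snps].sum(), min(block_size_snps, n - s)]
            for s in bounds
        ]
    )

    def combine(v):
        return v[0] / v[1] if v[1] > 0 else float("nan")

    est, se, z = block_jackknife(comps, combine)
    return ThreePopResult(est, se, z, len(bounds), n, labels)


# ---------------------------------------------------------------------------
# genotype correlation


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN when either has zero variance or fewer
    than two shared calls."""
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov**2 / (vx * vy))
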