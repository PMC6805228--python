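"""Genotype-phenotype and frequency-altitude association.

Two layers: (1) across populations, the correlation between a focal SNP's
population allele frequency and altitude; (2) within genotyped samples, a
one-way ANOVA of phenotype by genotype class, an allele-substitution effect
beta from a fixed-effect least-squares fit (phenotype ~ intercept + dosage
+ sex), and the variance explained by the SNP,

    VAR(%) = 2 p q beta^2 / S^2 * 100,

with p, q the allele frequencies and S^2 the sample phenotypic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import MISSING


@dataclass
class AssociationResult:
    """Per-SNP association summary across the implemented tests."""

    snp_id: str
    freq_altitude_r: float = np.nan
    freq_altitude_p: float = np.nan
    anova_f: float = np.nan
    anova_p: float = np.nan
    group_means: dict[int, float] = field(default_factory=dict)
    beta: float = np.nan
    p_allele: float = np.nan
    q_allele: float = np.nan
    s2: float = np.nan
    var_percent: float = np.nan


def freq_altitude_test(
    freqs: np.ndarray, altitudes: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of population allele frequency with altitude.

    Needs >= 3 populations and non-constant altitude; returns (r, two-sided
    p) from the t transform with n-2 df (or Spearman with
    ``method="spearman"``).  (NaN, NaN) when the correlation is undefined
    (constant frequencies).
    """
    freqs = np.asarray(freqs, dtype=float)
    altitudes = np.asarray(altitudes, dtype=float)
    if len(freqs) < 3:
        raise ValueError("need >= 3 populations")
    if np.ptp(altitudes) == 0:
        raise ValueError("altitude is constant across populations")
    if np.ptp(freqs) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        res = sps.pearsonr(freqs, altitudes)
    elif method == "spearman":
        res = sps.spearmanr(freqs, altitudes)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def genotype_anova(
    phenotypes: np.ndarray, genotypes: np.ndarray
) -> tuple[float, float, dict[int, float]]:
    """One-way ANOVA of phenotype across genotype classes (factor coding).

    Returns (F, p, per-genotype means) with F = MS_between/MS_within on
    (k-1, N-k) df.  All-equal observations give F = 0, p = 1.  Requires at
    least two classes with >= 2 observations each.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    genotypes = np.asarray(genotypes)
    ok = (genotypes != MISSING) & ~np.isnan(phenotypes)
    phenotypes, genotypes = phenotypes[ok], genotypes[ok]
    classes = np.unique(genotypes)
    groups = [phenotypes[genotypes == g] for g in classes]
    means = {int(g): float(v.mean()) for g, v in zip(classes, groups)}
    if len(classes) < 2:
        raise ValueError("need >= 2 genotype classes")
    if any(len(v) < 2 for v in groups):
        raise ValueError("each genotype class needs >= 2 observations")
    if np.ptp(phenotypes) == 0:
        return 0.0, 1.0, means
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-within-group warnings
        f, p = sps.f_oneway(*groups)
    return float(f), float(p), means


def allele_substitution_effect(
    phenotypes: np.ndarray, dosages: np.ndarray, sex: np.ndarray
) -> float:
    """Allele-substitution effect beta with a fixed-effect sex correction.

    Least-squares fit of phenotype on intercept + dosage + sex indicator;
    beta is the dosage coefficient.  Raises when dosage is constant or
    collinear with sex.
    """
    y = np.asarray(phenotypes, dtype=float)
    d = np.asarray(dosages, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = (np.asarray(dosages) != MISSING) & ~np.isnan(y) & ~np.isnan(s)
    y, d, s = y[ok], d[ok], s[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 samples")
    X = np.column_stack([np.ones_like(d), d, s])
    # drop the sex column if it carries no information (all one sex)
    if np.ptp(s) == 0:
        X = X[:, :2]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("dosage constant or collinear with sex")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1])


def variance_explained(p: float, q: float, beta: float, s2: float) -> float:
    """Phenotypic variance attributed to the SNP: 2*p*q*beta^2/S^2 * 100.

    Values above 100% are reported with a warning, not clamped."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError("p + q must equal 1")
    if s2 <= 0:
        raise ValueError("S^2 must be positive")
    var = 2.0 * p * q * beta**2 / s2 * 100.0
    if var > 100:
        warnings.warn(
            f"variance explained {var:.1f}% exceeds 100%", stacklevel=2
        )
    return var


def associate_snp(
    snp_id: str,
    dosages: np.ndarray,
    phenotype: np.ndarray,
    sex: np.ndarray,
    pop_freqs: np.ndarray | None = None,
    pop_altitudes: np.ndarray | None = None,
) -> AssociationResult:
    """Full per-SNP association bundle for one phenotype.

    Combines the genotype ANOVA, the sex-corrected allele-substitution
    effect, the variance-explained estimate (p/q from the observed allele
    counts of the analysed samples) and, when population frequencies with
    altitudes are given, the frequency-altitude correlation.
    """
    res = AssociationResult(snp_id=snp_id)
    d = np.asarray(dosages)
    y = np.asarray(phenotype, dtype=float)
    ok = (d != MISSING) & ~np.isnan(y)
    if ok.sum() >= 4 and len(np.unique(d[ok])) >= 2:
        try:
            res.anova_f, res.anova_p, res.group_means = genotype_anova(y[ok], d[ok])
        except ValueError:
            pass
        try:
            res.beta = allele_substitution_effect(y, d, sex)
        except ValueError:
            pass
        p = float(d[ok].sum()) / (2.0 * ok.sum())
        res.p_allele, res.q_allele = p, 1.0 - p
        res.s2 = float(np.var(y[ok], ddof=1))
        if 0 < p < 1 and res.s2 > 0 and not np.isnan(res.beta):
            res.var_percent = variance_explained(p, 1.0 - p, res.beta, res.s2)
    if pop_freqs is not None and pop_altitudes is not None:
        res.freq_altitude_r, res.freq_altitude_p = freq_altitude_test(
            pop_freqs, pop_altitudes
        )
    return res


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten AssociationResult records into a TSV-ready table."""
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id,
            "freq_altitude_r": r.freq_altitude_r,
            "freq_altitude_p": r.freq_altitude_p,
            "anova_F": r.anova_f,
            "anova_p": r.anova_p,
            "beta": r.beta,
            "p": r.p_allele,
            "q": r.q_allele,
            "S2": r.s2,
            "VAR_percent": r.var_percent,
        }
        for g, m in sorted(r.group_means.items()):
            row[f"mean_dosage{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)
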