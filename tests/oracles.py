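"""Independent brute-force oracles for the population-genetic statistics.

Deliberately written as naive scalar code, straight from the defining
formulas, sharing no implementation with the package: the package is
validated against these on small random instances.
"""

from __future__ import annotations

import math


def pi_site_bruteforce(n_ref: int, n_alt: int) -> float:
    """Mean pairwise difference at one site by enumerating all pairs."""
    alleles = [0] * n_ref + [1] * n_alt
    n = len(alleles)
    if n < 2:
        return float("nan")
    diffs = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if alleles[i] != alleles[j]:
                diffs += 1
    return diffs / pairs


def window_pi_bruteforce(counts: list[tuple[int, int]], span_bp: int) -> float:
    total = 0.0
    for n_ref, n_alt in counts:
        if n_ref + n_alt >= 2:
            total += pi_site_bruteforce(n_ref, n_alt)
    return total / span_bp


def hp_bruteforce(major_minor: list[tuple[int, int]]) -> float:
    s_maj = sum(max(a, b) for a, b in major_minor)
    s_min = sum(min(a, b) for a, b in major_minor)
    return 2.0 * s_maj * s_min / (s_maj + s_min) ** 2


def wc_fst_site_bruteforce(
    n1: int, p1: float, h1: float, n2: int, p2: float, h2: float
):
    """Weir & Cockerham (1984) two-population variance components for one
    site, from sample sizes (diploids), ALT frequencies and observed
    heterozygote proportions.  Returns (a, b, c)."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def tajimas_d_bruteforce(site_counts: list[tuple[int, int]], n: int) -> float:
    """Tajima's D from per-site (n_ref, n_alt) counts, all with total n."""
    S = 0
    pi_hat = 0.0
    for n_ref, n_alt in site_counts:
        assert n_ref + n_alt == n
        if 0 < n_alt < n:
            S += 1
            pi_hat += pi_site_bruteforce(n_ref, n_alt)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def patterson_d_bruteforce(freqs: list[tuple[float, float, float, float]]):
    num = 0.0
    den = 0.0
    for p1, p2, p3, p4 in freqs:
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        num += abba - baba
        den += abba + baba
    return num / den if den else float("nan")


def f3_bruteforce(
    triples: list[tuple[float, float, float]],
    nc: list[int] | None = None,
) -> float:
    total = 0.0
    for i, (pc, pa, pb) in enumerate(triples):
        term = (pc - pa) * (pc - pb)
        if nc is not None:
            hc = nc[i] / (nc[i] - 1.0) * pc * (1 - pc)
            term -= hc / nc[i]
        total += term
    return total / len(triples)


def jackknife_bruteforce(block_components, combine):
    B = len(block_components)
    k = len(block_components[0])
    totals = [sum(b[j] for b in block_components) for j in range(k)]
    est = combine(totals)
    thetas = []
    for b in block_components:
        thetas.append(combine([totals[j] - b[j] for j in range(k)]))
    mean = sum(thetas) / B
    se = math.sqrt((B - 1) / B * sum((t - mean) ** 2 for t in thetas))
    z = est / se if se > 0 else float("nan")
    return est, se, z


def r2_bruteforce(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    if vx == 0 or vy == 0:
        return float("nan")
    return cov * cov / (vx * vy)


def anova_f_bruteforce(groups: list[list[float]]):
    """One-way ANOVA F from explicit sums of squares."""
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / N
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df1 = k - 1
    df2 = N - k
    if ssw == 0:
        return (0.0, df1, df2) if ssb == 0 else (float("inf"), df1, df2)
    return (ssb / df1) / (ssw / df2), df1, df2
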