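"""Genotype-phenotype and frequency-altitude association at a focal SNP.

Simulates a data set whose phenotypes (three blood parameters) are linearly
coupled to the selected genotype with a sex covariate, then runs the full
association bundle: one-way ANOVA by genotype class, the sex-corrected
allele-substitution effect beta, the variance explained
VAR(%) = 2*p*q*beta^2/S^2 * 100, and the correlation of population allele
frequency with altitude.
"""

import numpy as np

from altiscan import SimConfig, associate_snp, simulate_demography
from altiscan.sim import DEMES, make_phenotype_table

cfg = SimConfig(seed=8)
result = simulate_demography(cfg)
matrix = result.to_genotype_matrix()
phenos = make_phenotype_table(matrix, result.truth, seed=cfg.seed)

row = int(np.flatnonzero(matrix.positions == cfg.selected_pos)[0])
dosages = matrix.dosages[row]
pop_freqs = []
for deme in DEMES:
    idx = matrix.sample_indices([s for s in matrix.sample_ids if s.startswith(deme)])
    pop_freqs.append(matrix.alt_freq(idx)[row])
altitudes = list(cfg.altitudes)

for pheno in ("rbcv", "hmg", "mchc"):
    res = associate_snp(
        f"chr1:{cfg.selected_pos}:{pheno}",
        dosages,
        phenos[pheno].to_numpy(),
        phenos["sex"].to_numpy(),
        pop_freqs=np.array(pop_freqs),
        pop_altitudes=np.array(altitudes),
    )
    print(f"{pheno}: ANOVA F = {res.anova_f:.1f} (p = {res.anova_p:.2e}), "
          f"beta = {res.beta:+.2f}, VAR = {res.var_percent:.1f}%")
print("  beta is the phenotype change per copy of the altitude allele "
      "after sex correction; VAR is the phenotypic variance it explains")
res = associate_snp("freq-alt", dosages, phenos["rbcv"].to_numpy(),
                    phenos["sex"].to_numpy(),
                    pop_freqs=np.array(pop_freqs),
                    pop_altitudes=np.array(altitudes))
print(f"population frequency vs altitude: r = {res.freq_altitude_r:.3f} "
      f"(p = {res.freq_altitude_p:.3f} across {len(pop_freqs)} populations)")
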