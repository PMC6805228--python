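"""Forward Wright-Fisher simulator with selection, migration and phenotypes.

Generates the statistical structure the scan assumes: a neutral burn-in in
an ancestral deme, a simultaneous three-way split into high-altitude (QT)
and two lowland (NC, SW) demes with asymmetric migration, one positively
selected locus arising in the QT deme, and phenotypes linearly coupled to
the selected genotype with a sex covariate.  Everything is explicit and
auditable: discrete generations, per-generation order migration ->
selection-weighted parent sampling -> recombination (Poisson crossovers) ->
infinite-sites mutation; the full QT allele-frequency trajectory is
recorded as ground truth.

Defaults are desk-scaled (small Ne, inflated per-bp rates) so that a 1 Mb
chromosome carries a few thousand SNPs and a replicate study runs in
seconds; they make no claim of matching genome-wide horse diversity.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .io import write_vcf
from .matrix import GenotypeMatrix

DEMES = ("QT", "NC", "SW")


@numba.njit(cache=True)
def _assemble_gametes(mat, hapA, hapB, k_arr, cps, cps_off, pos, child):
    """Fill ``child[:, :S]`` with recombinant gametes.

    For gamete g the contributing parental haplotype at a site is decided
    by the parity of the number of crossover points at or left of the
    site's position."""
    G, S = child.shape[0], pos.shape[0]
    for g in range(G):
        a = hapA[g]
        if k_arr[g] == 0:
            child[g, :S] = mat[a, :S]
        else:
            b = hapB[g]
            lo, hi = cps_off[g], cps_off[g + 1]
            for s in range(S):
                p = pos[s]
                parity = 0
                for c in range(lo, hi):
                    if cps[c] <= p:
                        parity ^= 1
                child[g, s] = mat[a, s] if parity == 0 else mat[b, s]


@dataclass
class PhenotypeSpec:
    """Linear genotype-phenotype coupling for one blood parameter:
    y = baseline + beta * dosage + gamma * sex + Normal(0, sigma^2)."""

    name: str
    beta: float
    gamma: float = 0.5
    sigma: float = 1.0
    baseline: float = 0.0


def default_phenotypes() -> list[PhenotypeSpec]:
    """Three blood parameters with the sign structure seen in high-altitude
    adaptation: carriers of the adaptive allele have lower red-cell volume
    and haemoglobin but higher corpuscular haemoglobin concentration."""
    return [
        PhenotypeSpec("rbcv", beta=-1.0, gamma=0.5, sigma=1.0, baseline=40.0),
        PhenotypeSpec("hmg", beta=-1.0, gamma=0.5, sigma=1.0, baseline=15.0),
        PhenotypeSpec("mchc", beta=1.0, gamma=0.5, sigma=1.0, baseline=35.0),
    ]


def _default_migration() -> np.ndarray:
    # m[i][j]: probability a lineage in deme i draws its parent from deme j.
    # Asymmetric, with the largest flows into SW (from QT, then NC).
    m = np.full((3, 3), 5.0e-4)
    m[2, 0] = 1.0e-3  # SW <- QT
    m[2, 1] = 7.5e-4  # SW <- NC
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


@dataclass
class SimConfig:
    """Demography, genetics and sampling for one simulated data set.

    Deme order everywhere is (QT, NC, SW).  ``split_generations`` is the
    desk-scale stand-in for the ~3,700-year (~460 generations at 8
    years/generation) divergence; at the desk-scale deme size of 100
    diploids it defaults to 150 generations so that the relative
    divergence T/2Ne stays moderate, as in the emulated study, instead of
    driving the demes to near-fixation.  ``onset_generation`` is measured
    in generations after the split and
    defaults to 60 generations before sampling, so the sweep is recent
    when the sample is drawn.  The selected mutation is injected into the
    QT deme at frequency ``f0`` at onset; the default f0 of one copy in
    2N models a de novo beneficial mutation (a hard sweep).  With
    ``reintroduce`` (default), a mutation lost to drift before
    establishing recurs the next generation, as recurrent mutation would.
    """

    ancestral_ne: int = 100
    deme_ne: tuple[int, int, int] = (100, 100, 100)
    split_generations: int = 150
    migration: np.ndarray = field(default_factory=_default_migration)
    chrom_length: int = 1_000_000
    mu: float = 1.0e-6
    rec: float = 2.0e-6
    selected_pos: int = 500_000
    s: float = 4.0
    h: float = 0.5
    onset_generation: int | None = None
    f0: float = 0.005
    reintroduce: bool = True
    sample_sizes: tuple[int, int, int] = (30, 30, 30)
    altitudes: tuple[float, float, float] = (4200.0, 500.0, 800.0)
    burn_in_factor: float = 10.0
    chrom_name: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (3, 3):
            raise ValueError("migration must be 3x3")
        off = self.migration.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any() or (off.sum(axis=1) >= 1).any():
            raise ValueError("off-diagonal migration rows must be >= 0, sum < 1")
        # rows are parent-source distributions: diagonal = stay-home mass
        np.fill_diagonal(off, 1.0 - off.sum(axis=1))
        self.migration = off
        for rate in (self.mu, self.rec):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.f0 <= 1:
            raise ValueError("f0 must lie in [0, 1]")
        if self.split_generations < 1:
            raise ValueError("split_generations must be >= 1")
        if not 1 <= self.selected_pos <= self.chrom_length:
            raise ValueError("selected_pos outside chromosome")
        if self.onset_generation is None:
            self.onset_generation = max(self.split_generations - 60, 0)
        if self.onset_generation > self.split_generations:
            raise ValueError(
                "onset_generation exceeds split_generations; pass it "
                "explicitly when shortening the split"
            )

    def symmetric(self, m: float = 2.5e-4) -> "SimConfig":
        """Copy with symmetric migration (null-calibration demography)."""
        mig = np.full((3, 3), m)
        np.fill_diagonal(mig, 0.0)
        np.fill_diagonal(mig, 1.0 - mig.sum(axis=1))
        return dataclasses.replace(self, migration=mig)


@dataclass
class SimTruth:
    """Simulator ground truth for downstream acceptance checks."""

    selected_pos: int
    selected_allele: str
    s: float
    h: float
    onset_generation: int
    f0: float
    final_freqs: dict[str, float]
    trajectory_qt: list[float]
    lost: bool
    seed: int
    n_injections: int = 1
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)


class ForwardSimulator:
    """Low-level forward engine over an arbitrary deme structure.

    Haplotypes are rows of a uint8 matrix whose columns are segregating
    mutations (positions 1..L, infinite sites with redraw on collision).
    ``deme_sizes`` lists diploid counts; haplotype rows are grouped by deme
    in order, two consecutive rows per individual.  Tests drive this
    directly for single-deme drift checks.
    """

    def __init__(
        self,
        chrom_length: int,
        mu: float,
        rec: float,
        rng: np.random.Generator,
        deme_sizes: list[int],
        reserved_pos: int | None = None,
    ):
        self.L = chrom_length
        self.mu = mu
        self.rec = rec
        self.rng = rng
        self.deme_sizes = list(deme_sizes)
        self.pos = np.empty(0, dtype=np.int64)
        H = 2 * sum(deme_sizes)
        self.mat = np.empty((H, 0), dtype=np.uint8)
        self.occupied = np.zeros(chrom_length + 1, dtype=bool)
        self.reserved_pos = reserved_pos
        if reserved_pos is not None:
            self.occupied[reserved_pos] = True

    # -- structure helpers --------------------------------------------------
    def deme_rows(self, i: int) -> np.ndarray:
        off = 2 * sum(self.deme_sizes[:i])
        return np.arange(off, off + 2 * self.deme_sizes[i])

    def col_of(self, position: int) -> int | None:
        hit = np.flatnonzero(self.pos == position)
        return int(hit[0]) if len(hit) else None

    def freq(self, position: int, deme: int | None = None) -> float:
        col = self.col_of(position)
        if col is None:
            return 0.0
        rows = self.deme_rows(deme) if deme is not None else slice(None)
        return float(self.mat[rows, col].mean())

    def inject(self, position: int, deme: int, f0: float) -> None:
        """Add a new mutation at ``position`` on round(f0 * 2N) randomly
        chosen haplotypes of ``deme`` (at least one when f0 > 0)."""
        if f0 <= 0:
            return
        rows = self.deme_rows(deme)
        k = max(1, int(round(f0 * len(rows))))
        chosen = self.rng.choice(rows, size=k, replace=False)
        existing = self.col_of(position)
        if existing is not None:  # reuse a (lost) retained column
            self.mat[chosen, existing] = 1
            return
        col = np.zeros((self.mat.shape[0], 1), dtype=np.uint8)
        col[chosen, 0] = 1
        self.mat = np.hstack([self.mat, col])
        self.pos = np.append(self.pos, position)
        self.occupied[position] = True

    # -- one generation ------------------------------------------------------
    def step(
        self,
        new_sizes: list[int] | None = None,
        source_probs: np.ndarray | None = None,
        fitness: list[np.ndarray | None] | None = None,
    ) -> None:
        """Advance one generation.

        ``source_probs[i, j]`` is the probability a gamete of new deme i
        draws its parent from current deme j (a migration matrix when the
        structure is unchanged; a split when new demes all source the
        ancestral deme).  ``fitness`` gives optional per-individual weights
        per current deme (selection acts on parents).  Per-generation order:
        migration (source-deme draw) -> selection-weighted parent sampling
        -> recombination (Poisson crossovers) -> mutation.
        """
        rng = self.rng
        cur_sizes = self.deme_sizes
        if new_sizes is None:
            new_sizes = cur_sizes
        n_cur = len(cur_sizes)
        if source_probs is None:
            source_probs = np.eye(len(new_sizes), n_cur)
        offsets = np.concatenate([[0], np.cumsum(cur_sizes)])
        G = 2 * sum(new_sizes)
        # deme of each child gamete
        child_deme = np.repeat(np.arange(len(new_sizes)), 2 * np.asarray(new_sizes))
        # source deme per gamete (migration)
        cum = np.cumsum(source_probs, axis=1)
        u = rng.random(G)
        src = np.empty(G, dtype=np.intp)
        for i in range(len(new_sizes)):
            sel = child_deme == i
            src[sel] = np.searchsorted(cum[i], u[sel], side="right")
        src = np.minimum(src, n_cur - 1)
        # parent individual (global index) per gamete, selection-weighted
        par = np.empty(G, dtype=np.intp)
        for j in range(n_cur):
            sel = np.flatnonzero(src == j)
            if len(sel) == 0:
                continue
            w = None
            if fitness is not None and fitness[j] is not None:
                w = fitness[j] / fitness[j].sum()
            par[sel] = offsets[j] + rng.choice(cur_sizes[j], size=len(sel), p=w)
        # recombination: one gamete per parent; crossover parity per site
        S = len(self.pos)
        k = rng.poisson(self.rec * self.L, G)
        lead = rng.integers(0, 2, G)
        hapA = 2 * par + lead
        hapB = 2 * par + 1 - lead
        # mutation counts drawn up-front so the child matrix is allocated once
        n_new = rng.poisson(self.mu * self.L, G)
        M = int(n_new.sum())
        child = np.zeros((G, S + M), dtype=np.uint8)
        cps = rng.random(int(k.sum())) * self.L
        cps_off = np.concatenate([[0], np.cumsum(k)]).astype(np.int64)
        _assemble_gametes(
            self.mat, hapA.astype(np.int64), hapB.astype(np.int64),
            k.astype(np.int64), cps, cps_off, self.pos, child,
        )
        # mutation: infinite sites on integer positions, redraw collisions
        new_pos = np.empty(M, dtype=np.int64)
        filled = 0
        while filled < M:
            cand = rng.integers(1, self.L + 1, M - filled)
            cand = pd.unique(cand[~self.occupied[cand]])
            take = cand[: M - filled]
            new_pos[filled : filled + len(take)] = take
            self.occupied[take] = True
            filled += len(take)
        if M:
            child[np.repeat(np.arange(G), n_new), S + np.arange(M)] = 1
            self.pos = np.concatenate([self.pos, new_pos])
        self.mat = child
        self.deme_sizes = list(new_sizes)
        self._purge()

    def _purge(self) -> None:
        """Drop globally lost or fixed mutations (their positions become
        reusable); the reserved selected position is never dropped."""
        if not len(self.pos):
            return
        count = self.mat.sum(axis=0, dtype=np.int64)
        keep = (count > 0) & (count < self.mat.shape[0])
        if self.reserved_pos is not None:
            keep |= self.pos == self.reserved_pos
        if keep.all():
            return
        freed = self.pos[~keep]
        freed = freed[freed != self.reserved_pos]
        self.occupied[freed] = False
        self.mat = self.mat[:, keep]
        self.pos = self.pos[keep]


@dataclass
class SimResult:
    """Sampled haplotypes per deme plus ground truth."""

    config: SimConfig
    positions: np.ndarray                  # sorted, ascending
    haplotypes: dict[str, np.ndarray]      # deme -> (2 * n_sampled, S) uint8
    truth: SimTruth

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for deme, n in zip(DEMES, self.config.sample_sizes):
            out += [f"{deme}{i + 1:03d}" for i in range(n)]
        return out

    def to_genotype_matrix(self) -> GenotypeMatrix:
        """Dosage matrix over all sampled individuals.

        Sites monomorphic across the whole sample are dropped, except the
        selected position, which is always retained when simulated."""
        hap = np.vstack([self.haplotypes[d] for d in DEMES])  # (2n_tot, S)
        dos = (hap[0::2] + hap[1::2]).T.astype(np.int8)       # (S, n_tot)
        tot = dos.sum(axis=1, dtype=np.int64)
        poly = (tot > 0) & (tot < 2 * dos.shape[1])
        keep = poly | (self.positions == self.truth.selected_pos)
        idx = np.flatnonzero(keep)
        n = len(idx)
        return GenotypeMatrix(
            chrom=np.full(n, self.config.chrom_name, dtype=object),
            positions=self.positions[idx],
            sample_ids=self.sample_ids,
            dosages=dos[idx],
            ref=np.full(n, "A", dtype=object),
            alt=np.full(n, "G", dtype=object),
        )


def simulate_demography(cfg: SimConfig) -> SimResult:
    """Run burn-in, split, selection and sampling for one configuration.

    Burn-in runs ``burn_in_factor * ancestral_ne`` generations in the
    ancestral deme to mutation-drift balance, then the population splits
    simultaneously into the three demes, which exchange migrants each
    generation.  The selected mutation appears in QT at
    ``onset_generation`` (after the split) at frequency ``f0`` and is
    advanced with fitnesses 1 : 1+hs : 1+s; if it is lost it is not
    reintroduced (recorded in the truth).  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    engine = ForwardSimulator(
        cfg.chrom_length, cfg.mu, cfg.rec, rng,
        deme_sizes=[cfg.ancestral_ne],
        reserved_pos=cfg.selected_pos,
    )
    for _ in range(int(cfg.burn_in_factor * cfg.ancestral_ne)):
        engine.step()
    # simultaneous trifurcation: every deme sources the ancestral pool
    engine.step(
        new_sizes=list(cfg.deme_ne),
        source_probs=np.ones((3, 1)),
    )
    trajectory: list[float] = []
    injected = False
    n_injections = 0
    for g in range(cfg.split_generations):
        if g >= cfg.onset_generation and (
            not injected
            or (cfg.reintroduce and engine.freq(cfg.selected_pos) == 0.0)
        ):
            engine.inject(cfg.selected_pos, deme=0, f0=cfg.f0)
            injected = True
            n_injections += 1
        fitness: list[np.ndarray | None] = [None, None, None]
        if injected and cfg.s != 0:
            col = engine.col_of(cfg.selected_pos)
            if col is not None:
                d = engine.mat[engine.deme_rows(0), col]
                dos = d[0::2].astype(int) + d[1::2].astype(int)
                fitness[0] = 1.0 + cfg.s * (dos == 2) + cfg.h * cfg.s * (dos == 1)
        engine.step(source_probs=cfg.migration, fitness=fitness)
        if injected:
            trajectory.append(engine.freq(cfg.selected_pos, deme=0))

    final_freqs = {
        deme: engine.freq(cfg.selected_pos, deme=i) for i, deme in enumerate(DEMES)
    }
    lost = injected and engine.freq(cfg.selected_pos) == 0.0
    # sample diploids per deme
    order = np.argsort(engine.pos, kind="stable")
    pos_sorted = engine.pos[order]
    mat_sorted = engine.mat[:, order]
    haplotypes: dict[str, np.ndarray] = {}
    for i, deme in enumerate(DEMES):
        n = cfg.sample_sizes[i]
        if n > cfg.deme_ne[i]:
            raise ValueError(f"cannot sample {n} diploids from deme of {cfg.deme_ne[i]}")
        chosen = np.sort(rng.choice(cfg.deme_ne[i], size=n, replace=False))
        rows = engine.deme_rows(i)
        hap_rows = np.column_stack([2 * chosen, 2 * chosen + 1]).ravel()
        haplotypes[deme] = mat_sorted[rows[hap_rows]].copy()
    truth = SimTruth(
        selected_pos=cfg.selected_pos,
        selected_allele="ALT",
        s=cfg.s,
        h=cfg.h,
        onset_generation=cfg.onset_generation,
        f0=cfg.f0,
        final_freqs=final_freqs,
        trajectory_qt=trajectory,
        lost=lost,
        seed=cfg.seed,
        n_injections=n_injections,
    )
    return SimResult(cfg, pos_sorted, haplotypes, truth)


def simulate_phenotypes(
    dosages: np.ndarray,
    sexes: np.ndarray,
    spec: PhenotypeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = baseline + beta * dosage + gamma * sex + Normal(0, sigma^2)."""
    if spec.sigma < 0:
        raise ValueError("sigma must be >= 0")
    d = np.asarray(dosages, dtype=float)
    s = np.asarray(sexes, dtype=float)
    noise = rng.normal(0.0, spec.sigma, len(d)) if spec.sigma > 0 else 0.0
    return spec.baseline + spec.beta * d + spec.gamma * s + noise


def make_phenotype_table(
    matrix: GenotypeMatrix,
    truth: SimTruth,
    specs: list[PhenotypeSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype table (sample, sex, one column per parameter) coupled to
    the selected genotype; records the specs used into the truth."""
    if specs is None:
        specs = default_phenotypes()
    rng = np.random.default_rng(seed)
    row = np.flatnonzero(matrix.positions == truth.selected_pos)
    if len(row):
        dos = matrix.dosages[row[0]].astype(float)
        dos[dos < 0] = 0.0
    else:
        dos = np.zeros(matrix.n_samples)
    sexes = rng.integers(0, 2, matrix.n_samples)
    out = pd.DataFrame({"sample": matrix.sample_ids, "sex": sexes})
    for spec in specs:
        out[spec.name] = simulate_phenotypes(dos, sexes, spec, rng)
    truth.phenotypes = list(specs)
    return out


def emit_dataset(
    result: SimResult,
    outdir: str | os.PathLike,
    phenotype_specs: list[PhenotypeSpec] | None = None,
    phenotype_seed: int | None = None,
) -> dict[str, str]:
    """Write VCF + population map TSV + phenotype TSV + truth JSON.

    The population map assigns group QT (altitude >= 3,300 m) to the
    high-altitude deme and LL (< 1,000 m) to NC and SW.  Returns the
    emitted paths keyed by kind.
    """
    cfg = result.config
    if not any(cfg.sample_sizes):
        raise ValueError("no samples to emit")
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "simulated.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    matrix = result.to_genotype_matrix()
    write_vcf(matrix, paths["vcf"])
    rows = []
    for i, deme in enumerate(DEMES):
        group = "QT" if deme == "QT" else "LL"
        for j in range(cfg.sample_sizes[i]):
            rows.append(
                {
                    "sample": f"{deme}{j + 1:03d}",
                    "population": deme,
                    "group": group,
                    "altitude": cfg.altitudes[i],
                }
            )
    pd.DataFrame(rows).to_csv(paths["popmap"], sep="\t", index=False)
    phen = make_phenotype_table(
        matrix,
        result.truth,
        specs=phenotype_specs,
        seed=cfg.seed if phenotype_seed is None else phenotype_seed,
    )
    phen.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(result.truth.to_json() + "\n")
    return paths
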