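"""Forward Wright-Fisher simulator: determinism, drift, selection and
emitted files.

Simulation-heavy properties use scaled-down configurations (short
chromosome, small demes) so the whole module runs in seconds; the
full-scale replicate studies live in the acceptance suite.
"""

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
import pytest

from altiscan import (
    ForwardSimulator,
    PhenotypeSpec,
    SimConfig,
    allele_substitution_effect,
    emit_dataset,
    read_phenotypes,
    read_population_map,
    read_vcf,
    simulate_demography,
    simulate_phenotypes,
)

SMALL = dict(
    ancestral_ne=40,
    deme_ne=(40, 40, 40),
    split_generations=40,
    chrom_length=150_000,
    selected_pos=75_000,
    sample_sizes=(12, 12, 12),
    burn_in_factor=5.0,
    onset_generation=10,
)


def small_config(**kw):
    return SimConfig(**{**SMALL, **kw})


class TestEngine:
    def test_heterozygosity_decays_at_drift_rate(self):
        """With mutation off, mean expected heterozygosity decays by
        (1 - 1/2N) per generation (averaged over replicates)."""
        N, T, reps = 30, 25, 40
        ratios = []
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            eng = ForwardSimulator(10_000, mu=0.0, rec=1e-5, rng=rng,
                                   deme_sizes=[N])
            # standing variation: 40 sites at random frequencies
            eng.pos = np.arange(100, 4100, 100)
            eng.mat = (rng.random((2 * N, 40)) <
                       rng.uniform(0.2, 0.8, 40)).astype(np.uint8)
            eng.occupied[eng.pos] = True

            def het(e):
                # divide by the initial site count: purged (lost or fixed)
                # sites contribute zero heterozygosity, not a smaller panel
                p = e.mat.mean(axis=0)
                return (2 * p * (1 - p)).sum() / 40

            h0 = het(eng)
            for _ in range(T):
                eng.step()
            if h0 > 0:
                ratios.append(het(eng) / h0)
        observed = np.mean(ratios)
        expected = (1 - 1 / (2 * N)) ** T
        assert observed == pytest.approx(expected, rel=0.12)

    def test_segregating_sites_near_watterson(self):
        """After burn-in the SNP count is within a factor of two of the
        Watterson prediction for the ancestral deme."""
        cfg = small_config(s=0.0, f0=0.0)
        res = simulate_demography(dataclasses.replace(cfg, split_generations=1,
                                                      onset_generation=0))
        n_hap = 2 * cfg.ancestral_ne
        theta_site = 4 * cfg.ancestral_ne * cfg.mu
        a_n = np.sum(1.0 / np.arange(1, n_hap))
        expected = theta_site * cfg.chrom_length * a_n
        assert expected / 2 < len(res.positions) < expected * 2


class TestSimulateDemography:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(seed=7)
        p1 = emit_dataset(simulate_demography(cfg), tmp_path / "a")
        p2 = emit_dataset(simulate_demography(cfg), tmp_path / "b")
        for k in p1:
            assert open(p1[k], "rb").read() == open(p2[k], "rb").read()

    def test_selection_drives_qt_but_not_lowland(self):
        """Strong selection from standing variation at the split fixes the
        allele in QT while the lowland demes stay at low frequency."""
        ok_qt = ok_ll = 0
        n = 10
        for seed in range(n):
            cfg = small_config(s=0.5, f0=0.05, onset_generation=0,
                               split_generations=60, seed=seed)
            res = simulate_demography(cfg)
            ok_qt += res.truth.final_freqs["QT"] > 0.9
            ok_ll += max(res.truth.final_freqs["NC"],
                         res.truth.final_freqs["SW"]) < 0.3
        assert ok_qt >= 0.7 * n
        assert ok_ll >= 0.7 * n

    def test_trajectory_recorded_and_bounded(self):
        res = simulate_demography(small_config(seed=3))
        traj = res.truth.trajectory_qt
        assert len(traj) == SMALL["split_generations"] - SMALL["onset_generation"]
        assert all(0.0 <= f <= 1.0 for f in traj)

    def test_neutral_allele_mostly_stays_rare(self):
        res = simulate_demography(small_config(s=0.0, seed=5))
        assert res.truth.final_freqs["QT"] <= 1.0  # defined even when lost

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="migration"):
            SimConfig(migration=np.full((3, 3), 0.5))
        with pytest.raises(ValueError, match="f0"):
            SimConfig(f0=1.5)
        with pytest.raises(ValueError, match="onset"):
            SimConfig(split_generations=150, onset_generation=200)
        with pytest.raises(ValueError):
            simulate_demography(small_config(sample_sizes=(100, 5, 5)))


class TestPhenotypes:
    def test_noiseless_model_is_exact(self):
        rng = np.random.default_rng(0)
        spec = PhenotypeSpec("x", beta=2.0, gamma=0.0, sigma=0.0, baseline=5.0)
        d = np.array([0, 1, 2])
        y = simulate_phenotypes(d, np.zeros(3), spec, rng)
        assert y.tolist() == [5.0, 7.0, 9.0]

    def test_opposite_betas_reverse_group_order(self):
        rng = np.random.default_rng(0)
        d = np.array([0] * 5 + [2] * 5)
        up = simulate_phenotypes(d, np.zeros(10),
                                 PhenotypeSpec("u", beta=1.0, sigma=0.0), rng)
        down = simulate_phenotypes(d, np.zeros(10),
                                   PhenotypeSpec("d", beta=-1.0, sigma=0.0), rng)
        assert up[5:].mean() > up[:5].mean()
        assert down[5:].mean() < down[:5].mean()

    def test_effect_recoverable_from_simulated_phenotypes(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = rng.integers(0, 3, 200)
            sex = rng.integers(0, 2, 200)
            y = simulate_phenotypes(d, sex,
                                    PhenotypeSpec("x", beta=1.0, gamma=0.5,
                                                  sigma=1.0), rng)
            hits += abs(allele_substitution_effect(y, d, sex) - 1.0) <= 0.3
        assert hits >= 19


class TestEmitDataset:
    def test_round_trip_and_truth(self, tmp_path):
        cfg = small_config(seed=11)
        res = simulate_demography(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # all outputs parse cleanly
            paths = emit_dataset(res, tmp_path)
            m = read_vcf(paths["vcf"])
            pm = read_population_map(paths["popmap"])
            ph = read_phenotypes(paths["phenotypes"])
        assert m == res.to_genotype_matrix()
        truth = json.load(open(paths["truth"]))
        assert truth["selected_pos"] in m.positions
        pm.check_samples(m.sample_ids)
        assert set(ph.index) == set(m.sample_ids)
        # altitude convention: QT high, lowland below 1,000 m
        assert pm.table.loc[pm.table.group == "QT", "altitude"].min() >= 3300
        assert pm.table.loc[pm.table.group == "LL", "altitude"].max() < 1000

    def test_empty_sample_set_rejected(self, tmp_path):
        cfg = small_config(seed=1, sample_sizes=(0, 0, 0))
        res = simulate_demography(cfg)
        with pytest.raises(ValueError, match="no samples"):
            emit_dataset(res, tmp_path)

    def test_phenotypes_follow_selected_genotype(self, tmp_path):
        cfg = small_config(seed=2, s=2.0, f0=0.1, onset_generation=0,
                           split_generations=60)
        res = simulate_demography(cfg)
        paths = emit_dataset(res, tmp_path)
        if res.truth.final_freqs["QT"] < 0.9:
            pytest.skip("allele did not sweep in this construction")
        ph = pd.read_csv(paths["phenotypes"], sep="\t").set_index("sample")
        qt = ph.loc[[s for s in ph.index if s.startswith("QT")], "rbcv"]
        ll = ph.loc[[s for s in ph.index if not s.startswith("QT")], "rbcv"]
        assert qt.mean() < ll.mean()  # negative beta on the swept dosage
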