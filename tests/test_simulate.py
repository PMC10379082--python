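"""Synthetic-data generators: determinism, truth recovery, planted signals."""

import numpy as np
import pytest

import radsweep as rs


class TestBaldingNichols:
    def test_fixed_seed_byte_identical_vcf(self, tmp_path):
        cfg = rs.SimulationConfig(seed=3, n_pops=2, samples_per_pop=5,
                                  n_chrom=2, n_snps=200)
        out = []
        for d in ("a", "b"):
            vt, gm, pmap, truth = rs.simulate_balding_nichols(cfg)
            paths = rs.write_simulation(tmp_path / d, vt, gm, pmap, truth)
            out.append(paths["vcf"].read_bytes())
        assert out[0] == out[1]

    def test_missingness_rate_within_one_percent(self):
        cfg = rs.SimulationConfig(seed=5, n_pops=2, samples_per_pop=25,
                                  n_chrom=2, n_snps=10_000, missing_rate=0.05)
        _, gm, _, _ = rs.simulate_balding_nichols(cfg)
        rate = (gm.dosages == rs.MISSING).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_truth_frequencies_match_realized(self, bn_two_pops):
        vt, gm, pmap, truth = bn_two_pops
        f = np.array(truth.pop_freqs["pop1"])
        idx = pmap.indices_for("pop1", gm.samples)
        dos = gm.dosages[idx].astype(float)
        dos[dos == rs.MISSING] = np.nan
        realized = np.nanmean(dos, axis=0) / 2
        # binomial sampling noise only
        assert np.nanmean(np.abs(realized - f)) < 0.1

    def test_generated_vcf_round_trips(self, tmp_path, bn_two_pops):
        vt, gm, pmap, truth = bn_two_pops
        paths = rs.write_simulation(tmp_path, vt, gm, pmap, truth)
        vt2, gm2 = rs.read_vcf(paths["vcf"])
        assert vt2.n_sites == vt.n_sites
        assert np.array_equal(gm2.dosages, gm.dosages)

    def test_invalid_config_fatal(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(seed=1, missing_rate=1.5)
        with pytest.raises(ValueError):
            rs.SimulationConfig(seed=1, n_pops=2, drift_f=(0.1, 0.2, 0.3))


class TestPlantSweeps:
    def _cfg(self, sweeps):
        return rs.SimulationConfig(
            seed=19, n_pops=2, samples_per_pop=30, n_chrom=2,
            chrom_length_bp=1_000_000, n_snps=4_000, drift_f=0.05,
            sweep_regions=sweeps, missing_rate=0.0,
        )

    def test_empty_sweep_list_identity(self):
        a = rs.simulate_balding_nichols(self._cfg([]))
        b = rs.simulate_balding_nichols(
            rs.SimulationConfig(seed=19, n_pops=2, samples_per_pop=30, n_chrom=2,
                                chrom_length_bp=1_000_000, n_snps=4_000,
                                drift_f=0.05, missing_rate=0.0)
        )
        assert np.array_equal(a[1].dosages, b[1].dosages)

    def test_unknown_chromosome_fatal(self):
        cfg = self._cfg([rs.SweepSpec("chr99", 1, 100_000, "pop2")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            rs.simulate_balding_nichols(cfg)

    def test_overlapping_regions_fatal(self):
        cfg = self._cfg([
            rs.SweepSpec("chr1", 1, 100_000, "pop2"),
            rs.SweepSpec("chr1", 50_000, 150_000, "pop2"),
        ])
        with pytest.raises(ValueError, match="overlapping"):
            rs.simulate_balding_nichols(cfg)

    def test_planted_region_loses_diversity_and_gains_fst(self):
        sweep = rs.SweepSpec("chr1", 400_001, 500_000, "pop2",
                             freq_shift=0.98, pi_reduction=10)
        vt, gm, pmap, _ = rs.simulate_balding_nichols(self._cfg([sweep]))
        focal = [s for s, p in pmap.assignments.items() if p == "pop2"]
        pi = rs.windowed_pi(gm, vt, focal, window_bp=100_000, step_bp=100_000)
        in_region = (pi["chrom"] == "chr1") & (pi["start"] == 400_001)
        region_pi = pi.loc[in_region, "pi"].iloc[0]
        genome_median = pi.loc[~in_region, "pi"].median()
        assert region_pi < 0.2 * genome_median
        a, abc = rs.site_fst_components(gm.dosages[:30], gm.dosages[30:])
        wf = rs.windowed_fst(vt, a, abc, window_bp=100_000, step_bp=100_000)
        region_fst = wf.loc[(wf["chrom"] == "chr1") & (wf["start"] == 400_001), "fst"].iloc[0]
        assert region_fst > np.nanquantile(wf["fst"], 0.99) or region_fst > 0.5


@pytest.fixture(scope="module")
def wf_small():
    cfg = rs.WrightFisherConfig(seed=31, census_n=50, chrom_length_bp=300_000,
                                mu_per_bp=2e-6, recomb_per_bp=1e-6, n_samples=25)
    return rs.simulate_wright_fisher(cfg), cfg


class TestWrightFisher:
    def test_segregating_sites_near_watterson(self, wf_small):
        (vt, gm, _, truth), cfg = wf_small
        n_hap = 2 * cfg.n_samples
        a_n = np.sum(1 / np.arange(1, n_hap))
        expected = 4 * cfg.census_n * cfg.mu_per_bp * cfg.chrom_length_bp * a_n
        assert 0.5 * expected < vt.n_sites < 1.5 * expected

    def test_fixed_seed_identical(self):
        cfg = rs.WrightFisherConfig(seed=8, census_n=20, chrom_length_bp=50_000,
                                    mu_per_bp=2e-6, recomb_per_bp=1e-6, n_samples=10)
        a = rs.simulate_wright_fisher(cfg)
        b = rs.simulate_wright_fisher(cfg)
        assert np.array_equal(a[0].pos, b[0].pos)
        assert np.array_equal(a[1].dosages, b[1].dosages)

    def test_no_recombination_gives_tight_ld(self):
        cfg = rs.WrightFisherConfig(seed=77, census_n=50, chrom_length_bp=100_000,
                                    mu_per_bp=3e-6, recomb_per_bp=0.0, n_samples=25)
        vt, gm, _, _ = rs.simulate_wright_fisher(cfg)
        # MAF-matched pairs on a single genealogy: near-complete LD
        dos = gm.dosages.astype(float)
        p = dos.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        common = np.flatnonzero(maf >= 0.2)
        r2s = []
        rng = np.random.default_rng(0)
        for _ in range(300):
            j, k = rng.choice(common, 2, replace=False)
            mj, mk = min(p[j], 1 - p[j]), min(p[k], 1 - p[k])
            if abs(mj - mk) < 0.05:
                r2s.append(rs.genotype_r2(gm.dosages[:, j], gm.dosages[:, k]))
        assert np.median(r2s) > 0.8

    def test_oversized_population_fatal(self):
        with pytest.raises(ValueError, match="desk-scale"):
            rs.WrightFisherConfig(seed=1, census_n=10_000)
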