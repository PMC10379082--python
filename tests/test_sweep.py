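"""Weir-Cockerham F_ST, Z-transform, pi-ratio and joint outlier calling."""

import numpy as np
import pandas as pd
import pytest

import radsweep as rs
from conftest import make_gm, make_vt


def wc_reference(n1, p1, h1, n2, p2, h2):
    """Scalar transcription of the Weir & Cockerham (1984) two-population
    variance components, independent of the vectorized implementation."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, a + b + c


class TestSiteComponents:
    def test_fixed_difference_is_one(self):
        a, abc = rs.site_fst_components(np.zeros((10, 1)), np.full((10, 1), 2))
        assert a[0] / abc[0] == pytest.approx(1.0)

    def test_identical_pops_nonpositive(self):
        dos = np.array([[0, 1, 2, 1, 0, 1]]).T.repeat(1, axis=1)
        a, abc = rs.site_fst_components(dos, dos.copy())
        assert a[0] <= 0
        assert a[0] / abc[0] <= 0

    def test_matches_scalar_reference(self):
        rng = np.random.default_rng(3)
        dos_a = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(12, 50)).astype(np.int8)
        dos_b = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(8, 50)).astype(np.int8)
        a, abc = rs.site_fst_components(dos_a, dos_b)
        for j in range(50):
            p1, p2 = dos_a[:, j].mean() / 2, dos_b[:, j].mean() / 2
            if not 0 < (12 * p1 + 8 * p2) / 20 < 1:
                assert a[j] == abc[j] == 0
                continue
            h1 = (dos_a[:, j] == 1).mean()
            h2 = (dos_b[:, j] == 1).mean()
            ra, rabc = wc_reference(12, p1, h1, 8, p2, h2)
            assert a[j] == pytest.approx(ra, abs=1e-12)
            assert abc[j] == pytest.approx(rabc, abs=1e-12)

    def test_monomorphic_site_excluded(self):
        a, abc = rs.site_fst_components(np.zeros((5, 1)), np.zeros((5, 1)))
        assert a[0] == 0 and abc[0] == 0

    def test_drift_recovery(self):
        # Balding-Nichols truth: mean windowed F_ST tracks the drift F
        cfg = rs.SimulationConfig(
            seed=13, n_pops=2, samples_per_pop=50, n_chrom=4,
            chrom_length_bp=1_000_000, n_snps=8_000, drift_f=0.1, missing_rate=0.0,
        )
        vt, gm, pmap, _ = rs.simulate_balding_nichols(cfg)
        a, abc = rs.site_fst_components(gm.dosages[:50], gm.dosages[50:])
        wf = rs.windowed_fst(vt, a, abc)
        assert np.nanmean(wf["fst"]) == pytest.approx(0.10, abs=0.02)


class TestWindowedFst:
    def test_single_site_window_equals_site_ratio(self):
        vt = make_vt([500])
        a, abc = np.array([0.03]), np.array([0.1])
        wf = rs.windowed_fst(vt, a, abc, window_bp=1000, step_bp=1000)
        assert wf["fst"].iloc[0] == pytest.approx(0.3)

    def test_all_fixed_windows_are_one(self):
        vt = make_vt([100, 200, 300])
        dos_a = np.zeros((6, 3))
        dos_b = np.full((6, 3), 2)
        a, abc = rs.site_fst_components(dos_a, dos_b)
        wf = rs.windowed_fst(vt, a, abc, window_bp=1000, step_bp=1000)
        assert wf["fst"].iloc[0] == pytest.approx(1.0)

    def test_uninformative_window_is_nan(self):
        vt = make_vt([100])
        wf = rs.windowed_fst(vt, np.array([0.0]), np.array([0.0]), 1000, 1000)
        assert np.isnan(wf["fst"].iloc[0])


class TestZTransform:
    def test_known_values(self):
        assert rs.z_transform(np.array([1.0, 2.0, 3.0])) == pytest.approx([-1, 0, 1])

    def test_shift_invariance(self):
        x = np.array([0.2, 0.5, 0.9, 1.7])
        assert rs.z_transform(x + 5) == pytest.approx(rs.z_transform(x))

    def test_zero_spread_fatal(self):
        with pytest.raises(ValueError):
            rs.z_transform(np.ones(5))

    def test_normal_percentile(self):
        rng = np.random.default_rng(1)
        z = rs.z_transform(rng.standard_normal(10_000))
        assert np.quantile(z, 0.95) == pytest.approx(1.645, abs=0.05)


class TestLog2PiRatio:
    def test_values(self):
        out = rs.log2_pi_ratio(np.array([0.2, 0.3, 0.0]), np.array([0.05, 0.3, 0.1]))
        assert out[0] == pytest.approx(2.0)
        assert out[1] == pytest.approx(0.0)
        assert np.isnan(out[2])


class TestJointOutliers:
    def test_construction(self):
        # 100 windows, the same 5 are top-5% in both statistics
        rng = np.random.default_rng(2)
        z = rng.uniform(-1, 1, 100)
        r = rng.uniform(-1, 1, 100)
        top = rng.choice(100, 5, replace=False)
        z[top] = 10 + np.arange(5)
        r[top] = 10 + np.arange(5)
        flags, tz, tr = rs.joint_outliers(z, r)
        assert set(np.flatnonzero(flags)) == set(top)

    def test_disjoint_tops_give_no_outliers(self):
        x = np.arange(100.0)
        flags, _, _ = rs.joint_outliers(x, -x)
        assert flags.sum() == 0

    def test_outlier_fraction_bounded(self, bn_two_pops):
        vt, gm, pmap, _ = bn_two_pops
        wf, _, _ = rs.sweep_scan(vt, gm, pmap, "pop1", "pop2")
        defined = np.isfinite(wf["z_fst"]) & np.isfinite(wf["log2_pi_ratio"])
        assert wf["outlier"].sum() <= 0.05 * defined.sum() + 1

    def test_too_few_windows_fatal(self):
        with pytest.raises(ValueError):
            rs.joint_outliers(np.arange(5.0), np.arange(5.0))


class TestMergeAndAnnotate:
    def _windows(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "z_fst", "log2_pi_ratio", "outlier"]
        )

    def test_overlap_merge(self):
        w = self._windows(
            [("chr1", 1, 100_000, 2.0, 2.0, True), ("chr1", 10_001, 110_000, 3.0, 1.0, True)]
        )
        regions = rs.merge_and_annotate(w)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_windows) == (1, 110_000, 2)
        assert r.peak_z_fst == 3.0 and r.peak_log2_pi_ratio == 2.0

    def test_gene_attachment(self):
        w = self._windows([("chr1", 1, 110_000, 2.0, 2.0, True)])
        genes = [
            rs.GeneInterval("chr1", 50_000, 60_000, "inside"),
            rs.GeneInterval("chr1", 200_000, 210_000, "outside"),
            rs.GeneInterval("chr2", 50_000, 60_000, "other_chrom"),
        ]
        regions = rs.merge_and_annotate(w, genes)
        assert regions[0].genes == ["inside"]

    def test_no_outliers(self):
        w = self._windows([("chr1", 1, 100_000, 2.0, 2.0, False)])
        assert rs.merge_and_annotate(w) == []


def test_panmictic_fst_near_zero():
    # two samples from one pool: mean windowed F_ST within +/-0.01 of 0
    cfg = rs.SimulationConfig(
        seed=21, n_pops=2, samples_per_pop=50, n_chrom=4,
        chrom_length_bp=1_000_000, n_snps=8_000, drift_f=0.0, missing_rate=0.0,
    )
    vt, gm, pmap, _ = rs.simulate_balding_nichols(cfg)
    a, abc = rs.site_fst_components(gm.dosages[:50], gm.dosages[50:])
    wf = rs.windowed_fst(vt, a, abc)
    assert abs(np.nanmean(wf["fst"])) < 0.01
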