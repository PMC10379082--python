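"""The filter cascade: annotations, clusters, depth, missingness/MAF, HWE."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radsweep as rs
from conftest import make_gm, make_vt


class TestSiteAnnotations:
    @pytest.mark.parametrize(
        "qd,fs,kept",
        [
            (1.9, 10.0, False),   # QD below threshold
            (5.0, 31.0, False),   # FS above threshold
            (2.0, 30.0, True),    # boundary values survive (strict inequalities)
            (np.nan, np.nan, True),  # unannotated sites retained
        ],
    )
    def test_thresholds(self, qd, fs, kept):
        vt = make_vt([100], qd=[qd], fs=[fs])
        keep, rep = rs.filter_site_annotations(vt)
        assert keep[0] == kept
        assert rep.n_input == 1

    def test_nonfinite_threshold_rejected(self):
        vt = make_vt([100])
        with pytest.raises(ValueError):
            rs.filter_site_annotations(vt, qd_min=np.inf)


class TestSnpClusters:
    @pytest.mark.parametrize(
        "positions,removed",
        [
            ([100, 110, 120, 130], [True] * 4),     # 4 SNPs inside 35 bp
            ([100, 150, 200], [False] * 3),
            ([100, 110, 120], [False] * 3),         # exactly 3 allowed
        ],
    )
    def test_rule(self, positions, removed):
        keep, _ = rs.filter_snp_clusters(make_vt(positions))
        assert list(~keep) == removed

    def test_cluster_confined_to_chromosome(self):
        vt = make_vt([100, 110, 120, 105], chrom=["chr1"] * 3 + ["chr2"])
        keep, _ = rs.filter_snp_clusters(vt)
        assert keep.all()


class TestDepthMask:
    @pytest.mark.parametrize("depth,kept", [(10, False), (11, True), (59, True), (60, False)])
    def test_open_interval(self, depth, kept):
        gm = make_gm([[1]], depths=np.array([[depth]]))
        out = rs.mask_genotypes_by_depth(gm)
        assert (out.dosages[0, 0] != rs.MISSING) == kept

    def test_depths_absent_fatal(self):
        with pytest.raises(ValueError, match="no depths"):
            rs.mask_genotypes_by_depth(make_gm([[1]]))


class TestMissingMaf:
    def test_twenty_percent_missing_removed(self):
        col = [1] * 8 + [rs.MISSING] * 2
        keep, _ = rs.filter_missing_maf(make_gm(np.array(col)[:, None]))
        assert not keep[0]

    def test_maf_boundary_retained(self):
        # 10 diploids, 1 alt / 19 ref -> MAF 0.05 exactly, kept
        col = [1] + [0] * 9
        keep, _ = rs.filter_missing_maf(make_gm(np.array(col)[:, None]))
        assert keep[0]

    def test_monomorphic_removed(self):
        keep, _ = rs.filter_missing_maf(make_gm(np.zeros((10, 1))))
        assert not keep[0]

    def test_zero_called_counted_separately(self):
        keep, rep = rs.filter_missing_maf(make_gm(np.full((4, 1), rs.MISSING)))
        assert not keep[0]
        assert "zero called" in rep.notes


def hwe_exact_oracle(n_rr: int, n_ra: int, n_aa: int) -> Fraction:
    """Brute-force exact HWE p by enumerating all genotype configurations
    with the observed allele counts, in exact rational arithmetic."""
    n = n_rr + n_ra + n_aa
    n_alt = n_ra + 2 * n_aa

    def weight(h):
        aa = (n_alt - h) // 2
        rr = n - h - aa
        if aa < 0 or rr < 0:
            return None
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(rr) * math.factorial(h) * math.factorial(aa),
        )

    ws = {h: w for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2)
          if (w := weight(h)) is not None}
    total = sum(ws.values())
    obs = ws[n_ra]
    return sum(w for w in ws.values() if w <= obs) / total


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert rs.hwe_exact_test(5, 0, 0) == 1.0

    def test_small_case_matches_enumeration(self):
        assert rs.hwe_exact_test(1, 2, 1) == pytest.approx(float(hwe_exact_oracle(1, 2, 1)), abs=1e-12)

    def test_matches_oracle_on_grid(self):
        for n in range(1, 13):
            for n_rr in range(n + 1):
                for n_ra in range(n - n_rr + 1):
                    n_aa = n - n_rr - n_ra
                    p = rs.hwe_exact_test(n_rr, n_ra, n_aa)
                    q = float(hwe_exact_oracle(n_rr, n_ra, n_aa))
                    assert p == pytest.approx(q, rel=1e-9), (n_rr, n_ra, n_aa)

    def test_exact_test_is_conservative_under_null(self):
        # simulated null at allele freq 0.5: rejection rate at alpha=0.05
        # must not exceed alpha (the exact test is conservative)
        rng = np.random.default_rng(123)
        n, reps = 50, 20_000
        genos = rng.multinomial(n, [0.25, 0.5, 0.25], size=reps)
        cache = {}
        rej = 0
        for rr, ra, aa in genos:
            key = (rr, ra, aa)
            if key not in cache:
                cache[key] = rs.hwe_exact_test(rr, ra, aa)
            rej += cache[key] < 0.05
        assert rej / reps <= 0.05

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_in_unit_interval(self, rr, ra, aa):
        if rr + ra + aa == 0:
            return
        p = rs.hwe_exact_test(rr, ra, aa)
        assert 0 < p <= 1


class TestHweFilter:
    def test_all_het_removed(self):
        gm = make_gm(np.ones((50, 1)))
        keep, _ = rs.hwe_filter(gm, alpha=0.001)
        assert not keep[0]
        assert hwe_exact_oracle(0, 50, 0) < Fraction(1, 1000)

    def test_balanced_site_retained(self):
        gm = make_gm(np.array([0, 1, 1, 2] * 5)[:, None])
        keep, _ = rs.hwe_filter(gm, alpha=0.001)
        assert keep[0]

    def test_alpha_zero_removes_nothing(self):
        gm = make_gm(np.ones((50, 1)))
        keep, _ = rs.hwe_filter(gm, alpha=0.0)
        assert keep.all()


class TestPipeline:
    def test_reports_chain_and_exact_removal(self):
        vt, gm, truth = rs.simulate_filter_testcase(seed=5)
        vt2, gm2, reports = rs.apply_filter_pipeline(vt, gm)
        by_stage = {r.stage: r for r in reports}
        # stage k input equals stage k-1 retained (depth stage removes no sites)
        site_stages = [r for r in reports if r.stage != "depth_mask"]
        for prev, cur in zip(site_stages, site_stages[1:]):
            assert cur.n_input == prev.n_retained
        # each planted violation removed by its own stage, nothing else
        for stage, planted in truth.items():
            assert by_stage[stage].n_removed == len(planted), stage
        removed_ids = set(vt.site_id) - set(vt2.site_id)
        assert removed_ids == set().union(*truth.values())

    def test_depth_mask_feeds_missingness(self):
        # depths of 5 at 3/10 samples push the site over the 10% missing cap
        dos = np.array([[1] * 10]).T
        depths = np.full((10, 1), 30)
        depths[:3, 0] = 5
        vt = make_vt([100])
        gm = make_gm(dos, depths=depths)
        _, gm2, reports = rs.apply_filter_pipeline(
            vt, gm, rs.FilterParams(hwe_alpha=None)
        )
        missing_maf = [r for r in reports if r.stage == "missing_maf"][0]
        assert missing_maf.n_removed == 1
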