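import numpy as np
import pytest

from hapflow.genodata import MISSING, PanelError
from hapflow.selstats import (
    candidate_regions,
    ehh,
    fst,
    ihs,
    integrated_ehh,
    rsb,
)
from hapflow.simpop import SimConfig, simulate_parental_panels

from conftest import (
    brute_force_ehh,
    brute_force_regions,
    make_map,
    make_panel,
)


class TestEHH:
    def test_core_value_is_one(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 2, size=(10, 20)))
        curve = ehh(panel, 10, int(panel.haplotypes[0, 10]))
        assert curve.left[0, 1] == 1.0
        assert curve.right[0, 1] == 1.0

    def test_hand_enumeration_four_carriers(self):
        # 4 carriers: two identical, two unique at the next site -> C(2,2)/C(4,2)
        haps = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, 1, 0],
                [1, 0, 1],
                [0, 0, 0],
            ],
            dtype=np.int8,
        )
        haps = np.vstack([haps, [0, 1, 1]])  # even row count
        panel = make_panel(haps, positions=[100, 200, 300])
        curve = ehh(panel, 0, 1)
        # extending right over sites 1..2: both must match
        assert curve.right[1, 1] == pytest.approx(
            brute_force_ehh(haps, 0, 1, 1)
        )
        assert curve.right[2, 1] == pytest.approx(1 / 6)

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(10, 50)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 5000), size=50, replace=False))
            panel = make_panel(haps, positions=pos)
            core = int(rng.integers(5, 45))
            allele = int(haps[0, core])
            curve = ehh(panel, core, allele, max_extension=10**9, max_gap=10**9)
            for step, (d, e) in enumerate(curve.right):
                assert e == pytest.approx(
                    brute_force_ehh(haps, core, allele, core + step)
                )
            for step, (d, e) in enumerate(curve.left):
                assert e == pytest.approx(
                    brute_force_ehh(haps, core, allele, core - step)
                )

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.integers(0, 2, size=(12, 40)))
        curve = ehh(panel, 20, 1, max_extension=10**9)
        assert (np.diff(curve.right[:, 1]) <= 1e-12).all()
        assert (np.diff(curve.left[:, 1]) <= 1e-12).all()

    def test_monomorphic_core_raises(self):
        haps = np.zeros((6, 5), dtype=np.int8)
        panel = make_panel(haps)
        with pytest.raises(PanelError, match="carriers"):
            ehh(panel, 2, 1)

    def test_missing_breaks_identity(self):
        haps = np.array(
            [[1, 0], [1, 0], [1, MISSING], [1, MISSING]], dtype=np.int8
        )
        panel = make_panel(haps, positions=[10, 20])
        curve = ehh(panel, 0, 1, max_extension=10**9)
        # only the two complete haplotypes pair up: C(2,2)/C(4,2)
        assert curve.right[1, 1] == pytest.approx(1 / 6)


class TestIHS:
    def test_symmetric_toy_gives_zero_raw(self):
        # derived and ancestral carriers with mirror-image structure
        block = np.array(
            [[0, 0, 0, 0, 0], [0, 1, 0, 1, 0], [1, 0, 0, 0, 1], [0, 1, 0, 0, 1]],
            dtype=np.int8,
        )  # core column (index 2) all ancestral
        mirror = block.copy()
        mirror[:, 2] = 1  # identical flanking patterns, core allele 1
        haps = np.vstack([block, mirror])
        panel = make_panel(haps, positions=[100, 200, 300, 400, 500])
        ihh_a, _ = integrated_ehh(panel, 2, 0, floor=0.0, max_extension=10**9)
        ihh_d, _ = integrated_ehh(panel, 2, 1, floor=0.0, max_extension=10**9)
        assert np.log(ihh_a / ihh_d) == pytest.approx(0.0, abs=1e-12)

    def test_bin_standardization_moments(self):
        cfg = SimConfig(n_per_breed=50, n_admixed=2, n_sites=2000,
                        chrom_lengths=(100_000_000,), seed=3)
        panel, _ = simulate_parental_panels(cfg)
        frame = ihs(panel)
        ok = np.isfinite(frame["ihs"])
        assert ok.sum() > 1000
        # moments hold within every sufficiently populated frequency bin
        daf_bin = (frame["daf"] // 0.05).astype(int)
        checked = 0
        for b, grp in frame[ok].groupby(daf_bin[ok]):
            if len(grp) >= 30:
                assert grp["ihs"].mean() == pytest.approx(0.0, abs=0.3)
                checked += 1
        assert checked >= 3
        assert frame["ihs"][ok].std(ddof=1) == pytest.approx(1.0, abs=0.1)

    def test_excluded_snps_flagged(self):
        cfg = SimConfig(n_per_breed=20, n_admixed=2, n_sites=300,
                        chrom_lengths=(15_000_000,), seed=4)
        panel, _ = simulate_parental_panels(cfg)
        frame = ihs(panel, maf_floor=0.2)
        rare = (frame["daf"] < 0.2) | (frame["daf"] > 0.8)
        assert frame.loc[rare, "excluded"].all()
        assert frame.loc[rare, "ihs"].isna().all()


class TestRsb:
    def test_identical_panels_give_zero_raw(self):
        cfg = SimConfig(n_per_breed=15, n_admixed=2, n_sites=200,
                        chrom_lengths=(10_000_000,), seed=6)
        panel, _ = simulate_parental_panels(cfg)
        frame = rsb(panel, panel)
        ok = np.isfinite(frame["raw"])
        assert ok.sum() > 100
        np.testing.assert_allclose(frame.loc[ok, "raw"], 0.0, atol=1e-12)

    def test_standardized_median_zero(self):
        cfg = SimConfig(n_per_breed=15, n_admixed=2, n_sites=400,
                        chrom_lengths=(20_000_000,), seed=7)
        p1, _ = simulate_parental_panels(cfg)
        cfg2 = SimConfig(n_per_breed=15, n_admixed=2, n_sites=400,
                         chrom_lengths=(20_000_000,), seed=8)
        p2, _ = simulate_parental_panels(cfg2)
        frame = rsb(p1, p2)
        ok = np.isfinite(frame["rsb"])
        assert np.median(frame.loc[ok, "rsb"]) == pytest.approx(0.0, abs=1e-12)

    def test_long_shared_haplotype_gives_positive_sign(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_per_breed=20, n_admixed=2, n_sites=300,
                            chrom_lengths=(15_000_000,), seed=seed)
            panel, _ = simulate_parental_panels(cfg)
            twin = make_panel(
                panel.haplotypes.copy(), positions=panel.map.pos,
                populations=list(panel.manifest.population),
            )
            # plant a long shared haplotype in panel around the mid SNP
            mid = 150
            sweep = panel.haplotypes.copy()
            sweep[: sweep.shape[0] // 2, mid - 20 : mid + 20] = sweep[
                0, mid - 20 : mid + 20
            ]
            swept = make_panel(
                sweep, positions=panel.map.pos,
                populations=list(panel.manifest.population),
            )
            frame = rsb(swept, twin)
            if frame["raw"].iloc[mid] > 0:
                hits += 1
        assert hits >= 8

    def test_map_mismatch_raises(self):
        cfg = SimConfig(n_per_breed=10, n_admixed=2, n_sites=100,
                        chrom_lengths=(5_000_000,), seed=1)
        p1, _ = simulate_parental_panels(cfg)
        cfg2 = SimConfig(n_per_breed=10, n_admixed=2, n_sites=120,
                         chrom_lengths=(5_000_000,), seed=1)
        p2, _ = simulate_parental_panels(cfg2)
        with pytest.raises(PanelError, match="marker map"):
            rsb(p1, p2)


class TestFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(10)
        haps = rng.integers(0, 2, size=(200, 2000)).astype(np.int8)
        panel = make_panel(
            haps, positions=1000 * np.arange(1, 2001),
            populations=["A"] * 50 + ["B"] * 50,
        )
        _, summary = fst(panel, "A", "B")
        assert abs(summary["mean"]) < 0.01

    def test_fixed_difference_is_one(self):
        haps = np.vstack([np.zeros((4, 3)), np.ones((4, 3))]).astype(np.int8)
        panel = make_panel(haps, populations=["A", "A", "B", "B"])
        frame, _ = fst(panel, "A", "B")
        np.testing.assert_allclose(frame["fst"], 1.0)

    def test_nei_hand_value(self):
        # p_A = 0.2, p_B = 0.8 -> H_S = 0.32, H_T = 0.5, F_ST = 0.36
        n = 200
        haps = np.zeros((2 * n, 1), dtype=np.int8)
        haps[: int(0.2 * n)] = 1  # 20% of A's n haplotypes
        haps[n : n + int(0.8 * n)] = 1
        panel = make_panel(haps, populations=["A"] * (n // 2) + ["B"] * (n // 2))
        nei_frame, _ = fst(panel, "A", "B", estimator="nei")
        assert nei_frame["fst"].iloc[0] == pytest.approx(0.36, abs=1e-9)
        # independent hand arithmetic for the Hudson route at these counts
        p1, p2, n1, n2 = 0.2, 0.8, 200, 200
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        hudson_frame, _ = fst(panel, "A", "B")
        assert hudson_frame["fst"].iloc[0] == pytest.approx(num / den, abs=1e-9)

    def test_monomorphic_sites_excluded(self):
        haps = np.zeros((8, 2), dtype=np.int8)
        haps[:4, 1] = 1
        panel = make_panel(haps, populations=["A", "A", "B", "B"])
        frame, summary = fst(panel, "A", "B")
        assert np.isnan(frame["fst"].iloc[0])
        assert summary["n_excluded"] == 1
        assert summary["n_sites"] == 1

    def test_unknown_estimator(self):
        haps = np.zeros((4, 2), dtype=np.int8)
        panel = make_panel(haps, populations=["A", "B"])
        with pytest.raises(PanelError, match="estimator"):
            fst(panel, "A", "B", estimator="weir")


class TestCandidateRegions:
    def test_no_significant_snps(self):
        m = make_map(1000 * np.arange(1, 21))
        assert candidate_regions(np.zeros(20), m) == []

    def test_three_close_hits_make_one_region(self):
        pos = 100_000 * np.arange(1, 21)
        scores = np.zeros(20)
        scores[5:8] = 4.0  # three hits within 0.2 Mb
        m = make_map(pos)
        regions = candidate_regions(scores, m)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (pos[5], pos[7])
        assert r.max_score == 4.0
        assert r.n_significant == 3

    def test_sparse_hits_do_not_call(self):
        pos = np.array([1, 2_000_000, 4_000_000, 6_000_000])
        scores = np.full(4, 5.0)
        m = make_map(pos)
        assert candidate_regions(scores, m, span=1_000_000) == []

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            pos = np.sort(rng.choice(np.arange(1, 10_000_000, 1000), n, replace=False))
            scores = rng.normal(scale=2.0, size=n)
            m = make_map(pos)
            got = sorted(
                (r.start_bp, r.end_bp) for r in candidate_regions(scores, m)
            )
            assert got == brute_force_regions(pos, scores)

    def test_signed_option(self):
        pos = 100_000 * np.arange(1, 10)
        scores = np.zeros(9)
        scores[2:5] = -4.0
        m = make_map(pos)
        assert len(candidate_regions(scores, m, use_abs=True)) == 1
        assert candidate_regions(scores, m, use_abs=False) == []
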