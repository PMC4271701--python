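import numpy as np
import pytest

from hapflow import hapwin
from hapflow.genodata import MISSING, PanelError
from hapflow.lancestry import (
    AncestryField,
    ancestry_field_from_truth,
    ancestry_summaries,
    infer_local_ancestry,
    read_external_ancestry,
    train_ancestry_model,
    write_ancestry_field,
)
from hapflow.simpop import SimConfig, simulate_admixed, simulate_parental_panels

from conftest import make_panel


def toy_parental(seed=0, n_sites=60, n_per_pop=5, pops=("A", "B")):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(2 * n_per_pop * len(pops), n_sites)).astype(np.int8)
    populations = [p for p in pops for _ in range(n_per_pop)]
    return make_panel(haps, populations=populations)


class TestTraining:
    def test_emission_lower_bound_for_panel_member(self):
        panel = toy_parental()
        grid = hapwin.build_windows(panel.map, size=30)
        model = train_ancestry_model(panel, grid, epsilon=0.01)
        query = panel.population_haplotypes("A")[0]
        log_em = model.log_emissions(query)
        n_a = panel.population_haplotypes("A").shape[0]
        bound = 30 * np.log(0.99) - np.log(n_a)
        assert (log_em[:, 0] >= bound - 1e-12).all()

    def test_identical_panels_give_equal_emissions(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
        haps = np.vstack([block, block])
        panel = make_panel(haps, populations=["A"] * 3 + ["B"] * 3)
        grid = hapwin.build_windows(panel.map, size=30)
        model = train_ancestry_model(panel, grid)
        query = rng.integers(0, 2, size=60).astype(np.int8)
        log_em = model.log_emissions(query)
        np.testing.assert_allclose(log_em[:, 0], log_em[:, 1])

    def test_emission_matches_brute_force(self):
        eps = 0.05
        panel = toy_parental(seed=2, n_sites=30, n_per_pop=5, pops=("A",))
        grid = hapwin.build_windows(panel.map, size=30)
        model = train_ancestry_model(panel, grid, epsilon=eps)
        rng = np.random.default_rng(3)
        query = rng.integers(0, 2, size=30).astype(np.int8)
        # independent oracle: direct probability sum over the 10 panel haplotypes
        total = 0.0
        for t in panel.haplotypes:
            mism = int((t != query).sum())
            total += eps**mism * (1 - eps) ** (30 - mism)
        expected = total / panel.n_haplotypes
        assert model.log_emissions(query)[0, 0] == pytest.approx(np.log(expected))

    def test_empty_breed_window_raises(self):
        panel = toy_parental(n_per_pop=2)
        panel.haplotypes[panel.haplotype_rows("B"), :5] = MISSING
        grid = hapwin.build_windows(panel.map, size=30)
        with pytest.raises(PanelError, match="zero complete haplotypes"):
            train_ancestry_model(panel, grid)

    def test_overlapping_grid_rejected(self):
        panel = toy_parental()
        grid = hapwin.build_windows(panel.map, size=30, step=15)
        with pytest.raises(PanelError, match="non-overlapping"):
            train_ancestry_model(panel, grid)


class TestInference:
    def test_copied_haplotype_recovers_source(self):
        # admixed haplotype copied verbatim from breed A under strong divergence
        hits = 0
        total = 0
        for seed in range(10):
            cfg = SimConfig(
                breed_names=("A", "B"), admix_props=(0.5, 0.5),
                n_per_breed=20, n_admixed=1, n_sites=300, divergence_f=0.2,
                chrom_lengths=(15_000_000,), seed=seed,
            )
            parental, _ = simulate_parental_panels(cfg)
            grid = hapwin.build_windows(parental.map, size=30)
            model = train_ancestry_model(parental, grid)
            rows = parental.haplotype_rows("A")
            query_panel = make_panel(
                parental.haplotypes[rows[:2]].copy(),
                positions=parental.map.pos,
                populations=["Q"],
                roles=["admixed"],
            )
            field = infer_local_ancestry(query_panel, model)
            hits += int((field.viterbi == 0).sum())
            total += field.viterbi.size
        assert hits / total > 0.95

    def test_identical_panels_posterior_equals_prior(self):
        rng = np.random.default_rng(4)
        block = rng.integers(0, 2, size=(8, 90)).astype(np.int8)
        panel = make_panel(
            np.vstack([block, block]), populations=["A"] * 4 + ["B"] * 4
        )
        grid = hapwin.build_windows(panel.map, size=30)
        pi = np.array([0.7, 0.3])
        model = train_ancestry_model(panel, grid, pi=pi)
        query = make_panel(
            rng.integers(0, 2, size=(2, 90)).astype(np.int8),
            positions=panel.map.pos, populations=["Q"], roles=["admixed"],
        )
        field = infer_local_ancestry(query, model)
        np.testing.assert_allclose(field.posteriors, np.broadcast_to(pi, field.posteriors.shape), atol=1e-9)

    def test_single_breed_posterior_is_one(self):
        panel = toy_parental(pops=("A",))
        grid = hapwin.build_windows(panel.map, size=30)
        model = train_ancestry_model(panel, grid)
        rng = np.random.default_rng(0)
        query = make_panel(
            rng.integers(0, 2, size=(2, 60)).astype(np.int8),
            positions=panel.map.pos, populations=["Q"], roles=["admixed"],
        )
        field = infer_local_ancestry(query, model)
        np.testing.assert_allclose(field.posteriors, 1.0)

    def test_map_mismatch_raises(self):
        panel = toy_parental()
        grid = hapwin.build_windows(panel.map, size=30)
        model = train_ancestry_model(panel, grid)
        other = toy_parental(n_sites=61)
        with pytest.raises(PanelError, match="map"):
            infer_local_ancestry(other, model)

    def test_recovery_improves_with_divergence(self):
        # donors are held out of training so accuracy reflects breed
        # divergence rather than exact-donor matching
        from hapflow.genodata import GenotypePanel

        accs = []
        for f in (0.02, 0.1, 0.2):
            cfg = SimConfig(
                n_per_breed=30, n_admixed=25, n_sites=900, divergence_f=f,
                chrom_lengths=(45_000_000,), seed=17,
            )
            parental, _ = simulate_parental_panels(cfg)
            donor_idx, train_idx = [], []
            for breed in cfg.breed_names:
                s = parental.manifest.sample_indices(breed)
                donor_idx.extend(s[:15])
                train_idx.extend(s[15:])
            rows = lambda idx: np.sort(
                np.concatenate([[2 * i, 2 * i + 1] for i in idx])
            )
            donors = GenotypePanel(
                haplotypes=parental.haplotypes[rows(donor_idx)],
                map=parental.map,
                manifest=parental.manifest.subset(sorted(donor_idx)),
            )
            trainers = GenotypePanel(
                haplotypes=parental.haplotypes[rows(train_idx)],
                map=parental.map,
                manifest=parental.manifest.subset(sorted(train_idx)),
            )
            admixed, truth = simulate_admixed(donors, cfg)
            grid = hapwin.build_windows(parental.map, size=30)
            model = train_ancestry_model(trainers, grid, breeds=list(cfg.breed_names))
            field = infer_local_ancestry(admixed, model)
            truth_lab = ancestry_field_from_truth(truth, grid).posteriors.argmax(axis=2)
            accs.append((field.viterbi == truth_lab).mean())
        assert accs[0] < accs[1] < accs[2]


class TestSummaries:
    def _field(self, posteriors):
        posteriors = np.asarray(posteriors, dtype=float)
        grid = hapwin.build_windows(
            make_panel(np.zeros((2, 2), dtype=np.int8)).map, size=2
        )
        return AncestryField(
            grid=grid,
            breeds=("A", "B", "C"),
            posteriors=posteriors,
            viterbi=posteriors.argmax(axis=2).astype(np.int32),
        )

    def test_degenerate_posteriors(self):
        field = self._field(np.tile([1.0, 0.0, 0.0], (4, 1, 1)))
        mean, _ = ancestry_summaries(field, "mean")
        minimum, flags = ancestry_summaries(field, "minimum")
        np.testing.assert_allclose(mean, [[1, 0, 0]])
        np.testing.assert_allclose(minimum, [[1, 0, 0]])
        assert not flags.any()

    def test_no_confident_haplotype_flags_window(self):
        field = self._field(np.tile([0.5, 0.5, 0.0], (4, 1, 1)))
        minimum, flags = ancestry_summaries(field, "minimum", tau=0.95)
        np.testing.assert_allclose(minimum, [[0, 0, 0]])
        assert flags.all()

    def test_minimum_close_to_mean_for_top_breed_on_sim(self):
        cfg = SimConfig(n_per_breed=20, n_admixed=30, n_sites=600,
                        divergence_f=0.2, chrom_lengths=(30_000_000,), seed=8)
        parental, _ = simulate_parental_panels(cfg)
        admixed, truth = simulate_admixed(parental, cfg)
        grid = hapwin.build_windows(parental.map, size=30)
        model = train_ancestry_model(parental, grid, breeds=list(cfg.breed_names))
        field = infer_local_ancestry(admixed, model)
        mean, _ = ancestry_summaries(field, "mean")
        minimum, flags = ancestry_summaries(field, "minimum")
        ok = ~flags
        assert np.abs(minimum[ok] - mean[ok]).max() < 0.2


class TestExternalAncestry:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        post = rng.dirichlet([1, 1, 1], size=(4, 2))
        grid = hapwin.build_windows(
            make_panel(np.zeros((2, 60), dtype=np.int8)).map, size=30
        )
        field = AncestryField(
            grid=grid, breeds=("A", "B", "C"), posteriors=post,
            viterbi=post.argmax(axis=2).astype(np.int32),
        )
        write_ancestry_field(field, tmp_path / "a.tsv")
        back = read_external_ancestry(tmp_path / "a.tsv", grid)
        np.testing.assert_allclose(back.posteriors, post, atol=1e-12)
        assert back.breeds == ("A", "B", "C")

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample\thap\twindow\tprob_A\tprob_B\n"
            "s0\t0\t0\t0.5\t0.5\n"
            "s0\t0\t1\t0.9\t0.3\n"
        )
        grid = hapwin.build_windows(
            make_panel(np.zeros((2, 60), dtype=np.int8)).map, size=30
        )
        with pytest.raises(PanelError, match="line 3"):
            read_external_ancestry(path, grid)
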