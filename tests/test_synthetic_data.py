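"""Synthetic generators: panel pileups, catalogs, SV sets, microhomology."""

import numpy as np
import pytest
import scipy.stats

from mutpanel.isocall import ALLELES
from mutpanel.svclass import classify_size, microhomology_length
from mutpanel.synthetic_data import (
    CatalogSimConfig,
    PanelSimConfig,
    SVSimConfig,
    plant_microhomology,
    simulate_catalog,
    simulate_panel,
    simulate_sv_set,
)

from conftest import brute_force_microhomology

REF_IDX = {a: i for i, a in enumerate(ALLELES)}


class TestPanel:
    def test_no_signal_panel_is_pure_reference(self):
        cfg = PanelSimConfig(n_samples=3, genome_length=300, mean_coverage=25, seed=1)
        reference, sites = simulate_panel(cfg)
        assert len(reference) == len(sites) == 300
        for site in sites:
            assert site.ref == reference[site.pos - 1]
            nonref = np.delete(site.counts, REF_IDX[site.ref], axis=1)
            assert nonref.sum() == 0
            assert (site.counts.sum(axis=1) >= 1).all()

    def test_saturated_vaf_converts_all_reads(self):
        cfg = PanelSimConfig(
            n_samples=2, genome_length=50, mean_coverage=20,
            planted_unique=[(0, 10, "A", "C", 1.0)], seed=2,
        )
        _, sites = simulate_panel(cfg)
        site = sites[9]
        assert site.counts[0, REF_IDX["A"]] == 0
        assert site.counts[0, REF_IDX["C"]] == site.counts[0].sum()
        # the other sample stays clean
        assert site.counts[1, REF_IDX["A"]] == site.counts[1].sum()

    def test_planted_vaf_mean_within_three_standard_errors(self):
        vaf, n = 0.4, 400
        planted = [(0, pos, "A", "C", vaf) for pos in range(1, n + 1)]
        cfg = PanelSimConfig(
            n_samples=2, genome_length=n, mean_coverage=40,
            planted_unique=planted, seed=3,
        )
        _, sites = simulate_panel(cfg)
        vafs = []
        for site in sites:
            tot = site.counts[0].sum()
            vafs.append(site.counts[0, REF_IDX["C"]] / tot)
        se = np.sqrt(vaf * (1 - vaf) / 40) / np.sqrt(n)
        assert abs(np.mean(vafs) - vaf) <= 3 * se

    def test_clonal_mutation_present_in_every_sample(self):
        cfg = PanelSimConfig(
            n_samples=4, genome_length=30, mean_coverage=60,
            planted_clonal=[(15, "G", "T")], seed=4,
        )
        _, sites = simulate_panel(cfg)
        site = sites[14]
        for s in range(4):
            assert site.counts[s, REF_IDX["T"]] > 0

    def test_position_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            PanelSimConfig(
                n_samples=2, genome_length=100, mean_coverage=30,
                planted_unique=[(0, 101, "A", "C", 0.5)],
            )

    def test_noise_rate_bounds_enforced(self):
        with pytest.raises(ValueError, match="noise_rate"):
            PanelSimConfig(n_samples=2, genome_length=10, mean_coverage=30, noise_rate=0.2)

    def test_deterministic_for_fixed_seed(self):
        cfg = PanelSimConfig(
            n_samples=3, genome_length=200, mean_coverage=25,
            planted_unique=[(1, 50, "C", "G", 0.5)], noise_rate=0.01, seed=11,
        )
        ref_a, sites_a = simulate_panel(cfg)
        ref_b, sites_b = simulate_panel(cfg)
        assert ref_a == ref_b
        assert all(np.array_equal(a.counts, b.counts) for a, b in zip(sites_a, sites_b))


class TestCatalog:
    def test_zero_mutations_gives_zero_spectrum(self, sigs):
        cfg = CatalogSimConfig(["SBS1"], [1.0], 0, seed=0)
        assert simulate_catalog(cfg, sigs).sum() == 0

    def test_counts_conserved(self, sigs):
        cfg = CatalogSimConfig(["SBS1", "SBS5"], [0.3, 0.7], 1234, seed=5)
        assert simulate_catalog(cfg, sigs).sum() == 1234

    def test_empirical_frequencies_converge_to_mixture(self, sigs):
        names, weights = ["SBS2", "SBS5"], [0.4, 0.6]
        p = 0.4 * sigs.column("SBS2") + 0.6 * sigs.column("SBS5")
        cfg = CatalogSimConfig(names, weights, 1_000_000, seed=6)
        freq = simulate_catalog(cfg, sigs) / 1_000_000
        assert np.max(np.abs(freq - p)) <= 1e-2

    def test_chi_square_goodness_of_fit_across_seeds(self, sigs):
        # draws should be consistent with the mixture in >= 19/20 seeds at 5%
        names, weights, n = ["SBS1", "SBS18"], [0.5, 0.5], 20_000
        p = 0.5 * sigs.column("SBS1") + 0.5 * sigs.column("SBS18")
        ok = 0
        for seed in range(20):
            counts = simulate_catalog(CatalogSimConfig(names, weights, n, seed=seed), sigs)
            _, pval = scipy.stats.chisquare(counts, n * p)
            ok += pval > 0.05
        assert ok >= 19

    def test_unknown_signature_name_rejected(self, sigs):
        cfg = CatalogSimConfig(["SBS99"], [1.0], 10, seed=0)
        with pytest.raises(KeyError):
            simulate_catalog(cfg, sigs)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CatalogSimConfig(["SBS1", "SBS5"], [0.5, 0.6], 10)


class TestSVSet:
    def test_exact_per_class_counts(self):
        cfg = SVSimConfig(n_small=30, n_mid=20, n_large=10, n_ctx=5, seed=7)
        records = simulate_sv_set(cfg)
        classes = [r.size_class for r in records]
        assert classes.count("small") == 30
        assert classes.count("mid") == 20
        assert classes.count("large") == 10
        assert sum(r.svtype == "CTX" for r in records) == 5
        assert all(r.length is None for r in records if r.svtype == "CTX")

    def test_lengths_respect_class_windows(self):
        cfg = SVSimConfig(n_small=50, n_mid=50, n_large=50, seed=8)
        for r in simulate_sv_set(cfg):
            assert 100 <= r.length <= 10**8
            assert classify_size(r.length) == r.size_class

    def test_only_requested_types_drawn(self):
        cfg = SVSimConfig(n_small=40, n_mid=0, n_large=0, type_mix={"DEL": 1.0}, seed=9)
        assert all(r.svtype == "DEL" for r in simulate_sv_set(cfg))

    def test_deterministic_for_fixed_seed(self):
        cfg = SVSimConfig(n_small=10, n_mid=10, n_large=10, n_ctx=2, seed=10)
        a = simulate_sv_set(cfg)
        b = simulate_sv_set(cfg)
        assert [(r.svtype, r.pos1, r.pos2, r.support) for r in a] == [
            (r.svtype, r.pos1, r.pos2, r.support) for r in b
        ]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SVSimConfig(n_small=-1, n_mid=0, n_large=0)


class TestPlantMicrohomology:
    def test_zero_homology_junction(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), 200))
        edited = plant_microhomology(ref, (50, 120), 0)
        assert microhomology_length(edited, (50, 120)) == 0

    def test_exact_k_round_trip(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), 300))
        for k in range(0, 11):
            edited = plant_microhomology(ref, (100, 200), k)
            assert microhomology_length(edited, (100, 200)) == k

    def test_matches_brute_force_oracle_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ref = "".join(rng.choice(list("ACGT"), 150))
            start = int(rng.integers(20, 60))
            end = int(rng.integers(start + 12, 120))
            k = int(rng.integers(0, 11))
            edited = plant_microhomology(ref, (start, end), k)
            assert brute_force_microhomology(edited, start, end) == k

    def test_too_short_deletion_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            plant_microhomology("A" * 100, (10, 12), 5)

    def test_insufficient_right_flank_rejected(self):
        with pytest.raises(ValueError, match="after the deletion"):
            plant_microhomology("A" * 50, (10, 45), 5)
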