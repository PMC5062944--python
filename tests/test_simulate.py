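"""Synthetic-data generators: determinism, stated-world shapes, calibration
hooks."""

import numpy as np
import pytest

from genoprivacy import distance as D
from genoprivacy import gwas, simulate
from genoprivacy.variants import MISSING, read_vcf


class TestGenotypeSimulator:
    def test_default_config_is_the_competition_shape(self):
        cfg = simulate.GenotypeSimConfig()
        assert (cfg.n_case, cfg.n_control, cfg.n_sites) == (200, 200, 311)
        assert cfg.haplotype_pool_size == 174

    def test_seeded_runs_are_identical(self):
        cfg = simulate.GenotypeSimConfig(n_sites=40, missing_rate=0.05, seed=7)
        a = simulate.simulate_genotypes(cfg)
        b = simulate.simulate_genotypes(cfg)
        assert (a.dosages == b.dosages).all()
        assert a.samples == b.samples

    def test_no_missing_when_rate_zero(self):
        gm = simulate.simulate_genotypes(
            simulate.GenotypeSimConfig(n_sites=50, missing_rate=0.0, seed=1)
        )
        assert (gm.dosages != MISSING).all()

    def test_null_sites_have_matched_group_frequencies(self):
        # OR=1, no associated sites: per-site case/control allele-frequency
        # gaps stay within binomial sampling bounds (~4 sd of the null)
        gm = simulate.simulate_genotypes(
            simulate.GenotypeSimConfig(n_sites=300, seed=11)
        )
        case = gm.dosages[gm.case_mask()].astype(float)
        ctrl = gm.dosages[~gm.case_mask()].astype(float)
        p_case = case.mean(axis=0) / 2
        p_ctrl = ctrl.mean(axis=0) / 2
        pbar = (p_case + p_ctrl) / 2
        se = np.sqrt(pbar * (1 - pbar) * (1 / 400 + 1 / 400))
        z = np.abs(p_case - p_ctrl) / np.maximum(se, 1e-9)
        assert np.mean(z > 4) < 0.01

    def test_associated_sites_rank_above_null_sites(self):
        # planted OR=2.0 effects dominate the chi-square ranking across seeds
        hits = 0
        for seed in range(10):
            cfg = simulate.GenotypeSimConfig(
                n_sites=60, n_assoc_sites=6, odds_ratio=2.0, seed=seed
            )
            gm = simulate.simulate_genotypes(cfg)
            stats = gwas.site_statistics(gm, p_values=False)
            chi2 = np.array([s.chi2 if s.chi2 is not None else 0.0 for s in stats])
            assoc = [gm.sites.index(s) for s in gm.meta["assoc_sites"]]
            null_mask = np.ones(cfg.n_sites, bool)
            null_mask[assoc] = False
            if np.median(chi2[assoc]) > np.median(chi2[null_mask]):
                hits += 1
        assert hits >= 9

    def test_iid_mode_and_infeasible_config_errors(self):
        gm = simulate.simulate_genotypes(
            simulate.GenotypeSimConfig(n_sites=20, mode="iid", seed=3)
        )
        assert gm.dosages.shape == (400, 20)
        with pytest.raises(ValueError):
            simulate.GenotypeSimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            simulate.GenotypeSimConfig(n_sites=5, n_assoc_sites=6)
        with pytest.raises(ValueError):
            simulate.GenotypeSimConfig(odds_ratio=0.0)

    def test_partition_splits_groups_evenly(self):
        gm = simulate.simulate_genotypes(
            simulate.GenotypeSimConfig(n_sites=10, seed=2)
        )
        a, b = simulate.partition_genotypes(gm)
        assert a.n_case == b.n_case == 100
        assert a.n_control == b.n_control == 100
        assert sorted(a.samples + b.samples) == sorted(gm.samples)


class TestGenomePairSimulator:
    def test_sizes_exact_and_overlap_within_one_key(self):
        cfg = simulate.GenomePairSimConfig(
            n_variants_each=(1000, 900), jaccard_overlap=0.65,
            site_universe_size=100_000, seed=5,
        )
        a, b, _ = simulate.simulate_genome_pair(cfg)
        assert (len(a), len(b)) == (1000, 900)
        assert abs(len(a.keys & b.keys) - round(0.65 * 900)) <= 1

    def test_full_overlap_gives_distance_zero(self):
        cfg = simulate.GenomePairSimConfig(
            n_variants_each=(300, 300), jaccard_overlap=1.0,
            site_universe_size=30_000, seed=6,
        )
        a, b, _ = simulate.simulate_genome_pair(cfg)
        assert D.hamming_distance(a, b).value == 0

    def test_planted_intersection_gives_expected_hamming(self):
        cfg = simulate.GenomePairSimConfig(
            n_variants_each=(1000, 1000), jaccard_overlap=0.6,
            site_universe_size=100_000, seed=7,
        )
        a, b, _ = simulate.simulate_genome_pair(cfg)
        assert D.hamming_distance(a, b).value == 1000 + 1000 - 2 * 600

    def test_vcf_round_trip_preserves_distances(self, tmp_path):
        cfg = simulate.GenomePairSimConfig(
            n_variants_each=(400, 400), jaccard_overlap=0.7,
            site_universe_size=50_000, seed=8,
        )
        a, b, paths = simulate.simulate_genome_pair(cfg, out_dir=tmp_path)
        a2 = read_vcf(paths[0], owner=a.owner)
        b2 = read_vcf(paths[1], owner=b.owner)
        assert a2.keys == a.keys and b2.keys == b.keys
        assert (
            D.hamming_distance(a2, b2).value == D.hamming_distance(a, b).value
        )

    def test_seeded_vcfs_are_byte_identical(self, tmp_path):
        cfg = simulate.GenomePairSimConfig(
            n_variants_each=(100, 100), seed=9, site_universe_size=10_000
        )
        _, _, p1 = simulate.simulate_genome_pair(cfg, out_dir=tmp_path / "x")
        _, _, p2 = simulate.simulate_genome_pair(cfg, out_dir=tmp_path / "y")
        assert p1[0].read_bytes() == p2[0].read_bytes()
        assert p1[1].read_bytes() == p2[1].read_bytes()

    def test_universe_too_small_errors(self):
        with pytest.raises(ValueError, match="universe"):
            simulate.simulate_genome_pair(
                simulate.GenomePairSimConfig(
                    n_variants_each=(500, 500), jaccard_overlap=0.0,
                    site_universe_size=900, seed=1,
                )
            )


class TestSegmentPairSimulator:
    def test_default_recipe_shape(self):
        cfg = simulate.SegmentSimConfig()
        assert cfg.ref_length == 5000
        assert cfg.n_variants_per_side == (25, 50)
        assert cfg.snv_fraction == 0.9
        assert cfg.min_spacing == 5

    def test_zero_variants_gives_identical_segments(self):
        cfg = simulate.SegmentSimConfig(
            ref_length=500, n_variants_per_side=(0, 0), seed=1
        )
        pairs = simulate.simulate_segment_pairs(cfg, n_pairs=3)
        for s1, s2, va, vb in pairs:
            assert s1.sequence == s2.sequence
            assert len(va) == len(vb) == 0
            assert D.edit_distance_dp(s1, s2) == 0

    def test_recorded_sets_reconstruct_segments_exactly(self):
        from genoprivacy.variants import VariantRecord

        cfg = simulate.SegmentSimConfig(ref_length=1500, seed=4)
        pairs = simulate.simulate_segment_pairs(cfg, n_pairs=5, include_ref=True)
        for ref, s1, s2, va, vb in pairs:
            for vset, seg in ((va, s1), (vb, s2)):
                assert 25 <= len(vset) <= 50
                recs = sorted(
                    (VariantRecord(k.chrom, k.pos, k.ref, k.alt, (1, 1))
                     for k in vset.keys),
                    key=lambda r: r.pos,
                )
                rebuilt = D.reconstruct_sequence(ref, recs)
                assert rebuilt.sequence == seg.sequence
            # a position hit by both sides carries the same biallelic form
            shared_sites = {
                (k.chrom, k.pos) for k in va.keys
            } & {(k.chrom, k.pos) for k in vb.keys}
            for site in shared_sites:
                ka = {k for k in va.keys if (k.chrom, k.pos) == site}
                kb = {k for k in vb.keys if (k.chrom, k.pos) == site}
                assert ka == kb

    def test_snv_only_disjoint_positions_always_exact(self):
        cfg = simulate.SegmentSimConfig(
            ref_length=2000, snv_fraction=1.0, seed=12
        )
        pairs = simulate.simulate_segment_pairs(cfg, n_pairs=10)
        rep = D.validate_approximation(pairs)
        assert rep.exact_count == 10
        assert rep.max_deviation_pct == 0.0

    def test_default_recipe_regime_mostly_exact_small_deviations(self):
        # across 5 seeds x 20 pairs, the approximation is exact for the vast
        # majority of pairs and any deviation stays small (rare interacting
        # indels cost ~1 edit on true distances of ~60-90)
        total_exact = 0
        worst = 0.0
        for seed in range(5):
            rep = D.validate_approximation(
                simulate.simulate_segment_pairs(
                    simulate.SegmentSimConfig(seed=seed), n_pairs=20
                )
            )
            total_exact += rep.exact_count
            worst = max(worst, rep.max_deviation_pct)
        assert total_exact >= 85
        assert worst <= 6.0

    def test_determinism_and_spacing_infeasibility(self):
        cfg = simulate.SegmentSimConfig(ref_length=800, seed=5)
        p1 = simulate.simulate_segment_pairs(cfg, n_pairs=2)
        p2 = simulate.simulate_segment_pairs(cfg, n_pairs=2)
        assert [(a.sequence, b.sequence) for a, b, _, _ in p1] == [
            (a.sequence, b.sequence) for a, b, _, _ in p2
        ]
        with pytest.raises(ValueError):
            simulate.SegmentSimConfig(ref_length=200, n_variants_per_side=(40, 50))
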