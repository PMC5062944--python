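"""Two-party protocols: additive shares, pooled GWAS, PSI-CA distances."""

import collections
import random

import numpy as np
import pytest
from scipy.stats import chisquare

from genoprivacy import gwas, smc
from genoprivacy.channel import Channel
from genoprivacy.distance import hamming_distance
from genoprivacy.simulate import (
    GenomePairSimConfig,
    partition_genotypes,
    simulate_genome_pair,
)
from genoprivacy.variants import GenotypeMatrix, MISSING


def _parties_for(gm, seed=0):
    a, b = partition_genotypes(gm)
    return (
        smc.PartyState("A", genotypes=a, rng=random.Random(2 * seed + 1)),
        smc.PartyState("B", genotypes=b, rng=random.Random(2 * seed + 2)),
    )


class TestShares:
    def test_round_trip_on_random_values(self, rng):
        for _ in range(1000):
            v = rng.randrange(smc.SHARE_PRIME)
            s1, s2 = smc.share_split(v, rng=rng)
            assert smc.share_reconstruct(s1, s2) == v

    def test_zero_splits_to_complementary_shares(self, rng):
        s1, s2 = smc.share_split(0, rng=rng)
        assert (s1.value + s2.value) % smc.SHARE_PRIME == 0

    def test_field_mismatch_rejected(self, rng):
        s1, _ = smc.share_split(5, rng=rng)
        t1, _ = smc.share_split(5, p=(1 << 31) - 1, rng=rng)
        with pytest.raises(ValueError, match="field"):
            smc.share_reconstruct(s1, t1)

    def test_first_share_marginal_is_uniform(self, rng):
        # 10,000 splits of a fixed value; coarse 16-bin goodness of fit on
        # the top bits of s1 should not reject uniformity
        counts = collections.Counter()
        for _ in range(10_000):
            s1, _ = smc.share_split(12345, rng=rng)
            counts[s1.value * 16 // smc.SHARE_PRIME] += 1
        obs = [counts[i] for i in range(16)]
        assert chisquare(obs).pvalue > 1e-4


class TestSmcGwas:
    def test_toy_partition_matches_centralized_oracle(self):
        gm = GenotypeMatrix(
            ["case_1", "case_2", "ctrl_1", "ctrl_2"],
            ["s1", "s2", "s3"],
            np.array([[0, 1, 2], [2, 1, 0], [1, 0, 1], [1, 2, 0]], dtype=np.int8),
            np.array(["case", "case", "control", "control"], dtype=object),
        )
        # duplicate the cohort across parties to get 2+2 per side
        pa, pb = _parties_for(gm)
        stats, report = smc.smc_gwas(pa, pb)
        oracle = gwas.site_statistics(gm)
        assert [(s.maf, s.chi2) for s in stats] == [(o.maf, o.chi2) for o in oracle]
        assert report.comm_bytes["A"] > 0 and report.comm_bytes["B"] > 0

    def test_cohort_bit_identical_to_centralized(self, cohort_311):
        pa, pb = _parties_for(cohort_311, seed=3)
        stats, _ = smc.smc_gwas(pa, pb)
        oracle = gwas.site_statistics(cohort_311)
        assert all(
            (s.site, s.maf, s.chi2, s.p_value) == (o.site, o.maf, o.chi2, o.p_value)
            for s, o in zip(stats, oracle)
        )

    def test_one_sided_site_reduces_to_other_party(self):
        # party A all-missing at s1: pooled counts equal B's alone
        gm_a = GenotypeMatrix(
            ["case_1", "ctrl_1"], ["s1"],
            np.array([[MISSING], [MISSING]], dtype=np.int8),
            np.array(["case", "control"], dtype=object),
        )
        gm_b = GenotypeMatrix(
            ["case_2", "ctrl_2"], ["s1"],
            np.array([[2], [1]], dtype=np.int8),
            np.array(["case", "control"], dtype=object),
        )
        pa = smc.PartyState("A", genotypes=gm_a, rng=random.Random(1))
        pb = smc.PartyState("B", genotypes=gm_b, rng=random.Random(2))
        stats, _ = smc.smc_gwas(pa, pb)
        oracle_b = gwas.site_statistics(gm_b)
        assert stats[0].table == oracle_b[0].table

    def test_site_universe_mismatch_aborts_with_names(self):
        gm_a = GenotypeMatrix(
            ["case_1"], ["sX"], np.array([[1]], dtype=np.int8),
            np.array(["case"], dtype=object),
        )
        gm_b = GenotypeMatrix(
            ["ctrl_1"], ["sY"], np.array([[1]], dtype=np.int8),
            np.array(["control"], dtype=object),
        )
        pa = smc.PartyState("A", genotypes=gm_a, rng=random.Random(1))
        pb = smc.PartyState("B", genotypes=gm_b, rng=random.Random(2))
        with pytest.raises(ValueError, match="site universe"):
            smc.smc_gwas(pa, pb)

    def test_share_payloads_look_uniform(self, cohort_311):
        # byte-level entropy of share messages should be near 8 bits
        pa, pb = _parties_for(cohort_311, seed=5)
        channel = Channel()
        smc.smc_gwas(pa, pb, channel=channel)
        blob = b"".join(
            m.payload for m in channel.transcript if m.tag == "gwas-shares"
        )
        # drop the 4-byte length prefixes and the top byte of each 8-byte
        # element (61-bit field: top 3 bits always 0)
        payload = bytearray()
        for i in range(4, len(blob), 8):
            payload += blob[i + 1 : i + 8]
        counts = np.bincount(np.frombuffer(bytes(payload), dtype=np.uint8),
                             minlength=256)
        p = counts / counts.sum()
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert entropy > 7.8

    def test_transcript_bytes_reproducible_for_fixed_seeds(self, cohort_311):
        c1, c2 = Channel(), Channel()
        smc.smc_gwas(*_parties_for(cohort_311, seed=9), channel=c1)
        smc.smc_gwas(*_parties_for(cohort_311, seed=9), channel=c2)
        assert [m.payload for m in c1.transcript] == [m.payload for m in c2.transcript]
        assert c1.bytes_by_sender == c2.bytes_by_sender


def _variant_parties(set_a, set_b, seed=0):
    return (
        smc.PartyState("A", variants=set_a, rng=random.Random(2 * seed + 1)),
        smc.PartyState("B", variants=set_b, rng=random.Random(2 * seed + 2)),
    )


class TestPsiCardinality:
    def _pair(self, na, nb, overlap_keys, seed=0):
        cfg = GenomePairSimConfig(
            n_variants_each=(na, nb),
            jaccard_overlap=overlap_keys / min(na, nb),
            site_universe_size=100 * max(na, nb),
            seed=seed,
        )
        a, b, _ = simulate_genome_pair(cfg)
        return a, b

    def test_identical_sets_full_cardinality(self):
        a, b = self._pair(100, 100, 100, seed=1)
        assert a.keys == b.keys
        pa, pb = _variant_parties(a, b)
        assert smc.psi_cardinality(pa, pb, group=smc.TEST_GROUP_512) == 100

    def test_disjoint_sets_zero(self):
        a, b = self._pair(80, 80, 0, seed=2)
        pa, pb = _variant_parties(a, b)
        assert smc.psi_cardinality(pa, pb, group=smc.TEST_GROUP_512) == 0

    def test_planted_overlap_recovered_exactly(self):
        a, b = self._pair(1000, 1000, 600, seed=3)
        pa, pb = _variant_parties(a, b)
        card = smc.psi_cardinality(pa, pb, group=smc.TEST_GROUP_512)
        assert card == len(a.keys & b.keys) == 600

    def test_party_symmetry(self):
        a, b = self._pair(150, 120, 60, seed=4)
        pa, pb = _variant_parties(a, b, seed=1)
        pb2, pa2 = _variant_parties(b, a, seed=2)
        c1 = smc.psi_cardinality(pa, pb, group=smc.TEST_GROUP_512)
        c2 = smc.psi_cardinality(pb2, pa2, group=smc.TEST_GROUP_512)
        assert c1 == c2 == len(a.keys & b.keys)

    def test_every_outgoing_vector_is_shuffled(self):
        # the mandatory shuffle before each send destroys the element/key
        # correspondence; count the shuffle calls on both parties' rngs
        class CountingRandom(random.Random):
            def __init__(self, seed):
                super().__init__(seed)
                self.shuffles = 0

            def shuffle(self, x):
                self.shuffles += 1
                super().shuffle(x)

        a, b = self._pair(200, 200, 100, seed=5)
        ra, rb = CountingRandom(1), CountingRandom(2)
        pa = smc.PartyState("A", variants=a, rng=ra)
        pb = smc.PartyState("B", variants=b, rng=rb)
        smc.psi_cardinality(pa, pb, group=smc.TEST_GROUP_512)
        # each party shuffles its own singles and the counterpart's doubled
        assert ra.shuffles == 2 and rb.shuffles == 2

    def test_key_mode_mismatch_rejected(self):
        from genoprivacy.variants import VariantKey, VariantSet

        a = VariantSet("a", frozenset([VariantKey("1", 1, "A", "G", "het")]),
                       key_mode="zygosity")
        b = VariantSet("b", frozenset([VariantKey("1", 1, "A", "G", None)]),
                       key_mode="site")
        with pytest.raises(ValueError, match="key mode"):
            smc.psi_cardinality(*_variant_parties(a, b))


class TestSmcDistance:
    def test_identical_genomes_distance_zero(self):
        cfg = GenomePairSimConfig(n_variants_each=(200, 200), jaccard_overlap=1.0,
                                  site_universe_size=20_000, seed=6)
        a, b, _ = simulate_genome_pair(cfg)
        res, _ = smc.smc_distance(
            *_variant_parties(a, b), kind="hamming", group=smc.TEST_GROUP_512
        )
        assert res.value == 0

    @pytest.mark.parametrize("kind", ["hamming", "edit_approx"])
    def test_matches_plaintext_oracle(self, kind):
        cfg = GenomePairSimConfig(n_variants_each=(500, 450), jaccard_overlap=0.6,
                                  site_universe_size=50_000, seed=7)
        a, b, _ = simulate_genome_pair(cfg)
        res, report = smc.smc_distance(
            *_variant_parties(a, b), kind=kind, group=smc.TEST_GROUP_512, seed=7
        )
        assert res.value == hamming_distance(a, b).value
        assert report.comm_bytes["A"] > 0 and report.comm_bytes["B"] > 0

    def test_byte_counts_deterministic(self):
        cfg = GenomePairSimConfig(n_variants_each=(120, 120), jaccard_overlap=0.5,
                                  site_universe_size=20_000, seed=8)
        a, b, _ = simulate_genome_pair(cfg)
        _, r1 = smc.smc_distance(*_variant_parties(a, b, seed=1),
                                 group=smc.TEST_GROUP_512)
        _, r2 = smc.smc_distance(*_variant_parties(a, b, seed=1),
                                 group=smc.TEST_GROUP_512)
        assert r1.comm_bytes == r2.comm_bytes
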