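"""Two-party semi-honest protocols over a byte-counting channel.

Two institutions that cannot exchange raw data jointly compute:

* pooled GWAS statistics on horizontally partitioned case/control cohorts,
  via additive secret sharing of per-site integer allele counts over a prime
  field (every message except the final pooled aggregates is a uniform field
  element); and
* the variant-set Hamming distance / set-difference edit-distance
  approximation across two genomes, via Diffie-Hellman private set
  intersection cardinality (PSI-CA): each party hashes its variant keys into
  the quadratic-residue subgroup of a safe-prime group, exponentiates with a
  secret, and the counterpart re-exponentiates and shuffles, so that equal
  double-exponentiated elements correspond to equal keys while only the set
  sizes and the intersection cardinality are revealed.

The default group is the 2048-bit RFC 3526 MODP group (a safe prime), which
comfortably clears the 80-bit security floor; secrets are 160-bit short
exponents (standard at this level).  ``TEST_GROUP_512`` is a fixed 512-bit
safe prime for fast correctness tests only — it is NOT secure.
"""

from __future__ import annotations

import hashlib
import random
import time
from dataclasses import dataclass, field
from typing import Sequence

from . import gwas
from .channel import Channel, decode_uints, encode_uints
from .distance import DistanceResult
from .metrics import MetricsReport, config_hash
from .variants import GenotypeMatrix, VariantSet

__all__ = [
    "SHARE_PRIME",
    "DHGroup",
    "RFC3526_GROUP_2048",
    "TEST_GROUP_512",
    "Share",
    "PartyState",
    "share_split",
    "share_reconstruct",
    "smc_gwas",
    "psi_cardinality",
    "smc_distance",
]

#: 61-bit Mersenne prime field for additive shares; allele counts of a
#: 200+200 cohort never exceed 1600, so overflow is unreachable.
SHARE_PRIME: int = (1 << 61) - 1
_SHARE_WIDTH = 8  # bytes per field element on the wire


@dataclass(frozen=True)
class DHGroup:
    """Safe-prime group for PSI-CA; elements live in the order-q subgroup of
    quadratic residues, q = (p-1)/2 prime."""

    name: str
    p: int
    secure: bool

    @property
    def q(self) -> int:
        return (self.p - 1) // 2

    @property
    def element_bytes(self) -> int:
        return (self.p.bit_length() + 7) // 8


# RFC 3526 group 14 (2048-bit MODP); p and (p-1)/2 are both prime.
RFC3526_GROUP_2048 = DHGroup(
    name="rfc3526-2048",
    p=int(
        "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
        "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
        "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
        "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
        "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
        "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
        "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
        "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
        16,
    ),
    secure=True,
)

# Fixed 512-bit safe prime — INSECURE, for fast correctness tests only.
TEST_GROUP_512 = DHGroup(
    name="test-512-insecure",
    p=int(
        "8fe80b490de2d390a0c1285d204de4c616be00a4d1c69fb9eddbfeff68782d6b"
        "d5d898affa73caecdc6e2747a415650f186ab4e2d3b606d0bc71211d751a557b",
        16,
    ),
    secure=False,
)

_EXPONENT_BITS = 160  # short exponents: ~80-bit DL security in these groups


@dataclass(frozen=True)
class Share:
    """One additive share of a value in Z_p."""

    value: int
    prime: int
    owner: str

    def __post_init__(self) -> None:
        if not 0 <= self.value < self.prime:
            raise ValueError("share outside the field")


@dataclass
class PartyState:
    """One institution's private state.  Local data never crosses the channel
    in plaintext — only shares, group elements, and agreed aggregates do."""

    party: str
    genotypes: GenotypeMatrix | None = None
    variants: VariantSet | None = None
    rng: random.Random = field(default_factory=random.SystemRandom)


def share_split(
    v: int, p: int = SHARE_PRIME, rng: random.Random | None = None
) -> tuple[Share, Share]:
    """Split v into two additive shares (s1 uniform, s2 = v - s1 mod p)."""
    if not 0 <= v < p:
        raise ValueError(f"value {v} outside Z_{p}")
    rng = rng or random.SystemRandom()
    s1 = rng.randrange(p)
    return Share(s1, p, "first"), Share((v - s1) % p, p, "second")


def share_reconstruct(s1: Share, s2: Share) -> int:
    if s1.prime != s2.prime:
        raise ValueError("shares from different fields cannot be combined")
    return (s1.value + s2.value) % s1.prime


def _local_counts(gm: GenotypeMatrix, names: Sequence[str]) -> list[int]:
    """Flattened per-site (case_alt, case_total, ctrl_alt, ctrl_total)."""
    flat: list[int] = []
    for name in names:
        flat.extend(gwas.raw_allele_counts(gm, gm.site_index(name)))
    return flat


def smc_gwas(
    party_a: PartyState,
    party_b: PartyState,
    sites: Sequence[str] | None = None,
    channel: Channel | None = None,
    seed: int | None = None,
) -> tuple[list[gwas.SiteStats], MetricsReport]:
    """Pooled MAF and chi-square over a horizontally partitioned cohort.

    Each party computes local integer allele counts per site, the counts are
    exchanged as additive shares, and only the pooled per-site sums are
    reconstructed (the sanctioned disclosure boundary); both parties then
    derive identical statistics, equal to the centralized pipeline on the
    concatenated matrix.  Party A sends first; serialization is fixed, so
    transcripts are reproducible.
    """
    if party_a.genotypes is None or party_b.genotypes is None:
        raise ValueError("both parties need a genotype partition")
    gm_a, gm_b = party_a.genotypes, party_b.genotypes
    if sites is None:
        if gm_a.sites != gm_b.sites:
            only_a = set(gm_a.sites) ^ set(gm_b.sites)
            raise ValueError(
                f"site universe mismatch between parties: {sorted(only_a)[:5]} ..."
            )
        names = list(gm_a.sites)
    else:
        names = list(sites)

    channel = channel if channel is not None else Channel()
    t0 = time.perf_counter()

    counts_a = _local_counts(gm_a, names)
    counts_b = _local_counts(gm_b, names)

    # A splits each local count; keeps s1, sends s2.  B mirrors.
    keep_a, send_a = zip(*(share_split(v, rng=party_a.rng) for v in counts_a))
    channel.send("A", "gwas-shares", encode_uints([s.value for s in send_a], _SHARE_WIDTH))
    keep_b, send_b = zip(*(share_split(v, rng=party_b.rng) for v in counts_b))
    channel.send("B", "gwas-shares", encode_uints([s.value for s in send_b], _SHARE_WIDTH))

    recv_b = decode_uints(channel.receive("B", "gwas-shares").payload, _SHARE_WIDTH)
    recv_a = decode_uints(channel.receive("A", "gwas-shares").payload, _SHARE_WIDTH)

    # each party sums its two share vectors; exchanging the sums reveals only
    # the pooled aggregates
    sum_a = [(k.value + r) % SHARE_PRIME for k, r in zip(keep_a, recv_a)]
    sum_b = [(k.value + r) % SHARE_PRIME for k, r in zip(keep_b, recv_b)]
    channel.send("A", "gwas-aggregate-share", encode_uints(sum_a, _SHARE_WIDTH))
    channel.send("B", "gwas-aggregate-share", encode_uints(sum_b, _SHARE_WIDTH))
    agg_at_b = decode_uints(channel.receive("B", "gwas-aggregate-share").payload, _SHARE_WIDTH)
    agg_at_a = decode_uints(channel.receive("A", "gwas-aggregate-share").payload, _SHARE_WIDTH)

    pooled_a = [(x + y) % SHARE_PRIME for x, y in zip(sum_a, agg_at_a)]
    pooled_b = [(x + y) % SHARE_PRIME for x, y in zip(sum_b, agg_at_b)]
    assert pooled_a == pooled_b  # both parties reconstruct the same sums

    pooled = [tuple(pooled_a[4 * j : 4 * j + 4]) for j in range(len(names))]
    stats = gwas.stats_from_pooled_counts(names, pooled)
    t1 = time.perf_counter()

    report = MetricsReport(
        task="gwas_smc",
        accuracy={"exact_match": None, "max_abs_deviation": None, "compared": len(names)},
        security_bits=80,
        time_s={"total": t1 - t0},
        storage_bytes=_SHARE_WIDTH * 4 * len(names) * 2,
        comm_bytes=dict(channel.bytes_by_sender),
        seed=seed,
        config=config_hash({"sites": len(names), "n_a": len(gm_a.samples),
                            "n_b": len(gm_b.samples)}),
    )
    return stats, report


# ---------------------------------------------------------------------------
# PSI cardinality and distances


def _hash_to_group(key_bytes: bytes, group: DHGroup) -> int:
    """SHA-256 (counter-mode expanded to the modulus width) mapped into the
    quadratic-residue subgroup by squaring."""
    n_blocks = (group.p.bit_length() + 255) // 256
    blob = b"".join(
        hashlib.sha256(i.to_bytes(2, "big") + key_bytes).digest()
        for i in range(n_blocks)
    )
    e = int.from_bytes(blob, "big") % group.p
    if e < 2:
        e += 2
    return pow(e, 2, group.p)


def _secret_exponent(rng: random.Random) -> int:
    return rng.randrange(1 << (_EXPONENT_BITS - 1), 1 << _EXPONENT_BITS)


def psi_cardinality(
    party_a: PartyState,
    party_b: PartyState,
    channel: Channel | None = None,
    group: DHGroup = RFC3526_GROUP_2048,
) -> int:
    """Exact |A ∩ B| of the two parties' variant-key sets, revealing only the
    set sizes and the cardinality (semi-honest model).

    DH double exponentiation: A sends {H(k)^a}, B sends {H(k)^b}; each side
    re-exponentiates the other's elements and returns them SHUFFLED, so the
    correspondence between returned elements and the sender's key order is
    destroyed.  Equal double-exponentiated values <=> equal keys (the hash is
    collision-resistant; a residual collision is detected and reported).
    """
    if party_a.variants is None or party_b.variants is None:
        raise ValueError("both parties need a variant set")
    sa, sb = party_a.variants, party_b.variants
    if sa.key_mode != sb.key_mode:
        raise ValueError("variant sets use different key modes")
    channel = channel if channel is not None else Channel()
    width = group.element_bytes

    hashed_a = [_hash_to_group(k.encode(), group) for k in sa.keys]
    hashed_b = [_hash_to_group(k.encode(), group) for k in sb.keys]
    if len(set(hashed_a)) != len(hashed_a) or len(set(hashed_b)) != len(hashed_b):
        raise RuntimeError("hash collision among variant keys (negligible; re-key)")

    exp_a = _secret_exponent(party_a.rng)
    exp_b = _secret_exponent(party_b.rng)

    singles_a = [pow(h, exp_a, group.p) for h in hashed_a]
    party_a.rng.shuffle(singles_a)
    channel.send("A", "psi-singles", encode_uints(singles_a, width))
    singles_b = [pow(h, exp_b, group.p) for h in hashed_b]
    party_b.rng.shuffle(singles_b)
    channel.send("B", "psi-singles", encode_uints(singles_b, width))

    got_a = decode_uints(channel.receive("B", "psi-singles").payload, width)
    doubled_a = [pow(v, exp_b, group.p) for v in got_a]  # {H(k)^(ab): k in A}
    party_b.rng.shuffle(doubled_a)
    channel.send("B", "psi-doubled", encode_uints(doubled_a, width))

    got_b = decode_uints(channel.receive("A", "psi-singles").payload, width)
    doubled_b = [pow(v, exp_a, group.p) for v in got_b]  # {H(k)^(ab): k in B}
    party_a.rng.shuffle(doubled_b)
    channel.send("A", "psi-doubled", encode_uints(doubled_b, width))

    # A: own keys doubled (received) vs B's keys doubled (computed locally)
    own_a = set(decode_uints(channel.receive("A", "psi-doubled").payload, width))
    card_a = len(own_a & set(doubled_b))
    own_b = set(decode_uints(channel.receive("B", "psi-doubled").payload, width))
    card_b = len(own_b & set(doubled_a))
    assert card_a == card_b  # same multiset intersection seen from both ends
    return card_a


def smc_distance(
    party_a: PartyState,
    party_b: PartyState,
    kind: str = "hamming",
    channel: Channel | None = None,
    group: DHGroup = RFC3526_GROUP_2048,
    seed: int | None = None,
) -> tuple[DistanceResult, MetricsReport]:
    """Cross-institution Hamming / approximate edit distance: PSI-CA for the
    intersection size, then |a| + |b| - 2 |a ∩ b| computed locally by each
    party (set sizes are exchanged in the clear, as agreed outputs)."""
    if kind not in ("hamming", "edit_approx"):
        raise ValueError(f"unknown distance kind {kind!r}")
    sa, sb = party_a.variants, party_b.variants
    if sa is None or sb is None:
        raise ValueError("both parties need a variant set")
    channel = channel if channel is not None else Channel()
    t0 = time.perf_counter()
    channel.send("A", "set-size", len(sa).to_bytes(8, "big"))
    channel.send("B", "set-size", len(sb).to_bytes(8, "big"))
    size_b = int.from_bytes(channel.receive("A", "set-size").payload, "big")
    size_a = int.from_bytes(channel.receive("B", "set-size").payload, "big")
    inter = psi_cardinality(party_a, party_b, channel=channel, group=group)
    value = size_a + size_b - 2 * inter
    t1 = time.perf_counter()
    result = DistanceResult(
        kind=kind,
        value=value,
        inputs=(sa.owner, sb.owner),
        method=f"psi-ca/{group.name}",
    )
    report = MetricsReport(
        task=f"dist_{kind}_smc",
        accuracy={"exact_match": None, "max_abs_deviation": None, "compared": 1},
        security_bits=80 if group.secure else 0,
        time_s={"total": t1 - t0},
        storage_bytes=group.element_bytes * 2 * (len(sa) + len(sb)),
        comm_bytes=dict(channel.bytes_by_sender),
        seed=seed,
        config=config_hash({"kind": kind, "group": group.name,
                            "n_a": len(sa), "n_b": len(sb)}),
    )
    return result, report
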