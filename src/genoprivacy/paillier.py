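"""Additively homomorphic Paillier cryptosystem and the GWAS outsourcing
protocol.

The cryptosystem is the simplified g = n + 1 variant: for modulus n = p q,

    E(m; r) = (1 + m n) r^n  mod n^2,        D(c) = L(c^lambda mod n^2) mu mod n

with lambda = lcm(p-1, q-1), mu = lambda^-1 mod n, L(x) = (x-1)/n.  Products
of ciphertexts decrypt to sums of plaintexts, and c^k decrypts to k m — which
is all the GWAS aggregation needs.

In the outsourcing protocol the data owner (client) encrypts, per sample and
per site, the alternate-allele dosage and twice the non-missing indicator;
a semi-honest server holding only the public key multiplies these into four
encrypted accumulators per site (case-alt, case-total, control-alt,
control-total); the client decrypts the aggregates and finishes the MAF and
chi-square in the clear.  The server object cannot be constructed with a
private key, so the role separation holds by construction.

Security floor: 1024-bit modulus (~80-bit security).  Smaller keys require
``allow_insecure=True`` and exist only to make correctness tests fast; they
offer no security whatsoever.
"""

from __future__ import annotations

import hashlib
import math
import random
import time
from dataclasses import dataclass
from typing import Sequence

import sympy

from . import gwas
from .channel import Channel, decode_uints, encode_uints
from .metrics import MetricsReport, config_hash
from .variants import MISSING, GenotypeMatrix

__all__ = [
    "PaillierPublicKey",
    "PaillierPrivateKey",
    "Ciphertext",
    "KeySecurityError",
    "keygen",
    "rsa_homomorphism_demo",
    "RSADemoRecord",
    "GwasOutsourcingClient",
    "GwasAggregationServer",
    "outsource_gwas",
]

SECURITY_FLOOR_BITS = 1024


class KeySecurityError(ValueError):
    """Key size below the 80-bit-security floor without an explicit opt-out."""


def _random_prime(bits: int, rng: random.Random) -> int:
    """Random prime with the top two bits set (so p*q has exactly 2*bits
    bits).  sympy's isprime is Baillie-PSW + strong tests; the error rate for
    random candidates is far below 2^-80."""
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if sympy.isprime(cand):
            return cand


@dataclass(frozen=True)
class PaillierPublicKey:
    n: int
    bits: int

    @property
    def g(self) -> int:
        return self.n + 1

    @property
    def n_squared(self) -> int:
        return self.n * self.n

    @property
    def fingerprint(self) -> str:
        return hashlib.sha256(str(self.n).encode()).hexdigest()[:16]

    @property
    def ciphertext_bytes(self) -> int:
        """Serialized size of one ciphertext (an element of Z_{n^2})."""
        return (2 * self.bits + 7) // 8

    def encrypt(
        self, m: int, rng: random.Random | None = None, r: int | None = None
    ) -> "Ciphertext":
        if not 0 <= m < self.n:
            raise ValueError(f"plaintext {m} outside [0, n)")
        if r is None:
            rng = rng or random.SystemRandom()
            while True:
                r = rng.randrange(1, self.n)
                if math.gcd(r, self.n) == 1:
                    break
        n2 = self.n_squared
        c = (1 + m * self.n) % n2 * pow(r, self.n, n2) % n2
        return Ciphertext(c, self.fingerprint)

    def _check(self, *cts: "Ciphertext") -> None:
        for c in cts:
            if c.key_fp != self.fingerprint:
                raise ValueError("ciphertext was produced under a different key")

    def he_add(self, c1: "Ciphertext", c2: "Ciphertext") -> "Ciphertext":
        """Ciphertext of m1 + m2 (mod n)."""
        self._check(c1, c2)
        return Ciphertext(c1.value * c2.value % self.n_squared, self.fingerprint)

    def he_scalar_mul(self, c: "Ciphertext", k: int) -> "Ciphertext":
        """Ciphertext of k * m (mod n), k a non-negative integer."""
        self._check(c)
        if k < 0:
            raise ValueError("scalar must be non-negative")
        return Ciphertext(pow(c.value, k, self.n_squared), self.fingerprint)

    def encrypt_zero_accumulator(self) -> "Ciphertext":
        """Deterministic E(0) with unit randomness — the neutral element for
        homomorphic accumulation (not semantically hiding, never transmitted
        as data)."""
        return Ciphertext(1, self.fingerprint)


@dataclass(frozen=True)
class PaillierPrivateKey:
    public: PaillierPublicKey
    lam: int  # lcm(p-1, q-1)
    mu: int   # lam^-1 mod n

    def decrypt(self, c: "Ciphertext") -> int:
        if c.key_fp != self.public.fingerprint:
            raise ValueError("ciphertext was produced under a different key")
        n, n2 = self.public.n, self.public.n_squared
        x = pow(c.value, self.lam, n2)
        return (x - 1) // n * self.mu % n


@dataclass(frozen=True)
class Ciphertext:
    value: int
    key_fp: str

    def to_bytes(self, pk: PaillierPublicKey) -> bytes:
        return self.value.to_bytes(pk.ciphertext_bytes, "big")


def keygen(
    bits: int = SECURITY_FLOOR_BITS,
    rng: random.Random | None = None,
    allow_insecure: bool = False,
) -> tuple[PaillierPublicKey, PaillierPrivateKey]:
    """Generate a Paillier keypair with an exactly ``bits``-bit modulus.

    ``rng`` may be a seeded ``random.Random`` for reproducible test keys; the
    default draws from OS entropy.  Keys below 1024 bits raise
    :class:`KeySecurityError` unless ``allow_insecure`` is set.
    """
    if bits < SECURITY_FLOOR_BITS and not allow_insecure:
        raise KeySecurityError(
            f"{bits}-bit modulus is below the 80-bit security floor "
            f"({SECURITY_FLOOR_BITS} bits); pass allow_insecure=True only for "
            "throwaway test keys"
        )
    if bits < 16 or bits % 2:
        raise ValueError("modulus size must be an even number of bits >= 16")
    rng = rng or random.SystemRandom()
    half = bits // 2
    p = _random_prime(half, rng)
    while True:
        q = _random_prime(half, rng)
        if q != p:
            break
    n = p * q
    lam = math.lcm(p - 1, q - 1)
    pk = PaillierPublicKey(n=n, bits=bits)
    sk = PaillierPrivateKey(public=pk, lam=lam, mu=pow(lam, -1, n))
    return pk, sk


# ---------------------------------------------------------------------------
# didactic multiplicative homomorphism of unpadded ("textbook") RSA


@dataclass(frozen=True)
class RSADemoRecord:
    modulus: int
    exponent: int
    c1: int
    c2: int
    product_of_ciphertexts: int
    ciphertext_of_product: int
    identity_holds: bool
    wrapped: bool  # x1*x2 >= modulus: the identity holds only modulo m


def rsa_homomorphism_demo(
    x1: int, x2: int, bits: int = 512, seed: int | None = None
) -> RSADemoRecord:
    """Demonstrate the multiplicative homomorphism of unpadded RSA:
    E(x) = x^e mod m satisfies E(x1) E(x2) mod m = E(x1 x2).

    DIDACTIC AND INSECURE: textbook RSA is deterministic and malleable; this
    exists to show why a single-operation (partial) homomorphic scheme cannot
    also support the additions a chi-square needs.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("demo inputs must be non-negative")
    rng = random.Random(seed) if seed is not None else random.SystemRandom()
    e = 65537
    half = bits // 2
    while True:
        p = _random_prime(half, rng)
        q = _random_prime(half, rng)
        if p != q and (p - 1) % e and (q - 1) % e:
            break
    m = p * q
    c1 = pow(x1, e, m)
    c2 = pow(x2, e, m)
    lhs = c1 * c2 % m
    rhs = pow(x1 * x2, e, m)
    return RSADemoRecord(
        modulus=m,
        exponent=e,
        c1=c1,
        c2=c2,
        product_of_ciphertexts=lhs,
        ciphertext_of_product=rhs,
        identity_holds=lhs == rhs,
        wrapped=x1 * x2 >= m,
    )


# ---------------------------------------------------------------------------
# secure outsourcing of the GWAS statistics


class GwasOutsourcingClient:
    """Data owner: holds the genotype matrix and both keys; encrypts
    per-sample contributions, decrypts only aggregate counts."""

    def __init__(
        self,
        gm: GenotypeMatrix,
        pk: PaillierPublicKey,
        sk: PaillierPrivateKey,
        rng: random.Random | None = None,
    ) -> None:
        self.gm = gm
        self.pk = pk
        self.sk = sk
        self.rng = rng or random.SystemRandom()

    def send_encrypted_contributions(
        self, channel: Channel, sites: Sequence[str] | None = None
    ) -> list[str]:
        """Encrypt, per sample and per selected site, the alternate-allele
        dosage and 2x the non-missing indicator, and stream them to the
        server together with the (non-sensitive) group labels."""
        gm = self.gm
        names = list(sites) if sites is not None else list(gm.sites)
        idx = [gm.site_index(s) for s in names]
        width = self.pk.ciphertext_bytes
        header = ("\x1f".join(names) + "\x1e" + "\x1f".join(gm.labels)).encode()
        channel.send("client", "gwas-header", header)
        for i in range(len(gm.samples)):
            row = gm.dosages[i]
            cts: list[int] = []
            for j in idx:
                d = int(row[j])
                alt = 0 if d == MISSING else d
                present = 0 if d == MISSING else 2
                cts.append(self.pk.encrypt(alt, rng=self.rng).value)
                cts.append(self.pk.encrypt(present, rng=self.rng).value)
            channel.send("client", "gwas-sample", encode_uints(cts, width))
        return names

    def finish(
        self, channel: Channel, names: Sequence[str]
    ) -> list[gwas.SiteStats]:
        """Decrypt the four aggregate counts per site and compute MAF and
        chi-square in the clear (the sanctioned final step)."""
        width = self.pk.ciphertext_bytes
        payload = channel.receive("client", "gwas-aggregates").payload
        values = decode_uints(payload, width)
        if len(values) != 4 * len(names):
            raise RuntimeError("aggregate bundle has wrong arity")
        pooled = []
        for j in range(len(names)):
            ca, ct, na, nt = (
                self.sk.decrypt(Ciphertext(v, self.pk.fingerprint))
                for v in values[4 * j : 4 * j + 4]
            )
            for v in (ca, ct, na, nt):
                if v >= self.pk.n // 2:
                    raise OverflowError("aggregate count wrapped the modulus")
            pooled.append((ca, ct, na, nt))
        return gwas.stats_from_pooled_counts(names, pooled)


class GwasAggregationServer:
    """Semi-honest server: sees only the public key and ciphertexts, and sums
    contributions homomorphically.  Constructing it with anything but a bare
    public key is an architectural error."""

    def __init__(self, pk: PaillierPublicKey) -> None:
        if not isinstance(pk, PaillierPublicKey) or hasattr(pk, "lam"):
            raise TypeError(
                "the aggregation server takes a PaillierPublicKey only; "
                "it must never hold private key material"
            )
        self.pk = pk
        self.storage_bytes = 0

    def aggregate(self, channel: Channel) -> None:
        """Consume the client's stream and reply with the 4-per-site
        encrypted count bundle."""
        pk = self.pk
        width = pk.ciphertext_bytes
        header = channel.receive("server", "gwas-header").payload.decode()
        site_blob, label_blob = header.split("\x1e")
        n_sites = len(site_blob.split("\x1f"))
        labels = label_blob.split("\x1f")
        acc = [pk.encrypt_zero_accumulator() for _ in range(4 * n_sites)]
        for lab in labels:
            payload = channel.receive("server", "gwas-sample").payload
            self.storage_bytes += len(payload)
            cts = decode_uints(payload, width)
            if len(cts) != 2 * n_sites:
                raise RuntimeError("sample message has wrong arity")
            off = 0 if lab == "case" else 2
            for j in range(n_sites):
                alt = Ciphertext(cts[2 * j], pk.fingerprint)
                present = Ciphertext(cts[2 * j + 1], pk.fingerprint)
                acc[4 * j + off] = pk.he_add(acc[4 * j + off], alt)
                acc[4 * j + off + 1] = pk.he_add(acc[4 * j + off + 1], present)
        channel.send(
            "server", "gwas-aggregates", encode_uints([c.value for c in acc], width)
        )


def outsource_gwas(
    gm: GenotypeMatrix,
    pk: PaillierPublicKey,
    sk: PaillierPrivateKey,
    sites: Sequence[str] | None = None,
    rng: random.Random | None = None,
    seed: int | None = None,
) -> tuple[list[gwas.SiteStats], MetricsReport]:
    """Run the full outsourcing round trip on one machine and report the
    competition metrics.  The returned statistics are exactly those of the
    plaintext pipeline on the same matrix."""
    if rng is None and seed is not None:
        rng = random.Random(seed)
    channel = Channel()
    client = GwasOutsourcingClient(gm, pk, sk, rng=rng)
    server = GwasAggregationServer(pk)

    t0 = time.perf_counter()
    names = client.send_encrypted_contributions(channel, sites)
    t_enc = time.perf_counter()
    server.aggregate(channel)
    t_comp = time.perf_counter()
    stats = client.finish(channel, names)
    t_dec = time.perf_counter()

    report = MetricsReport(
        task="gwas_he",
        accuracy={"exact_match": None, "max_abs_deviation": None, "compared": len(names)},
        security_bits=80 if pk.bits >= SECURITY_FLOOR_BITS else 0,
        time_s={
            "encrypt": t_enc - t0,
            "compute": t_comp - t_enc,
            "decrypt": t_dec - t_comp,
        },
        storage_bytes=server.storage_bytes,
        comm_bytes=dict(channel.bytes_by_sender),
        seed=seed,
        config=config_hash(
            {"bits": pk.bits, "sites": len(names), "samples": len(gm.samples)}
        ),
    )
    return stats, report
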