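"""Synthetic benchmark inputs at desk scale.

Three generators emulate the structure of the competition datasets:

* :func:`simulate_genotypes` — a 200-case / 200-control cohort over a few
  hundred SNP sites.  Individuals draw haplotype pairs from a finite pool of
  simulated haplotypes (default 174 founders, so 348 haplotypes), mirroring
  a cohort simulated from a haplotype panel; truly associated sites shift the
  case allele frequency to a chosen odds ratio.  At null sites cases and
  controls are sampled identically from the same pool, so the allelic
  chi-square is calibrated under the null by construction.
* :func:`simulate_genome_pair` — two whole-genome variation sets with a
  controlled shared-key fraction, emitted as single-sample VCFs, standing in
  for a pair of personal genomes at reduced scale.
* :func:`simulate_segment_pairs` — pairs of ~5000-nt segments derived from a
  common reference, for validating the set-difference approximation against
  the exact DP distance.  Every reference position carries ONE predetermined
  variant form (emulating biallelic polymorphic sites), shared by the two
  sides of a pair, so a position hit by both sides yields the same key and
  cancels in the symmetric difference exactly as it cancels in the true edit
  distance; deviations arise only from rare interacting indels.

No LD structure, recombination, or demography is modelled — these are
benchmark inputs, not population-genetic simulations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .distance import Segment, reconstruct_sequence
from .variants import (
    KEY_MODE_SITE,
    KEY_MODE_ZYGOSITY,
    MISSING,
    GenotypeMatrix,
    VariantKey,
    VariantRecord,
    VariantSet,
    write_vcf,
)

__all__ = [
    "GenotypeSimConfig",
    "GenomePairSimConfig",
    "SegmentSimConfig",
    "simulate_genotypes",
    "partition_genotypes",
    "simulate_genome_pair",
    "simulate_segment_pairs",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# case/control genotype matrices


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Cohort emulation: 200+200 individuals, 311 sites, haplotype pool of
    174 founders by default — the competition's training-cohort shape."""

    n_case: int = 200
    n_control: int = 200
    n_sites: int = 311
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_assoc_sites: int = 0
    odds_ratio: float = 1.0
    missing_rate: float = 0.0
    haplotype_pool_size: int = 174
    mode: str = "pool"  # "pool" | "iid"
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_assoc_sites > self.n_sites:
            raise ValueError("n_assoc_sites exceeds n_sites")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if self.mode not in ("pool", "iid"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _case_frequency(p: float, odds_ratio: float) -> float:
    """Allele frequency giving the requested allelic odds ratio vs p."""
    odds = odds_ratio * p / (1.0 - p)
    pc = odds / (1.0 + odds)
    if not pc < 1.0:
        raise ValueError(f"odds ratio {odds_ratio} pushes frequency past 1")
    return pc


def simulate_genotypes(cfg: GenotypeSimConfig) -> GenotypeMatrix:
    """Simulate a labelled dosage matrix; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_control
    p_site = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_sites)
    assoc = rng.choice(cfg.n_sites, size=cfg.n_assoc_sites, replace=False)

    if cfg.mode == "pool":
        n_hap = 2 * cfg.haplotype_pool_size
        pool = (rng.random((n_hap, cfg.n_sites)) < p_site).astype(np.int8)
        picks = rng.integers(0, n_hap, size=(n, 2))
        dos = (pool[picks[:, 0]] + pool[picks[:, 1]]).astype(np.int8)
    else:
        dos = rng.binomial(2, p_site, size=(n, cfg.n_sites)).astype(np.int8)

    if cfg.n_assoc_sites:
        p_case = np.array([_case_frequency(p_site[j], cfg.odds_ratio) for j in assoc])
        dos[: cfg.n_case, assoc] = rng.binomial(
            2, p_case, size=(cfg.n_case, cfg.n_assoc_sites)
        ).astype(np.int8)

    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = MISSING

    samples = [f"case_{i+1:04d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i+1:04d}" for i in range(cfg.n_control)
    ]
    labels = np.array(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, dtype=object
    )
    sites = [f"site_{j+1:05d}" for j in range(cfg.n_sites)]
    meta = {
        "generator": "simulate_genotypes",
        "seed": cfg.seed,
        "mode": cfg.mode,
        "odds_ratio": cfg.odds_ratio,
        "assoc_sites": [sites[j] for j in sorted(int(j) for j in assoc)],
    }
    return GenotypeMatrix(samples, sites, dos, labels, meta=meta)


def partition_genotypes(
    gm: GenotypeMatrix, seed: int | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Horizontally partition a cohort into two institutions, half the cases
    and half the controls each (shuffled if a seed is given) — the two-party
    collaboration setting."""
    case_idx = np.flatnonzero(gm.case_mask())
    ctrl_idx = np.flatnonzero(~gm.case_mask())
    if seed is not None:
        r = np.random.default_rng(seed)
        case_idx = r.permutation(case_idx)
        ctrl_idx = r.permutation(ctrl_idx)
    half_a = np.concatenate([case_idx[: len(case_idx) // 2], ctrl_idx[: len(ctrl_idx) // 2]])
    mask_a = np.zeros(len(gm.samples), dtype=bool)
    mask_a[half_a] = True
    return gm.subset_samples(mask_a), gm.subset_samples(~mask_a)


# ---------------------------------------------------------------------------
# paired whole-genome variation sets


@dataclass(frozen=True)
class GenomePairSimConfig:
    """Two personal genomes at reduced scale.  Defaults give 5000-key sets
    with 70 % of the smaller set shared — the spirit of two PGP genomes whose
    variant sets overlap heavily, subsampled to the competition's 5K input
    size."""

    n_variants_each: tuple[int, int] = (5000, 5000)
    jaccard_overlap: float = 0.7  # shared fraction of the smaller set
    site_universe_size: int = 1_000_000
    indel_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.jaccard_overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")


def _random_key(pos: int, rng: random.Random, indel_fraction: float) -> VariantKey:
    ref = rng.choice(_BASES)
    if rng.random() < indel_fraction:
        if rng.random() < 0.5:  # deletion: 2-bp ref anchored at pos
            return VariantKey("1", pos, ref + rng.choice(_BASES), ref,
                              rng.choice(("het", "hom")))
        return VariantKey("1", pos, ref, ref + rng.choice(_BASES),
                          rng.choice(("het", "hom")))
    alt = rng.choice([b for b in _BASES if b != ref])
    return VariantKey("1", pos, ref, alt, rng.choice(("het", "hom")))


def _key_to_record(k: VariantKey) -> VariantRecord:
    gt = (1, 1) if k.zygosity == "hom" else (0, 1)
    return VariantRecord(k.chrom, k.pos, k.ref, k.alt, gt)


def simulate_genome_pair(
    cfg: GenomePairSimConfig, out_dir: str | Path | None = None
) -> tuple[VariantSet, VariantSet, tuple[Path, Path] | None]:
    """Shared-core-plus-private construction: target sizes are hit exactly
    and the shared-key count equals round(overlap * min sizes).  Optionally
    writes the two single-sample VCFs."""
    na, nb = cfg.n_variants_each
    n_shared = round(cfg.jaccard_overlap * min(na, nb))
    n_total = na + nb - n_shared
    if n_total > cfg.site_universe_size:
        raise ValueError(
            f"site universe of {cfg.site_universe_size} too small for "
            f"{n_total} distinct variants"
        )
    rng = random.Random(cfg.seed)
    positions = rng.sample(range(1, cfg.site_universe_size + 1), n_total)
    keys = [_random_key(p, rng, cfg.indel_fraction) for p in positions]
    shared = keys[:n_shared]
    priv_a = keys[n_shared : n_shared + (na - n_shared)]
    priv_b = keys[n_shared + (na - n_shared) :]
    set_a = VariantSet(
        "genomeA", frozenset(shared + priv_a), KEY_MODE_ZYGOSITY,
        source=f"simulated(seed={cfg.seed})",
    )
    set_b = VariantSet(
        "genomeB", frozenset(shared + priv_b), KEY_MODE_ZYGOSITY,
        source=f"simulated(seed={cfg.seed})",
    )
    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pa = write_vcf([_key_to_record(k) for k in set_a.keys],
                       out_dir / "genomeA.vcf", sample="genomeA")
        pb = write_vcf([_key_to_record(k) for k in set_b.keys],
                       out_dir / "genomeB.vcf", sample="genomeB")
        paths = (pa, pb)
    return set_a, set_b, paths


# ---------------------------------------------------------------------------
# segment pairs for the approximation validation


@dataclass(frozen=True)
class SegmentSimConfig:
    """~5000-nt segment pairs carrying tens of variants each: 25-50 variants
    per side, 90 % SNVs / 10 % single-base indels, minimum spacing 5."""

    ref_length: int = 5000
    n_variants_per_side: tuple[int, int] = (25, 50)
    snv_fraction: float = 0.9
    indel_length_range: tuple[int, int] = (1, 1)
    min_spacing: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if not 0.0 <= self.snv_fraction <= 1.0:
            raise ValueError("snv_fraction must be in [0, 1]")
        max_var = self.n_variants_per_side[1]
        worst = max_var * (self.min_spacing + self.indel_length_range[1])
        if self.ref_length <= worst:
            raise ValueError(
                f"ref_length {self.ref_length} cannot fit {max_var} variants "
                f"at spacing {self.min_spacing}"
            )


def _spaced_positions(
    rng: random.Random, n: int, lo: int, hi: int, spacing: int
) -> list[int]:
    """n sorted positions in [lo, hi], pairwise gaps >= spacing (uniform via
    the subtract-the-gaps transform)."""
    span = hi - lo - (n - 1) * spacing
    if span < n:
        raise ValueError("spacing infeasible for requested variant count")
    raw = sorted(rng.sample(range(span), n))
    return [lo + r + i * spacing for i, r in enumerate(raw)]


def _site_variant_spec(
    ref_seq: str, pos: int, pair_tag: str, cfg: SegmentSimConfig
) -> tuple[str, str]:
    """The (ref_allele, alt_allele) carried at one reference position —
    deterministic per (pair, position), shared by both sides, emulating a
    biallelic polymorphic site."""
    r = random.Random(f"{pair_tag}:{pos}")
    base = ref_seq[pos - 1]
    if r.random() < cfg.snv_fraction:
        return base, r.choice([b for b in _BASES if b != base])
    length = r.randint(*cfg.indel_length_range)
    ins = "".join(r.choice(_BASES) for _ in range(length))
    if r.random() < 0.5:  # insertion after the anchor base
        return base, base + ins
    # deletion of `length` bases after the anchor
    return ref_seq[pos - 1 : pos + length], base


def simulate_segment_pairs(
    cfg: SegmentSimConfig, n_pairs: int = 20, include_ref: bool = False
) -> list[tuple]:
    """Generate segment pairs with exactly-recorded variant sets.

    Each pair derives from one random reference; each side independently
    draws its variant positions (spacing enforced within a side), then
    applies the per-position variant spec.  The recorded variant sets
    reconstruct the emitted segments exactly.

    Returns ``(seg_a, seg_b, set_a, set_b)`` tuples, prefixed with the
    shared reference segment when ``include_ref`` is set.
    """
    rng = random.Random(cfg.seed)
    max_del = cfg.indel_length_range[1]
    pairs = []
    for i in range(n_pairs):
        ref_seq = "".join(rng.choice(_BASES) for _ in range(cfg.ref_length))
        ref = Segment(id=f"pair{i:02d}_ref", sequence=ref_seq)
        pair_tag = f"{cfg.seed}:{i}"
        sides = []
        for side in ("a", "b"):
            n_var = rng.randint(*cfg.n_variants_per_side)
            positions = _spaced_positions(
                rng, n_var, 1, cfg.ref_length - max_del, cfg.min_spacing + max_del
            )
            records = []
            for pos in positions:
                ra, aa = _site_variant_spec(ref_seq, pos, pair_tag, cfg)
                records.append(VariantRecord("seg", pos, ra, aa, genotype=(1, 1)))
            seg = reconstruct_sequence(ref, records, seg_id=f"pair{i:02d}_{side}")
            vset = VariantSet(
                owner=seg.id,
                keys=frozenset(r.key(KEY_MODE_SITE) for r in records),
                key_mode=KEY_MODE_SITE,
                source=f"simulated(pair={i},side={side},seed={cfg.seed})",
            )
            sides.append((seg, vset))
        (seg_a, set_a), (seg_b, set_b) = sides
        if include_ref:
            pairs.append((ref, seg_a, seg_b, set_a, set_b))
        else:
            pairs.append((seg_a, seg_b, set_a, set_b))
    return pairs
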