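"""Variant and genotype data model.

A genome is represented by its differences from the reference (VCF), reduced
to a set of hashable :class:`VariantKey` tuples — the substrate for the
Hamming distance and the set-difference approximation of edit distance.
Case/control cohorts are represented by a :class:`GenotypeMatrix` of allele
dosages in {0, 1, 2} with per-sample labels — the substrate for the
association statistics.

Conventions fixed here and relied on everywhere else:

* coordinates are VCF-native: 1-based, inclusive, no conversion anywhere;
* alleles are uppercased on ingest, but indels are NOT left-aligned or
  trimmed — keys compare representations byte-for-byte;
* only records whose FILTER is PASS or "." are retained;
* the default key mode is zygosity-aware: a heterozygous and a
  homozygous-alternate call at the same site are different keys, because a
  genotype difference at a shared site is a genomic difference.  Site-only
  keys are available for sensitivity analysis.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "KEY_MODE_ZYGOSITY",
    "KEY_MODE_SITE",
    "VariantRecord",
    "VariantKey",
    "VariantSet",
    "GenotypeMatrix",
    "VCFError",
    "read_vcf",
    "write_vcf",
    "select_sites",
    "select_paired_sites",
    "read_genotype_matrix",
    "write_genotype_matrix",
]

#: sentinel dosage for a missing genotype call
MISSING: int = -1

KEY_MODE_ZYGOSITY = "zygosity"
KEY_MODE_SITE = "site"

_BASES = frozenset("ACGT")


class VCFError(ValueError):
    """Raised for unreadable, empty, or malformed VCF input."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant call: a (chrom, pos, ref, alt) difference plus the diploid
    genotype carrying it.  ``genotype`` holds allele indices, e.g. (0, 1) for
    a heterozygous call of the first alternate allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        ref = self.ref.upper()
        alt = self.alt.upper()
        if not ref or not alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if not set(ref) <= _BASES or not set(alt) <= _BASES:
            raise ValueError(f"alleles must be over ACGT: {ref!r}/{alt!r}")
        if ref == alt:
            raise ValueError(f"ref == alt ({ref!r}) is not a variant")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    @property
    def zygosity(self) -> str | None:
        """"hom" if both alleles are alternate, "het" otherwise; None if the
        genotype is unknown."""
        if self.genotype is None:
            return None
        a, b = self.genotype
        return "hom" if (a != 0 and b != 0) else "het"

    def key(self, key_mode: str = KEY_MODE_ZYGOSITY) -> "VariantKey":
        if key_mode == KEY_MODE_ZYGOSITY:
            if self.genotype is None:
                raise ValueError(
                    "zygosity-aware key requested but record has no genotype"
                )
            return VariantKey(self.chrom, self.pos, self.ref, self.alt, self.zygosity)
        if key_mode == KEY_MODE_SITE:
            return VariantKey(self.chrom, self.pos, self.ref, self.alt, None)
        raise ValueError(f"unknown key_mode {key_mode!r}")


@dataclass(frozen=True)
class VariantKey:
    """Canonical hashable identity of a variant; equality is exact tuple
    equality (no normalization beyond uppercasing)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str | None = None

    def as_tuple(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.zygosity)

    def encode(self) -> bytes:
        """Stable byte encoding used for hashing into cryptographic groups."""
        z = self.zygosity or "-"
        return f"{self.chrom}\x1f{self.pos}\x1f{self.ref}\x1f{self.alt}\x1f{z}".encode()


@dataclass(frozen=True)
class VariantSet:
    """One genome's variation set: distinct keys plus provenance."""

    owner: str
    keys: frozenset[VariantKey]
    key_mode: str = KEY_MODE_ZYGOSITY
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.keys, frozenset):
            object.__setattr__(self, "keys", frozenset(self.keys))

    def __len__(self) -> int:
        return len(self.keys)

    def sites(self) -> frozenset[tuple[str, int]]:
        """Distinct (chrom, pos) coordinates covered by this set."""
        return frozenset((k.chrom, k.pos) for k in self.keys)


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    s = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if s.isdigit():
        return (0, int(s))
    if isinstance(s, str) and s:
        return (1, s)
    raise VCFError(f"unsortable chromosome label {chrom!r}")


def read_vcf(
    path: str | Path, key_mode: str = KEY_MODE_ZYGOSITY, owner: str | None = None
) -> VariantSet:
    """Read a single-sample VCF into a :class:`VariantSet`.

    Multi-allelic records are split into one key per alternate allele (in
    zygosity mode, per alternate allele actually carried by the genotype).
    Records failing FILTER are dropped; FILTER of PASS or "." is retained.
    """
    from cyvcf2 import VCF  # deferred: import cost, and htslib stderr noise

    path = Path(path)
    if not path.exists():
        raise VCFError(f"no such VCF: {path}")
    if path.stat().st_size == 0:
        raise VCFError(f"empty VCF file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError on garbage input
        raise VCFError(f"cannot parse VCF {path}: {exc}") from exc

    keys: set[VariantKey] = set()
    line_no = 0
    try:
        for v in vcf:
            line_no += 1
            if v.FILTER is not None:  # None <=> PASS or "."
                continue
            alts = [a.upper() for a in (v.ALT or [])]
            ref = v.REF.upper()
            gt: tuple[int, int] | None = None
            if len(v.genotypes) >= 1:
                g = v.genotypes[0]
                if len(g) >= 2 and g[0] >= 0 and g[1] >= 0:
                    gt = (int(g[0]), int(g[1]))
            for j, alt in enumerate(alts, start=1):
                if not alt or not set(alt) <= _BASES:
                    continue  # symbolic / spanning-deletion alleles
                if key_mode == KEY_MODE_ZYGOSITY:
                    if gt is None:
                        raise VCFError(
                            f"{path} record {line_no}: zygosity-aware keys "
                            "require a GT field"
                        )
                    carried = (gt[0] == j) + (gt[1] == j)
                    if carried == 0:
                        continue
                    zyg = "hom" if carried == 2 else "het"
                    keys.add(VariantKey(v.CHROM, v.POS, ref, alt, zyg))
                else:
                    keys.add(VariantKey(v.CHROM, v.POS, ref, alt, None))
    except VCFError:
        raise
    except Exception as exc:
        raise VCFError(f"malformed VCF {path} near record {line_no + 1}: {exc}") from exc
    finally:
        vcf.close()

    return VariantSet(
        owner=owner or path.stem, keys=frozenset(keys), key_mode=key_mode,
        source=str(path),
    )


def write_vcf(
    records: Sequence[VariantRecord], path: str | Path, sample: str = "SAMPLE"
) -> Path:
    """Write records as a minimal single-sample VCF 4.2 file.

    Records are sorted by (chrom, pos); the GT field reflects each record's
    genotype (``1/1`` when absent).  Round-trips through :func:`read_vcf`.
    """
    path = Path(path)
    recs = sorted(records, key=lambda r: (_chrom_sort_key(r.chrom), r.pos))
    chroms: list[str] = []
    for r in recs:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=genoprivacy\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in recs:
            gt = "/".join(map(str, r.genotype)) if r.genotype is not None else "1/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )
    return path


def select_sites(vs: VariantSet, n: int, seed: int) -> VariantSet:
    """Uniformly random size-``n`` subset of a variation set's keys,
    reproducible for a fixed seed."""
    if n > len(vs):
        raise ValueError(f"cannot select {n} keys from a set of {len(vs)}")
    rng = random.Random(seed)
    ordered = sorted(vs.keys, key=VariantKey.as_tuple)
    chosen = frozenset(rng.sample(ordered, n))
    return replace(vs, keys=chosen, source=f"{vs.source}|subset(n={n},seed={seed})")


def select_paired_sites(
    a: VariantSet, b: VariantSet, n: int, seed: int
) -> tuple[VariantSet, VariantSet]:
    """Subsample a PAIR of genomes over a common site universe.

    ``n`` (chrom, pos) coordinates are drawn uniformly from the union of the
    two genomes' sites; each genome keeps its keys at the selected
    coordinates.  This mirrors subsetting two VCFs to a shared random panel
    of variation sites.
    """
    if a.key_mode != b.key_mode:
        raise ValueError("paired selection requires matching key modes")
    universe = sorted(a.sites() | b.sites())
    if n > len(universe):
        raise ValueError(
            f"cannot select {n} sites from a universe of {len(universe)}"
        )
    rng = random.Random(seed)
    chosen = set(rng.sample(universe, n))

    def _restrict(vs: VariantSet) -> VariantSet:
        kept = frozenset(k for k in vs.keys if (k.chrom, k.pos) in chosen)
        return replace(
            vs, keys=kept, source=f"{vs.source}|sites(n={n},seed={seed})"
        )

    return _restrict(a), _restrict(b)


# ---------------------------------------------------------------------------
# genotype matrices


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix (0/1/2, MISSING = -1) with case/control
    labels."""

    samples: list[str]
    sites: list[str]
    dosages: np.ndarray
    labels: np.ndarray  # array of "case" / "control", parallel to samples
    meta: dict = field(default_factory=dict)  # provenance: seeds, generator config

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.labels.shape != (len(self.samples),):
            raise ValueError("labels must be parallel to samples")
        bad = set(np.unique(self.labels)) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        vals = np.unique(self.dosages)
        if not set(vals.tolist()) <= {MISSING, 0, 1, 2}:
            raise ValueError(f"dosages outside {{0,1,2,MISSING}}: {vals}")

    @property
    def n_case(self) -> int:
        return int(np.sum(self.labels == "case"))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.labels == "control"))

    def case_mask(self) -> np.ndarray:
        return self.labels == "case"

    def site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}") from None

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            dosages=self.dosages[idx],
            labels=self.labels[idx],
            meta=dict(self.meta),
        )


def read_genotype_matrix(
    path: str | Path,
    format: str = "tsv",
    labels: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV (native layout) or a multi-sample VCF.

    TSV layout: header ``sample_id<TAB>label<TAB><site ids...>``, one row per
    sample; dosages are 0/1/2 or "." for missing, never imputed here.  For
    VCF input, labels come from the ``labels`` mapping or, failing that, from
    a ``case``/``control`` prefix of the sample name.
    """
    path = Path(path)
    if format == "tsv":
        return _read_matrix_tsv(path)
    if format == "vcf":
        return _read_matrix_vcf(path, labels)
    raise ValueError(f"unknown genotype matrix format {format!r}")


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(
            f"{path}: expected header 'sample_id<TAB>label<TAB><site ids>'"
        )
    sites = list(df.columns[2:])
    samples = df["sample_id"].tolist()
    lab = df["label"].tolist()
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    dos = np.empty(raw.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(raw):
        s = str(v).strip()
        if s in (".", "", "nan", "NA"):
            dos[i, j] = MISSING
        elif s in ("0", "1", "2"):
            dos[i, j] = int(s)
        else:
            raise ValueError(
                f"{path}: dosage {s!r} for sample {samples[i]} site {sites[j]} "
                "is outside {0,1,2,.}"
            )
    return GenotypeMatrix(samples, sites, dos, np.array(lab, dtype=object))


def _label_for(sample: str, labels: Mapping[str, str] | None) -> str:
    if labels is not None:
        try:
            return labels[sample]
        except KeyError:
            raise ValueError(f"no label provided for sample {sample!r}") from None
    low = sample.lower()
    if low.startswith("case"):
        return "case"
    if low.startswith(("control", "ctrl")):
        return "control"
    raise ValueError(
        f"cannot infer case/control label from sample name {sample!r}; "
        "pass an explicit labels mapping"
    )


def _read_matrix_vcf(path: Path, labels: Mapping[str, str] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VCFError(f"{path}: VCF has no sample columns")
    lab = np.array([_label_for(s, labels) for s in samples], dtype=object)
    sites: list[str] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if v.FILTER is not None:
            continue
        alt0 = (v.ALT or ["?"])[0]
        sites.append(f"{v.CHROM}:{v.POS}:{v.REF}:{alt0}")
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            if len(g) < 2 or g[0] < 0 or g[1] < 0:
                col[i] = MISSING
            else:
                col[i] = (g[0] > 0) + (g[1] > 0)
        cols.append(col)
    vcf.close()
    if not sites:
        raise VCFError(f"{path}: no usable records")
    return GenotypeMatrix(samples, sites, np.stack(cols, axis=1), lab)


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write the native TSV layout (inverse of the TSV reader)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\t" + "\t".join(gm.sites) + "\n")
        for i, s in enumerate(gm.samples):
            row = [
                "." if d == MISSING else str(int(d)) for d in gm.dosages[i]
            ]
            fh.write(f"{s}\t{gm.labels[i]}\t" + "\t".join(row) + "\n")
    return path
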