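"""Plaintext minor-allele-frequency and case-control chi-square statistics.

This module is the reference pipeline: every secure protocol in the package
(homomorphically outsourced or two-party) must reproduce its output exactly,
because the protocols exchange the same integer allele counts this module
computes and then apply the same closed-form statistic.

The test is the 2x2 *allelic* Pearson chi-square (1 df) on the table of
(case/control) x (minor/major) allele counts:

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d

with no continuity correction, so the statistic is an exact rational in the
integer counts.  The minor allele is defined on the combined cohort; missing
genotypes are excluded from that site's denominators (dosage k contributes k
alternate and 2-k reference alleles).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


from .variants import MISSING, GenotypeMatrix

__all__ = [
    "AlleleCountTable",
    "SiteStats",
    "DegenerateSiteError",
    "allele_counts",
    "raw_allele_counts",
    "table_from_raw_counts",
    "maf",
    "chi2_allelic",
    "chi2_p_value",
    "site_statistics",
    "stats_from_pooled_counts",
    "write_site_statistics",
]


class DegenerateSiteError(ValueError):
    """A site whose table cannot support the statistic (all-missing site or a
    zero marginal).  Reported downstream as NA, never silently as 0."""


@dataclass(frozen=True)
class AlleleCountTable:
    """2x2 allele-count table: a/b = case minor/major, c/d = control
    minor/major."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_rows(self) -> "AlleleCountTable":
        return AlleleCountTable(self.c, self.d, self.a, self.b)

    def swapped_cols(self) -> "AlleleCountTable":
        return AlleleCountTable(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class SiteStats:
    """Per-site association result; ``chi2``/``p_value`` are None for
    degenerate sites."""

    site: str
    table: AlleleCountTable | None
    maf: float | None
    chi2: float | None
    p_value: float | None
    df: int = 1


def raw_allele_counts(
    gm: GenotypeMatrix, site_idx: int
) -> tuple[int, int, int, int]:
    """Raw per-group counts at one site: (case_alt, case_total_alleles,
    control_alt, control_total_alleles), missing samples excluded.

    These four integers are exactly what the secure protocols aggregate.
    """
    col = gm.dosages[:, site_idx]
    case = gm.case_mask()
    ok = col != MISSING
    case_ok = ok & case
    ctrl_ok = ok & ~case
    case_alt = int(col[case_ok].sum())
    ctrl_alt = int(col[ctrl_ok].sum())
    return case_alt, 2 * int(case_ok.sum()), ctrl_alt, 2 * int(ctrl_ok.sum())


def table_from_raw_counts(
    case_alt: int, case_total: int, ctrl_alt: int, ctrl_total: int
) -> AlleleCountTable:
    """Orient raw alternate-allele counts into a minor/major table using the
    combined-cohort minor allele."""
    total = case_total + ctrl_total
    if total == 0:
        raise DegenerateSiteError("all genotypes missing at site")
    alt = case_alt + ctrl_alt
    if 2 * alt <= total:  # alternate allele is the minor (ties: alt)
        return AlleleCountTable(
            case_alt, case_total - case_alt, ctrl_alt, ctrl_total - ctrl_alt
        )
    return AlleleCountTable(
        case_total - case_alt, case_alt, ctrl_total - ctrl_alt, ctrl_alt
    )


def allele_counts(gm: GenotypeMatrix, site: str) -> AlleleCountTable:
    """Minor/major allele-count table for one site of a genotype matrix."""
    return table_from_raw_counts(*raw_allele_counts(gm, gm.site_index(site)))


def maf(t: AlleleCountTable) -> float:
    """Minor allele frequency min(p, 1-p), p = (a+c)/N, on [0, 0.5]."""
    if t.n == 0:
        raise DegenerateSiteError("empty table has no allele frequency")
    p = (t.a + t.c) / t.n
    return min(p, 1.0 - p)


def chi2_allelic(t: AlleleCountTable) -> float:
    """Pearson 2x2 allelic chi-square, exact rational form, no continuity
    correction.  Raises :class:`DegenerateSiteError` on a zero marginal."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateSiteError("zero marginal: chi-square undefined")
    det = t.a * t.d - t.b * t.c
    return t.n * det * det / (r1 * r2 * c1 * c2)


def chi2_p_value(chi2: float, df: int = 1) -> float:
    from scipy.stats import chi2 as chi2_dist

    return float(chi2_dist.sf(chi2, df))


def site_statistics(
    gm: GenotypeMatrix, sites: Sequence[str] | None = None, p_values: bool = True
) -> list[SiteStats]:
    """MAF and allelic chi-square for every requested site (default: all)."""
    names = list(sites) if sites is not None else list(gm.sites)
    pooled = [raw_allele_counts(gm, gm.site_index(n)) for n in names]
    return stats_from_pooled_counts(names, pooled, p_values=p_values)


def stats_from_pooled_counts(
    sites: Sequence[str],
    pooled: Sequence[tuple[int, int, int, int]],
    p_values: bool = True,
) -> list[SiteStats]:
    """Site statistics from already-aggregated raw counts — the final, clear
    step shared by the plaintext, outsourced, and two-party pipelines."""
    out: list[SiteStats] = []
    for name, (ca, ct, na, nt) in zip(sites, pooled):
        try:
            t = table_from_raw_counts(ca, ct, na, nt)
        except DegenerateSiteError:
            out.append(SiteStats(name, None, None, None, None))
            continue
        f = maf(t)
        try:
            x2 = chi2_allelic(t)
        except DegenerateSiteError:
            out.append(SiteStats(name, t, f, None, None))
            continue
        pv = chi2_p_value(x2) if p_values else None
        out.append(SiteStats(name, t, f, x2, pv))
    return out


def write_site_statistics(stats: Sequence[SiteStats], path: str | Path) -> Path:
    """Results TSV: one row per site, NA for degenerate sites."""
    import pandas as pd

    rows = []
    for s in stats:
        t = s.table
        rows.append(
            {
                "site_id": s.site,
                "case_minor": t.a if t else "NA",
                "case_major": t.b if t else "NA",
                "control_minor": t.c if t else "NA",
                "control_major": t.d if t else "NA",
                "maf": s.maf if s.maf is not None else "NA",
                "chi2": repr(s.chi2) if s.chi2 is not None else "NA",
                "p_value": repr(s.p_value) if s.p_value is not None else "NA",
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
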