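"""High-confidence heterozygous-site filtering.

Candidate heterozygous SNVs of the diploid donor are the substrate of
sperm phasing; a miscalled site propagates into every sperm genotype, so
the filter is deliberately strict: phred site quality >= 30, minor-allele
depth >= 5, and a 1 d.f. chi-square test of the expected 1:1 allelic
segregation at P = 0.05.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

#: chi-square critical value at P = 0.05 with 1 degree of freedom
CHI2_CRIT_1DF_P05 = 3.841459

DEFAULT_MIN_QUALITY = 30.0
DEFAULT_MIN_MINOR_DEPTH = 5

_SNV_BASES = frozenset("ACGT")


def chi_square_1to1(depth_a: int, depth_b: int, critical: float = CHI2_CRIT_1DF_P05) -> tuple[float, bool]:
    """Chi-square statistic for a 1:1 allele-depth ratio and its pass flag.

    With expected counts (n/2, n/2) the statistic collapses to
    ``(depth_a - depth_b)**2 / (depth_a + depth_b)`` on 1 d.f.; a site
    passes when the statistic is below the P = 0.05 critical value (no
    continuity correction).
    """
    n = depth_a + depth_b
    if n <= 0:
        raise ValueError("chi_square_1to1 undefined for zero total depth")
    stat = (depth_a - depth_b) ** 2 / n
    return stat, stat < critical


@dataclass
class FilterResult:
    sites: pd.DataFrame
    tally: Counter
    n_input: int

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.sites, self.tally))


def filter_het_sites(
    records: Iterable[dict],
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_minor_depth: int = DEFAULT_MIN_MINOR_DEPTH,
    chi2_critical: float = CHI2_CRIT_1DF_P05,
    chromosomes: Iterable[str] | None = None,
) -> FilterResult:
    """Filter candidate variant records to the phasing-substrate site set.

    Parameters
    ----------
    records:
        Iterable of dicts with keys ``chrom, pos, allele_a, allele_b,
        depth_a, depth_b, quality`` (see :func:`gametophase.io.read_vcf_sites`).
        Multiallelic records, indels and malformed records are skipped and
        tallied.
    chromosomes:
        Optional chromosome whitelist; sites elsewhere are kept but flagged
        ``unplaced`` (only chromosome-assigned sites feed phasing by
        default).

    Returns a :class:`FilterResult` whose ``tally`` sums, together with the
    retained count, to the number of input records.
    """
    chrom_set = set(chromosomes) if chromosomes is not None else None
    tally: Counter = Counter()
    kept = []
    n_input = 0
    for rec in records:
        n_input += 1
        try:
            chrom = rec["chrom"]
            pos = int(rec["pos"])
            a, b = rec["allele_a"], rec["allele_b"]
            da, db = int(rec["depth_a"]), int(rec["depth_b"])
            qual = float(rec["quality"])
        except (KeyError, TypeError, ValueError):
            tally["malformed"] += 1
            continue
        if a == b or a not in _SNV_BASES or b not in _SNV_BASES:
            tally["not_biallelic_snv"] += 1
            continue
        if pos < 1 or da < 0 or db < 0:
            tally["malformed"] += 1
            continue
        if qual < min_quality:
            tally["low_quality"] += 1
            continue
        if min(da, db) < min_minor_depth:
            tally["low_minor_depth"] += 1
            continue
        stat, ok = chi_square_1to1(da, db, critical=chi2_critical)
        if not ok:
            tally["segregation_distorted"] += 1
            continue
        kept.append(
            {
                "chrom": chrom,
                "pos": pos,
                "allele_a": a,
                "allele_b": b,
                "depth_a": da,
                "depth_b": db,
                "quality": qual,
                "chi2": stat,
                "unplaced": chrom_set is not None and chrom not in chrom_set,
            }
        )
    sites = pd.DataFrame(
        kept,
        columns=[
            "chrom", "pos", "allele_a", "allele_b",
            "depth_a", "depth_b", "quality", "chi2", "unplaced",
        ],
    )
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return FilterResult(sites=sites, tally=tally, n_input=n_input)


def records_from_table(sites: pd.DataFrame) -> Iterator[dict]:
    """Adapt a site table back into the record-stream form the filter eats."""
    for row in sites.itertuples(index=False):
        yield {
            "chrom": row.chrom,
            "pos": row.pos,
            "allele_a": row.allele_a,
            "allele_b": row.allele_b,
            "depth_a": row.depth_a,
            "depth_b": row.depth_b,
            "quality": row.quality,
        }
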