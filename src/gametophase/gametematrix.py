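"""Sperm x site allele-call matrix and per-sperm quality control.

The gamete matrix is the central object of the phasing pipeline: every
heterozygous site of the diploid donor defines a row, every sequenced sperm
a column, and each entry records which of the two donor alleles that sperm
carries (or that no call was made, the common case under single-cell
whole-genome-amplification dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: integer codes used in the call matrix
CALL_A = 0  # allele_a (REF) of the site
CALL_B = 1  # allele_b (ALT) of the site
MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "allele_a", "allele_b"]


@dataclass
class GameteMatrix:
    """Allele calls of a sperm population over the donor's het sites.

    Attributes
    ----------
    sites:
        DataFrame with at least ``chrom, pos, allele_a, allele_b`` sorted by
        (chrom, pos); one row per heterozygous site.
    sperm_ids:
        Ordered sperm identifiers (column order of ``calls``).
    calls:
        ``int8`` array of shape (n_sites, n_sperm) over {0, 1, -1} where
        0/1 mean allele_a/allele_b of the site and -1 means missing.
    """

    sites: pd.DataFrame
    sperm_ids: list[str]
    calls: np.ndarray
    mismatch_count: int = 0
    duplicate_count: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.sperm_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.sperm_ids)} sperm"
            )
        bad = ~np.isin(self.calls, (CALL_A, CALL_B, MISSING))
        if bad.any():
            raise ValueError("calls must be coded 0 (allele_a), 1 (allele_b) or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_sperm(self) -> int:
        return len(self.sperm_ids)

    def sperm_index(self, sperm_id: str) -> int:
        try:
            return self.sperm_ids.index(sperm_id)
        except ValueError:
            raise KeyError(f"unknown sperm id {sperm_id!r}") from None

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of ``sites``/``calls`` covering one chromosome."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no sites on chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class SpermQC:
    sperm_id: str
    covered_fraction: float
    mean_depth: float | None = None


def _sorted_sites(sites: pd.DataFrame) -> pd.DataFrame:
    out = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def build_matrix(
    sites: pd.DataFrame,
    call_tables: Mapping[str, pd.DataFrame],
) -> GameteMatrix:
    """Assemble the sperm x site matrix from per-sperm allele-call tables.

    Parameters
    ----------
    sites:
        Filtered het-site table (``chrom, pos, allele_a, allele_b`` ...).
    call_tables:
        Mapping of sperm id to a DataFrame with columns ``chrom, pos,
        allele`` and optionally ``depth``.  Calls at coordinates outside
        ``sites`` are ignored; calls matching neither site allele become
        missing and are tallied; duplicated coordinates within one sperm
        keep the higher-depth call.
    """
    sites = _sorted_sites(sites)
    sperm_ids = sorted(call_tables)
    n_sites, n_sperm = len(sites), len(sperm_ids)
    site_index = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    allele_a = sites["allele_a"].to_numpy()
    allele_b = sites["allele_b"].to_numpy()

    calls = np.full((n_sites, n_sperm), MISSING, dtype=np.int8)
    mismatches = 0
    duplicates = 0
    for j, sid in enumerate(sperm_ids):
        tab = call_tables[sid]
        depth = tab["depth"] if "depth" in tab.columns else pd.Series(1, index=tab.index)
        best_depth: dict[int, float] = {}
        for chrom, pos, allele, d in zip(tab["chrom"], tab["pos"], tab["allele"], depth):
            i = site_index.get((chrom, int(pos)))
            if i is None:
                continue
            if i in best_depth:
                duplicates += 1
                if d <= best_depth[i]:
                    continue
            best_depth[i] = d
            if allele == allele_a[i]:
                calls[i, j] = CALL_A
            elif allele == allele_b[i]:
                calls[i, j] = CALL_B
            else:
                mismatches += 1
                calls[i, j] = MISSING
    return GameteMatrix(sites, sperm_ids, calls,
                        mismatch_count=mismatches, duplicate_count=duplicates)


def qc_sperm(matrix: GameteMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-sperm coverage QC and population summary.

    Returns a DataFrame (``sperm_id, covered_fraction, flagged``) and a
    summary dict with the population mean covered fraction and the fraction
    of sites genotyped in at least one sperm.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    observed = matrix.calls != MISSING
    frac = observed.mean(axis=0)
    qc = pd.DataFrame(
        {
            "sperm_id": matrix.sperm_ids,
            "covered_fraction": frac,
            "flagged": frac == 0.0,
        }
    )
    summary = {
        "mean_covered_fraction": float(frac.mean()),
        "fraction_sites_genotyped": float(observed.any(axis=1).mean()),
        "n_sperm": matrix.n_sperm,
        "n_sites": matrix.n_sites,
    }
    return qc, summary


def select_reference_sperm(qc: pd.DataFrame) -> str:
    """Sperm with the highest site coverage; ties break to the smaller id.

    The highest-coverage sperm serves as the coordinate frame for relative
    genotyping of the whole population.
    """
    if len(qc) < 2:
        raise ValueError("need at least two sperm to choose a reference")
    best = qc.sort_values(
        ["covered_fraction", "sperm_id"], ascending=[False, True], kind="mergesort"
    ).iloc[0]
    return str(best["sperm_id"])
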