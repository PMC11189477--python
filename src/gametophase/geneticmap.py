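"""Gamete genetic map: recombination fractions and Kosambi distances.

Because the bins of the bin map are already in physical order, the map
needs no de-novo marker ordering: adjacent-bin recombination fractions are
estimated directly from the gamete genotypes and accumulated into
centimorgan positions with the Kosambi mapping function
``d = 25 * ln((1 + 2r) / (1 - 2r))``, which allows for moderate crossover
interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gametematrix import MISSING
from .phasing import BinMap

R_CAP = 0.4999


def kosambi(r):
    """Kosambi map distance in centimorgans for recombination fraction r."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Recombination fraction for a Kosambi distance in centimorgans."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def recombination_fraction(
    bin_map: BinMap, bin_i: int, bin_j: int
) -> tuple[float, int]:
    """Recombination fraction between two bins of one chromosome.

    r = (# sperm with different genotypes at the two bins) / (# sperm
    informative at both); capped just below 0.5 with a warning because the
    Kosambi function diverges there.  Returns (r, n_informative); r is NaN
    when no sperm is informative at both bins (a map gap).
    """
    ci = bin_map.bins["chrom"].iat[bin_i]
    cj = bin_map.bins["chrom"].iat[bin_j]
    if ci != cj:
        raise ValueError("recombination fraction is defined within a chromosome")
    gi = bin_map.genotypes[:, bin_i]
    gj = bin_map.genotypes[:, bin_j]
    both = (gi != MISSING) & (gj != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    r = float((gi[both] != gj[both]).mean())
    if r >= 0.5:
        warnings.warn(
            f"recombination fraction {r:.3f} between bins {bin_i} and {bin_j} "
            f"capped at {R_CAP}",
            stacklevel=2,
        )
        r = R_CAP
    return r, n


def build_genetic_map(bin_map: BinMap) -> pd.DataFrame:
    """Cumulative Kosambi map over the ordered bins of every chromosome.

    Returns a Marey-map-ready table with one row per bin: ``chrom, bin_id,
    midpoint_bp, r_prev, n_prev, d_prev_cM, cum_cM, gap``.  The first bin
    of each chromosome sits at 0 cM; adjacent-pair distances accumulate.
    Pairs with no informative sperm are map gaps: their r and distance are
    NaN, contribute 0 to the cumulative position and are flagged.
    """
    rows = []
    chrom_arr = bin_map.bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        idx = bin_map.chrom_bin_idx(chrom)
        if idx.size == 1:
            warnings.warn(f"chromosome {chrom} has a single bin: zero-length map", stacklevel=2)
        cum = 0.0
        prev = None
        for b in idx:
            mid = 0.5 * (bin_map.bins["start"].iat[b] + bin_map.bins["end"].iat[b])
            if prev is None:
                r, n, d, gap = np.nan, 0, np.nan, False
            else:
                r, n = recombination_fraction(bin_map, prev, b)
                gap = n == 0
                d = kosambi(r) if not gap else np.nan
                cum += 0.0 if gap else d
            rows.append(
                {
                    "chrom": chrom,
                    "bin_id": bin_map.bins["bin_id"].iat[b],
                    "midpoint_bp": mid,
                    "r_prev": r,
                    "n_prev": n,
                    "d_prev_cM": d,
                    "cum_cM": cum,
                    "gap": gap,
                }
            )
            prev = b
    return pd.DataFrame(rows)


def map_summary(genetic_map: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome and genome-wide map length (cM) and bin counts."""
    per_chrom = (
        genetic_map.groupby("chrom", sort=False)
        .agg(n_bins=("bin_id", "size"), length_cM=("cum_cM", "max"), n_gaps=("gap", "sum"))
        .reset_index()
    )
    total = pd.DataFrame(
        [
            {
                "chrom": "genome",
                "n_bins": int(per_chrom["n_bins"].sum()),
                "length_cM": float(per_chrom["length_cM"].sum()),
                "n_gaps": int(per_chrom["n_gaps"].sum()),
            }
        ]
    )
    return pd.concat([per_chrom, total], ignore_index=True)


def plot_marey(genetic_map: pd.DataFrame, path: str) -> None:
    """Write a Marey map (physical bp vs cumulative cM) per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(genetic_map["chrom"]))
    ncol = min(5, len(chroms))
    nrow = int(np.ceil(len(chroms) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = genetic_map[genetic_map["chrom"] == chrom]
        ax.plot(sub["midpoint_bp"] / 1e6, sub["cum_cM"], ".-", ms=3)
        ax.set_title(chrom, fontsize=8)
        ax.set_xlabel("Mb", fontsize=7)
        ax.set_ylabel("cM", fontsize=7)
    for ax in axes.ravel()[len(chroms):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
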