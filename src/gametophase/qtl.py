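"""LOD interval scanning of gamete phenotypes over the bin map.

A haploid gamete population needs no dominance terms: at each position on
a 1-cM grid the expected haplotype (0/1) given the flanking bin genotypes
is regressed against the phenotype (Haley-Knott style), optionally with
forward-selected cofactor markers excluded within a 10-cM window of the
test position, and the LOD is the log10 likelihood ratio of the QTL model
over the null.  Regions with LOD >= 2.5 are reported as QTL intervals
with their peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gametematrix import MISSING
from .geneticmap import kosambi_inverse
from .phasing import BinMap

DEFAULT_WALK_CM = 1.0
DEFAULT_WINDOW_CM = 10.0
DEFAULT_LOD_THRESHOLD = 2.5
DEFAULT_MAX_COFACTORS = 5
DEFAULT_MIN_COFACTOR_LOD = 1.5
LOD_CAP = 50.0


@dataclass
class QtlScan:
    positions: pd.DataFrame  # chrom, cM, bp, lod
    intervals: pd.DataFrame  # chrom, cm_start, cm_end, peak_cM, peak_bp, peak_lod
    cofactors: list[int] = field(default_factory=list)
    threshold: float = DEFAULT_LOD_THRESHOLD

    @property
    def peak(self) -> pd.Series | None:
        if self.positions.empty:
            return None
        return self.positions.loc[self.positions["lod"].idxmax()]


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _lod_from_rss(rss0: float, rss1: float, n: int, cap: float = LOD_CAP) -> float:
    if rss0 <= 0.0:
        return 0.0
    if rss1 <= rss0 * 10 ** (-2 * cap / n):
        warnings.warn("perfect fit: LOD capped", stacklevel=3)
        return cap
    return max(0.0, (n / 2.0) * np.log10(rss0 / rss1))


def lod_at_marker(genotypes, phenotypes, cap: float = LOD_CAP) -> float:
    """Single-marker LOD from regressing phenotype on 0/1 genotype.

    LOD = (n/2) * log10(RSS0 / RSS1) where RSS0 is the residual sum of
    squares of the intercept-only model.  Missing genotypes (-1 or NaN)
    are excluded pairwise; a monomorphic marker scores 0; a degenerate
    perfect fit is capped at ``cap`` with a warning.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(y) & (g != MISSING)
    g, y = g[ok], y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 informative sperm")
    if np.all(g == g[0]):
        return 0.0
    rss0 = _rss(y, np.ones((n, 1)))
    rss1 = _rss(y, np.column_stack([np.ones(n), g]))
    return _lod_from_rss(rss0, rss1, n, cap)


def _imputed_genotypes(bin_map: BinMap, rows: np.ndarray) -> np.ndarray:
    """Bin genotypes of selected sperm with missing entries mean-imputed."""
    G = bin_map.genotypes[rows].astype(float)
    G[G == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing bins
        col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
    nan_r, nan_c = np.where(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    return G


def select_cofactors(
    bin_map: BinMap,
    phenotypes: pd.DataFrame,
    max_cofactors: int = DEFAULT_MAX_COFACTORS,
    min_lod_gain: float = DEFAULT_MIN_COFACTOR_LOD,
) -> list[int]:
    """Forward-select cofactor bins by conditional single-marker LOD.

    Starting from the intercept-only model, repeatedly add the bin whose
    genotype most improves the fit, until ``max_cofactors`` are chosen or
    no remaining bin adds LOD > ``min_lod_gain``.  Returns global bin
    (column) indices into the bin map.
    """
    if max_cofactors <= 0 or bin_map.n_bins == 0:
        return []
    sid_to_row = {sid: i for i, sid in enumerate(bin_map.sperm_ids)}
    keep = phenotypes["sperm_id"].map(sid_to_row).dropna()
    rows = keep.to_numpy(dtype=int)
    y = phenotypes.loc[keep.index, "grade"].to_numpy(dtype=float)
    G = _imputed_genotypes(bin_map, rows)
    n = len(y)
    chosen: list[int] = []
    X = np.ones((n, 1))
    rss_cur = _rss(y, X)
    while len(chosen) < max_cofactors:
        best, best_lod, best_rss = None, min_lod_gain, None
        for b in range(bin_map.n_bins):
            if b in chosen or np.ptp(G[:, b]) == 0:
                continue
            rss_b = _rss(y, np.column_stack([X, G[:, b]]))
            lod = _lod_from_rss(rss_cur, rss_b, n)
            if lod > best_lod:
                best, best_lod, best_rss = b, lod, rss_b
        if best is None:
            break
        chosen.append(best)
        X = np.column_stack([X, G[:, best]])
        rss_cur = best_rss
    return chosen


def _expected_genotype(
    c: float,
    marker_cm: np.ndarray,
    g: np.ndarray,
) -> np.ndarray:
    """P(haplotype 1 at map position c) per sperm given flanking markers.

    Flanking probabilities combine through inverse-Kosambi recombination
    fractions assuming no interference between the two flanks; sperm with
    a single observed flank use that flank alone, sperm with none get NaN.
    """
    n_sperm, n_markers = g.shape
    p1 = np.full(n_sperm, np.nan)
    for s in range(n_sperm):
        obs = np.flatnonzero(g[s] != MISSING)
        if obs.size == 0:
            continue
        m = marker_cm[obs]
        j = int(np.searchsorted(m, c, side="right"))
        li = obs[j - 1] if j > 0 else None
        ri = obs[j] if j < obs.size else None
        if li is not None and marker_cm[li] == c:
            p1[s] = g[s, li]
            continue
        if ri is not None and marker_cm[ri] == c:
            p1[s] = g[s, ri]
            continue
        if li is not None and ri is not None:
            r1 = kosambi_inverse(c - marker_cm[li])
            r2 = kosambi_inverse(marker_cm[ri] - c)
            a1 = (1.0 - r1) if g[s, li] == 1 else r1  # P(g=1 | left)
            b1 = (1.0 - r2) if g[s, ri] == 1 else r2  # P(right | g=1)
            a0 = 1.0 - a1
            b0 = r2 if g[s, ri] == 1 else (1.0 - r2)  # P(right | g=0)
            denom = a1 * b1 + a0 * b0
            p1[s] = a1 * b1 / denom if denom > 0 else 0.5
        elif li is not None:
            r1 = kosambi_inverse(c - marker_cm[li])
            p1[s] = (1.0 - r1) if g[s, li] == 1 else r1
        else:
            r2 = kosambi_inverse(marker_cm[ri] - c)
            p1[s] = (1.0 - r2) if g[s, ri] == 1 else r2
    return p1


def interval_scan(
    bin_map: BinMap,
    genetic_map: pd.DataFrame,
    phenotypes: pd.DataFrame,
    walk_cM: float = DEFAULT_WALK_CM,
    window_cM: float = DEFAULT_WINDOW_CM,
    cofactors: list[int] | None = None,
    threshold: float = DEFAULT_LOD_THRESHOLD,
    lod_cap: float = LOD_CAP,
) -> QtlScan:
    """LOD scan on a ``walk_cM`` grid along the genetic map.

    At each grid point the expected haplotype given the flanking bins is
    regressed against the phenotype together with the cofactor bin
    genotypes, excluding cofactors within ``window_cM`` of the test
    position on the same chromosome; the LOD compares that model with the
    cofactor-only null.  Contiguous regions with LOD >= ``threshold`` are
    reported with their peak.
    """
    if len(genetic_map) != bin_map.n_bins or not (
        genetic_map["bin_id"].to_numpy() == bin_map.bins["bin_id"].to_numpy()
    ).all():
        raise ValueError("genetic map and bin map are inconsistent")
    sid_to_row = {sid: i for i, sid in enumerate(bin_map.sperm_ids)}
    keep = phenotypes["sperm_id"].map(sid_to_row).dropna()
    if keep.empty:
        raise ValueError("no phenotyped sperm overlap the bin map")
    rows = keep.to_numpy(dtype=int)
    y_all = phenotypes.loc[keep.index, "grade"].to_numpy(dtype=float)
    G_raw = bin_map.genotypes[rows]  # (n_pheno_sperm, n_bins), with MISSING
    G_imp = _imputed_genotypes(bin_map, rows)
    cofactors = list(cofactors or [])
    cof_cm = genetic_map["cum_cM"].to_numpy()
    cof_chrom = genetic_map["chrom"].to_numpy()

    out_rows = []
    chrom_arr = genetic_map["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        midx = np.flatnonzero(chrom_arr == chrom)
        marker_cm = genetic_map["cum_cM"].to_numpy()[midx]
        marker_bp = genetic_map["midpoint_bp"].to_numpy()[midx]
        g_chrom = G_raw[:, midx]
        top = marker_cm[-1]
        grid = np.arange(0.0, top + walk_cM * 0.5, walk_cM)
        if grid.size == 0 or grid[-1] < top:
            grid = np.append(grid, top)
        for c in grid:
            active = [
                b
                for b in cofactors
                if not (cof_chrom[b] == chrom and abs(cof_cm[b] - c) < window_cM)
            ]
            p1 = _expected_genotype(float(c), marker_cm, g_chrom)
            ok = ~np.isnan(p1)
            n = int(ok.sum())
            if n < 3 or np.ptp(p1[ok]) == 0:
                lod = 0.0
            else:
                Xc = G_imp[ok][:, active] if active else np.empty((n, 0))
                X0 = np.column_stack([np.ones(n), Xc])
                X1 = np.column_stack([X0, p1[ok]])
                lod = _lod_from_rss(_rss(y_all[ok], X0), _rss(y_all[ok], X1), n, lod_cap)
            bp = float(np.interp(c, marker_cm, marker_bp))
            out_rows.append({"chrom": chrom, "cM": float(c), "bp": bp, "lod": lod})
    positions = pd.DataFrame(out_rows)

    intervals = []
    for chrom in dict.fromkeys(positions["chrom"]):
        sub = positions[positions["chrom"] == chrom].reset_index(drop=True)
        above = sub["lod"].to_numpy() >= threshold
        i = 0
        while i < len(sub):
            if above[i]:
                j = i
                while j + 1 < len(sub) and above[j + 1]:
                    j += 1
                seg = sub.iloc[i : j + 1]
                peak = seg.loc[seg["lod"].idxmax()]
                intervals.append(
                    {
                        "chrom": chrom,
                        "cm_start": float(seg["cM"].iloc[0]),
                        "cm_end": float(seg["cM"].iloc[-1]),
                        "peak_cM": float(peak["cM"]),
                        "peak_bp": float(peak["bp"]),
                        "peak_lod": float(peak["lod"]),
                    }
                )
                i = j + 1
            else:
                i += 1
    intervals_df = pd.DataFrame(
        intervals, columns=["chrom", "cm_start", "cm_end", "peak_cM", "peak_bp", "peak_lod"]
    )
    return QtlScan(positions=positions, intervals=intervals_df, cofactors=cofactors, threshold=threshold)
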