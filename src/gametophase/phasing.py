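"""Parental haplotype inference from a sperm population.

The algorithm works in the coordinate frame of a single reference sperm
(the highest-coverage cell): every other sperm is genotyped as
same/different relative to it, crossovers appear as state switches along a
chromosome, and crossovers of the reference sperm itself appear as
population-wide switches ("false recombination sites") that are detected
by consensus and corrected by toggling all downstream states.  After
correction the same/different states are chromosome-level absolute
genotypes (haplotype 0 is the reference sperm's starting haplotype), from
which the bin map, the per-sperm crossover counts and the phased
haplotype markers follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gametematrix import GameteMatrix, MISSING

SAME = 0
DIFFERENT = 1

DEFAULT_WINDOW = 15
DEFAULT_MIN_SUPPORT = 5
DEFAULT_CONSENSUS_FRACTION = 0.9
DEFAULT_TOLERANCE_BP = 200_000
DEFAULT_MIN_POPULATION = 5
DEFAULT_INTERVAL_BP = 100_000
DEFAULT_MIN_EVENT_SPACING_BP = 2_000_000
DEFAULT_MIN_MARKER_CONFIDENCE = 0.9


@dataclass
class RelativeTracks:
    """Per-sperm same/different-vs-reference state at every het site.

    ``states`` is (n_sites, n_sperm) over {0 same, 1 different, -1 missing};
    a state is defined only where both the sperm and the reference carry a
    call.  After false-recombination correction (``corrected=True``) state
    0/1 means haplotype H0/H1, where H0 is the reference sperm's starting
    haplotype on each chromosome.
    """

    sites: pd.DataFrame
    sperm_ids: list[str]
    ref_id: str
    states: np.ndarray
    corrected: bool = False

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class CrossoverEvent:
    sperm_id: str
    chrom: str
    left_bp: int
    right_bp: int
    support_left: int
    support_right: int

    @property
    def mid(self) -> float:
        return 0.5 * (self.left_bp + self.right_bp)


@dataclass
class CorrectionResult:
    tracks: RelativeTracks
    events: dict[str, list[CrossoverEvent]]
    reference_positions: dict[str, list[float]]
    flagged_clusters: list[dict] = field(default_factory=list)


@dataclass
class BinMap:
    """Genotypes of the sperm population over merged 100-kb bins.

    ``bins`` uses half-open 0-based [start, end) coordinates; ``genotypes``
    is (n_sperm, n_bins) over {0 H0, 1 H1, -1 missing}.
    """

    bins: pd.DataFrame  # chrom, start, end, bin_id
    sperm_ids: list[str]
    genotypes: np.ndarray
    interval_bp: int = DEFAULT_INTERVAL_BP
    reference_positions: dict[str, list[float]] | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_bin_idx(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())


def genotype_against_reference(matrix: GameteMatrix, ref_id: str) -> RelativeTracks:
    """Genotype every sperm as same/different relative to the reference.

    The reference sperm's own track is all-same wherever it has a call.
    """
    j = matrix.sperm_index(ref_id)
    ref = matrix.calls[:, j]
    both = (matrix.calls != MISSING) & (ref[:, None] != MISSING)
    states = np.where(both, (matrix.calls != ref[:, None]).astype(np.int8), MISSING)
    return RelativeTracks(
        sites=matrix.sites[["chrom", "pos"]].copy(),
        sperm_ids=list(matrix.sperm_ids),
        ref_id=ref_id,
        states=states.astype(np.int8),
    )


def _majority_smooth(s: np.ndarray) -> np.ndarray:
    """Centered width-3 majority filter; the two ends keep the input."""
    n = len(s)
    if n < 3:
        return s.copy()
    out = s.copy()
    tri = s[:-2].astype(int) + s[1:-1] + s[2:]
    out[1:-1] = (tri >= 2).astype(s.dtype)
    return out


def _segment_informative(
    s: np.ndarray, min_support: int
) -> list[tuple[int, int, int]]:
    """Segment an informative state sequence into supported runs.

    Candidate segments are the maximal runs of the majority-smoothed
    sequence; a segment's support is the number of raw sites concordant
    with its state.  Segments with support below ``min_support`` are
    treated as noise (or gene-conversion-scale artifacts) and merged into
    their neighbours, weakest first, until every remaining segment is
    supported.  Returns (start, stop, state) triples over informative
    indices.
    """
    sm = _majority_smooth(s)
    bounds = [0, *(int(b) + 1 for b in np.flatnonzero(sm[:-1] != sm[1:])), len(s)]
    segs = [[a, b, int(sm[a])] for a, b in zip(bounds[:-1], bounds[1:])]

    def support(seg: list[int]) -> int:
        a, b, st = seg
        return int((s[a:b] == st).sum())

    while len(segs) > 1:
        sup = [support(seg) for seg in segs]
        k = int(np.argmin(sup))
        if sup[k] >= min_support:
            break
        if k == 0:
            segs[1][0] = segs[0][0]
            del segs[0]
        elif k == len(segs) - 1:
            segs[-2][1] = segs[-1][1]
            del segs[-1]
        else:  # neighbours share a state by alternation
            segs[k - 1][1] = segs[k + 1][1]
            del segs[k : k + 2]
    return [(a, b, st) for a, b, st in segs]


def detect_breakpoints(
    states: np.ndarray,
    positions: np.ndarray,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    sperm_id: str = "",
    chrom: str = "",
) -> list[CrossoverEvent]:
    """Sliding-window crossover detection on one sperm's chromosome track.

    Isolated flips are first suppressed by a width-3 majority filter; the
    smoothed sequence is segmented into state runs and runs with fewer
    than ``min_support`` concordant informative sites are absorbed as
    noise.  A breakpoint is called between the informative sites flanking
    each surviving segment boundary; the reported support counts the
    concordant sites within up to ``window`` informative sites on each
    side.  Isolated single-site flips are therefore never breakpoints,
    and a state switch needs ``min_support`` concordant sites on both
    flanks to be called.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    states = np.asarray(states)
    keep = states != MISSING
    s = states[keep].astype(np.int8)
    pos = np.asarray(positions)[keep]
    if len(s) < 2:
        return []
    segs = _segment_informative(s, min_support)
    events: list[CrossoverEvent] = []
    for left, right in zip(segs[:-1], segs[1:]):
        j = left[1] - 1  # last informative index of the left segment
        trail = s[max(left[0], j - window + 1) : j + 1]
        lead = s[right[0] : min(right[1], right[0] + window)]
        sup_l = int((trail == left[2]).sum())
        sup_r = int((lead == right[2]).sum())
        events.append(
            CrossoverEvent(sperm_id, chrom, int(pos[j]), int(pos[j + 1]), sup_l, sup_r)
        )
    return events


def detect_all_breakpoints(
    tracks: RelativeTracks,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, list[CrossoverEvent]]:
    """Run breakpoint detection for every sperm over every chromosome."""
    events: dict[str, list[CrossoverEvent]] = {sid: [] for sid in tracks.sperm_ids}
    pos_all = tracks.sites["pos"].to_numpy()
    for chrom in tracks.chromosomes():
        sl = tracks.chrom_slice(chrom)
        pos = pos_all[sl]
        for j, sid in enumerate(tracks.sperm_ids):
            events[sid].extend(
                detect_breakpoints(
                    tracks.states[sl, j], pos, window, min_support, sperm_id=sid, chrom=chrom
                )
            )
    return events


def _consensus_flip_regions(
    states: np.ndarray,
    positions: np.ndarray,
    consensus_fraction: float,
    tolerance_bp: float,
    min_population: int,
    exclude: int | None = None,
) -> tuple[list[float], list[dict]]:
    """Positions where (nearly) the whole population flips state at once.

    For every sperm, each pair of consecutive informative sites with
    different states defines a flip, located at the interval midpoint.  A
    candidate position is supported by a sperm when that sperm has a flip
    within ``tolerance_bp``; candidates are the flip midpoints
    themselves.  Greedily, the candidate with the highest supported
    fraction of the sperm spanning it is declared (at the median of the
    supporting flips) while that fraction reaches
    ``consensus_fraction``; supporting flips are then retired.  Isolated
    flips of individual sperm never come close to consensus because
    genuine crossovers are private to each gamete.

    Two artifact classes are recognized before declaring:

    * anchored artifacts — a genotyping error of the reference sperm
      flips every informative sperm at one shared site.  Interior blips
      of that kind are removed by per-sperm majority smoothing; at the
      track ends a shared first- or last-site error survives as a
      terminal switch.  Its signature is a consensus whose supporting
      flips are dominated by one shared endpoint site *and* are terminal
      in each sperm's own track; a mid-chromosome crossover is never
      terminal, however tightly dropout-free data concentrate its
      flanking sites.  Such consensus is flagged, not declared.
    * crossover pairs — two reference crossovers within the tolerance
      make most sperm flip twice inside the window.  When most
      supporting sperm carry two flips, the two flip groups are declared
      as two positions (toggling twice restores phase on both sides and
      in between).
    """
    n_sperm = states.shape[1]
    mids: list[float] = []
    lefts: list[float] = []
    rights: list[float] = []
    sids: list[int] = []
    term_l: list[bool] = []
    term_r: list[bool] = []
    firsts = np.full(n_sperm, np.inf)
    lasts = np.full(n_sperm, -np.inf)
    for s in range(n_sperm):
        if s == exclude:  # the reference cannot witness its own crossover
            continue
        obs = np.flatnonzero(states[:, s] != MISSING)
        if obs.size == 0:
            continue
        firsts[s] = positions[obs[0]]
        lasts[s] = positions[obs[-1]]
        st = _majority_smooth(states[obs, s])
        for f in np.flatnonzero(st[:-1] != st[1:]):
            lefts.append(float(positions[obs[f]]))
            rights.append(float(positions[obs[f + 1]]))
            mids.append(0.5 * (lefts[-1] + rights[-1]))
            sids.append(s)
            term_l.append(f == 0)
            term_r.append(f + 1 == obs.size - 1)
    if not mids:
        return [], []
    order = np.argsort(mids)
    mids_arr = np.asarray(mids, dtype=float)[order]
    lefts_arr = np.asarray(lefts, dtype=float)[order]
    rights_arr = np.asarray(rights, dtype=float)[order]
    sids_arr = np.asarray(sids)[order]
    term_l_arr = np.asarray(term_l, dtype=bool)[order]
    term_r_arr = np.asarray(term_r, dtype=bool)[order]
    active = np.ones(len(mids_arr), dtype=bool)
    firsts_sorted = np.sort(firsts)
    lasts_sorted = np.sort(lasts)
    declared: list[float] = []
    flagged: list[dict] = []
    while True:
        candidates = []
        for i in np.flatnonzero(active):
            x = mids_arr[i]
            lo = int(np.searchsorted(mids_arr, x - tolerance_bp))
            hi = int(np.searchsorted(mids_arr, x + tolerance_bp, side="right"))
            members = np.flatnonzero(active[lo:hi]) + lo
            support = len(set(sids_arr[members]))
            eligible = int(
                np.searchsorted(firsts_sorted, x) - np.searchsorted(lasts_sorted, x)
            )
            if eligible <= 0:
                continue
            frac = support / eligible
            if frac >= consensus_fraction:
                candidates.append((frac, support, -x, tuple(members), eligible))
        if not candidates:
            break
        _frac, support, _negx, members, eligible = max(candidates)
        members = np.asarray(members)
        center = float(np.median(mids_arr[members]))
        per_sperm: dict[int, list[float]] = {}
        for j in members:
            per_sperm.setdefault(int(sids_arr[j]), []).append(float(mids_arr[j]))
        n_double = sum(1 for v in per_sperm.values() if len(v) >= 2)
        modal_left = max(np.unique(lefts_arr[members], return_counts=True)[1])
        modal_right = max(np.unique(rights_arr[members], return_counts=True)[1])
        n = len(members)
        anchored = (
            modal_left / n >= 0.8 and term_l_arr[members].mean() >= 0.5
        ) or (
            modal_right / n >= 0.8 and term_r_arr[members].mean() >= 0.5
        )
        if anchored:
            flagged.append(
                {"position": center, "n_sperm": support,
                 "n_eligible": eligible, "reason": "anchored_single_site"}
            )
        elif eligible < min_population:
            flagged.append(
                {"position": center, "n_sperm": support,
                 "n_eligible": eligible, "reason": "below_min_population"}
            )
        elif n_double / len(per_sperm) >= 0.5:
            left_pos = float(np.median([min(v) for v in per_sperm.values() if len(v) >= 2]))
            right_pos = float(np.median([max(v) for v in per_sperm.values() if len(v) >= 2]))
            declared.extend([left_pos, right_pos])
        else:
            declared.append(center)
        active[members] = False
    return sorted(declared), flagged


def correct_false_recombination(
    tracks: RelativeTracks,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    consensus_fraction: float = DEFAULT_CONSENSUS_FRACTION,
    tolerance_bp: float = DEFAULT_TOLERANCE_BP,
    min_population: int = DEFAULT_MIN_POPULATION,
) -> CorrectionResult:
    """Detect and undo the reference sperm's own crossovers.

    A crossover of the reference sperm makes every other sperm appear to
    recombine at the same position; such positions are found where at
    least ``consensus_fraction`` of the sperm with data on both sides
    carry a state flip spanning the position.  All states downstream of
    each declared position are toggled (recomputed from the raw states,
    not patched per event) and breakpoints are re-detected on the
    corrected tracks, whose same/different codes are thereafter absolute
    chromosome-level genotypes (H0 = the reference sperm's starting
    haplotype); the reference sperm's own corrected track carries exactly
    the declared events.  Candidates observed by fewer than
    ``min_population`` sperm are left uncorrected and flagged.  The
    operation is idempotent: on corrected tracks no position reaches
    consensus again.
    """
    pos_all = tracks.sites["pos"].to_numpy()
    ref_idx = tracks.sperm_ids.index(tracks.ref_id)
    reference_positions: dict[str, list[float]] = {}
    flagged: list[dict] = []
    for chrom in tracks.chromosomes():
        sl = tracks.chrom_slice(chrom)
        declared, chrom_flagged = _consensus_flip_regions(
            tracks.states[sl], pos_all[sl],
            consensus_fraction, tolerance_bp, min_population,
            exclude=ref_idx,
        )
        for f in chrom_flagged:
            flagged.append({"chrom": chrom, **f})
        reference_positions[chrom] = sorted(declared)

    corrected = tracks.states.copy()
    for chrom, positions in reference_positions.items():
        if not positions:
            continue
        sl = tracks.chrom_slice(chrom)
        parity = (np.searchsorted(np.asarray(positions), pos_all[sl]) % 2).astype(np.int8)
        block = corrected[sl]
        block[block != MISSING] ^= np.broadcast_to(parity[:, None], block.shape)[block != MISSING]
    out_tracks = replace(tracks, states=corrected, corrected=True)
    corrected_events = detect_all_breakpoints(out_tracks, window, min_support)
    return CorrectionResult(
        tracks=out_tracks,
        events=corrected_events,
        reference_positions=reference_positions,
        flagged_clusters=flagged,
    )


def filter_suspicious(
    events: dict[str, list[CrossoverEvent]],
    min_spacing_bp: float = DEFAULT_MIN_EVENT_SPACING_BP,
) -> tuple[dict[str, list[CrossoverEvent]], int]:
    """Drop crossover pairs in one sperm closer than ``min_spacing_bp``.

    Two switches a short physical distance apart in the same gamete are
    far more likely a gene-conversion tract or residual genotyping error
    than a genuine double crossover, so both members of such a pair are
    removed.
    """
    filtered: dict[str, list[CrossoverEvent]] = {}
    removed = 0
    for sid, evs in events.items():
        kept: list[CrossoverEvent] = []
        by_chrom: dict[str, list[CrossoverEvent]] = {}
        for ev in evs:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom_events in by_chrom.values():
            chrom_events.sort(key=lambda e: e.mid)
            i = 0
            while i < len(chrom_events):
                if (
                    i + 1 < len(chrom_events)
                    and chrom_events[i + 1].mid - chrom_events[i].mid < min_spacing_bp
                ):
                    removed += 2
                    i += 2
                else:
                    kept.append(chrom_events[i])
                    i += 1
        kept.sort(key=lambda e: (e.chrom, e.mid))
        filtered[sid] = kept
    return filtered, removed


def build_bin_map(
    tracks: RelativeTracks,
    events: dict[str, list[CrossoverEvent]],
    interval_bp: int = DEFAULT_INTERVAL_BP,
    chrom_lengths: dict[str, int] | None = None,
    reference_positions: dict[str, list[float]] | None = None,
) -> BinMap:
    """Merge 100-kb intervals into bins delimited by population crossovers.

    Every detected crossover midpoint is snapped to the nearest 100-kb
    grid line; bins are the maximal runs of intervals between snapped
    breakpoints, so adjacent bins differ in at least one sperm.  Each
    sperm's bin genotype comes from its own event-delimited segmentation
    (each segment labelled by the majority of its informative sites),
    evaluated over the sperm's sites in the bin — missing where the sperm
    has no informative site; a final pass re-merges adjacent bins whose
    genotype vectors came out identical.
    """
    if not tracks.corrected:
        raise ValueError("build_bin_map expects corrected tracks")
    pos_all = tracks.sites["pos"].to_numpy()
    bins_rows = []
    genotype_cols: list[np.ndarray] = []
    n_sperm = len(tracks.sperm_ids)
    for chrom in tracks.chromosomes():
        sl = tracks.chrom_slice(chrom)
        pos = pos_all[sl]
        if chrom_lengths and chrom in chrom_lengths:
            L = int(chrom_lengths[chrom])
        else:
            L = int(np.ceil(pos[-1] / interval_bp) * interval_bp)
        n_intervals = max(1, int(np.ceil(L / interval_bp)))
        mids = sorted(
            ev.mid for evs in events.values() for ev in evs if ev.chrom == chrom
        )
        cuts = sorted(
            {
                int(np.clip(round(m / interval_bp), 1, n_intervals - 1)) * interval_bp
                for m in mids
            }
            if n_intervals > 1
            else set()
        )
        edges = [0, *cuts, L]
        states = tracks.states[sl]
        # per-sperm step function: segment states between its own events,
        # each segment labelled by the majority of its informative sites
        step = np.full((len(pos), n_sperm), MISSING, dtype=np.int8)
        for j, sid in enumerate(tracks.sperm_ids):
            obs = np.flatnonzero(states[:, j] != MISSING)
            if obs.size == 0:
                continue
            mids = np.array(
                sorted(ev.mid for ev in events.get(sid, []) if ev.chrom == chrom)
            )
            seg_of_site = np.searchsorted(mids, pos[obs])
            st = states[obs, j]
            for k in range(len(mids) + 1):
                in_seg = seg_of_site == k
                if not in_seg.any():
                    continue
                ones = int((st[in_seg] == 1).sum())
                zeros = int(in_seg.sum()) - ones
                if ones > zeros:
                    seg_state = 1
                elif zeros > ones:
                    seg_state = 0
                else:
                    seg_state = int(st[in_seg][0])
                step[obs[in_seg], j] = seg_state
        for start, end in zip(edges[:-1], edges[1:]):
            in_bin = (pos - 1 >= start) & (pos - 1 < end)
            block = step[in_bin]
            geno = np.full(n_sperm, MISSING, dtype=np.int8)
            if block.size:
                ones = (block == 1).sum(axis=0)
                zeros = (block == 0).sum(axis=0)
                geno[ones > zeros] = 1
                geno[zeros > ones] = 0
            bins_rows.append({"chrom": chrom, "start": start, "end": end})
            genotype_cols.append(geno)
    genotypes = np.column_stack(genotype_cols) if genotype_cols else np.empty((n_sperm, 0), np.int8)

    # re-merge adjacent bins with identical genotype vectors
    keep: list[int] = []
    for i in range(len(bins_rows)):
        if (
            keep
            and bins_rows[i]["chrom"] == bins_rows[keep[-1]]["chrom"]
            and np.array_equal(genotypes[:, i], genotypes[:, keep[-1]])
        ):
            bins_rows[keep[-1]]["end"] = bins_rows[i]["end"]
        else:
            keep.append(i)
    bins = pd.DataFrame([bins_rows[i] for i in keep])
    bins["bin_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    return BinMap(
        bins=bins.reset_index(drop=True),
        sperm_ids=list(tracks.sperm_ids),
        genotypes=genotypes[:, keep],
        interval_bp=interval_bp,
        reference_positions=reference_positions,
    )


def count_crossovers(bin_map: BinMap) -> tuple[pd.Series, float]:
    """Per-sperm crossover counts over the bin map and their mean.

    A crossover is an H0<->H1 transition along a chromosome's bin
    sequence; missing bins are bridged (the comparison is against the last
    observed genotype).
    """
    counts = np.zeros(len(bin_map.sperm_ids), dtype=int)
    chrom_arr = bin_map.bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        g = bin_map.genotypes[:, idx]
        for s in range(g.shape[0]):
            row = g[s][g[s] != MISSING]
            if row.size > 1:
                counts[s] += int((row[1:] != row[:-1]).sum())
    series = pd.Series(counts, index=bin_map.sperm_ids, name="n_crossovers")
    return series, float(series.mean())


def emit_haplotype_markers(
    bin_map: BinMap,
    matrix: GameteMatrix,
    min_marker_confidence: float = DEFAULT_MIN_MARKER_CONFIDENCE,
) -> tuple[pd.DataFrame, dict]:
    """Phase every het site into hap0/hap1 alleles via its bin's genotypes.

    Within a bin, sperm assigned H0 vote with their observed allele for
    the hap0 allele of each site (and H1 sperm symmetrically); the
    assignment is the majority pattern, its confidence the fraction of
    informative votes consistent with it.  Sites with confidence below
    ``min_marker_confidence``, or in bins with no informative sperm, are
    dropped and reported.  Because bin genotypes are chromosome-level
    (H0 = reference sperm's starting haplotype), marker phase is
    consistent across bins of a chromosome.
    """
    sites = matrix.sites
    n_sites = len(sites)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    rows = []
    n_unphased = 0
    n_low_conf = 0
    bin_chrom = bin_map.bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        site_idx = np.flatnonzero(chrom_arr == chrom)
        bidx = np.flatnonzero(bin_chrom == chrom)
        if bidx.size == 0:
            n_unphased += site_idx.size
            continue
        starts = bin_map.bins["start"].to_numpy()[bidx]
        ends = bin_map.bins["end"].to_numpy()[bidx]
        which = np.searchsorted(starts, pos_arr[site_idx] - 1, side="right") - 1
        which = np.clip(which, 0, len(bidx) - 1)
        in_span = (pos_arr[site_idx] - 1 >= starts[which]) & (pos_arr[site_idx] - 1 < ends[which])
        calls = matrix.calls[site_idx]  # (n_chrom_sites, n_sperm)
        G = bin_map.genotypes[:, bidx[which]].T  # (n_chrom_sites, n_sperm)
        valid = (calls != MISSING) & (G != MISSING) & in_span[:, None]
        votes_a = ((calls == G) & valid).sum(axis=1)  # hap0 carries allele_a
        votes_b = ((calls != G) & valid).sum(axis=1)
        total = votes_a + votes_b
        for k, i in enumerate(site_idx):
            if total[k] == 0:
                n_unphased += 1
                continue
            hap0_is_a = votes_a[k] >= votes_b[k]
            conf = max(votes_a[k], votes_b[k]) / total[k]
            if conf < min_marker_confidence:
                n_low_conf += 1
                continue
            a = sites["allele_a"].iat[i]
            b = sites["allele_b"].iat[i]
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos_arr[i]),
                    "hap0": a if hap0_is_a else b,
                    "hap1": b if hap0_is_a else a,
                    "bin_id": bin_map.bins["bin_id"].iat[bidx[which[k]]],
                    "confidence": float(conf),
                }
            )
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "hap0", "hap1", "bin_id", "confidence"])
    report = {
        "n_sites": n_sites,
        "n_phased": len(markers),
        "n_unphased_no_info": n_unphased,
        "n_dropped_low_confidence": n_low_conf,
    }
    return markers, report


def phase_pipeline(
    matrix: GameteMatrix,
    ref_id: str,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    consensus_fraction: float = DEFAULT_CONSENSUS_FRACTION,
    tolerance_bp: float = DEFAULT_TOLERANCE_BP,
    min_population: int = DEFAULT_MIN_POPULATION,
    interval_bp: int = DEFAULT_INTERVAL_BP,
    min_event_spacing_bp: float = DEFAULT_MIN_EVENT_SPACING_BP,
    min_marker_confidence: float = DEFAULT_MIN_MARKER_CONFIDENCE,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[BinMap, pd.DataFrame, CorrectionResult, dict]:
    """End-to-end phasing: relative genotyping through marker emission."""
    tracks = genotype_against_reference(matrix, ref_id)
    correction = correct_false_recombination(
        tracks, window, min_support, consensus_fraction, tolerance_bp, min_population
    )
    events, n_suspicious = filter_suspicious(correction.events, min_event_spacing_bp)
    bin_map = build_bin_map(
        correction.tracks,
        events,
        interval_bp,
        chrom_lengths,
        reference_positions=correction.reference_positions,
    )
    markers, marker_report = emit_haplotype_markers(bin_map, matrix, min_marker_confidence)
    marker_report["n_suspicious_events_removed"] = n_suspicious
    return bin_map, markers, correction, marker_report
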