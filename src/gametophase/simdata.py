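"""Synthetic donors, meioses, sperm genotypes, long reads and phenotypes.

This module generates data with the statistical structure the phasing
pipeline assumes, and carries the ground truth alongside so every stage can
be scored: a diploid donor with two parental haplotypes over a
multi-chromosome genome, Poisson crossovers per chromosome (optionally
truncated at one to emulate the obligate chiasma), heavy per-sperm dropout
of heterozygous sites as produced by single-cell whole-genome amplification
(about half the sites per sperm, with wide cell-to-cell variation),
genotyping error, an X/Y-bearing split near 1:1, haplotype-tagged long
reads, and a graded motility-like phenotype with an optional planted QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gametematrix import GameteMatrix, MISSING

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated single-sperm sequencing experiment.

    Defaults are scaled-down analogues of a real boar experiment: 19
    autosomes, 102 sperm, ~50% het-site dropout per sperm, about one
    crossover per chromosome per meiosis (18 genome-wide over 19
    autosomes) and roughly one informative het site per 10 kb.
    """

    n_chromosomes: int = 19
    chrom_length_bp: int = 10_000_000
    het_density: float = 1e-4  # sites per bp
    n_sperm: int = 102
    mean_crossovers_per_chrom: float = 18.0 / 19.0
    obligate_crossover: bool = False
    dropout_rate: float = 0.5
    genotype_error_rate: float = 0.01
    frac_y_bearing: float = 0.5
    read_length_bp: int = 15_000
    read_depth: float = 4.0
    donor_depth: int = 30
    qtl_position: tuple[str, int] | None = None
    qtl_effect: float = 0.0
    per_sperm_coverage_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1 or self.n_sperm < 1:
            raise ConfigurationError("counts and lengths must be positive")
        if self.het_density <= 0:
            raise ConfigurationError("het_density must be positive")
        if self.mean_crossovers_per_chrom < 0:
            raise ConfigurationError("mean_crossovers_per_chrom must be >= 0")
        for name in ("dropout_rate", "genotype_error_rate", "frac_y_bearing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.read_length_bp < 1 or self.read_depth < 0:
            raise ConfigurationError("read parameters must be positive")
        if self.read_length_bp > self.chrom_length_bp:
            raise ConfigurationError("read_length_bp exceeds chromosome length")
        if self.per_sperm_coverage_range is not None:
            lo, hi = self.per_sperm_coverage_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError("per_sperm_coverage_range must be ordered in [0, 1]")
        if self.qtl_position is not None:
            chrom, pos = self.qtl_position
            if chrom not in self.chrom_names() or not 1 <= pos <= self.chrom_length_bp:
                raise ConfigurationError("qtl_position outside the simulated genome")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic child generator for a named simulation stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``origins`` (filled by :func:`simulate_meiosis`) is the per-sperm
    haplotype-origin code (0/1) at every het site; ``hap0_is_a`` says which
    of the site's two observable alleles (allele_a = REF, allele_b = ALT)
    parental haplotype 0 carries, so truth call codes are
    ``origin XOR (1 - hap0_is_a)``.
    """

    config: SimConfig
    sites: pd.DataFrame  # chrom,pos,allele_a,allele_b,depth_a,depth_b,quality
    hap0_is_a: np.ndarray  # bool per site
    crossovers: list[dict[str, np.ndarray]] | None = None  # per sperm, bp positions
    start_phase: np.ndarray | None = None  # (n_sperm, n_chrom) in {0,1}
    origins: np.ndarray | None = None  # (n_sperm, n_sites) in {0,1}
    sex: np.ndarray | None = None  # "X"/"Y" per sperm
    sperm_ids: list[str] = field(default_factory=list)
    phenotype_latent: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0)

    def truth_codes(self) -> np.ndarray:
        """Noiseless call codes (n_sites, n_sperm): 0 = allele_a, 1 = allele_b."""
        if self.origins is None:
            raise ValueError("meioses not simulated yet")
        flip = (~self.hap0_is_a).astype(np.int8)
        return (self.origins.T.astype(np.int8) ^ flip[:, None]).astype(np.int8)

    def origin_at(self, sperm: int, chrom: str, pos: int) -> int:
        """Haplotype origin of one sperm at an arbitrary coordinate."""
        if self.crossovers is None or self.start_phase is None:
            raise ValueError("meioses not simulated yet")
        ci = self.config.chrom_names().index(chrom)
        xs = self.crossovers[sperm].get(chrom, np.empty(0))
        return int(self.start_phase[sperm, ci]) ^ (int(np.searchsorted(xs, pos)) % 2)

    def haplotype_allele(self, site_row: int, haplotype: int) -> str:
        a = self.sites["allele_a"].iat[site_row]
        b = self.sites["allele_b"].iat[site_row]
        if haplotype == 0:
            return a if self.hap0_is_a[site_row] else b
        return b if self.hap0_is_a[site_row] else a

    def chromosome_sequence(self, chrom: str, haplotype: int | None = None) -> str:
        """Reference (or one parental haplotype's) sequence of a chromosome.

        Generated deterministically from the seed on demand; the reference
        carries allele_a (REF) at every het site, haplotypes substitute
        their own allele.
        """
        names = self.config.chrom_names()
        ci = names.index(chrom)
        rng = self.config.rng(7, ci)
        seq = rng.integers(0, 4, self.config.chrom_length_bp)
        arr = _BASES[seq]
        sl = self.site_slice(chrom)
        pos0 = self.sites["pos"].to_numpy()[sl] - 1
        if haplotype is None:
            arr[pos0] = self.sites["allele_a"].to_numpy()[sl]
        else:
            alleles = [
                self.haplotype_allele(i, haplotype) for i in range(sl.start, sl.stop)
            ]
            arr[pos0] = alleles
        return "".join(arr)


@dataclass
class SimRead:
    read_id: str
    chrom: str
    start: int  # 1-based
    haplotype: int
    sequence: str

    @property
    def description(self) -> str:
        return f"hap={self.haplotype} chrom={self.chrom} start={self.start}"


def simulate_donor(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw the donor's het-site table and parental allele assignment.

    Sites are placed uniformly at ``het_density`` per chromosome with
    distinct positions; each site receives two distinct alleles, per-allele
    sequencing depths around ``donor_depth`` (binomially split, as expected
    for a balanced heterozygote) and a phred-like site quality.
    """
    rng = config.rng(1)
    n_per_chrom = int(round(config.chrom_length_bp * config.het_density))
    if n_per_chrom < 1:
        raise ConfigurationError("het_density too low: no sites per chromosome")
    rows = []
    for chrom in config.chrom_names():
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), size=n_per_chrom, replace=False)
        )
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(rows, ignore_index=True)
    n = len(sites)
    a_idx = rng.integers(0, 4, n)
    b_idx = (a_idx + rng.integers(1, 4, n)) % 4
    total_depth = rng.poisson(config.donor_depth, n).clip(min=2)
    depth_a = rng.binomial(total_depth, 0.5)
    sites["allele_a"] = _BASES[a_idx]
    sites["allele_b"] = _BASES[b_idx]
    sites["depth_a"] = depth_a
    sites["depth_b"] = total_depth - depth_a
    sites["quality"] = np.round(rng.normal(60.0, 10.0, n).clip(min=1.0), 1)
    hap0_is_a = rng.random(n) < 0.5
    truth = SimTruth(config=config, sites=sites, hap0_is_a=hap0_is_a)
    return sites, truth


def _crossover_count(rng: np.random.Generator, mean: float, obligate: bool) -> int:
    k = rng.poisson(mean)
    if obligate:
        while k == 0:  # zero-truncated Poisson
            k = rng.poisson(mean)
    return int(k)


def simulate_meiosis(truth: SimTruth, config: SimConfig | None = None) -> SimTruth:
    """Fill per-sperm crossover positions, haplotype-origin tracks and sex.

    Crossover counts per chromosome are Poisson with the configured mean
    (zero-truncated when the obligate-crossover flag is set); breakpoints
    fall uniformly on the chromosome and the origin track alternates at
    each breakpoint starting from a fair random parental phase.  No
    crossover interference is modelled.
    """
    config = config or truth.config
    rng = config.rng(2)
    names = config.chrom_names()
    n_sperm, n_chrom = config.n_sperm, config.n_chromosomes
    truth.sperm_ids = [f"s{i + 1:03d}" for i in range(n_sperm)]
    truth.start_phase = rng.integers(0, 2, (n_sperm, n_chrom)).astype(np.int8)
    truth.sex = np.where(rng.random(n_sperm) < config.frac_y_bearing, "Y", "X")
    truth.crossovers = []
    positions = truth.sites["pos"].to_numpy()
    origins = np.empty((n_sperm, truth.n_sites), dtype=np.int8)
    slices = {c: truth.site_slice(c) for c in names}
    for s in range(n_sperm):
        per_chrom: dict[str, np.ndarray] = {}
        for ci, chrom in enumerate(names):
            k = _crossover_count(rng, config.mean_crossovers_per_chrom, config.obligate_crossover)
            xs = np.sort(rng.uniform(1, config.chrom_length_bp, k)) if k else np.empty(0)
            per_chrom[chrom] = xs
            sl = slices[chrom]
            n_switch = np.searchsorted(xs, positions[sl])
            origins[s, sl] = (truth.start_phase[s, ci] + n_switch) % 2
        truth.crossovers.append(per_chrom)
    truth.origins = origins
    return truth


def simulate_sperm_calls(truth: SimTruth, config: SimConfig | None = None) -> GameteMatrix:
    """Observe each het site in each sperm through dropout and error.

    Each sperm sees each site independently with probability
    ``1 - dropout_rate`` (or with a per-sperm coverage drawn uniformly from
    ``per_sperm_coverage_range`` when set, approximating amplification-bias
    variation between cells); observed calls equal the allele of the
    sperm's haplotype of origin, flipped with ``genotype_error_rate``.
    """
    config = config or truth.config
    if truth.origins is None:
        raise ValueError("run simulate_meiosis first")
    rng = config.rng(3)
    codes = truth.truth_codes()  # (n_sites, n_sperm)
    n_sites, n_sperm = codes.shape
    if config.per_sperm_coverage_range is not None:
        lo, hi = config.per_sperm_coverage_range
        coverage = rng.uniform(lo, hi, n_sperm)
    else:
        coverage = np.full(n_sperm, 1.0 - config.dropout_rate)
    observed = rng.random((n_sites, n_sperm)) < coverage[None, :]
    flips = rng.random((n_sites, n_sperm)) < config.genotype_error_rate
    calls = np.where(observed, codes ^ (flips & observed), MISSING).astype(np.int8)
    site_cols = truth.sites[["chrom", "pos", "allele_a", "allele_b"]].copy()
    return GameteMatrix(site_cols, list(truth.sperm_ids), calls)


def simulate_long_reads(
    truth: SimTruth,
    config: SimConfig | None = None,
    chroms: Sequence[str] | None = None,
) -> list[SimRead]:
    """Haplotype-tagged error-free long reads at the configured depth.

    Each read is drawn from one parental haplotype (fair coin), starts
    uniformly on the chromosome, has fixed length and carries that
    haplotype's alleles at every covered het site.  The tag records the
    true haplotype for downstream scoring of read partitioning.
    """
    config = config or truth.config
    rng = config.rng(4)
    chroms = list(chroms) if chroms is not None else config.chrom_names()
    reads: list[SimRead] = []
    L, rl = config.chrom_length_bp, config.read_length_bp
    for chrom in chroms:
        hap_seqs = {h: truth.chromosome_sequence(chrom, h) for h in (0, 1)}
        n_reads = int(round(config.read_depth * L / rl))
        haps = rng.integers(0, 2, n_reads)
        starts = rng.integers(1, L - rl + 2, n_reads)
        for i, (h, st) in enumerate(zip(haps, starts)):
            seq = hap_seqs[int(h)][st - 1 : st - 1 + rl]
            reads.append(SimRead(f"{chrom}_read{i + 1:05d}", chrom, int(st), int(h), seq))
    return reads


def simulate_phenotypes(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Graded (1-3) motility-like phenotype with an optional planted QTL.

    The latent value is ``qtl_effect x (haplotype at qtl_position)`` plus
    standard-normal noise; latent-value tertiles map to grades 1-3 with
    grade 1 the best.  Without a QTL the grades are pure noise.
    """
    config = config or truth.config
    if truth.origins is None:
        raise ValueError("run simulate_meiosis first")
    rng = config.rng(5)
    n = config.n_sperm
    latent = rng.normal(0.0, 1.0, n)
    if config.qtl_position is not None:
        chrom, pos = config.qtl_position
        g = np.array([truth.origin_at(s, chrom, pos) for s in range(n)])
        latent = latent + config.qtl_effect * g
    order = np.argsort(-latent, kind="stable")
    grades = np.empty(n, dtype=int)
    for grade, chunk in enumerate(np.array_split(order, 3), start=1):
        grades[chunk] = grade
    truth.phenotype_latent = latent
    return pd.DataFrame({"sperm_id": truth.sperm_ids, "grade": grades, "latent": latent})


def simulate_coverage_table(truth: SimTruth, noise_sd: float = 0.05) -> pd.DataFrame:
    """Per-sperm normalized fold-coverage over autosome/X/Y scaffold classes.

    Emulates the input of X/Y sorting: a Y-bearing sperm has ~1x of the
    haploid autosomal coverage on Y-candidate scaffolds and background on
    X, and vice versa.
    """
    if truth.sex is None:
        raise ValueError("run simulate_meiosis first")
    rng = truth.config.rng(6)
    n = len(truth.sex)
    is_y = truth.sex == "Y"
    auto = rng.normal(1.0, noise_sd, n).clip(min=0.1)
    y_cov = np.where(is_y, rng.normal(0.95, noise_sd, n), rng.normal(0.02, 0.01, n)).clip(min=0.0)
    x_cov = np.where(~is_y, rng.normal(0.95, noise_sd, n), rng.normal(0.02, 0.01, n)).clip(min=0.0)
    return pd.DataFrame(
        {"sperm_id": truth.sperm_ids, "y_cov": y_cov, "x_cov": x_cov, "auto_cov": auto}
    )


# ---------------------------------------------------------------------------
# truth-based scoring helpers


def marker_accuracy(markers: pd.DataFrame, truth: SimTruth) -> float:
    """Fraction of phased sites matching truth after per-chromosome swap.

    The hap0/hap1 labels of inferred markers are arbitrary per chromosome,
    so each chromosome is scored under its better of the two label
    assignments and the result is the site-weighted average.
    """
    t = truth.sites[["chrom", "pos"]].copy()
    t["true_hap0"] = [
        truth.haplotype_allele(i, 0) for i in range(truth.n_sites)
    ]
    merged = markers.merge(t, on=["chrom", "pos"], how="inner")
    if merged.empty:
        return 0.0
    n_match = 0
    for chrom, sub in merged.groupby("chrom", sort=False):
        same = int((sub["hap0"] == sub["true_hap0"]).sum())
        n_match += max(same, len(sub) - same)
    return n_match / len(merged)


def crossover_recovery(
    events: dict[str, list],
    truth: SimTruth,
    tolerance_bp: float = 100_000.0,
) -> dict:
    """Match detected crossover events against true breakpoints.

    A true crossover is recovered when the same sperm has a detected
    event whose midpoint lies within ``tolerance_bp``; each detected
    event may claim one true crossover (greedy nearest matching).
    Returns recall, precision and the count-exact fraction of sperm.
    """
    if truth.crossovers is None:
        raise ValueError("run simulate_meiosis first")
    n_true = n_recovered = n_detected = n_matched_det = 0
    n_count_exact = 0
    for s, sid in enumerate(truth.sperm_ids):
        evs = events.get(sid, [])
        n_detected += len(evs)
        true_total = det_total = 0
        for chrom, xs in truth.crossovers[s].items():
            mids = sorted(ev.mid for ev in evs if ev.chrom == chrom)
            true_total += len(xs)
            det_total += len(mids)
            n_true += len(xs)
            used = [False] * len(mids)
            for x in xs:
                best, best_d = None, tolerance_bp
                for i, m in enumerate(mids):
                    if not used[i] and abs(m - x) <= best_d:
                        best, best_d = i, abs(m - x)
                if best is not None:
                    used[best] = True
                    n_recovered += 1
                    n_matched_det += 1
        if true_total == det_total:
            n_count_exact += 1
    return {
        "recall": n_recovered / n_true if n_true else 1.0,
        "precision": n_matched_det / n_detected if n_detected else 1.0,
        "count_exact_fraction": n_count_exact / len(truth.sperm_ids),
        "n_true": n_true,
        "n_detected": n_detected,
    }


def reference_event_recovery(
    reference_positions: dict[str, list[float]],
    truth: SimTruth,
    ref_id: str,
    tolerance_bp: float = 200_000.0,
    min_spacing_bp: float = 0.0,
    flank_positions: dict[str, np.ndarray] | None = None,
    min_flank_sites: int = 2,
) -> dict:
    """Score declared reference-sperm crossovers against identifiable truth.

    Two classes of true crossovers are excluded from the reference truth
    before matching because no population-consensus method can recover
    them: pairs closer than ``min_spacing_bp`` (for most sperm a
    sub-resolution double crossover flips at most one marker and is
    indistinguishable from genotyping error — the pipeline's
    suspicious-pair rule discards such pairs for every sperm, the
    reference included), and crossovers with fewer than
    ``min_flank_sites`` reference-informative het sites on a flank
    (``flank_positions`` maps chromosome to the sorted positions where
    the reference sperm has calls; with a single flanking site, a
    crossover is indistinguishable from an error at that site).
    """
    if truth.crossovers is None:
        raise ValueError("run simulate_meiosis first")
    s = truth.sperm_ids.index(ref_id)
    n_true = n_declared = n_matched = 0
    for chrom in truth.config.chrom_names():
        xs = sorted(float(x) for x in truth.crossovers[s].get(chrom, []))
        if min_spacing_bp > 0:
            kept: list[float] = []
            i = 0
            while i < len(xs):
                if i + 1 < len(xs) and xs[i + 1] - xs[i] < min_spacing_bp:
                    i += 2
                else:
                    kept.append(xs[i])
                    i += 1
            xs = kept
        if flank_positions is not None:
            p = np.asarray(flank_positions.get(chrom, []), dtype=float)
            xs = [
                x
                for x in xs
                if (p < x).sum() >= min_flank_sites
                and (p > x).sum() >= min_flank_sites
            ]
        declared = list(reference_positions.get(chrom, []))
        n_true += len(xs)
        n_declared += len(declared)
        used = [False] * len(declared)
        for x in xs:
            for i, d in enumerate(declared):
                if not used[i] and abs(d - x) <= tolerance_bp:
                    used[i] = True
                    n_matched += 1
                    break
    return {
        "n_true": n_true,
        "n_declared": n_declared,
        "n_matched": n_matched,
        "exact": n_true == n_declared == n_matched,
    }


# ---------------------------------------------------------------------------
# X/Y read-selection scenario


@dataclass
class XYScenario:
    """Synthetic genome and read sets for Y-specific read selection.

    The Y chromosome carries a segment copied from the X at the configured
    identity (the X/Y pseudo-homologous region that confounds naive read
    selection); short reads come from haploid Y-bearing sperm (autosomes +
    Y) with alignment classes as they would appear against an assembly
    lacking the Y, long reads come from the diploid donor.
    """

    autosome_seq: str
    x_seq: str
    y_seq: str
    homology_bp: int
    short_reads: pd.DataFrame  # read_id, sperm_id, origin, target_class, sequence
    long_reads: pd.DataFrame  # read_id, origin, sequence

    @property
    def assembly_without_y(self) -> list[str]:
        return [self.autosome_seq, self.x_seq]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    shift = rng.integers(1, 4, hit.size)
    idx = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(idx + shift) % 4]
    return "".join(arr)


def simulate_xy_scenario(
    seed: int,
    autosome_bp: int = 100_000,
    x_bp: int = 60_000,
    y_bp: int = 40_000,
    homology_bp: int = 4_000,
    identity: float = 0.95,
    n_y_sperm: int = 8,
    short_read_len: int = 150,
    short_depth: float = 10.0,
    unaligned_rate: float = 0.01,
    long_read_len: int = 2_000,
    n_long_reads: int = 400,
) -> XYScenario:
    """Build the planted-homology scenario used to score Y read selection."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    autosome = _random_seq(rng, autosome_bp)
    x_seq = _random_seq(rng, x_bp)
    y_seq = _random_seq(rng, y_bp)
    y_seq = _mutate(rng, x_seq[:homology_bp], 1.0 - identity) + y_seq[homology_bp:]

    # short reads from haploid Y-bearing sperm: one autosome copy + Y
    sources = [("autosome", autosome), ("Y", y_seq)]
    weights = np.array([len(autosome), len(y_seq)], dtype=float)
    weights /= weights.sum()
    n_short = int(round(short_depth * (autosome_bp + y_bp) / short_read_len))
    rows = []
    for i in range(n_short):
        origin, seq = sources[rng.choice(len(sources), p=weights)]
        start = int(rng.integers(0, len(seq) - short_read_len + 1))
        read = seq[start : start + short_read_len]
        if origin == "autosome":
            cls = "unaligned" if rng.random() < unaligned_rate else "autosome"
        else:  # Y is absent from the assembly; the homologous head maps to X
            cls = "X" if start + short_read_len <= homology_bp else "unaligned"
        rows.append(
            {
                "read_id": f"sr{i:05d}",
                "sperm_id": f"y{int(rng.integers(0, n_y_sperm)) + 1:02d}",
                "origin": origin,
                "target_class": cls,
                "sequence": read,
            }
        )
    short_reads = pd.DataFrame(rows)

    # long reads from the diploid donor: 2x autosomes, 1x X, 1x Y
    lsources = [("autosome", autosome), ("X", x_seq), ("Y", y_seq)]
    lweights = np.array([2.0 * len(autosome), float(len(x_seq)), float(len(y_seq))])
    lweights /= lweights.sum()
    lrows = []
    for i in range(n_long_reads):
        origin, seq = lsources[rng.choice(len(lsources), p=lweights)]
        start = int(rng.integers(0, len(seq) - long_read_len + 1))
        lrows.append(
            {
                "read_id": f"lr{i:05d}",
                "origin": origin,
                "sequence": seq[start : start + long_read_len],
            }
        )
    long_reads = pd.DataFrame(lrows)
    return XYScenario(autosome, x_seq, y_seq, homology_bp, short_reads, long_reads)
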