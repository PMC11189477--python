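"""Haplotype partitioning of long reads using phased marker probes.

Each phased het site yields two short probes (the site's hap0 and hap1
allele centered in its flanking reference sequence); long reads are
classified by exact probe matches on either strand.  HiFi-grade accuracy
makes exact 21-mer matching an adequate stand-in for alignment at this
scale.  Reads that cannot be classified are duplicated into both groups
so each group remains a complete read set for assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_FLANK_BP = 10
DEFAULT_MIN_PROBE_LEN = 15
DEFAULT_MIN_MARGIN = 1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeSet:
    """Exact-match probe index: probe sequence -> (chrom, marker pos, hap).

    Probes of several lengths can coexist (markers near contig ends get
    truncated probes); ``by_length`` groups them so reads are scanned once
    per distinct length.  Probes whose sequence collides between markers
    or haplotypes are dropped as ambiguous.
    """

    by_length: dict[int, dict[str, tuple[str, int, int]]] = field(default_factory=dict)
    n_markers: int = 0
    n_skipped: int = 0
    n_ambiguous: int = 0

    def add(self, probe: str, chrom: str, pos: int, hap: int) -> None:
        table = self.by_length.setdefault(len(probe), {})
        for variant in (probe, revcomp(probe)):
            if variant not in table:
                table[variant] = (chrom, pos, hap)
            elif table[variant] is not None and table[variant] != (chrom, pos, hap):
                table[variant] = None  # collision: ambiguous probe, never counted
                self.n_ambiguous += 1


@dataclass
class ReadAssignment:
    read_id: str
    hap0_hits: int
    hap1_hits: int
    markers_covered: int
    group: str  # "hap0" | "hap1" | "both"


def index_markers(
    markers: pd.DataFrame,
    reference: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
    min_probe_len: int = DEFAULT_MIN_PROBE_LEN,
) -> ProbeSet:
    """Build hap0/hap1 probes of length ``2*flank_bp + 1`` per marker.

    Probes center the marker allele in its flanking reference sequence;
    probes truncated by a contig end are kept when at least
    ``min_probe_len`` long, probes containing ambiguous bases and markers
    outside the reference are skipped and counted.
    """
    probes = ProbeSet()
    min_probe_len = min(min_probe_len, 2 * flank_bp + 1)
    for row in markers.itertuples(index=False):
        seq = reference.get(row.chrom)
        p0 = row.pos - 1
        if seq is None or not 0 <= p0 < len(seq):
            probes.n_skipped += 1
            continue
        lo = max(0, p0 - flank_bp)
        hi = min(len(seq), p0 + flank_bp + 1)
        if hi - lo < min_probe_len:
            probes.n_skipped += 1
            continue
        left, right = seq[lo:p0], seq[p0 + 1 : hi]
        if set(left + right) - _UNAMBIGUOUS or {row.hap0, row.hap1} - _UNAMBIGUOUS:
            probes.n_skipped += 1
            continue
        probes.add(left + row.hap0 + right, row.chrom, int(row.pos), 0)
        probes.add(left + row.hap1 + right, row.chrom, int(row.pos), 1)
        probes.n_markers += 1
    return probes


def classify_read(
    read_id: str,
    sequence: str,
    probes: ProbeSet,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> ReadAssignment:
    """Assign one read to hap0/hap1 by distinct marker probe hits.

    The read goes to hap0 when ``hap0_hits - hap1_hits >= min_margin``
    (hap1 symmetrically) and to both groups otherwise — including empty
    reads, reads covering no marker, ties within the margin, and reads
    hitting markers of more than one chromosome (likely chimeras).
    """
    seq = sequence.upper()
    hits: dict[tuple[str, int], set[int]] = {}
    chroms: set[str] = set()
    for length, table in probes.by_length.items():
        if len(seq) < length:
            continue
        for i in range(len(seq) - length + 1):
            entry = table.get(seq[i : i + length])
            if entry is None:
                continue
            chrom, pos, hap = entry
            hits.setdefault((chrom, pos), set()).add(hap)
            chroms.add(chrom)
    # a marker matched by both its allele probes is self-contradictory
    hap0 = sum(1 for h in hits.values() if h == {0})
    hap1 = sum(1 for h in hits.values() if h == {1})
    if len(chroms) > 1:
        group = "both"
    elif hap0 - hap1 >= min_margin:
        group = "hap0"
    elif hap1 - hap0 >= min_margin:
        group = "hap1"
    else:
        group = "both"
    return ReadAssignment(read_id, hap0, hap1, len(hits), group)


def partition_reads(
    reads: Iterable[tuple[str, str]],
    probes: ProbeSet,
    min_margin: int = DEFAULT_MIN_MARGIN,
    genome_size_bp: int | None = None,
) -> tuple[list[str], list[str], pd.DataFrame, dict]:
    """Split reads into two haplotype groups; unclassified go to both.

    ``reads`` yields (read_id, sequence).  Returns the two groups' read id
    lists, the per-read assignment table and a report with read/base
    counts per group (and fold-coverage when ``genome_size_bp`` given).
    """
    group0: list[str] = []
    group1: list[str] = []
    rows = []
    bases = {"hap0": 0, "hap1": 0}
    for read_id, seq in reads:
        a = classify_read(read_id, seq, probes, min_margin)
        rows.append(a)
        if a.group in ("hap0", "both"):
            group0.append(read_id)
            bases["hap0"] += len(seq)
        if a.group in ("hap1", "both"):
            group1.append(read_id)
            bases["hap1"] += len(seq)
    table = pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "hap0_hits": a.hap0_hits,
                "hap1_hits": a.hap1_hits,
                "markers_covered": a.markers_covered,
                "group": a.group,
            }
            for a in rows
        ]
    )
    report = {
        "n_reads": len(rows),
        "n_hap0": int((table["group"] == "hap0").sum()) if len(rows) else 0,
        "n_hap1": int((table["group"] == "hap1").sum()) if len(rows) else 0,
        "n_both": int((table["group"] == "both").sum()) if len(rows) else 0,
        "bases_group0": bases["hap0"],
        "bases_group1": bases["hap1"],
    }
    if genome_size_bp:
        report["depth_group0"] = bases["hap0"] / genome_size_bp
        report["depth_group1"] = bases["hap1"] / genome_size_bp
    return group0, group1, table, report
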