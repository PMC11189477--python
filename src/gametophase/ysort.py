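"""X/Y sperm classification and Y-specific read selection.

A sperm is haploid, so a Y-bearing cell shows ~1x of its autosomal
coverage on Y-candidate scaffolds and background on the X (and vice
versa); that ratio classifies cells.  Short reads of Y-bearing sperm that
do not align to autosomes are Y-specific; long reads are rescued by
k-mer sharing with that short-read set and then purged of anything that
matches the rest of the assembly (autosomes and X), which removes reads
from X/Y homologous regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .readbin import revcomp

DEFAULT_MIN_RATIO = 0.3
DEFAULT_K = 31
DEFAULT_MIN_SHARED = 10


@dataclass(frozen=True)
class SexCall:
    sperm_id: str
    y_cov: float
    x_cov: float
    auto_cov: float
    call: str  # "Y-bearing" | "X-bearing" | "ambiguous"


def call_sex(coverage: pd.DataFrame, min_ratio: float = DEFAULT_MIN_RATIO) -> pd.DataFrame:
    """Classify sperm as X- or Y-bearing from scaffold-class coverage.

    Coverages are first normalized by each sperm's autosomal mean; a cell
    is Y-bearing when its normalized Y coverage is at least ``min_ratio``
    and its X coverage below it (X-bearing symmetrically), otherwise
    ambiguous.  Cells with zero autosomal coverage are ambiguous.
    """
    calls = []
    for row in coverage.itertuples(index=False):
        if row.auto_cov <= 0:
            call = "ambiguous"
        else:
            y = row.y_cov / row.auto_cov
            x = row.x_cov / row.auto_cov
            if y >= min_ratio and x < min_ratio:
                call = "Y-bearing"
            elif x >= min_ratio and y < min_ratio:
                call = "X-bearing"
            else:
                call = "ambiguous"
        calls.append(call)
    out = coverage[["sperm_id", "y_cov", "x_cov", "auto_cov"]].copy()
    out["call"] = calls
    return out


def select_y_short_reads(
    alignments: pd.DataFrame,
    sex_calls: pd.DataFrame,
    autosome_classes: Sequence[str] = ("autosome",),
) -> tuple[pd.DataFrame, dict]:
    """Keep reads of Y-bearing sperm that do not align to autosomes.

    ``alignments`` needs columns ``read_id, sperm_id, target_class``
    (unaligned reads use class ``"unaligned"``); reads hitting any class
    in ``autosome_classes`` are removed, everything else from Y-bearing
    cells — including unaligned reads — is kept.
    """
    y_sperm = set(sex_calls.loc[sex_calls["call"] == "Y-bearing", "sperm_id"])
    from_y = alignments["sperm_id"].isin(y_sperm)
    autosomal = alignments["target_class"].isin(set(autosome_classes))
    kept = alignments[from_y & ~autosomal].copy()
    report = {
        "n_input": len(alignments),
        "n_from_y_sperm": int(from_y.sum()),
        "n_removed_autosomal": int((from_y & autosomal).sum()),
        "n_kept": len(kept),
    }
    return kept, report


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-canonical k-mer set (lexicographic min of k-mer/revcomp)."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def kmer_index(sequences: Iterable[str], k: int = DEFAULT_K) -> set[str]:
    index: set[str] = set()
    for seq in sequences:
        index |= canonical_kmers(seq, k)
    return index


def select_y_long_reads(
    long_reads: pd.DataFrame,
    y_short_kmers: set[str],
    exclusion_kmers: set[str] | None = None,
    k: int = DEFAULT_K,
    min_shared: int = DEFAULT_MIN_SHARED,
    exclusion_fraction: float = 0.25,
    min_excluded: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescue Y-candidate long reads by k-mer sharing, then purge homologs.

    A long read (columns ``read_id, sequence``) is a candidate when it
    shares at least ``min_shared`` distinct canonical k-mers with the
    Y-specific short-read set; a second pass drops candidates whose
    k-mers match ``exclusion_kmers`` — the assembly without the Y — at
    ``exclusion_fraction`` or more of the read (an alignment-like
    identity criterion: it removes autosomal stragglers and X reads
    wholesale, while a read that merely brushes an X/Y homologous
    segment, whose diverged sequence matches only a minority of k-mers,
    is kept).  Pass ``min_excluded`` to use an absolute count threshold
    instead.  Returns (kept reads, per-read score table).
    """
    scores = []
    for row in long_reads.itertuples(index=False):
        kmers = canonical_kmers(row.sequence, k)
        shared = len(kmers & y_short_kmers)
        excluded = len(kmers & exclusion_kmers) if exclusion_kmers is not None else 0
        cutoff = min_excluded if min_excluded is not None else max(
            1, int(np.ceil(exclusion_fraction * max(1, len(kmers))))
        )
        keep = shared >= min_shared and excluded < cutoff
        scores.append(
            {
                "read_id": row.read_id,
                "shared_y_kmers": shared,
                "excluded_kmers": excluded,
                "kept": keep,
            }
        )
    score_df = pd.DataFrame(scores)
    kept = long_reads[score_df["kept"].to_numpy()] if len(scores) else long_reads.iloc[:0]
    return kept.copy(), score_df
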