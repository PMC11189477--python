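"""Plain-text readers and writers for every pipeline artifact.

All intermediate files are documented text formats that round-trip
losslessly: sites as minimal VCF 4.2, the gamete matrix and per-sperm
calls as TSV, the bin map as a BED-like table plus a genotype matrix,
markers and maps as TSV, reads as FASTA/FASTQ (gzip-transparent).
Coordinates follow VCF convention (1-based inclusive) in site files and
BED convention (0-based half-open) in bin files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .gametematrix import GameteMatrix, MISSING
from .phasing import BinMap

_GENO_LABEL = {0: "H0", 1: "H1", MISSING: "NA"}
_GENO_CODE = {v: k for k, v in _GENO_LABEL.items()}


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF


def write_sites_vcf(sites: pd.DataFrame, path) -> None:
    """Write het sites as a minimal single-sample VCF 4.2 (QUAL, AD, GQ)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in dict.fromkeys(sites["chrom"]):
            sub = sites[sites["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdonor\n")
        for row in sites.itertuples(index=False):
            gq = int(round(row.quality))
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.allele_a}\t{row.allele_b}\t"
                f"{row.quality}\t.\t.\tGT:AD:GQ\t0/1:{row.depth_a},{row.depth_b}:{gq}\n"
            )


def read_vcf_sites(path, quality_from: str = "qual") -> Iterator[dict]:
    """Stream variant records from a VCF as plain dicts.

    Yields ``chrom, pos, allele_a, allele_b, depth_a, depth_b, quality``
    per record (multiallelic ALT strings pass through and fail the SNV
    filter downstream).  ``quality_from`` selects site QUAL (default) or
    the donor genotype's GQ.  Records without AD get zero depths and a
    ``depthless`` flag.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else ""
        if quality_from == "gq":
            try:
                quality = float(np.asarray(v.format("GQ")).ravel()[0])
            except (TypeError, ValueError):
                quality = float(v.QUAL or 0.0)
        else:
            quality = float(v.QUAL or 0.0)
        rec = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "allele_a": v.REF,
            "allele_b": alt,
            "quality": quality,
        }
        ad = v.format("AD")
        if ad is None:
            rec.update(depth_a=0, depth_b=0, depthless=True)
        else:
            ad = np.asarray(ad).ravel()
            rec.update(depth_a=int(ad[0]), depth_b=int(ad[1]) if ad.size > 1 else 0)
        yield rec
    vcf.close()


# ---------------------------------------------------------------------------
# gamete matrix and per-sperm calls


def write_matrix_tsv(matrix: GameteMatrix, path) -> None:
    """Sites x sperm TSV; entries are allele letters or NA."""
    a = matrix.sites["allele_a"].to_numpy()
    b = matrix.sites["allele_b"].to_numpy()
    cols = {"chrom": matrix.sites["chrom"], "pos": matrix.sites["pos"],
            "allele_a": a, "allele_b": b}
    for j, sid in enumerate(matrix.sperm_ids):
        col = np.where(
            matrix.calls[:, j] == MISSING, "NA", np.where(matrix.calls[:, j] == 0, a, b)
        )
        cols[sid] = col
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> GameteMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    meta = ["chrom", "pos", "allele_a", "allele_b"]
    sperm_ids = [c for c in df.columns if c not in meta]
    sites = df[meta].copy()
    a = sites["allele_a"].to_numpy()
    b = sites["allele_b"].to_numpy()
    calls = np.full((len(df), len(sperm_ids)), MISSING, dtype=np.int8)
    for j, sid in enumerate(sperm_ids):
        col = df[sid].to_numpy()
        calls[col == a, j] = 0
        calls[col == b, j] = 1
    return GameteMatrix(sites, sperm_ids, calls)


def write_call_tables(matrix: GameteMatrix, outdir) -> None:
    """One 3-column TSV (chrom, pos, allele) per sperm."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a = matrix.sites["allele_a"].to_numpy()
    b = matrix.sites["allele_b"].to_numpy()
    for j, sid in enumerate(matrix.sperm_ids):
        obs = matrix.calls[:, j] != MISSING
        allele = np.where(matrix.calls[obs, j] == 0, a[obs], b[obs])
        pd.DataFrame(
            {
                "chrom": matrix.sites["chrom"].to_numpy()[obs],
                "pos": matrix.sites["pos"].to_numpy()[obs],
                "allele": allele,
            }
        ).to_csv(outdir / f"{sid}.tsv", sep="\t", index=False)


def read_call_tables(calls_dir) -> dict[str, pd.DataFrame]:
    """Load per-sperm call TSVs (``<sperm_id>.tsv``) from a directory."""
    tables = {}
    for path in sorted(Path(calls_dir).glob("*.tsv")):
        tables[path.stem] = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not tables:
        raise FileNotFoundError(f"no per-sperm call tables under {calls_dir}")
    return tables


# ---------------------------------------------------------------------------
# bin map / markers / genetic map


def write_bin_map(bin_map: BinMap, prefix) -> None:
    """BED-like bin table (``<prefix>.bins.tsv``) + genotype matrix TSV."""
    prefix = str(prefix)
    bin_map.bins.to_csv(prefix + ".bins.tsv", sep="\t", index=False)
    geno = pd.DataFrame(
        {"bin_id": bin_map.bins["bin_id"]}
        | {
            sid: [_GENO_LABEL[int(g)] for g in bin_map.genotypes[j]]
            for j, sid in enumerate(bin_map.sperm_ids)
        }
    )
    geno.to_csv(prefix + ".genotypes.tsv", sep="\t", index=False)


def read_bin_map(prefix) -> BinMap:
    prefix = str(prefix)
    bins = pd.read_csv(prefix + ".bins.tsv", sep="\t", dtype={"chrom": str})
    geno = pd.read_csv(prefix + ".genotypes.tsv", sep="\t", keep_default_na=False)
    sperm_ids = [c for c in geno.columns if c != "bin_id"]
    codes = np.array(
        [[_GENO_CODE[v] for v in geno[sid]] for sid in sperm_ids], dtype=np.int8
    )
    return BinMap(bins=bins, sperm_ids=sperm_ids, genotypes=codes)


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# reads


def read_seqs(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA/FASTQ, gzip-transparent."""
    path = str(path)
    base = path[:-3] if path.endswith(".gz") else path
    fmt = "fastq" if base.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, description, sequence) triples as FASTA."""
    with _open_text(path, "wt") as fh:
        for rid, desc, seq in records:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_reference_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
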