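"""Readers and writers for the standard interchange formats.

VCF (haploid GT or phased diploid) in and out of :class:`HaplotypeMatrix`,
FASTA sequences, JASPAR plain-text PFMs into :class:`MotifMatrix`, BED-like
TSV intervals, and the vial-level viability / qPCR sample tables.
External coordinates are 1-based inclusive (VCF convention); interval tables
are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hapstats import HaplotypeMatrix
from .synthetic_data import Panel
from .te_annotation import MotifMatrix

__all__ = [
    "read_vcf_haplotypes",
    "write_vcf",
    "write_panel",
    "read_fasta",
    "write_fasta",
    "read_jaspar_pfm",
    "read_intervals_tsv",
    "read_viability_tsv",
    "write_viability_tsv",
]


def read_vcf_haplotypes(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Read phased haplotypes and per-site variant kinds from a VCF.

    Haploid GT fields contribute one haplotype per sample; phased diploid
    "a|b" calls contribute two. Unphased diploid calls are rejected (the
    haplotype statistics require phase). Sites are classified snp/indel from
    REF/ALT lengths. ``region`` is (chrom, start, end) 1-based inclusive.
    Missing calls are rejected (resolve missingness upstream).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    columns, positions, kinds = [], [], []
    chrom_seen = None
    for i, rec in enumerate(vf.fetch() if vf.index is not None else vf):
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start <= rec.pos <= end):
                continue
        if chrom_seen is None:
            chrom_seen = rec.chrom
        elif rec.chrom != chrom_seen:
            raise ValueError("multi-contig VCFs must be read with a region")
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"record {i + 1} at {rec.pos}: need exactly one ALT")
        col = []
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or any(a is None for a in gt):
                raise ValueError(f"record {i + 1} at {rec.pos}: missing call for {s}")
            if len(gt) == 1:
                col.append(gt[0])
            elif len(gt) == 2:
                if not call.phased:
                    raise ValueError(
                        f"record {i + 1} at {rec.pos}: unphased diploid call for {s}"
                    )
                col.extend(gt)
            else:
                raise ValueError(f"record {i + 1} at {rec.pos}: ploidy > 2")
        columns.append(col)
        positions.append(rec.pos)
        is_snp = len(rec.ref) == 1 and len(rec.alts[0]) == 1
        kinds.append("snp" if is_snp else "indel")
    vf.close()
    if not columns:
        raise ValueError("no variant records in the requested region")
    n_haps = len(columns[0])
    alleles = np.array(columns, dtype=np.int8).T  # (haplotypes, sites)
    if all(len(c) == len(samples) for c in columns):
        ids = tuple(samples)
    else:
        ids = tuple(f"{s}|{k}" for s in samples for k in (1, 2))[:n_haps]
    hm = HaplotypeMatrix(alleles, np.array(positions), chrom_seen or "unknown", ids)
    return hm, np.array(kinds)


def write_vcf(hm: HaplotypeMatrix, path: str | Path) -> None:
    """Write a haplotype matrix as a haploid-GT single-contig VCF."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hm.strain_ids) + "\n")
        for j in range(hm.n_sites):
            gts = "\t".join(str(int(a)) for a in hm.alleles[:, j])
            fh.write(f"{hm.chrom}\t{hm.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_panel(panel: Panel, vcf_path: str | Path, genotype_tsv: str | Path) -> None:
    """Panel to VCF plus a (strain_id, insertion_id) TSV sidecar."""
    write_vcf(panel.haplotypes, vcf_path)
    pd.DataFrame({
        "strain_id": panel.strain_ids,
        "insertion_id": panel.insertion_genotype,
    }).to_csv(genotype_tsv, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar_pfm(path: str | Path, name: str | None = None,
                    background=None) -> MotifMatrix:
    """Read a JASPAR plain-text PFM (4 count rows, optional '>' header)."""
    text = Path(path).read_text()
    handle = _io.StringIO(text)
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    motif = motifs.read(handle, fmt)
    counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)
    return MotifMatrix.from_counts(
        counts, name or (motif.name or "motif"), background=background
    )


def read_intervals_tsv(path: str | Path) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end[, strand, id] (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"interval table needs columns {sorted(required)}")
    if (df["end"] <= df["start"]).any():
        raise ValueError("intervals must be non-empty half-open")
    return df


def read_viability_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "genotype", "replicate", "vial", "emerged", "total"}
    if not required <= set(df.columns):
        raise ValueError(f"viability table needs columns {sorted(required)}")
    return df


def write_viability_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
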