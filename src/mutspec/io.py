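"""File formats: FASTA, GFF3, VCF v4.2, BED masks, TSV tables.

Reading goes through the standard libraries (Bio.SeqIO, gffutils, pysam);
writing emits deterministic plain text so fixed-seed simulations are
byte-reproducible. VCF records are sites-only v4.2 with DP, MQ and VAF in
INFO and the variant quality in QUAL; multi-allelic records are split into
per-allele records on read.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filtering import VariantRecord
from .genome import GeneModel, GenomeModel


def write_fasta(genome: GenomeModel, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(genome: GenomeModel, path: str | os.PathLike) -> None:
    """Write gene and CDS records (1-based inclusive, GFF3)."""
    lines = ["##gff-version 3"]
    for name, seq in genome.contigs:
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in genome.genes:
        attrs = (
            f"ID={g.gene_id};promoter_length={g.promoter_length};"
            f"terminator_length={g.terminator_length}"
        )
        lines.append(
            "\t".join(
                [g.contig, "mutspec", "gene", str(g.start), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        coding_order = (
            g.cds_intervals if g.strand == "+" else tuple(reversed(g.cds_intervals))
        )
        phase: dict[tuple[int, int], int] = {}
        seen = 0
        for s, e in coding_order:
            phase[(s, e)] = (3 - seen % 3) % 3
            seen += e - s + 1
        for i, (s, e) in enumerate(g.cds_intervals, start=1):
            lines.append(
                "\t".join(
                    [g.contig, "mutspec", "CDS", str(s), str(e), ".", g.strand,
                     str(phase[(s, e)]), f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models (gene + CDS records) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            ((c.start, c.end) for c in db.children(gene, featuretype="CDS")),
        )
        if not cds:
            continue
        promoter = int(gene.attributes.get("promoter_length", ["1000"])[0])
        terminator = int(gene.attributes.get("terminator_length", ["200"])[0])
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(cds),
                promoter_length=promoter,
                terminator_length=terminator,
            )
        )
    return genes


def read_genome(
    fasta_path: str | os.PathLike, gff_path: str | os.PathLike
) -> GenomeModel:
    return GenomeModel(read_fasta(fasta_path), read_gff3(gff_path))


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
"""


def write_vcf(
    records: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write a sites-only VCF v4.2 with deterministic byte output."""
    lines = [_VCF_HEADER.rstrip("\n")]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt)):
        info = f"DP={r.depth};MQ={r.mapping_quality:g};VAF={r.variant_allele_fraction:g}"
        lines.append(
            "\t".join(
                [r.contig, str(r.pos), ".", r.ref, r.alt,
                 f"{r.variant_quality:g}", ".", info]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike, sample_id: str = "") -> list[VariantRecord]:
    """Read variant records; multi-allelic rows are split per allele."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            depth = info.get("DP")
            mq = info.get("MQ")
            vaf = info.get("VAF")
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=int(depth) if depth is not None else None,
                        variant_quality=(
                            float(rec.qual) if rec.qual is not None else None
                        ),
                        mapping_quality=float(mq) if mq is not None else None,
                        variant_allele_fraction=(
                            float(vaf) if vaf is not None else None
                        ),
                        sample_id=sample_id,
                    )
                )
    return out


def write_truth_table(truth: Iterable[dict], path: str | os.PathLike) -> None:
    pd.DataFrame(
        truth, columns=["contig", "pos", "ref", "alt", "violated_criterion"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed_mask(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Read a BED mask (0-based half-open) into 1-based inclusive intervals."""
    mask: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        mask.setdefault(contig, []).append((start + 1, end))
    return mask
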