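"""Toy annotated haploid genome: in-memory models and a seeded generator.

The genome model is the geometric substrate for every downstream stage:
feature assignment needs strand-aware gene boundaries with promoter and
terminator margins, and codon-level impact needs valid open reading frames.
The generator lays out non-overlapping protein-coding genes (single-CDS by
default, optionally intron-split) on random background sequence with a
target GC content, so the whole pipeline is testable without external data.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomePlacementError(ValueError):
    """Raised when the requested genes cannot be placed on the contig."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand-aware CDS intervals plus flanking margins.

    ``cds_intervals`` are 1-based inclusive ``(start, end)`` pairs in
    ascending genome coordinates; for minus-strand genes the coding order is
    the reverse of the stored order. Promoter and terminator lengths define
    the regulatory margins used by feature assignment (upstream of the 5'
    gene boundary and downstream of the 3' boundary on the coding strand).
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    promoter_length: int = 1000
    terminator_length: int = 200

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = tuple((int(s), int(e)) for s, e in self.cds_intervals)
        if not ivs:
            raise ValueError(f"{self.gene_id}: gene needs at least one CDS interval")
        for s, e in ivs:
            if s > e or s < 1:
                raise ValueError(f"{self.gene_id}: bad CDS interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or unsorted")
        object.__setattr__(self, "cds_intervals", ivs)

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the CDS span."""
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate of the CDS span."""
        return self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)

    def contains_intron(self, pos: int) -> bool:
        return self.start <= pos <= self.end and not self.contains_cds(pos)

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the coding sequence.

        Counted 5'→3' on the coding strand; ``None`` if the position is not
        inside a CDS interval.
        """
        off = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                ascending = off + (pos - s)
                if self.strand == "+":
                    return ascending
                return self.cds_length - 1 - ascending
            off += e - s + 1
        return None

    def cds_sequence(self, contig_seq: str) -> str:
        """Spliced coding sequence, 5'→3' on the coding strand."""
        spliced = "".join(contig_seq[s - 1 : e] for s, e in self.cds_intervals)
        return spliced if self.strand == "+" else revcomp(spliced)


@dataclass
class GenomeModel:
    """Reference sequence plus gene models defining feature geometry."""

    contigs: list[tuple[str, str]]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._seq = {name: seq for name, seq in self.contigs}
        self._genes_by_contig: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._genes_by_contig.setdefault(g.contig, []).append(g)
        for gs in self._genes_by_contig.values():
            gs.sort(key=lambda g: g.start)

    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    def contig_sequence(self, name: str) -> str:
        try:
            return self._seq[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def genes_on(self, contig: str) -> list[GeneModel]:
        return self._genes_by_contig.get(contig, [])

    def base_at(self, contig: str, pos: int) -> str:
        return self.contig_sequence(contig)[pos - 1]

    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on violation."""
        from Bio.Seq import Seq

        for name, seq in self.contigs:
            if set(seq) - set(BASES):
                bad = sorted(set(seq) - set(BASES))
                raise ValueError(f"contig {name}: non-ACGT characters {bad}")
        for contig, gs in self._genes_by_contig.items():
            seq = self.contig_sequence(contig)
            prev_end = 0
            for g in sorted(gs, key=lambda g: g.start):
                if g.end > len(seq):
                    raise ValueError(f"{g.gene_id}: extends past end of {contig}")
                if g.start <= prev_end:
                    raise ValueError(f"{g.gene_id}: CDS overlaps previous gene")
                prev_end = g.end
                if g.cds_length % 3:
                    raise ValueError(f"{g.gene_id}: CDS length not a multiple of 3")
                cds = g.cds_sequence(seq)
                aa = str(Seq(cds).translate())
                if not cds.startswith(START_CODON):
                    raise ValueError(f"{g.gene_id}: CDS does not begin with ATG")
                if not aa.endswith("*"):
                    raise ValueError(f"{g.gene_id}: CDS does not end with a stop codon")
                if "*" in aa[:-1]:
                    raise ValueError(f"{g.gene_id}: internal stop codon")

    def reverse_complemented(self) -> "GenomeModel":
        """The same genome read from the opposite strand.

        Every contig is reverse-complemented and gene coordinates are
        mirrored with strands flipped; all analyses must be invariant under
        this transformation.
        """
        new_contigs = [(name, revcomp(seq)) for name, seq in self.contigs]
        lengths = {name: len(seq) for name, seq in self.contigs}
        new_genes = []
        for g in self.genes:
            n = lengths[g.contig]
            ivs = tuple(
                sorted((n - e + 1, n - s + 1) for s, e in g.cds_intervals)
            )
            new_genes.append(
                replace(g, strand="-" if g.strand == "+" else "+", cds_intervals=ivs)
            )
        return GenomeModel(new_contigs, new_genes)


def _random_codon(rng: np.random.Generator, base_p: np.ndarray) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3, p=base_p))
        if codon not in STOP_CODONS:
            return codon


def _build_orf(rng: np.random.Generator, n_codons: int, base_p: np.ndarray) -> str:
    body = "".join(_random_codon(rng, base_p) for _ in range(n_codons - 2))
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return START_CODON + body + stop


def generate_genome(
    n_contigs: int = 1,
    contig_length: int = 50_000,
    n_genes: int = 10,
    gc_content: float = 0.38,
    seed: int = 0,
    *,
    cds_codon_range: tuple[int, int] = (100, 300),
    intron_fraction: float = 0.0,
    intron_length_range: tuple[int, int] = (60, 200),
    promoter_length: int = 1000,
    terminator_length: int = 200,
) -> GenomeModel:
    """Generate an annotated haploid toy genome, deterministically per seed.

    Genes are laid out left to right with at least ``promoter_length +
    terminator_length`` bases between gene bodies (and at contig edges), so
    regulatory margins never overlap coding sequence of a neighbour. Strand
    is random per gene; a fraction of genes carry a single intron. Background
    sequence is drawn i.i.d. with the requested GC content; ORF codons are
    drawn from the same base distribution with stop codons rejected, so the
    realized genome GC tracks the target.

    Raises :class:`GenomePlacementError` when the contig cannot hold the
    requested genes with their margins.
    """
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    base_p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1

    contigs: list[tuple[str, str]] = []
    genes: list[GeneModel] = []
    margin = promoter_length + terminator_length
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq = np.array(list(BASES))[
            rng.choice(4, size=contig_length, p=base_p)
        ]
        k = per_contig[ci]
        # Draw gene bodies first so feasibility can be checked up front.
        bodies = []
        for gi in range(k):
            n_codons = int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
            orf = _build_orf(rng, n_codons, base_p)
            intron = ""
            split = None
            if rng.random() < intron_fraction:
                ilen = int(rng.integers(intron_length_range[0], intron_length_range[1] + 1))
                intron = "".join(rng.choice(list(BASES), size=ilen, p=base_p))
                split = int(rng.integers(3, len(orf) - 3))
            bodies.append((orf, intron, split))
        total_body = sum(len(orf) + len(intron) for orf, intron, _ in bodies)
        needed = total_body + (k + 1) * margin
        if needed > contig_length:
            raise GenomePlacementError(
                f"contig {name} ({contig_length} bp) cannot hold {k} genes with "
                f"promoter ({promoter_length} bp) and terminator "
                f"({terminator_length} bp) margins: needs at least {needed} bp"
            )
        slack = contig_length - needed
        extras = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) if k else []
        cursor = 0
        for gi, (orf, intron, split) in enumerate(bodies):
            cursor += margin + int(extras[gi])
            start0 = cursor  # 0-based start of the gene body
            strand = "+" if rng.random() < 0.5 else "-"
            if intron:
                coding_body = orf[:split] + intron + orf[split:]
                exons_coding = [(0, split), (split + len(intron), len(coding_body))]
            else:
                coding_body = orf
                exons_coding = [(0, len(orf))]
            if strand == "+":
                genomic_body = coding_body
                ivs = [(start0 + a + 1, start0 + b) for a, b in exons_coding]
            else:
                genomic_body = revcomp(coding_body)
                L = len(coding_body)
                ivs = sorted(
                    (start0 + L - b + 1, start0 + L - a) for a, b in exons_coding
                )
            seq[start0 : start0 + len(genomic_body)] = list(genomic_body)
            genes.append(
                GeneModel(
                    gene_id=f"gene{len(genes) + 1:03d}",
                    contig=name,
                    strand=strand,
                    cds_intervals=tuple(ivs),
                    promoter_length=promoter_length,
                    terminator_length=terminator_length,
                )
            )
            cursor += len(genomic_body)
        contigs.append((name, "".join(seq)))

    genome = GenomeModel(contigs, genes)
    genome.validate()
    return genome
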