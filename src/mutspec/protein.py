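"""Codon-level consequences of exonic SNVs and the protein-level table.

Each exonic substitution is mapped onto the coding strand of its gene
(minus-strand genes are reverse-complemented), the affected codon and
within-codon position are located, and the standard nuclear genetic code
decides whether the amino acid is preserved, changed, or a stop codon is
gained. Amino-acid changes are split into conservative and nonconservative
by the BLOSUM62 matrix (conservative iff the matrix score is strictly
positive by default), and a structure indicator counts stop gains together
with substitutions involving glycine or proline — residues whose gain or
loss tends to disturb backbone geometry — over all amino-acid-level events
(changes plus stops).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome import GeneModel, GenomeModel, revcomp

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

EFFECTS = ("preserved", "changed", "stop_gained")


def blosum62_score(aa1: str, aa2: str) -> int:
    """BLOSUM62 entry for an amino-acid pair (``*`` rows included)."""
    return int(_BLOSUM62[aa1, aa2])


def classify_conservation(
    ref_aa: str, alt_aa: str, *, threshold: int = 0
) -> tuple[str, int]:
    """Classify an amino-acid change as conservative or nonconservative.

    Conservative iff BLOSUM62(ref, alt) > ``threshold`` (default 0, i.e.
    strictly positive scores). Identity and stop codons are errors here —
    they belong to the preserved/stop effect classes.
    """
    if ref_aa == alt_aa:
        raise ValueError(f"{ref_aa}→{alt_aa} is not an amino-acid change")
    if "*" in (ref_aa, alt_aa):
        raise ValueError("stop codons are classified by effect, not conservation")
    score = blosum62_score(ref_aa, alt_aa)
    return ("conservative" if score > threshold else "nonconservative"), score


@dataclass(frozen=True)
class ProteinImpactRecord:
    """Codon-level consequence of one exonic substitution."""

    gene_id: str
    codon_index: int  # 1-based codon number in the CDS
    codon_position: int  # 1, 2 or 3: mutated base within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # preserved / changed / stop_gained
    blosum_score: int | None
    conservation: str  # conservative / nonconservative / not_applicable


def _find_gene(genome: GenomeModel, contig: str, pos: int) -> GeneModel:
    for g in genome.genes_on(contig):
        if g.contains_cds(pos):
            return g
    raise ValueError(f"no CDS contains {contig}:{pos}")


def codon_effect(
    call,
    genome: GenomeModel,
    *,
    gene: GeneModel | None = None,
    conservative_threshold: int = 0,
) -> ProteinImpactRecord:
    """Compute the codon-level impact of an exonic substitution.

    ``call`` needs ``contig``, ``pos``, ``ref`` and ``alt`` attributes (or
    is a ``(contig, pos, ref, alt)`` tuple). For minus-strand genes the
    change is reverse-complemented onto the coding strand before codon
    lookup; ``codon_position`` is the within-codon index on the coding
    strand. A stop codon that stays a stop is preserved; a lost stop or
    start is an ordinary change.
    """
    if isinstance(call, tuple):
        contig, pos, ref, alt = call
    else:
        contig, pos, ref, alt = call.contig, call.pos, call.ref, call.alt
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("codon effects are defined for substitutions only")
    if gene is None:
        gene = _find_gene(genome, contig, pos)
    if gene.cds_length % 3:
        raise ValueError(f"{gene.gene_id}: CDS length is not a multiple of 3")
    seq = genome.contig_sequence(contig)
    if seq[pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: genome has {seq[pos - 1]}, "
            f"call says {ref}"
        )
    offset = gene.cds_offset(pos)
    if offset is None:
        raise ValueError(f"{contig}:{pos} is not inside the CDS of {gene.gene_id}")
    coding_ref = ref if gene.strand == "+" else _COMP[ref]
    coding_alt = alt if gene.strand == "+" else _COMP[alt]
    cds = gene.cds_sequence(seq)
    codon_index = offset // 3
    codon_position = offset % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    assert ref_codon[codon_position] == coding_ref
    alt_codon = (
        ref_codon[:codon_position] + coding_alt + ref_codon[codon_position + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if alt_aa == "*" and ref_aa != "*":
        effect = "stop_gained"
    elif ref_aa == alt_aa:
        effect = "preserved"
    else:
        effect = "changed"

    blosum: int | None = None
    conservation = "not_applicable"
    if effect == "changed":
        if "*" in (ref_aa, alt_aa):
            # stop-loss: treated as an ordinary (and structurally drastic,
            # hence nonconservative) change; BLOSUM62 carries a * row.
            blosum = blosum62_score(ref_aa, alt_aa)
            conservation = "nonconservative"
        else:
            conservation, blosum = classify_conservation(
                ref_aa, alt_aa, threshold=conservative_threshold
            )
    return ProteinImpactRecord(
        gene_id=gene.gene_id,
        codon_index=codon_index + 1,
        codon_position=codon_position + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
        blosum_score=blosum,
        conservation=conservation,
    )


@dataclass(frozen=True)
class ProteinLevelTable:
    """Counts behind the protein-level summary of exonic substitutions.

    ``stop_and_glypro`` counts stop gains plus amino-acid changes in which
    either residue is Gly or Pro; its percentage denominator is the number
    of amino-acid-level events (changed + stop), and the internal stop vs
    Gly/Pro split is expressed over the indicator subset itself.
    """

    total: int
    preserved: int
    changed: int
    stop: int
    codon_position_counts: tuple[int, int, int]
    conservative: int
    nonconservative: int
    stop_and_glypro: int
    glypro_changes: int

    def __post_init__(self) -> None:
        assert self.preserved + self.changed + self.stop == self.total
        assert sum(self.codon_position_counts) == self.total
        assert self.conservative + self.nonconservative == self.changed
        assert self.stop_and_glypro == self.stop + self.glypro_changes

    @staticmethod
    def _pct(n: int, d: int) -> float:
        return float("nan") if d == 0 else round(100.0 * n / d, 1)

    def percentages(self) -> dict[str, float]:
        """Report percentages, rounded to one decimal, with the same
        denominators as the published-style table: effect classes and codon
        positions over total; conservation over changes; the structure
        indicator over (changed + stop); its split over the indicator."""
        events = self.changed + self.stop
        p = {
            "preserved": self._pct(self.preserved, self.total),
            "changed": self._pct(self.changed, self.total),
            "stop": self._pct(self.stop, self.total),
            "codon_position_1": self._pct(self.codon_position_counts[0], self.total),
            "codon_position_2": self._pct(self.codon_position_counts[1], self.total),
            "codon_position_3": self._pct(self.codon_position_counts[2], self.total),
            "conservative": self._pct(self.conservative, self.changed),
            "nonconservative": self._pct(self.nonconservative, self.changed),
            "stop_and_glypro": self._pct(self.stop_and_glypro, events),
            "stop_of_indicator": self._pct(self.stop, self.stop_and_glypro),
            "glypro_of_indicator": self._pct(self.glypro_changes, self.stop_and_glypro),
        }
        return p


def _is_glypro_change(rec: ProteinImpactRecord, direction: str) -> bool:
    if rec.effect != "changed":
        return False
    if direction == "either":
        return rec.ref_aa in "GP" or rec.alt_aa in "GP"
    if direction == "to":
        return rec.alt_aa in "GP"
    if direction == "from":
        return rec.ref_aa in "GP"
    raise ValueError(f"unknown Gly/Pro direction {direction!r}")


def protein_table(
    impacts: Iterable[ProteinImpactRecord], *, glypro_direction: str = "either"
) -> ProteinLevelTable:
    """Aggregate codon-level impacts into the protein-level table.

    ``glypro_direction`` controls which amino-acid changes count toward the
    structure indicator: substitutions ``to``, ``from``, or (default)
    involving ``either`` a Gly or Pro residue.
    """
    impacts = list(impacts)
    pos_counts = [0, 0, 0]
    preserved = changed = stop = conservative = nonconservative = glypro = 0
    for rec in impacts:
        pos_counts[rec.codon_position - 1] += 1
        if rec.effect == "preserved":
            preserved += 1
        elif rec.effect == "stop_gained":
            stop += 1
        else:
            changed += 1
            if rec.conservation == "conservative":
                conservative += 1
            else:
                nonconservative += 1
            if _is_glypro_change(rec, glypro_direction):
                glypro += 1
    return ProteinLevelTable(
        total=len(impacts),
        preserved=preserved,
        changed=changed,
        stop=stop,
        codon_position_counts=tuple(pos_counts),
        conservative=conservative,
        nonconservative=nonconservative,
        stop_and_glypro=stop + glypro,
        glypro_changes=glypro,
    )


def protein_table_rows(table: ProteinLevelTable) -> list[dict]:
    """Long-form rows (category, n, percent) for report output."""
    p = table.percentages()
    return [
        {"category": "total", "n": table.total, "percent": 100.0 if table.total else float("nan")},
        {"category": "preserved", "n": table.preserved, "percent": p["preserved"]},
        {"category": "changed", "n": table.changed, "percent": p["changed"]},
        {"category": "stop", "n": table.stop, "percent": p["stop"]},
        {"category": "codon_position_1", "n": table.codon_position_counts[0], "percent": p["codon_position_1"]},
        {"category": "codon_position_2", "n": table.codon_position_counts[1], "percent": p["codon_position_2"]},
        {"category": "codon_position_3", "n": table.codon_position_counts[2], "percent": p["codon_position_3"]},
        {"category": "conservative", "n": table.conservative, "percent": p["conservative"]},
        {"category": "nonconservative", "n": table.nonconservative, "percent": p["nonconservative"]},
        {"category": "stop_and_glypro", "n": table.stop_and_glypro, "percent": p["stop_and_glypro"]},
        {"category": "stop_of_indicator", "n": table.stop, "percent": p["stop_of_indicator"]},
        {"category": "glypro_of_indicator", "n": table.glypro_changes, "percent": p["glypro_of_indicator"]},
    ]
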