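"""Substitution-spectrum and gene-feature classification.

Single-base substitutions are pooled with their reverse complements (A→C
and T→G are the same event on double-stranded DNA), giving six classes:
two transitions (A:T>G:C, G:C>A:T) and four transversions. Gene-feature
assignment places each SNV in exactly one of exon / intron / promoter /
terminator / intergenic, with precedence exon > intron > promoter >
terminator > intergenic and nearest-gene tie-breaking for regulatory
margins shared by two genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome import GenomeModel

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical order of the six complementary-pooled substitution classes.
CLASS_LABELS = ("A:T>G:C", "G:C>A:T", "A:T>T:A", "A:T>C:G", "G:C>T:A", "G:C>C:G")
TRANSITION_LABELS = frozenset({"A:T>G:C", "G:C>A:T"})

FEATURES = ("exon", "intron", "promoter", "terminator", "intergenic")


@dataclass(frozen=True)
class SubstitutionClass:
    label: str

    @property
    def is_transition(self) -> bool:
        return self.label in TRANSITION_LABELS


def _directed_pairs(label: str) -> list[tuple[str, str]]:
    # "X:Y>W:Z" pools the directed changes X→W and Y→Z.
    src, dst = label.split(">")
    x, y = src.split(":")
    w, z = dst.split(":")
    return [(x, w), (y, z)]


#: (ref, alt) → pooled class label, for all 12 directed substitutions.
PAIR_TO_CLASS: dict[tuple[str, str], str] = {}
#: (class label, ref base) → alt base, used by the mutation simulator.
ALT_FOR: dict[tuple[str, str], str] = {}
for _label in CLASS_LABELS:
    for _ref, _alt in _directed_pairs(_label):
        PAIR_TO_CLASS[(_ref, _alt)] = _label
        ALT_FOR[(_label, _ref)] = _alt


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Pooled substitution class of a single-base change.

    Symmetric under complementation: ``classify_substitution(ref, alt) ==
    classify_substitution(comp(ref), comp(alt))``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}→{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}→{alt}")
    return SubstitutionClass(PAIR_TO_CLASS[(ref, alt)])


@dataclass(frozen=True)
class SpectrumSummary:
    """Per-class counts and relative frequencies of a pooled SNV set."""

    counts: dict[str, int]
    scope: str = "genome_wide"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float] | None:
        """Relative frequencies per class; ``None`` for an empty spectrum."""
        if self.total == 0:
            return None
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def transition_fraction(self) -> float | None:
        if self.total == 0:
            return None
        ti = sum(v for k, v in self.counts.items() if k in TRANSITION_LABELS)
        return ti / self.total

    @property
    def transversion_fraction(self) -> float | None:
        ti = self.transition_fraction
        return None if ti is None else 1.0 - ti


def spectrum_summary(calls: Iterable, scope: str = "genome_wide") -> SpectrumSummary:
    """Pool substitution calls into a six-class spectrum.

    ``calls`` may be any objects with ``ref`` and ``alt`` single-base
    attributes (variant records or annotated mutation calls). With
    ``scope="nonsynonymous_only"`` each call must additionally carry an
    ``impact`` attribute and only amino-acid-changing and stop-gaining
    calls are counted.
    """
    if scope not in ("genome_wide", "nonsynonymous_only"):
        raise ValueError(f"unknown scope {scope!r}")
    counts = {label: 0 for label in CLASS_LABELS}
    for call in calls:
        if scope == "nonsynonymous_only":
            impact = getattr(call, "impact", None)
            if impact is None:
                raise ValueError(
                    "nonsynonymous_only scope requires protein impact annotations"
                )
            if impact.effect not in ("changed", "stop_gained"):
                continue
        counts[classify_substitution(call.ref, call.alt).label] += 1
    return SpectrumSummary(counts=counts, scope=scope)


@dataclass(frozen=True)
class FeatureAssignment:
    feature: str
    gene_id: str | None = None


def _promoter_interval(gene) -> tuple[int, int]:
    if gene.strand == "+":
        return (gene.start - gene.promoter_length, gene.start - 1)
    return (gene.end + 1, gene.end + gene.promoter_length)


def _terminator_interval(gene) -> tuple[int, int]:
    if gene.strand == "+":
        return (gene.end + 1, gene.end + gene.terminator_length)
    return (gene.start - gene.terminator_length, gene.start - 1)


def assign_feature(contig: str, pos: int, genome: GenomeModel) -> FeatureAssignment:
    """Assign a position to exactly one gene-feature category.

    Exons and introns take precedence over regulatory margins; where the
    promoter of one gene overlaps the terminator of another, the gene whose
    boundary is nearest wins (ties by lower gene start).
    """
    n = len(genome.contig_sequence(contig))  # raises KeyError for unknown contig
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside contig {contig} (length {n})")
    genes = genome.genes_on(contig)
    for g in genes:
        if g.contains_cds(pos):
            return FeatureAssignment("exon", g.gene_id)
    for g in genes:
        if g.contains_intron(pos):
            return FeatureAssignment("intron", g.gene_id)
    # candidates: (distance to gene boundary, gene start, feature, gene_id)
    candidates: list[tuple[int, int, str, str]] = []
    for g in genes:
        ps, pe = _promoter_interval(g)
        if ps <= pos <= pe:
            dist = g.start - pos if g.strand == "+" else pos - g.end
            candidates.append((dist, g.start, "promoter", g.gene_id))
        ts, te = _terminator_interval(g)
        if ts <= pos <= te:
            dist = pos - g.end if g.strand == "+" else g.start - pos
            candidates.append((dist, g.start, "terminator", g.gene_id))
    if candidates:
        # promoter beats terminator; among candidates of the winning kind the
        # nearest gene wins, ties by lower gene start — deterministic.
        candidates.sort(key=lambda c: (0 if c[2] == "promoter" else 1, c[0], c[1]))
        _, _, feature, gene_id = candidates[0]
        return FeatureAssignment(feature, gene_id)
    return FeatureAssignment("intergenic", None)


def feature_counts(assignments: Iterable[FeatureAssignment]) -> dict[str, int]:
    """Tally assignments into the five feature categories."""
    counts = {f: 0 for f in FEATURES}
    for a in assignments:
        counts[a.feature] += 1
    return counts
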