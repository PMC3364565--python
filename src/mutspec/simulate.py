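"""Mutagen simulation: induced mutations and noisy variant-call rendering.

A :class:`MutagenProfile` is a probability distribution over the six
complementary-pooled substitution classes. The two presets encode the
aggregate biases of the mutagens under study — EMS-style alkylation
(transitions 97%, dominated by G:C>A:T chemistry) and an error-prone
polymerase-delta mutator (transversions 72%) — with the split inside each
aggregate uniform by default and fully overridable. True mutations are
rendered as variant-call records with overdispersed depth and clean
haploid evidence; decoy records are constructed to violate exactly one
named filter criterion each, with the violated criterion recorded as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filtering import VariantRecord
from .genome import BASES, GenomeModel
from .spectrum import ALT_FOR, CLASS_LABELS, TRANSITION_LABELS


@dataclass(frozen=True)
class MutagenProfile:
    """Probability weights over the six pooled substitution classes."""

    class_weights: dict[str, float]
    indel_rate: float = 0.0  # expected indels per SNV

    def __post_init__(self) -> None:
        unknown = set(self.class_weights) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
        w = self.weights_array()
        if (w < 0).any():
            raise ValueError("class weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1, got {w.sum()!r}")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be non-negative")

    def weights_array(self) -> np.ndarray:
        return np.array([self.class_weights.get(c, 0.0) for c in CLASS_LABELS])

    @classmethod
    def from_aggregate(
        cls, transition_fraction: float, indel_rate: float = 0.0
    ) -> "MutagenProfile":
        """Profile with the given pooled transition fraction, uniform within
        the transition and transversion aggregates."""
        if not 0.0 <= transition_fraction <= 1.0:
            raise ValueError("transition_fraction must be in [0, 1]")
        weights = {}
        for label in CLASS_LABELS:
            if label in TRANSITION_LABELS:
                weights[label] = transition_fraction / 2
            else:
                weights[label] = (1.0 - transition_fraction) / 4
        return cls(class_weights=weights, indel_rate=indel_rate)

    @classmethod
    def ems(cls, indel_rate: float = 0.0) -> "MutagenProfile":
        """EMS-style alkylating mutagen: 97% transitions."""
        return cls.from_aggregate(0.97, indel_rate)

    @classmethod
    def mutator(cls, indel_rate: float = 0.0) -> "MutagenProfile":
        """Error-prone polymerase-delta mutator: 72% transversions."""
        return cls.from_aggregate(0.28, indel_rate)


@dataclass(frozen=True)
class NoiseModel:
    """Statistical structure of the rendered variant calls.

    Depth is drawn from a negative binomial with the given mean and
    dispersion (Poisson overdispersed by coverage variability); true calls
    get a clean haploid allele fraction and qualities above every filter
    threshold, decoy calls get evidence drawn below the one threshold they
    are built to violate.
    """

    mean_depth: float = 50.0
    depth_dispersion: float = 5.0
    clean_vaf: float = 1.0
    contaminant_vaf_range: tuple[float, float] = (0.10, 0.90)
    min_clean_depth: int = 10
    clean_quality_range: tuple[float, float] = (55.0, 90.0)
    clean_mapping_quality_range: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        for f in (self.clean_vaf, *self.contaminant_vaf_range):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele fractions must be in [0, 1]")

    def draw_depth(self, rng: np.random.Generator) -> int:
        k = self.depth_dispersion
        p = k / (k + self.mean_depth)
        return int(max(self.min_clean_depth, rng.negative_binomial(k, p)))


def sample_mutations(
    genome: GenomeModel,
    profile: MutagenProfile,
    n_mutations: int,
    seed: int,
    *,
    exclude_positions: frozenset[tuple[str, int]] = frozenset(),
) -> list[tuple[str, int, str, str]]:
    """Draw induced substitutions at unique genomic sites.

    Each mutation's pooled class is drawn from the profile weights; A:T
    classes are placed at A/T sites and G:C classes at G/C sites, sampled
    without replacement so positions are unique genome-wide (and outside
    ``exclude_positions``). Raises if a class with positive drawn count has
    no eligible sites, or if the genome has fewer eligible sites than
    requested.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    rng = np.random.default_rng(seed)
    at_sites: list[tuple[str, int, str]] = []
    gc_sites: list[tuple[str, int, str]] = []
    for name, seq in genome.contigs:
        for i, base in enumerate(seq):
            if (name, i + 1) in exclude_positions:
                continue
            (at_sites if base in "AT" else gc_sites).append((name, i + 1, base))
    counts = rng.multinomial(n_mutations, profile.weights_array())
    need_at = sum(
        int(c) for label, c in zip(CLASS_LABELS, counts) if label.startswith("A:T")
    )
    need_gc = n_mutations - need_at
    for label, c in zip(CLASS_LABELS, counts):
        pool = at_sites if label.startswith("A:T") else gc_sites
        if c > 0 and not pool:
            raise ValueError(
                f"profile puts weight on class {label} but the genome has no "
                "eligible sites for it"
            )
    if need_at > len(at_sites) or need_gc > len(gc_sites):
        raise ValueError(
            f"genome too small: need {need_at} A/T and {need_gc} G/C sites, "
            f"have {len(at_sites)} and {len(gc_sites)}"
        )
    at_idx = iter(rng.choice(len(at_sites), size=need_at, replace=False))
    gc_idx = iter(rng.choice(len(gc_sites), size=need_gc, replace=False))
    mutations = []
    for label, c in zip(CLASS_LABELS, counts):
        pool, idx = (
            (at_sites, at_idx) if label.startswith("A:T") else (gc_sites, gc_idx)
        )
        for _ in range(int(c)):
            contig, pos, ref = pool[int(next(idx))]
            mutations.append((contig, pos, ref, ALT_FOR[(label, ref)]))
    mutations.sort(key=lambda m: (m[0], m[1]))
    return mutations


def sample_indels(
    genome: GenomeModel,
    n_insertions: int,
    n_deletions: int,
    seed: int,
    *,
    max_length: int = 3,
    exclude_positions: frozenset[tuple[str, int]] = frozenset(),
) -> list[tuple[str, int, str, str]]:
    """Draw small insertions and deletions with VCF-style anchor bases."""
    rng = np.random.default_rng(seed)
    out: list[tuple[str, int, str, str]] = []
    contigs = genome.contigs
    used = set(exclude_positions)
    for kind, n in (("insertion", n_insertions), ("deletion", n_deletions)):
        for _ in range(n):
            for _try in range(1000):
                name, seq = contigs[int(rng.integers(len(contigs)))]
                length = int(rng.integers(1, max_length + 1))
                pos = int(rng.integers(1, len(seq) - max_length))
                if (name, pos) in used:
                    continue
                anchor = seq[pos - 1]
                if kind == "insertion":
                    ins = "".join(
                        BASES[int(b)] for b in rng.integers(0, 4, size=length)
                    )
                    out.append((name, pos, anchor, anchor + ins))
                else:
                    out.append((name, pos, anchor + seq[pos : pos + length], anchor))
                used.add((name, pos))
                break
            else:
                raise ValueError("could not place indel at a free position")
    out.sort(key=lambda m: (m[0], m[1]))
    return out


#: Decoy categories, one per filter criterion.
DECOY_CRITERIA = ("depth", "quality", "mapping_quality", "vaf", "in_parental")


def _clean_record(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str,
) -> VariantRecord:
    is_sub = len(ref) == len(alt)
    qlo, qhi = noise.clean_quality_range
    mlo, mhi = noise.clean_mapping_quality_range
    return VariantRecord(
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        depth=noise.draw_depth(rng),
        variant_quality=round(float(rng.uniform(max(qlo, 55.0) if not is_sub else qlo, qhi)), 2),
        mapping_quality=round(float(rng.uniform(mlo, mhi)), 2),
        variant_allele_fraction=noise.clean_vaf,
        sample_id=sample_id,
    )


def render_variant_calls(
    genome: GenomeModel,
    true_mutations: list[tuple[str, int, str, str]],
    parental_variants: list[tuple[str, int, str, str]],
    noise: NoiseModel,
    n_decoys: int,
    seed: int,
    *,
    sample_id: str = "sample",
    true_indels: list[tuple[str, int, str, str]] = [],
    exclude_positions: frozenset[tuple[str, int]] = frozenset(),
) -> tuple[list[VariantRecord], list[VariantRecord], list[dict]]:
    """Render a per-sample call set, the parental call set, and a truth table.

    The sample set contains every true mutation and indel with clean
    evidence, the inherited parental variants (called against the reference
    just like real resequencing would), and ``n_decoys`` decoy records that
    each violate one filter criterion, cycling through depth, quality,
    mapping quality, allele fraction and presence-in-parental. The truth
    table records, for every sample record, which criterion (if any) it was
    built to violate.
    """
    rng = np.random.default_rng(seed)
    sample: list[VariantRecord] = []
    parental: list[VariantRecord] = []
    truth: list[dict] = []
    used = {(m[0], m[1]) for m in true_mutations}
    used |= {(m[0], m[1]) for m in true_indels}
    used |= {(m[0], m[1]) for m in parental_variants}
    used |= set(exclude_positions)  # decoy sites must avoid these too

    for contig, pos, ref, alt in parental_variants:
        parental.append(
            _clean_record(contig, pos, ref, alt, noise, rng, "parental")
        )
        sample.append(_clean_record(contig, pos, ref, alt, noise, rng, sample_id))
        truth.append(
            dict(contig=contig, pos=pos, ref=ref, alt=alt, violated_criterion="in_parental")
        )
    for contig, pos, ref, alt in list(true_mutations) + list(true_indels):
        sample.append(_clean_record(contig, pos, ref, alt, noise, rng, sample_id))
        truth.append(
            dict(contig=contig, pos=pos, ref=ref, alt=alt, violated_criterion="none")
        )

    def free_site() -> tuple[str, int, str]:
        for _try in range(10000):
            name, seq = genome.contigs[int(rng.integers(len(genome.contigs)))]
            pos = int(rng.integers(1, len(seq) + 1))
            if (name, pos) not in used:
                used.add((name, pos))
                return name, pos, seq[pos - 1]
        raise ValueError("could not find a free decoy site")

    vlo, vhi = noise.contaminant_vaf_range
    for i in range(n_decoys):
        criterion = DECOY_CRITERIA[i % len(DECOY_CRITERIA)]
        contig, pos, ref = free_site()
        alt = rng.choice([b for b in BASES if b != ref])
        rec = _clean_record(contig, pos, ref, str(alt), noise, rng, sample_id)
        if criterion == "depth":
            rec = replace(rec, depth=int(rng.integers(0, 10)))
        elif criterion == "quality":
            rec = replace(rec, variant_quality=round(float(rng.uniform(0, 19.9)), 2))
        elif criterion == "mapping_quality":
            rec = replace(rec, mapping_quality=round(float(rng.uniform(0, 29.9)), 2))
        elif criterion == "vaf":
            rec = replace(
                rec, variant_allele_fraction=round(float(rng.uniform(vlo, vhi)), 3)
            )
        elif criterion == "in_parental":
            parental.append(replace(rec, sample_id="parental"))
        sample.append(rec)
        truth.append(
            dict(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                violated_criterion=criterion,
            )
        )

    sample.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))
    parental.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))
    truth.sort(key=lambda t: (t["contig"], t["pos"], t["ref"], t["alt"]))
    return sample, parental, truth
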