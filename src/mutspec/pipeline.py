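"""End-to-end orchestration: simulate a study, run the full analysis, write
the report bundle.

``simulate_study`` produces a complete input bundle (reference FASTA, GFF3
annotation, parental VCF, per-sample VCFs for two mutagen groups, truth
tables). ``run_pipeline`` consumes such a bundle — or real files with the
same formats — and executes parental subtraction, the filtering cascade,
feature assignment, substitution-spectrum pooling, codon-level impact, and
the count/spectrum/feature/protein report tables, all deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .filtering import (
    CountSummary,
    FilterConfig,
    FilterOutcome,
    apply_filters,
    apply_region_mask,
    subtract_parental,
    summarize_counts,
)
from .genome import GenomeModel, generate_genome
from .protein import ProteinImpactRecord, codon_effect, protein_table, protein_table_rows
from .simulate import (
    MutagenProfile,
    NoiseModel,
    render_variant_calls,
    sample_indels,
    sample_mutations,
)
from .spectrum import (
    TRANSITION_LABELS,
    FeatureAssignment,
    SpectrumSummary,
    assign_feature,
    classify_substitution,
    feature_counts,
    spectrum_summary,
)

logger = logging.getLogger("mutspec")


@dataclass(frozen=True)
class MutationCall:
    """A variant that passed all filters, with its annotations."""

    record: object  # VariantRecord
    feature: FeatureAssignment | None = None
    substitution_class: str | None = None
    impact: ProteinImpactRecord | None = None

    @property
    def ref(self) -> str:
        return self.record.ref

    @property
    def alt(self) -> str:
        return self.record.alt


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run."""

    reference_fasta: str
    annotation_gff: str
    parental_vcf: str
    sample_vcfs: dict[str, str]  # sample_id -> path
    groups: dict[str, str]  # sample_id -> group label
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    generations: dict[str, float] = field(default_factory=dict)  # group -> divisions
    callable_sites: float | None = None  # per-strain callable site count
    mask_bed: str | None = None
    out_dir: str = "mutspec_report"
    seed: int = 0

    def validate(self) -> None:
        missing = [
            p
            for p in [self.reference_fasta, self.annotation_gff, self.parental_vcf,
                      *self.sample_vcfs.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        unlabeled = set(self.sample_vcfs) - set(self.groups)
        if unlabeled:
            raise ValueError(f"samples without a group label: {sorted(unlabeled)}")


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run (everything is also on disk)."""

    counts: CountSummary
    outcomes: dict[str, list[FilterOutcome]]
    calls_by_group: dict[str, list[MutationCall]]
    spectra: dict[tuple[str, str], SpectrumSummary]  # (group, scope) -> summary
    features: dict[str, dict[str, int]]  # group -> feature counts
    protein_tables: dict[str, object]  # group -> ProteinLevelTable
    rates: pd.DataFrame | None
    out_dir: Path


def _annotate(record, genome: GenomeModel) -> MutationCall:
    feature = assign_feature(record.contig, record.pos, genome)
    sub_class = classify_substitution(record.ref, record.alt).label
    impact = None
    if feature.feature == "exon":
        impact = codon_effect(record, genome)
    return MutationCall(
        record=record,
        feature=feature,
        substitution_class=sub_class,
        impact=impact,
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write the report bundle.

    Stages: parental subtraction → five-criterion filtering → gene-feature
    assignment → substitution-class pooling → codon-level impact → report
    tables (per-sample counts, per-group spectra genome-wide and
    nonsynonymous-only, feature distribution, protein-level table, and —
    when callable sites are configured — per-site rates). Identical inputs
    give identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = mio.read_genome(config.reference_fasta, config.annotation_gff)
    contig_lengths = {name: len(seq) for name, seq in genome.contigs}
    parental = mio.read_vcf(config.parental_vcf, sample_id="parental")
    mask = mio.read_bed_mask(config.mask_bed) if config.mask_bed else None
    log: list[dict] = []

    outcomes: dict[str, list[FilterOutcome]] = {}
    rejection_rows = []
    for sample_id, path in sorted(config.sample_vcfs.items()):
        calls = mio.read_vcf(path, sample_id=sample_id)
        n_in = len(calls)
        if mask:
            calls, masked = apply_region_mask(calls, mask)
        else:
            masked = []
        calls = subtract_parental(calls, parental)
        outs = apply_filters(calls, config.filter_config)
        outcomes[sample_id] = outs
        passed = [o.record for o in outs if o.passed]
        mio.write_vcf(passed, contig_lengths, out / f"{sample_id}.filtered.vcf")
        for o in outs:
            if not o.passed:
                rejection_rows.append(
                    {
                        "sample": sample_id,
                        "contig": o.record.contig,
                        "pos": o.record.pos,
                        "ref": o.record.ref,
                        "alt": o.record.alt,
                        "failed_criteria": ",".join(sorted(o.failed_criteria)),
                    }
                )
        log.append(
            {
                "stage": "filter",
                "sample": sample_id,
                "records_in": n_in,
                "masked": len(masked),
                "passed": len(passed),
                "rejected": len(outs) - len(passed),
            }
        )
        logger.info("filter %s: %d in, %d passed", sample_id, n_in, len(passed))
    pd.DataFrame(
        rejection_rows,
        columns=["sample", "contig", "pos", "ref", "alt", "failed_criteria"],
    ).to_csv(out / "rejections.tsv", sep="\t", index=False)

    counts = summarize_counts(outcomes, config.groups)
    counts.per_sample.to_csv(out / "counts_per_sample.tsv", sep="\t", index=False)
    counts.per_group.to_csv(out / "counts_per_group.tsv", sep="\t", index=False)
    if counts.welch is not None:
        counts.welch.to_csv(out / "counts_welch.tsv", sep="\t", index=False)

    calls_by_group: dict[str, list[MutationCall]] = {}
    snv_counts_by_group: dict[str, list[int]] = {}
    for sample_id, outs in outcomes.items():
        group = config.groups[sample_id]
        snvs = [
            o.record
            for o in outs
            if o.passed and o.record.kind == "substitution"
        ]
        snv_counts_by_group.setdefault(group, []).append(len(snvs))
        annotated = [_annotate(r, genome) for r in snvs]
        calls_by_group.setdefault(group, []).extend(annotated)
        log.append({"stage": "annotate", "sample": sample_id, "snvs": len(snvs)})

    spectra: dict[tuple[str, str], SpectrumSummary] = {}
    features: dict[str, dict[str, int]] = {}
    tables: dict[str, object] = {}
    spec_rows, feat_rows, prot_rows = [], [], []
    for group in sorted(calls_by_group):
        calls = calls_by_group[group]
        for scope in ("genome_wide", "nonsynonymous_only"):
            scoped = (
                calls
                if scope == "genome_wide"
                else [c for c in calls if c.impact is not None]
            )
            summ = spectrum_summary(scoped, scope=scope)
            spectra[(group, scope)] = summ
            freqs = summ.frequencies or {}
            for label, count in summ.counts.items():
                spec_rows.append(
                    {
                        "group": group,
                        "scope": scope,
                        "class": label,
                        "transition": label in TRANSITION_LABELS,
                        "count": count,
                        "frequency": freqs.get(label, float("nan")),
                    }
                )
            spec_rows.append(
                {
                    "group": group,
                    "scope": scope,
                    "class": "transition_fraction",
                    "transition": True,
                    "count": sum(
                        v for k, v in summ.counts.items() if k in TRANSITION_LABELS
                    ),
                    "frequency": summ.transition_fraction
                    if summ.transition_fraction is not None
                    else float("nan"),
                }
            )
        fc = feature_counts(c.feature for c in calls)
        features[group] = fc
        total = sum(fc.values())
        for feat, count in fc.items():
            feat_rows.append(
                {
                    "group": group,
                    "feature": feat,
                    "count": count,
                    "frequency": count / total if total else float("nan"),
                }
            )
        table = protein_table(c.impact for c in calls if c.impact is not None)
        tables[group] = table
        for row in protein_table_rows(table):
            prot_rows.append({"group": group, **row})
    pd.DataFrame(spec_rows).to_csv(out / "spectrum.tsv", sep="\t", index=False)
    pd.DataFrame(feat_rows).to_csv(out / "features.tsv", sep="\t", index=False)
    pd.DataFrame(prot_rows).to_csv(out / "protein_table.tsv", sep="\t", index=False)

    rates_df = None
    if config.callable_sites is not None:
        from .rates import per_site_rate

        rrows = []
        for group, ns in sorted(snv_counts_by_group.items()):
            g = config.generations.get(group, 1.0)
            est = per_site_rate(ns, [config.callable_sites] * len(ns), g)
            rrows.append(
                {
                    "group": group,
                    "generations": g,
                    "per_site_rate": est.per_site_rate,
                    "standard_error": est.standard_error,
                    "n_strains": est.n_strains,
                }
            )
        rates_df = pd.DataFrame(rrows)
        rates_df.to_csv(out / "per_site_rates.tsv", sep="\t", index=False)

    (out / "pipeline_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return PipelineReport(
        counts=counts,
        outcomes=outcomes,
        calls_by_group=calls_by_group,
        spectra=spectra,
        features=features,
        protein_tables=tables,
        rates=rates_df,
        out_dir=out,
    )


@dataclass
class StudyConfig:
    """Parameters of the simulated two-mutagen resequencing study.

    Defaults emulate the study conditions: two groups of five clones, an
    EMS-like group averaging 56 SNVs per strain (transition-dominated) and
    a polymerase-delta mutator group averaging 7 (transversion-dominated),
    with Poisson strain-to-strain variation, small indel loads, inherited
    parental variants, and one decoy per filter criterion per sample — all
    on a 50 kb single-contig toy genome with 10 genes.
    """

    out_dir: str = "mutspec_study"
    seed: int = 0
    samples_per_group: int = 5
    mean_snvs: dict[str, float] = field(
        default_factory=lambda: {"ems": 56.0, "mutator": 7.0}
    )
    mean_deletions: dict[str, float] = field(
        default_factory=lambda: {"ems": 2.8, "mutator": 1.6}
    )
    mean_insertions: dict[str, float] = field(
        default_factory=lambda: {"ems": 0.6, "mutator": 0.2}
    )
    profiles: dict[str, MutagenProfile] = field(
        default_factory=lambda: {
            "ems": MutagenProfile.ems(),
            "mutator": MutagenProfile.mutator(),
        }
    )
    generations: dict[str, float] = field(
        default_factory=lambda: {"ems": 1.0, "mutator": 30.0}
    )
    n_parental_variants: int = 30
    n_decoys_per_sample: int = 5
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_contigs: int = 1
    contig_length: int = 50_000
    n_genes: int = 10
    gc_content: float = 0.38
    intron_fraction: float = 0.0
    poisson_strain_counts: bool = True


@dataclass
class StudyBundle:
    """File paths of a simulated study plus a ready-to-run PipelineConfig."""

    genome: GenomeModel
    reference_fasta: str
    annotation_gff: str
    parental_vcf: str
    sample_vcfs: dict[str, str]
    groups: dict[str, str]
    truth_tables: dict[str, str]
    pipeline_config: PipelineConfig


def simulate_study(cfg: StudyConfig) -> StudyBundle:
    """Generate a full input bundle for :func:`run_pipeline`, per seed."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome = generate_genome(
        n_contigs=cfg.n_contigs,
        contig_length=cfg.contig_length,
        n_genes=cfg.n_genes,
        gc_content=cfg.gc_content,
        seed=int(rng.integers(2**31)),
        intron_fraction=cfg.intron_fraction,
    )
    contig_lengths = {name: len(seq) for name, seq in genome.contigs}
    fasta = out / "reference.fasta"
    gff = out / "annotation.gff3"
    mio.write_fasta(genome, fasta)
    mio.write_gff3(genome, gff)

    # Parental variants: substitutions the parent carries vs the reference.
    parental_mutations = sample_mutations(
        genome,
        MutagenProfile.from_aggregate(0.5),
        cfg.n_parental_variants,
        seed=int(rng.integers(2**31)),
    )

    sample_vcfs: dict[str, str] = {}
    groups: dict[str, str] = {}
    truths: dict[str, str] = {}
    parental_records_all: list | None = None

    # Draw every sample's true mutations and indels before rendering any
    # decoys, so decoy sites (which can enter the shared parental VCF as
    # present-in-parental decoys) never collide with a true mutation of a
    # different sample.
    drawn: list[tuple[str, list, list]] = []  # (sample_id, muts, indels)
    global_sites: set[tuple[str, int]] = {(m[0], m[1]) for m in parental_mutations}
    for group in sorted(cfg.mean_snvs):
        profile = cfg.profiles[group]
        for i in range(1, cfg.samples_per_group + 1):
            sample_id = f"{group}{i}"
            groups[sample_id] = group
            mean = cfg.mean_snvs[group]
            n_snv = (
                int(rng.poisson(mean)) if cfg.poisson_strain_counts else int(round(mean))
            )
            n_del = int(rng.poisson(cfg.mean_deletions.get(group, 0.0)))
            n_ins = int(rng.poisson(cfg.mean_insertions.get(group, 0.0)))
            muts = sample_mutations(
                genome,
                profile,
                n_snv,
                seed=int(rng.integers(2**31)),
                exclude_positions=frozenset(
                    (m[0], m[1]) for m in parental_mutations
                ),
            )
            exclude = frozenset(
                global_sites | {(m[0], m[1]) for m in muts}
            )
            indels = sample_indels(
                genome,
                n_ins,
                n_del,
                seed=int(rng.integers(2**31)),
                exclude_positions=exclude,
            )
            drawn.append((sample_id, muts, indels))
            global_sites |= {(m[0], m[1]) for m in muts}
            global_sites |= {(m[0], m[1]) for m in indels}

    for sample_id, muts, indels in drawn:
        sample_recs, parental_recs, truth = render_variant_calls(
            genome,
            muts,
            parental_mutations,
            cfg.noise,
            cfg.n_decoys_per_sample,
            seed=int(rng.integers(2**31)),
            sample_id=sample_id,
            true_indels=indels,
            exclude_positions=frozenset(global_sites),
        )
        # decoy sites included, so no later sample reuses them
        global_sites |= {(r["contig"], r["pos"]) for r in truth}
        if parental_records_all is None:
            parental_records_all = parental_recs
        else:
            # keep the in-parental decoy records of every sample
            seen = {r.key for r in parental_records_all}
            parental_records_all.extend(
                r for r in parental_recs if r.key not in seen
            )
        vcf_path = out / f"{sample_id}.vcf"
        mio.write_vcf(sample_recs, contig_lengths, vcf_path)
        truth_path = out / f"{sample_id}.truth.tsv"
        mio.write_truth_table(truth, truth_path)
        sample_vcfs[sample_id] = str(vcf_path)
        truths[sample_id] = str(truth_path)

    parental_vcf = out / "parental.vcf"
    mio.write_vcf(parental_records_all or [], contig_lengths, parental_vcf)

    pipeline_config = PipelineConfig(
        reference_fasta=str(fasta),
        annotation_gff=str(gff),
        parental_vcf=str(parental_vcf),
        sample_vcfs=sample_vcfs,
        groups=groups,
        generations=dict(cfg.generations),
        out_dir=str(out / "report"),
        seed=cfg.seed,
    )
    return StudyBundle(
        genome=genome,
        reference_fasta=str(fasta),
        annotation_gff=str(gff),
        parental_vcf=str(parental_vcf),
        sample_vcfs=sample_vcfs,
        groups=groups,
        truth_tables=truths,
        pipeline_config=pipeline_config,
    )
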