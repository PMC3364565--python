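"""Variant filtering: parental subtraction plus the five acceptance criteria.

A called variant is accepted as a mutation only when all of the following
hold: read depth at the site is at least 10; the variant is absent from the
sequenced parental strain; the Phred-scaled variant quality reaches 20 for
substitutions or 50 for indels; mapping quality reaches 30; and the variant
allele fraction strictly exceeds 0.90 (haploid expectation). Every rejected
record carries the complete set of criteria it violated, so the filtering
waterfall is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Names of the five rejection criteria, in reporting order.
CRITERIA = ("depth", "in_parental", "quality", "mapping_quality", "vaf")


class MissingAnnotationError(ValueError):
    """A record lacks an annotation the filter needs (never a silent pass)."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with the evidence annotations the filter consumes.

    ``kind`` is derived from the alleles: equal-length single bases are
    substitutions, longer alt is an insertion, longer ref a deletion.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int | None
    variant_quality: float | None
    mapping_quality: float | None
    variant_allele_fraction: float | None
    sample_id: str = ""
    in_parental: bool = False

    def __post_init__(self) -> None:
        if len(self.ref) == len(self.alt) and len(self.ref) != 1:
            raise ValueError(
                f"{self.contig}:{self.pos} {self.ref}>{self.alt}: "
                "multi-nucleotide substitutions are not supported"
            )
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")
        vaf = self.variant_allele_fraction
        if vaf is not None and not 0.0 <= vaf <= 1.0:
            raise ValueError("variant allele fraction must be in [0, 1]")

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt):
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Acceptance thresholds. Depth/quality/MQ are inclusive minima; the
    allele-fraction bound is exclusive ("exceeds 90%")."""

    min_depth: int = 10
    min_quality_substitution: float = 20.0
    min_quality_indel: float = 50.0
    min_mapping_quality: float = 30.0
    min_vaf_exclusive: float = 0.90

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_quality_substitution",
            "min_quality_indel",
            "min_mapping_quality",
            "min_vaf_exclusive",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FilterOutcome:
    record: VariantRecord
    failed_criteria: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def subtract_parental(
    sample_calls: Iterable[VariantRecord],
    parental_calls: Iterable[VariantRecord],
) -> list[VariantRecord]:
    """Flag sample calls that are present in the parental strain.

    A call matches the parental set when an identical (contig, pos, ref,
    alt) record exists there. All input records are preserved, with the
    ``in_parental`` flag set accordingly. A contig seen in the sample but
    never in a non-empty parental set draws a warning and is treated as
    not-parental.
    """
    parental = list(parental_calls)
    parental_keys = {p.key for p in parental}
    parental_contigs = {p.contig for p in parental}
    out = []
    warned: set[str] = set()
    for rec in sample_calls:
        if (
            parental
            and rec.contig not in parental_contigs
            and rec.contig not in warned
        ):
            warnings.warn(
                f"contig {rec.contig!r} absent from the parental call set; "
                "treating its calls as not-parental",
                stacklevel=2,
            )
            warned.add(rec.contig)
        out.append(replace(rec, in_parental=rec.key in parental_keys))
    return out


def _check_annotations(rec: VariantRecord) -> None:
    for attr in ("depth", "variant_quality", "mapping_quality", "variant_allele_fraction"):
        if getattr(rec, attr) is None:
            raise MissingAnnotationError(
                f"record {rec.contig}:{rec.pos} {rec.ref}>{rec.alt} "
                f"(sample {rec.sample_id!r}) is missing {attr}"
            )


def apply_filters(
    calls: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[FilterOutcome]:
    """Evaluate every call against all criteria; record every violation.

    Records must carry depth, both qualities and the allele fraction —
    a missing annotation raises :class:`MissingAnnotationError` rather
    than passing silently.
    """
    outcomes = []
    for rec in calls:
        _check_annotations(rec)
        failed = set()
        if rec.depth < config.min_depth:
            failed.add("depth")
        min_q = (
            config.min_quality_substitution
            if rec.kind == "substitution"
            else config.min_quality_indel
        )
        if rec.variant_quality < min_q:
            failed.add("quality")
        if rec.mapping_quality < config.min_mapping_quality:
            failed.add("mapping_quality")
        if not rec.variant_allele_fraction > config.min_vaf_exclusive:
            failed.add("vaf")
        if rec.in_parental:
            failed.add("in_parental")
        outcomes.append(FilterOutcome(record=rec, failed_criteria=frozenset(failed)))
    return outcomes


def apply_region_mask(
    calls: Iterable[VariantRecord],
    mask_intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split calls into (kept, excluded) by a mask of 1-based inclusive
    intervals per contig (e.g. repetitive regions excluded upstream of
    variant calling in the original protocol)."""
    kept, excluded = [], []
    for rec in calls:
        ivs = mask_intervals.get(rec.contig, ())
        if any(s <= rec.pos <= e for s, e in ivs):
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


KINDS = ("substitution", "insertion", "deletion")


@dataclass(frozen=True)
class CountSummary:
    """Per-sample accepted-mutation counts and per-group mean ± SE."""

    per_sample: pd.DataFrame  # sample, group, substitution, insertion, deletion
    per_group: pd.DataFrame  # group, kind, n_samples, mean, se
    welch: pd.DataFrame | None  # kind, group_a, group_b, t, p (two groups only)


def summarize_counts(
    outcomes_by_sample: Mapping[str, Sequence[FilterOutcome]],
    groups: Mapping[str, str] | None = None,
) -> CountSummary:
    """Count accepted mutations per sample and summarize per group.

    Mean is the arithmetic mean over samples in a group; SE is the sample
    standard deviation divided by sqrt(n); with a single sample the SE is
    reported as not-available (NaN). With exactly two groups a Welch
    two-sample t-test compares them per mutation kind.
    """
    if not outcomes_by_sample:
        raise ValueError("need at least one sample")
    groups = groups or {s: "all" for s in outcomes_by_sample}
    rows = []
    for sample, outcomes in outcomes_by_sample.items():
        row = {"sample": sample, "group": groups.get(sample, "all")}
        for kind in KINDS:
            row[kind] = sum(
                1 for o in outcomes if o.passed and o.record.kind == kind
            )
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    grows = []
    for group, sub in per_sample.groupby("group"):
        for kind in KINDS:
            vals = sub[kind].to_numpy(dtype=float)
            se = (
                float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
            grows.append(
                {
                    "group": group,
                    "kind": kind,
                    "n_samples": len(vals),
                    "mean": float(np.mean(vals)),
                    "se": se,
                }
            )
    per_group = pd.DataFrame(grows)

    welch = None
    group_names = sorted(per_sample["group"].unique())
    if len(group_names) == 2:
        a, b = group_names
        wrows = []
        for kind in KINDS:
            xa = per_sample.loc[per_sample["group"] == a, kind]
            xb = per_sample.loc[per_sample["group"] == b, kind]
            if len(xa) > 1 and len(xb) > 1:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
            else:
                t, p = float("nan"), float("nan")
            wrows.append(
                {"kind": kind, "group_a": a, "group_b": b, "t": float(t), "p": float(p)}
            )
        welch = pd.DataFrame(wrows)
    return CountSummary(per_sample=per_sample, per_group=per_group, welch=welch)
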