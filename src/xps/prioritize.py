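"""The extreme-phenotype case/control/panel prioritization cascade.

Given site-filtered, consequence-annotated variants, three steps shrink
the candidate list:

(i)   ``case_exclusive``  -- keep variants whose alternate allele is
      carried by every extreme-phenotype case and by no sequenced control;
(ii)  ``effect_partition`` -- keep large-effect variants (stop_gained,
      frameshift, splice_site) and, separately, missense variants;
(iii) ``panel_exclude``   -- drop anything whose identical normalized
      allele is carried in a population panel of unaffected genomes.

``run_prioritization`` chains the site filters, annotation and the three
steps on in-memory objects; ``run_pipeline`` is the file-level driver that
reads a YAML-style config, runs everything and serializes the report.
The candidate set can only shrink at each stage, and every removed variant
is attributable to one stage through the shared :class:`FilterTrace`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .consequence import ConsequenceCall, annotate_variants
from .io_formats import (
    CohortDesign,
    GeneModel,
    GenomicVariant,
    RepeatMask,
    read_bed,
    read_fasta,
    read_gff,
    read_variants,
)
from .site_filters import ClusterParams, FilterTrace, apply_site_filters

log = logging.getLogger(__name__)

STAGE_CASE = "case_exclusive"
STAGE_EFFECT = "effect"
STAGE_PANEL = "panel"

LARGE_EFFECTS = frozenset({"stop_gained", "frameshift", "splice_site"})

VariantKey = tuple[str, int, str, str]


def case_exclusive(
    variants: Sequence[GenomicVariant],
    design: CohortDesign,
    min_case_carriers: int | None = None,
    trace: FilterTrace | None = None,
) -> list[GenomicVariant]:
    """Step (i): variants carried by every case and by no control.

    ``min_case_carriers`` relaxes the all-cases rule for designs with more
    cases; the default requires carriage in every case.  A case sample
    entirely absent from the genotype map is an error -- exclusivity
    cannot be asserted without evidence.  A missing *control* genotype is
    treated as non-carriage but logged.
    """
    if trace is not None:
        trace.register(variants)
    need = len(design.case_ids) if min_case_carriers is None else min_case_carriers
    retained: list[GenomicVariant] = []
    for v in variants:
        absent_cases = [c for c in design.case_ids if c not in v.genotypes]
        if absent_cases:
            raise ValueError(
                f"case sample(s) {absent_cases} absent from variant "
                f"{v.chrom}:{v.pos}; cannot assert case-exclusivity"
            )
        carriers = sum(1 for c in design.case_ids if v.carries_alt(c))
        control_hit = False
        for c in design.control_ids:
            gt = v.genotypes.get(c)
            if gt is None or all(a is None for a in gt):
                log.debug(
                    "missing control genotype %s at %s:%d treated as non-carrier",
                    c, v.chrom, v.pos,
                )
                continue
            if 1 in gt:
                control_hit = True
                break
        if carriers >= need and not control_hit:
            retained.append(v)
        elif trace is not None:
            trace.mark_removed(v.key, STAGE_CASE)
    return retained


@dataclass(frozen=True)
class EffectPartition:
    large_effect: tuple[GenomicVariant, ...]
    missense: tuple[GenomicVariant, ...]
    dropped: tuple[GenomicVariant, ...]


def effect_partition(
    variants: Sequence[GenomicVariant],
    calls: Mapping[VariantKey, ConsequenceCall],
    large_effects: frozenset[str] = LARGE_EFFECTS,
    trace: FilterTrace | None = None,
) -> EffectPartition:
    """Step (ii): exact partition into large-effect / missense / dropped.

    Every variant must carry a worst-effect call; a missing call is an
    error because annotation has to precede this step.
    """
    large: list[GenomicVariant] = []
    mis: list[GenomicVariant] = []
    dropped: list[GenomicVariant] = []
    for v in variants:
        call = calls.get(v.key)
        if call is None:
            raise ValueError(f"variant {v.key} has no consequence call")
        if call.effect in large_effects:
            large.append(v)
        elif call.effect == "missense":
            mis.append(v)
        else:
            dropped.append(v)
            if trace is not None:
                trace.mark_removed(v.key, STAGE_EFFECT)
    return EffectPartition(tuple(large), tuple(mis), tuple(dropped))


def panel_carried_keys(
    panel_variants: Iterable[GenomicVariant],
    panel_ids: Sequence[str] | None = None,
) -> set[VariantKey]:
    """Normalized keys of alleles carried by at least one panel sample.

    Missing panel genotypes do not count as carriage.  ``panel_ids=None``
    means every sample in the panel records; an explicit empty sequence
    means a zero-genome panel (nothing is carried).
    """
    keys: set[VariantKey] = set()
    for v in panel_variants:
        samples = list(v.genotypes) if panel_ids is None else list(panel_ids)
        if any(v.carries_alt(s) for s in samples):
            keys.add(v.key)
    return keys


def panel_exclude(
    variants: Sequence[GenomicVariant],
    panel_variants: Iterable[GenomicVariant],
    panel_ids: Sequence[str] | None = None,
    trace: FilterTrace | None = None,
) -> list[GenomicVariant]:
    """Step (iii): drop variants observed in the population panel."""
    carried = panel_carried_keys(panel_variants, panel_ids)
    retained = []
    for v in variants:
        if v.key in carried:
            if trace is not None:
                trace.mark_removed(v.key, STAGE_PANEL)
        else:
            retained.append(v)
    return retained


@dataclass(frozen=True)
class Candidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    effect: str
    protein_change: str
    case_zygosity: Mapping[str, str]

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PrioritizationReport:
    """Stage-by-stage accounting of one cascade run."""

    stage_counts: dict[str, int]
    effect_breakdown: dict[str, int]
    candidates: list[Candidate]
    missense_candidates: list[Candidate]
    trace: FilterTrace

    def __post_init__(self) -> None:
        ordered = [
            self.stage_counts[k]
            for k in (
                "input",
                "after_cluster",
                "after_repeat",
                "after_region",
                "after_case_exclusive",
                "after_effect",
                "final",
            )
        ]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"stage counts must be non-increasing: {self.stage_counts}")

    def to_dict(self) -> dict:
        def cand(c: Candidate) -> dict:
            d = dataclasses.asdict(c)
            d["case_zygosity"] = dict(c.case_zygosity)
            return d

        return {
            "stage_counts": self.stage_counts,
            "effect_breakdown": self.effect_breakdown,
            "candidates": [cand(c) for c in self.candidates],
            "missense_candidates": [cand(c) for c in self.missense_candidates],
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        rows = [
            {**dataclasses.asdict(c), "tier": tier, "case_zygosity": ";".join(
                f"{k}={v}" for k, v in c.case_zygosity.items())}
            for tier, cands in (
                ("large_effect", self.candidates),
                ("missense", self.missense_candidates),
            )
            for c in cands
        ]
        pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "gene_id", "transcript_id",
                     "effect", "protein_change", "tier", "case_zygosity"],
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        self.trace.write_tsv(out / "trace.tsv")


@dataclass(frozen=True)
class PipelineParams:
    cluster: ClusterParams = field(default_factory=ClusterParams)
    splice_window: int = 2
    min_case_carriers: int | None = None
    large_effects: frozenset[str] = LARGE_EFFECTS


def run_prioritization(
    cohort_variants: Sequence[GenomicVariant],
    panel_variants: Sequence[GenomicVariant],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    repeat_mask: RepeatMask,
    design: CohortDesign,
    params: PipelineParams | None = None,
) -> PrioritizationReport:
    """Full cascade on in-memory objects; deterministic given its inputs."""
    params = params or PipelineParams()
    variants = sorted(cohort_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    trace = FilterTrace()
    trace.register(variants)

    from .site_filters import cluster_filter, region_filter, repeat_filter

    counts: dict[str, int] = {"input": len(variants)}
    v, _ = cluster_filter(variants, params.cluster, trace)
    counts["after_cluster"] = len(v)
    v, _ = repeat_filter(v, repeat_mask, trace)
    counts["after_repeat"] = len(v)
    v, _ = region_filter(v, gene_models, params.splice_window, trace)
    counts["after_region"] = len(v)
    log.info("site filters: %d -> %d variants", counts["input"], counts["after_region"])

    calls = annotate_variants(v, gene_models, genome, params.splice_window)

    v = case_exclusive(v, design, params.min_case_carriers, trace)
    counts["after_case_exclusive"] = len(v)

    part = effect_partition(v, calls, params.large_effects, trace)
    breakdown: dict[str, int] = {e: 0 for e in sorted(params.large_effects)}
    for var in part.large_effect:
        breakdown[calls[var.key].effect] += 1
    breakdown["missense"] = len(part.missense)
    counts["after_effect"] = len(part.large_effect) + len(part.missense)

    panel_ids = design.panel_ids or None
    large = panel_exclude(part.large_effect, panel_variants, panel_ids, trace)
    mis = panel_exclude(part.missense, panel_variants, panel_ids, trace)
    counts["final"] = len(large) + len(mis)
    log.info(
        "cascade: %d case-exclusive, %d large-effect + %d missense, "
        "%d + %d after panel exclusion",
        counts["after_case_exclusive"], len(part.large_effect), len(part.missense),
        len(large), len(mis),
    )

    def to_candidate(var: GenomicVariant) -> Candidate:
        call = calls[var.key]
        gene = next(
            (m.gene_id for m in gene_models if m.transcript_id == call.transcript_id),
            "",
        )
        return Candidate(
            chrom=var.chrom, pos=var.pos, ref=var.ref, alt=var.alt,
            gene_id=gene, transcript_id=call.transcript_id,
            effect=call.effect, protein_change=call.protein_change,
            case_zygosity={c: var.zygosity(c) for c in design.case_ids},
        )

    for var in large:
        trace.mark_final(var.key, "candidate_large")
    for var in mis:
        trace.mark_final(var.key, "candidate_missense")

    return PrioritizationReport(
        stage_counts=counts,
        effect_breakdown=breakdown,
        candidates=[to_candidate(x) for x in large],
        missense_candidates=[to_candidate(x) for x in mis],
        trace=trace,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """File-level pipeline configuration (mirrors the YAML config keys)."""

    cohort_vcf: str
    panel_vcf: str
    gff: str
    fasta: str
    design: CohortDesign
    repeats_bed: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = CohortDesign(
            case_ids=tuple(raw["cases"]),
            control_ids=tuple(raw.get("controls", ())),
            panel_ids=tuple(raw.get("panel", ())),
            cohort_size=int(raw.get("cohort_size", 0)),
        )
        params = PipelineParams(
            cluster=ClusterParams(
                window_bp=int(raw.get("cluster_window", 25)),
                min_variants=int(raw.get("cluster_min", 5)),
            ),
            splice_window=int(raw.get("splice_window", 2)),
            min_case_carriers=raw.get("min_case_carriers"),
            large_effects=frozenset(raw.get("large_effects", sorted(LARGE_EFFECTS))),
        )
        return cls(
            cohort_vcf=raw["cohort_vcf"],
            panel_vcf=raw["panel_vcf"],
            gff=raw["gff"],
            fasta=raw["fasta"],
            repeats_bed=raw.get("repeats_bed"),
            design=design,
            params=params,
            out_dir=raw.get("out_dir"),
        )


def run_pipeline(config: PipelineConfig) -> PrioritizationReport:
    """Load the configured inputs, run the cascade and write outputs."""
    needed = list(config.design.case_ids) + list(config.design.control_ids)
    cohort = read_variants(config.cohort_vcf, samples=needed)
    panel = read_variants(
        config.panel_vcf, samples=config.design.panel_ids or None
    )
    models = read_gff(config.gff)
    genome = read_fasta(config.fasta)
    mask = (
        read_bed(config.repeats_bed)
        if config.repeats_bed
        else RepeatMask(intervals={})
    )
    report = run_prioritization(
        cohort, panel, models, genome, mask, config.design, config.params
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
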