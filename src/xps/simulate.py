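"""Synthetic study generator: genomes, cohort variants, ASE counts, phenotypes.

Emits a complete desk-scale study with the statistical structure the
prioritization analysis assumes, so every stage of the pipeline is
exercisable without external data:

* a small multi-gene reference (FASTA + GFF3) with multi-exon genes on
  both strands, ATG starts, clean open reading frames and tandem-repeat
  regions recorded as BED;
* cohort genotypes (cases + sequenced controls) and a population-panel
  VCF containing shared polymorphisms, clustered artifact variants,
  repeat-region variants, case-private decoys of every consequence class
  -- each constructed to violate exactly one cascade stage -- and exactly
  one planted case-shared heterozygous stop-gain that satisfies them all;
* a truth table assigning every emitted variant its intended fate, which
  is what pipeline traces are checked against;
* RNA-seq allele counts at the planted site under the NMD degradation
  model (mutant reads ~ Binomial(depth, (1-delta)/(2-delta)));
* a longitudinal log-normal insulin/glucose phenotype table with the two
  planted hyperinsulinemic outliers.

Default geometry mirrors the motivating study design: 2 extreme cases,
5 sequenced controls, a 31-genome panel, and a 57-animal screening cohort
(39 normal + 18 metabolic-syndrome non-case subjects).  Every output is a
pure function of the config (same seed, byte-identical files).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ase_nmd import AseObservation, expected_mutant_fraction, write_ase_table
from .consequence import CODON_TABLE, CodingSequence, build_cds, revcomp
from .io_formats import (
    CohortDesign,
    GeneModel,
    GenomicVariant,
    RepeatMask,
    write_bed,
    write_fasta,
    write_gff,
    write_vcf,
)
from .prioritize import STAGE_CASE, STAGE_EFFECT, STAGE_PANEL
from .site_filters import STAGE_CLUSTER, STAGE_REGION, STAGE_REPEAT

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_BASES = "ACGT"

# rng stream tags so each generator draws independently from one seed
_TAG_GENOME, _TAG_COHORT, _TAG_ASE, _TAG_PHENO = 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; every output is a function of this.

    The defaults are the study conditions the package documents: cohort
    geometry 2 cases / 5 controls / 31 panel genomes / 57-animal screen, a
    6-fold case insulin elevation over the metabolic-syndrome group, ~30%
    within-group biological variation of fasting insulin (log-SD 0.3),
    RNA depth of ~100 reads over the candidate site and an NMD efficiency
    of 0.8.
    """

    seed: int = 0
    # genome geometry
    n_genes: int = 8
    codon_range: tuple[int, int] = (40, 80)
    exon_range: tuple[int, int] = (2, 4)
    intron_range: tuple[int, int] = (60, 150)
    utr_length: int = 20
    intergenic_range: tuple[int, int] = (250, 500)
    n_repeat_regions: int = 3
    repeat_unit: str = "AC"
    repeat_copies: int = 30
    chrom: str = "chr1"
    # cohort genotypes
    n_cases: int = 2
    n_controls: int = 5
    n_panel: int = 31
    cohort_total: int = 57
    n_background: int = 60
    af_beta: tuple[float, float] = (2.0, 5.0)
    n_clusters: int = 2
    cluster_size: int = 6
    cluster_span: int = 21
    n_repeat_decoys: int = 2
    min_site_spacing: int = 30
    force_control_carrier: bool = True
    plant_causal: bool = True
    plant_decoys: bool = True
    # ASE / NMD
    nmd_delta: float = 0.8
    rna_depth: int = 100
    dna_depth: int = 100
    tissues: tuple[str, ...] = ("muscle", "adipose")
    # phenotypes
    n_normal: int = 39
    n_mets_noncase: int = 18
    insulin_median_normal: float = 25.0
    insulin_median_mets: float = 60.0
    insulin_log_sd: float = 0.3
    case_fold: float = 6.0
    glucose_median_normal: float = 4.6
    glucose_median_mets: float = 5.4
    glucose_log_sd: float = 0.08
    glucose_insulin_coupling: float = -0.1
    case_glucose_factor: float = 0.9
    timepoints_months: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nmd_delta <= 1.0:
            raise ValueError("nmd_delta must be in [0, 1]")
        for name in ("n_genes", "n_cases", "n_controls", "rna_depth", "cohort_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def case_ids(self) -> tuple[str, ...]:
        named = ("950807", "960109")
        if self.n_cases <= len(named):
            return named[: self.n_cases]
        return named + tuple(f"case{i}" for i in range(3, self.n_cases + 1))

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(f"ctrl{i}" for i in range(1, self.n_controls + 1))

    @property
    def panel_ids(self) -> tuple[str, ...]:
        return tuple(f"panel{i:02d}" for i in range(1, self.n_panel + 1))

    @property
    def design(self) -> CohortDesign:
        return CohortDesign(
            case_ids=self.case_ids,
            control_ids=self.control_ids,
            panel_ids=self.panel_ids,
            cohort_size=self.cohort_total,
        )

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    models: list[GeneModel]
    repeats: RepeatMask

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_gff(out / "genes.gff3", self.models)
        write_bed(out / "repeats.bed", self.repeats)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NON_STOP, size=n_codons - 2)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(body) + stop


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, min_len: int = 8
) -> list[int]:
    """Random composition of `total` into `parts` chunks of >= min_len."""
    if parts * min_len > total:
        parts = max(1, total // min_len)
    for _ in range(100):
        if parts == 1:
            return [total]
        cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
        lengths = np.diff(np.concatenate([[0], cuts, [total]]))
        if lengths.min() >= min_len:
            return [int(x) for x in lengths]
    # fall back to an even split
    base = total // parts
    lengths = [base] * parts
    lengths[-1] += total - base * parts
    return lengths


def _phases(cds_plain: list[tuple[int, int]], strand: str) -> list[tuple[int, int, int]]:
    order = cds_plain if strand == "+" else list(reversed(cds_plain))
    out, cum = [], 0
    for s, e in order:
        out.append((s, e, (3 - cum % 3) % 3))
        cum += e - s + 1
    return sorted(out)


def gen_genome(cfg: SimConfig) -> SyntheticGenome:
    """Generate a single-chromosome reference with clean multi-exon genes.

    Every CDS starts with ATG, ends with a stop, contains no internal stop
    and has length divisible by 3; tandem-repeat tracts are embedded in
    some intergenic gaps and reported as the repeat mask.
    """
    rng = cfg.rng(_TAG_GENOME)
    pieces: list[str] = []
    cursor = 0  # 0-based length so far
    models: list[GeneModel] = []
    repeat_ivs: list[tuple[int, int]] = []
    repeat_gaps = set(
        rng.choice(cfg.n_genes, size=min(cfg.n_repeat_regions, cfg.n_genes), replace=False)
    )

    for gi in range(cfg.n_genes):
        gap_len = int(rng.integers(*cfg.intergenic_range))
        gap = _random_seq(rng, gap_len)
        if gi in repeat_gaps:
            tract = cfg.repeat_unit * cfg.repeat_copies
            offset = gap_len // 4
            gap = gap[:offset] + tract + gap[offset + len(tract):]
            if len(gap) < offset + len(tract):
                gap = gap[:offset] + tract
            repeat_ivs.append((cursor + offset, cursor + offset + len(tract)))
        pieces.append(gap)
        cursor += len(gap)

        n_codons = int(rng.integers(cfg.codon_range[0], cfg.codon_range[1] + 1))
        cds_seq = _random_cds(rng, n_codons)
        n_exons = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
        chunks = _split_lengths(rng, len(cds_seq), n_exons)
        n_exons = len(chunks)

        # assemble the gene left-to-right in transcription orientation
        local: list[str] = [_random_seq(rng, cfg.utr_length)]
        exon_local: list[tuple[int, int]] = []  # 0-based half-open, local
        cds_local: list[tuple[int, int]] = []
        off = cfg.utr_length
        cds_pos = 0
        for ci, chunk_len in enumerate(chunks):
            chunk = cds_seq[cds_pos : cds_pos + chunk_len]
            cds_pos += chunk_len
            local.append(chunk)
            exon_start = off - (cfg.utr_length if ci == 0 else 0)
            exon_end = off + chunk_len + (cfg.utr_length if ci == n_exons - 1 else 0)
            exon_local.append((exon_start, exon_end))
            cds_local.append((off, off + chunk_len))
            off += chunk_len
            if ci < n_exons - 1:
                intron = _random_seq(rng, int(rng.integers(*cfg.intron_range)))
                local.append(intron)
                off += len(intron)
        local.append(_random_seq(rng, cfg.utr_length))
        off += cfg.utr_length
        gene_seq = "".join(local)
        assert len(gene_seq) == off

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            gene_seq = revcomp(gene_seq)
            exon_local = sorted((off - e, off - s) for s, e in exon_local)
            cds_local = sorted((off - e, off - s) for s, e in cds_local)

        exons = tuple((cursor + s + 1, cursor + e) for s, e in exon_local)
        cds_plain = [(cursor + s + 1, cursor + e) for s, e in cds_local]
        models.append(
            GeneModel(
                gene_id=f"gene{gi + 1}",
                transcript_id=f"gene{gi + 1}.t1",
                chrom=cfg.chrom,
                strand=strand,
                exons=exons,
                cds=tuple(_phases(cds_plain, strand)),
            )
        )
        pieces.append(gene_seq)
        cursor += len(gene_seq)

    pieces.append(_random_seq(rng, int(rng.integers(*cfg.intergenic_range))))
    genome = {cfg.chrom: "".join(pieces)}
    return SyntheticGenome(
        genome=genome,
        models=models,
        repeats=RepeatMask.from_intervals({cfg.chrom: repeat_ivs}),
    )


# ---------------------------------------------------------------------------
# cohort variants
# ---------------------------------------------------------------------------

CANDIDATE_LARGE = "candidate_large"
CANDIDATE_MISSENSE = "candidate_missense"


@dataclass
class CohortSim:
    cohort_variants: list[GenomicVariant]
    panel_variants: list[GenomicVariant]
    truth: pd.DataFrame
    design: CohortDesign
    planted_key: tuple[str, int, str, str] | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        samples = list(self.design.case_ids) + list(self.design.control_ids)
        write_vcf(out / "cohort.vcf", self.cohort_variants, samples=samples)
        write_vcf(out / "panel.vcf", self.panel_variants,
                  samples=list(self.design.panel_ids))
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


class _SiteRegistry:
    """Tracks claimed positions and enforces a minimum spacing."""

    def __init__(self, spacing: int) -> None:
        self.spacing = spacing
        self._positions: list[int] = []

    def free(self, pos: int) -> bool:
        i = bisect_left(self._positions, pos)
        for j in (i - 1, i):
            if 0 <= j < len(self._positions):
                if abs(self._positions[j] - pos) < self.spacing:
                    return False
        return True

    def free_range(self, lo: int, hi: int) -> bool:
        return all(self.free(p) for p in (lo, hi)) and not any(
            lo <= p <= hi for p in self._positions
        )

    def claim(self, pos: int) -> None:
        insort(self._positions, pos)


def _snv_sites(
    model: GeneModel, cds: CodingSequence, genome: Mapping[str, str]
) -> dict[str, list[tuple[int, str, str]]]:
    """All single-base substitutions per effect class over a CDS.

    Start and stop codons are skipped so the classes stay unambiguous.
    Returned tuples are (genomic pos, ref, alt) on the forward strand.
    """
    out: dict[str, list[tuple[int, str, str]]] = {
        "stop_gained": [], "missense": [], "synonymous": []
    }
    chrom_seq = genome[model.chrom]
    n_codons = len(cds.seq) // 3
    for codon_i in range(1, n_codons - 1):  # skip start and stop codons
        ref_codon = cds.seq[codon_i * 3 : codon_i * 3 + 3]
        ref_aa = CODON_TABLE[ref_codon]
        for offset in range(3):
            idx = codon_i * 3 + offset
            gpos = cds.genomic_positions[idx]
            gref = chrom_seq[gpos - 1]
            for base in _BASES:
                if base == ref_codon[offset]:
                    continue
                alt_codon = ref_codon[:offset] + base + ref_codon[offset + 1 :]
                alt_aa = CODON_TABLE[alt_codon]
                if ref_aa == alt_aa:
                    cls = "synonymous"
                elif alt_aa == "*":
                    cls = "stop_gained"
                elif ref_aa == "*":
                    continue
                else:
                    cls = "missense"
                galt = base if model.strand == "+" else revcomp(base)
                out[cls].append((gpos, gref, galt))
    return out


def _genotypes(
    samples: Sequence[str], carriers: Mapping[str, str]
) -> dict[str, tuple[int | None, ...]]:
    gts: dict[str, tuple[int | None, ...]] = {}
    for s in samples:
        zyg = carriers.get(s, "hom_ref")
        gts[s] = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}[zyg]
    return gts


def _draw_af_genotypes(
    rng: np.random.Generator, samples: Sequence[str], af: float
) -> dict[str, tuple[int, int]]:
    draws = rng.random((len(samples), 2)) < af
    return {s: (int(draws[i, 0]), int(draws[i, 1])) for i, s in enumerate(samples)}


def _overlaps_coding_or_splice(
    pos: int, models: Sequence[GeneModel], splice_window: int = 2
) -> bool:
    for m in models:
        for s, e, _ in m.cds:
            if s <= pos <= e:
                return True
        for s, e in m.splice_windows(splice_window):
            if s <= pos <= e:
                return True
    return False


def gen_cohort(cfg: SimConfig, syn: SyntheticGenome) -> CohortSim:
    """Generate cohort + panel variant calls with a complete truth table.

    Decoys are constructed to violate exactly one cascade stage each, so
    the truth table's ``expected_stage`` is checkable against the pipeline
    trace; backgrounds get their expected stage from geometry and drawn
    genotypes.  With ``plant_causal`` the single causal variant is a
    heterozygous stop-gain shared by all cases and absent from controls
    and panel.
    """
    rng = cfg.rng(_TAG_COHORT)
    design = cfg.design
    cohort_samples = list(design.case_ids) + list(design.control_ids)
    chrom_seq = syn.genome[cfg.chrom]
    registry = _SiteRegistry(cfg.min_site_spacing)

    models = list(syn.models)
    cds_cache = {m.transcript_id: build_cds(m, syn.genome) for m in models}
    site_pools = {
        m.transcript_id: _snv_sites(m, cds_cache[m.transcript_id], syn.genome)
        for m in models
    }
    gene_order = list(rng.permutation(len(models)))

    cohort_variants: list[GenomicVariant] = []
    panel_variants: list[GenomicVariant] = []
    truth_rows: list[dict] = []
    planted_key = None

    def pick_snv(gene_idx: int, cls: str) -> tuple[int, str, str]:
        pool = site_pools[models[gene_idx].transcript_id][cls]
        order = rng.permutation(len(pool))
        for i in order:
            pos, ref, alt = pool[int(i)]
            if registry.free(pos):
                return pos, ref, alt
        raise RuntimeError(
            f"no spaced {cls} site left on gene {models[gene_idx].gene_id}; "
            "increase gene sizes or lower variant density"
        )

    def emit(pos: int, ref: str, alt: str, carriers: Mapping[str, str],
             kind: str, expected: str, in_panel: bool) -> GenomicVariant:
        nonlocal planted_key
        v = GenomicVariant(
            chrom=cfg.chrom, pos=pos, ref=ref, alt=alt,
            genotypes=_genotypes(cohort_samples, carriers),
        )
        registry.claim(pos)
        cohort_variants.append(v)
        truth_rows.append(
            {"chrom": cfg.chrom, "pos": pos, "ref": ref, "alt": alt,
             "kind": kind, "expected_stage": expected}
        )
        if in_panel:
            carrier = str(rng.choice(list(design.panel_ids)))
            panel_variants.append(
                GenomicVariant(
                    chrom=cfg.chrom, pos=pos, ref=ref, alt=alt,
                    genotypes=_genotypes(design.panel_ids, {carrier: "het"}),
                )
            )
        return v

    all_cases = {c: "het" for c in design.case_ids}
    one_case = {design.case_ids[0]: "het"}
    cases_and_control = dict(all_cases, **{design.control_ids[1 % len(design.control_ids)]: "het"})

    gi = iter(gene_order * 4)  # cycle genes; each picker claims spaced sites

    # the planted causal stop-gain
    if cfg.plant_causal:
        g = next(gi)
        pos, ref, alt = pick_snv(g, "stop_gained")
        v = emit(pos, ref, alt, all_cases, "causal_stop_gain", CANDIDATE_LARGE, False)
        planted_key = v.key

    if cfg.plant_decoys:
        # case-private decoys, each violating exactly one stage
        g = next(gi); pos, ref, alt = pick_snv(g, "stop_gained")
        emit(pos, ref, alt, one_case, "one_case_stop", STAGE_CASE, False)

        g = next(gi); pos, ref, alt = pick_snv(g, "stop_gained")
        emit(pos, ref, alt, cases_and_control, "control_carrier_stop", STAGE_CASE, False)

        g = next(gi); pos, ref, alt = pick_snv(g, "synonymous")
        emit(pos, ref, alt, all_cases, "synonymous_decoy", STAGE_EFFECT, False)

        g = next(gi); pos, ref, alt = pick_snv(g, "missense")
        emit(pos, ref, alt, all_cases, "missense_candidate", CANDIDATE_MISSENSE, False)

        g = next(gi); pos, ref, alt = pick_snv(g, "stop_gained")
        emit(pos, ref, alt, all_cases, "panel_stop", STAGE_PANEL, True)

        # frameshift decoy: 1-bp insertion inside CDS, present in the panel
        g = next(gi)
        model = models[g]
        cds = cds_cache[model.transcript_id]
        for idx in rng.permutation(len(cds.genomic_positions)):
            pos = cds.genomic_positions[int(idx)]
            if registry.free(pos):
                break
        ref = chrom_seq[pos - 1]
        ins = ref + str(rng.choice(list(_BASES)))
        emit(pos, ref, ins, all_cases, "panel_frameshift", STAGE_PANEL, True)

        # splice-site decoy: first intronic donor/acceptor base, in the panel
        g = next(gi)
        model = models[g]
        windows = model.splice_windows(1)
        ws, _ = windows[int(rng.integers(len(windows)))]
        ref = chrom_seq[ws - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        emit(ws, ref, alt, all_cases, "panel_splice", STAGE_PANEL, True)

        # deep-intron and UTR decoys: genic but neither coding nor splice
        g = next(gi)
        model = models[g]
        first_exon_end = model.exons[0][1]
        intron_pos = first_exon_end + 10
        ref = chrom_seq[intron_pos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        emit(intron_pos, ref, alt, all_cases, "intron_decoy", STAGE_REGION, False)

        g = next(gi)
        model = models[g]
        utr_pos = None
        for p in range(model.exons[0][0], model.exons[0][1] + 1):
            if not _overlaps_coding_or_splice(p, [model]) and registry.free(p):
                utr_pos = p
                break
        if utr_pos is not None:
            ref = chrom_seq[utr_pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            emit(utr_pos, ref, alt, all_cases, "utr_decoy", STAGE_REGION, False)

        # in-frame 3-bp deletion: passes filters, dropped at the effect step
        g = next(gi)
        model = models[g]
        iv = max(model.cds, key=lambda t: t[1] - t[0])
        for start in rng.permutation(np.arange(iv[0] + 1, iv[1] - 4)):
            start = int(start)
            if registry.free(start) and registry.free(start + 3):
                ref4 = chrom_seq[start - 1 : start + 3]
                if ref4[-1] != ref4[0]:  # keep the minimal representation stable
                    emit(start, ref4, ref4[0], all_cases, "inframe_decoy",
                         STAGE_EFFECT, False)
                    break

        # clustered artifact decoys: >= cluster_size sites inside one window
        for _ in range(cfg.n_clusters):
            for g in rng.permutation(len(models)):
                model = models[int(g)]
                iv = max(model.cds, key=lambda t: t[1] - t[0])
                if iv[1] - iv[0] + 1 < cfg.cluster_span + 4:
                    continue
                base = int(iv[0]) + 2
                span_positions = [
                    base + round(j * (cfg.cluster_span - 1) / (cfg.cluster_size - 1))
                    for j in range(cfg.cluster_size)
                ]
                if not registry.free_range(base - cfg.min_site_spacing,
                                           span_positions[-1] + cfg.min_site_spacing):
                    continue
                for pos in span_positions:
                    ref = chrom_seq[pos - 1]
                    alt = str(rng.choice([b for b in _BASES if b != ref]))
                    emit(pos, ref, alt, all_cases, "cluster_decoy", STAGE_CLUSTER, False)
                break

        # repeat-region decoys
        repeat_ivs = list(syn.repeats.intervals.get(cfg.chrom, ()))
        for i in range(min(cfg.n_repeat_decoys, len(repeat_ivs))):
            s, e = repeat_ivs[i % len(repeat_ivs)]
            pos = s + 5 + i * cfg.min_site_spacing
            if pos > e:
                pos = s + 1
            ref = chrom_seq[pos - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            emit(pos, ref, alt, all_cases, "repeat_decoy", STAGE_REPEAT, False)

    # shared background polymorphisms at drawn allele frequencies
    chrom_len = len(chrom_seq)
    placed = 0
    attempts = 0
    while placed < cfg.n_background and attempts < cfg.n_background * 100:
        attempts += 1
        pos = int(rng.integers(1, chrom_len + 1))
        if not registry.free(pos):
            continue
        af = float(rng.beta(*cfg.af_beta))
        gts = _draw_af_genotypes(rng, cohort_samples, af)
        if cfg.force_control_carrier and not any(
            1 in gts[c] for c in design.control_ids
        ):
            forced = str(rng.choice(list(design.control_ids)))
            gts[forced] = (0, 1)
        if not any(1 in g for g in gts.values()):
            continue
        ref = chrom_seq[pos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        v = GenomicVariant(chrom=cfg.chrom, pos=pos, ref=ref, alt=alt, genotypes=gts)
        registry.claim(pos)
        cohort_variants.append(v)
        truth_rows.append(
            {"chrom": cfg.chrom, "pos": pos, "ref": ref, "alt": alt,
             "kind": "background",
             "expected_stage": _background_stage(v, syn, design)}
        )
        panel_gts = _draw_af_genotypes(rng, design.panel_ids, af)
        if any(1 in g for g in panel_gts.values()):
            panel_variants.append(
                GenomicVariant(chrom=cfg.chrom, pos=pos, ref=ref, alt=alt,
                               genotypes=panel_gts)
            )
        placed += 1
    if placed < cfg.n_background:
        log.warning("placed only %d/%d background variants", placed, cfg.n_background)

    cohort_variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    panel_variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return CohortSim(
        cohort_variants=cohort_variants,
        panel_variants=panel_variants,
        truth=truth,
        design=design,
        planted_key=planted_key,
    )


def _background_stage(
    v: GenomicVariant, syn: SyntheticGenome, design: CohortDesign
) -> str:
    """Intended first-removal stage of a background polymorphism."""
    s, e = v.span0
    if syn.repeats.overlaps(v.chrom, s, e):
        return STAGE_REPEAT
    if not _overlaps_coding_or_splice(v.pos, syn.models):
        return STAGE_REGION
    in_all_cases = all(v.carries_alt(c) for c in design.case_ids)
    in_control = any(v.carries_alt(c) for c in design.control_ids)
    if not in_all_cases or in_control:
        return STAGE_CASE
    return ""  # coding, case-exclusive background: fate depends on effect/panel


# ---------------------------------------------------------------------------
# ASE counts and phenotypes
# ---------------------------------------------------------------------------


def gen_ase_counts(
    cfg: SimConfig, variant_key: tuple[str, int, str, str] | str = "planted"
) -> list[AseObservation]:
    """RNA/DNA allele counts at a heterozygous site under the NMD model.

    Per tissue, mutant RNA reads ~ Binomial(rna_depth, (1-d)/(2-d)) and
    DNA reads ~ Binomial(dna_depth, 1/2), tissues independent.
    """
    rng = cfg.rng(_TAG_ASE)
    f = expected_mutant_fraction(cfg.nmd_delta)
    out = []
    for tissue in cfg.tissues:
        alt = int(rng.binomial(cfg.rna_depth, f))
        dna_alt = int(rng.binomial(cfg.dna_depth, 0.5))
        out.append(
            AseObservation(
                variant_key=variant_key,
                tissue=tissue,
                rna_ref_count=cfg.rna_depth - alt,
                rna_alt_count=alt,
                dna_ref_count=cfg.dna_depth - dna_alt,
                dna_alt_count=dna_alt,
            )
        )
    return out


def gen_phenotypes(cfg: SimConfig) -> pd.DataFrame:
    """Longitudinal fasting insulin/glucose table for the whole cohort.

    Insulin is log-normal per group (normal and metabolic-syndrome
    medians, common log-SD); the planted cases are metabolic-syndrome
    draws multiplied by ``case_fold``.  Glucose is mildly anti-correlated
    with the insulin deviation and slightly depressed in cases
    (hyperinsulinemia lowers fasting glucose).  Long format with explicit
    units.
    """
    rng = cfg.rng(_TAG_PHENO)
    subjects: list[tuple[str, str]] = []
    subjects += [(f"N{i:02d}", "control") for i in range(1, cfg.n_normal + 1)]
    subjects += [(f"M{i:02d}", "MetS") for i in range(1, cfg.n_mets_noncase + 1)]
    subjects += [(c, "case") for c in cfg.case_ids]

    rows = []
    for subject, group in subjects:
        ins_median = (
            cfg.insulin_median_normal if group == "control" else cfg.insulin_median_mets
        )
        glu_median = (
            cfg.glucose_median_normal if group == "control" else cfg.glucose_median_mets
        )
        fold = cfg.case_fold if group == "case" else 1.0
        g_factor = cfg.case_glucose_factor if group == "case" else 1.0
        for t in cfg.timepoints_months:
            z = float(rng.standard_normal())
            insulin = ins_median * np.exp(cfg.insulin_log_sd * z) * fold
            glucose = (
                glu_median
                * np.exp(
                    cfg.glucose_log_sd * float(rng.standard_normal())
                    + cfg.glucose_insulin_coupling * z
                )
                * g_factor
            )
            rows.append((subject, group, t, "fasting_insulin", round(insulin, 3), "uU/ml"))
            rows.append((subject, group, t, "fasting_glucose", round(glucose, 3), "mmol/L"))
    return pd.DataFrame(
        rows, columns=["subject", "group", "timepoint_months", "analyte", "value", "unit"]
    )


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SimConfig
    genome: SyntheticGenome
    cohort: CohortSim
    ase: list[AseObservation]
    phenotypes: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.write(out)
        self.cohort.write(out)
        write_ase_table(out / "ase_counts.tsv", self.ase)
        self.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study from one config."""
    syn = gen_genome(cfg)
    cohort = gen_cohort(cfg, syn)
    key = cohort.planted_key if cohort.planted_key else "planted"
    return SyntheticStudy(
        config=cfg,
        genome=syn,
        cohort=cohort,
        ase=gen_ase_counts(cfg, key),
        phenotypes=gen_phenotypes(cfg),
    )
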