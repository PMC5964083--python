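"""Consequence classification vs independent full-CDS re-translation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from xps.consequence import (
    SEVERITY_ORDER,
    ConsequenceCall,
    build_cds,
    classify,
    revcomp,
    worst_effect,
)
from xps.io_formats import GeneModel, GenomicVariant


def splice_cds_independent(model: GeneModel, genome: dict[str, str]) -> str:
    """Independent splicing: plain string slicing + Biopython revcomp."""
    seq = "".join(genome[model.chrom][s - 1 : e] for s, e, _ in model.cds)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def oracle_classify_snv(variant: GenomicVariant, model: GeneModel,
                        genome: dict[str, str]):
    """Re-translate the full mutant CDS with Biopython and compare proteins.

    Completely independent of the classifier's codon bookkeeping: mutate
    the genome string, re-splice, translate both CDS with Bio.Seq, and
    diff the proteins.
    """
    chrom = genome[variant.chrom]
    mutant = dict(genome)
    assert chrom[variant.pos - 1] == variant.ref
    mutant[variant.chrom] = (
        chrom[: variant.pos - 1] + variant.alt + chrom[variant.pos:]
    )
    cds_ref = splice_cds_independent(model, genome)
    cds_alt = splice_cds_independent(model, mutant)
    if cds_ref == cds_alt:
        return None  # not a CDS position
    prot_ref = str(Seq(cds_ref).translate())
    prot_alt = str(Seq(cds_alt).translate())
    diff = [i for i, (x, y) in enumerate(zip(prot_ref, prot_alt)) if x != y]
    codon_changed = next(
        i // 3 for i in range(len(cds_ref)) if cds_ref[i] != cds_alt[i]
    )
    if codon_changed == 0 and cds_ref[:3] == "ATG" and cds_alt[:3] != "ATG":
        effect = "start_lost"
        j = 0
    elif not diff:
        effect = "synonymous"
        j = codon_changed
    else:
        j = diff[0]
        ref_aa, alt_aa = prot_ref[j], prot_alt[j]
        if ref_aa != "*" and alt_aa == "*":
            effect = "stop_gained"
        elif ref_aa == "*" and alt_aa != "*":
            effect = "stop_lost"
        else:
            effect = "missense"
    x = "X" if prot_ref[j] == "*" else prot_ref[j]
    y = "X" if prot_alt[j] == "*" else prot_alt[j]
    return effect, f"{x}{j + 1}{y}", j + 1


def all_cds_snvs(model, genome):
    cds = build_cds(model, genome)
    chrom = genome[model.chrom]
    for pos in cds.genomic_positions:
        ref = chrom[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                yield GenomicVariant(model.chrom, pos, ref, alt,
                                     genotypes={"s": (0, 1)})


def flip_genome_and_model(genome, model):
    """Reverse-complement the chromosome and mirror the gene model."""
    seq = genome[model.chrom]
    L = len(seq)
    flipped = {model.chrom: revcomp(seq)}
    exons = tuple(sorted((L - e + 1, L - s + 1) for s, e in model.exons))
    cds_plain = sorted((L - e + 1, L - s + 1) for s, e, _ in model.cds)
    strand = "-" if model.strand == "+" else "+"
    order = cds_plain if strand == "+" else list(reversed(cds_plain))
    phased, cum = [], 0
    for s, e in order:
        phased.append((s, e, (3 - cum % 3) % 3))
        cum += e - s + 1
    m2 = GeneModel(model.gene_id, model.transcript_id, model.chrom, strand,
                   exons=exons, cds=tuple(sorted(phased)))
    return flipped, m2, L


class TestBuildCds:
    def test_toy_gene_codons_and_map(self, toy_gene):
        genome, model = toy_gene
        cds = build_cds(model, genome)
        assert len(cds.seq) == 72 and cds.seq.startswith("ATG")
        assert cds.seq.endswith("TAA")
        assert cds.codon(5) == "CTT"
        # coordinate map inverts both ways, including the junction codon
        for i, gpos in enumerate(cds.genomic_positions):
            assert cds.index_of(gpos) == i
        assert cds.codon_of(121) == (1, 0)
        assert cds.codon_of(150) == (10, 2)   # last base of exon1 CDS
        assert cds.codon_of(201) == (11, 0)   # continues across the junction
        assert cds.codon_of(160) is None      # intronic

    def test_minus_strand_splices_to_same_cds(self, toy_gene):
        """Mirroring the genome and model leaves the spliced CDS unchanged."""
        genome, model = toy_gene
        flipped, m2, _ = flip_genome_and_model(genome, model)
        assert build_cds(m2, flipped).seq == build_cds(model, genome).seq

    def test_non_acgt_cds_is_error(self, toy_gene):
        genome, model = toy_gene
        bad = {model.chrom: genome[model.chrom][:130] + "N" + genome[model.chrom][131:]}
        with pytest.raises(ValueError, match="non-ACGT"):
            build_cds(model, bad)


class TestClassify:
    def test_k410x_nonsense_label(self, long_gene):
        """AAA -> TAA at codon 410 is a stop gain labelled K410X."""
        genome, model = long_gene
        cds = build_cds(model, genome)
        pos = cds.genomic_positions[409 * 3]  # first base of codon 410
        v = GenomicVariant(model.chrom, pos, "A", "T", genotypes={"s": (0, 1)})
        call = classify(v, model, genome)
        assert call.effect == "stop_gained"
        assert call.protein_change == "K410X"
        assert call.codon_number == 410

    def test_wobble_synonymous(self, toy_gene):
        genome, model = toy_gene
        cds = build_cds(model, genome)
        pos = cds.genomic_positions[4 * 3 + 2]  # third base of codon 5 (CTT)
        v = GenomicVariant(model.chrom, pos, "T", "C", genotypes={"s": (0, 1)})
        call = classify(v, model, genome)
        assert call.effect == "synonymous" and call.protein_change == "L5L"

    def test_cds_indels_by_frame(self, toy_gene):
        genome, model = toy_gene
        ref1 = genome[model.chrom][129]
        ins = GenomicVariant(model.chrom, 130, ref1, ref1 + "A", genotypes={"s": (0, 1)})
        assert classify(ins, model, genome).effect == "frameshift"
        ref4 = genome[model.chrom][129:133]
        if ref4[0] != ref4[-1]:  # avoid trimming ambiguity in the fixture
            dele = GenomicVariant(model.chrom, 130, ref4, ref4[0],
                                  genotypes={"s": (0, 1)})
            assert classify(dele, model, genome).effect == "inframe_indel"

    def test_splice_window_and_precedence(self, toy_gene):
        genome, model = toy_gene
        g = genome[model.chrom]
        donor = GenomicVariant(model.chrom, 151, g[150],
                               "A" if g[150] != "A" else "C", genotypes={"s": (0, 1)})
        assert classify(donor, model, genome).effect == "splice_site"
        # deletion spanning CDS end and the donor window: CDS effect wins
        span = GenomicVariant(model.chrom, 149, g[148:153], g[148],
                              genotypes={"s": (0, 1)})
        assert classify(span, model, genome).effect in ("frameshift", "inframe_indel")
        deep = GenomicVariant(model.chrom, 155, g[154],
                              "A" if g[154] != "A" else "C", genotypes={"s": (0, 1)})
        assert classify(deep, model, genome).effect == "noncoding"

    def test_reference_mismatch_raises(self, toy_gene):
        genome, model = toy_gene
        ref = genome[model.chrom][129]
        wrong = "A" if ref != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        v = GenomicVariant(model.chrom, 130, wrong, alt, genotypes={"s": (0, 1)})
        with pytest.raises(ValueError, match="mismatch"):
            classify(v, model, genome)

    def test_every_snv_matches_retranslation_oracle(self, toy_gene, long_gene):
        for genome, model in (toy_gene, long_gene):
            for v in all_cds_snvs(model, genome):
                expected = oracle_classify_snv(v, model, genome)
                call = classify(v, model, genome)
                assert expected is not None
                assert (call.effect, call.protein_change, call.codon_number) == expected

    def test_strand_invariance(self, toy_gene):
        """Mirrored genome + model give identical calls for mirrored SNVs."""
        genome, model = toy_gene
        flipped, m2, L = flip_genome_and_model(genome, model)
        comp = dict(zip("ACGT", "TGCA"))
        for v in itertools.islice(all_cds_snvs(model, genome), 0, None, 7):
            v2 = GenomicVariant(model.chrom, L - v.pos + 1, comp[v.ref], comp[v.alt],
                                genotypes={"s": (0, 1)})
            c1 = classify(v, model, genome)
            c2 = classify(v2, m2, flipped)
            assert (c1.effect, c1.protein_change) == (c2.effect, c2.protein_change)


class TestWorstEffect:
    def test_severity_pairs_total_and_antisymmetric(self):
        def call(effect, tx="t1"):
            pc = ""
            if effect in ("stop_gained", "missense", "synonymous",
                          "stop_lost", "start_lost"):
                pc = "A1A"
            return ConsequenceCall(("c", 1, "A", "G"), tx, effect, pc,
                                   1 if pc else None)

        for e1, e2 in itertools.product(SEVERITY_ORDER, repeat=2):
            w = worst_effect([call(e1, "t1"), call(e2, "t2")])
            expected = min((e1, e2), key=SEVERITY_ORDER.index)
            assert w.effect == expected
            if e1 == e2:
                assert w.transcript_id == "t1"  # tie -> lowest transcript id

    def test_single_call_is_identity(self):
        c = ConsequenceCall(("c", 1, "A", "G"), "t", "noncoding")
        assert worst_effect([c]) is c

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            worst_effect([])

    def test_stop_gain_labels_end_in_x(self, study):
        """Every stop-gain call on synthetic cohorts carries an X label."""
        from xps.consequence import annotate_variants

        calls = annotate_variants(
            study.cohort.cohort_variants, study.genome.models, study.genome.genome
        )
        stop_calls = [c for c in calls.values() if c.effect == "stop_gained"]
        assert stop_calls and all(c.protein_change.endswith("X") for c in stop_calls)
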