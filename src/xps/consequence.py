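"""Self-contained variant-effect classification against transcript models.

Classifies biallelic variants into the effect vocabulary consumed by the
prioritization cascade -- stop_gained, frameshift, splice_site, missense,
synonymous, inframe_indel, stop_lost, start_lost, noncoding -- and labels
amino-acid changes in the conventional ``K410X`` style (reference residue,
codon number, alternate residue, premature stops written ``X``).

The classifier works directly from the spliced CDS built by
:func:`build_cds`: an SNV mutates a single codon which is re-translated
with the standard genetic code; coding indels are frameshift or in-frame
by length difference modulo 3; alleles overlapping a splice window are
splice_site unless they also touch CDS (the CDS effect wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneModel, GenomicVariant

log = logging.getLogger(__name__)

# effect classes, most severe first
SEVERITY_ORDER: tuple[str, ...] = (
    "stop_gained",
    "frameshift",
    "splice_site",
    "start_lost",
    "stop_lost",
    "missense",
    "inframe_indel",
    "synonymous",
    "noncoding",
)
_RANK = {e: i for i, e in enumerate(SEVERITY_ORDER)}

# classes that carry a protein-change label and codon number
_LABELLED = frozenset({"stop_gained", "missense", "synonymous", "stop_lost", "start_lost"})

# standard genetic code, hard-coded (base order TCAG per axis)
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AAS[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame nucleotide sequence, stops as ``*``."""
    if len(cds) % 3:
        raise ValueError("sequence length not divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class ConsequenceCall:
    """One variant's effect on one transcript."""

    variant_key: tuple[str, int, str, str]
    transcript_id: str
    effect: str
    protein_change: str = ""
    codon_number: int | None = None

    def __post_init__(self) -> None:
        if self.effect not in _RANK:
            raise ValueError(f"unknown effect {self.effect!r}")
        if (self.effect in _LABELLED) != bool(self.protein_change):
            raise ValueError(
                f"protein_change must be non-empty iff effect is one of "
                f"{sorted(_LABELLED)}; got {self.effect} / {self.protein_change!r}"
            )

    @property
    def severity_rank(self) -> int:
        return _RANK[self.effect]


@dataclass(frozen=True)
class CodingSequence:
    """Spliced CDS in transcription order with a genomic coordinate map.

    ``genomic_positions[i]`` is the 1-based genomic position of CDS base
    ``i``; for minus-strand transcripts the sequence is the reverse
    complement and positions run descending, so the map is invertible on
    CDS positions in both directions.
    """

    transcript_id: str
    strand: str
    seq: str
    genomic_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.genomic_positions)}
        )

    def index_of(self, genomic_pos: int) -> int | None:
        """CDS index (0-based, transcription order) of a genomic position."""
        return self._index.get(genomic_pos)

    def codon_of(self, genomic_pos: int) -> tuple[int, int] | None:
        """(codon_number >= 1, position-in-codon 0..2) for a CDS position."""
        i = self.index_of(genomic_pos)
        if i is None:
            return None
        return i // 3 + 1, i % 3

    def codon(self, codon_number: int) -> str:
        return self.seq[(codon_number - 1) * 3 : codon_number * 3]


def build_cds(model: GeneModel, genome: Mapping[str, str]) -> CodingSequence:
    """Splice a transcript's CDS out of the genome, transcription order.

    Minus-strand transcripts are reverse-complemented.  Non-ACGT bases in
    the CDS are an error; a missing ATG start is only a warning since
    classification remains well defined.
    """
    chrom_seq = genome[model.chrom]
    parts: list[str] = []
    positions: list[int] = []
    for s, e, _ in model.cds:
        if e > len(chrom_seq):
            raise ValueError(
                f"CDS interval {s}-{e} of {model.transcript_id} exceeds "
                f"{model.chrom} length {len(chrom_seq)}"
            )
        parts.append(chrom_seq[s - 1 : e])
        positions.extend(range(s, e + 1))
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = revcomp(seq)
        positions.reverse()
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"CDS of {model.transcript_id} contains non-ACGT bases")
    if not seq.startswith("ATG"):
        log.warning("CDS of %s does not start with ATG", model.transcript_id)
    return CodingSequence(
        transcript_id=model.transcript_id,
        strand=model.strand,
        seq=seq,
        genomic_positions=tuple(positions),
    )


def _overlaps_any(span: tuple[int, int], intervals0: Sequence[tuple[int, int]]) -> bool:
    s, e = span
    return any(s < ie and is_ < e for is_, ie in intervals0)


def _aa_label(aa: str) -> str:
    return "X" if aa == "*" else aa


def classify(
    variant: GenomicVariant,
    model: GeneModel,
    genome: Mapping[str, str],
    splice_window: int = 2,
    cds: CodingSequence | None = None,
) -> ConsequenceCall:
    """Classify one variant against one transcript.

    A pre-built :class:`CodingSequence` may be passed to avoid re-splicing
    when classifying many variants on the same transcript.  SNVs are
    checked against the reference genome; a mismatch raises.
    """
    if cds is None:
        cds = build_cds(model, genome)
    span0 = variant.span0
    in_cds = _overlaps_any(span0, model.cds_intervals0())
    in_splice = _overlaps_any(
        span0, [(s - 1, e) for s, e in model.splice_windows(splice_window)]
    )

    def call(effect: str, protein_change: str = "", codon_number: int | None = None):
        return ConsequenceCall(
            variant_key=variant.key,
            transcript_id=model.transcript_id,
            effect=effect,
            protein_change=protein_change,
            codon_number=codon_number,
        )

    if in_cds:
        if variant.is_snv:
            genome_base = genome[variant.chrom][variant.pos - 1].upper()
            if genome_base != variant.ref:
                raise ValueError(
                    f"reference mismatch at {variant.chrom}:{variant.pos}: "
                    f"VCF says {variant.ref}, genome has {genome_base}"
                )
            codon_number, offset = cds.codon_of(variant.pos)
            ref_codon = cds.codon(codon_number)
            alt_base = variant.alt if model.strand == "+" else revcomp(variant.alt)
            alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
            ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
            label = f"{_aa_label(ref_aa)}{codon_number}{_aa_label(alt_aa)}"
            if codon_number == 1 and ref_codon == "ATG" and alt_codon != "ATG":
                return call("start_lost", label, 1)
            if ref_aa != "*" and alt_aa == "*":
                return call("stop_gained", label, codon_number)
            if ref_aa == "*" and alt_aa != "*":
                return call("stop_lost", label, codon_number)
            if ref_aa == alt_aa:
                return call("synonymous", label, codon_number)
            return call("missense", label, codon_number)
        # indel touching CDS: frame arithmetic decides
        length_change = abs(len(variant.ref) - len(variant.alt))
        effect = "frameshift" if length_change % 3 else "inframe_indel"
        anchor = cds.codon_of(variant.pos)
        codon_number = anchor[0] if anchor else None
        return call(effect, "", codon_number)
    if in_splice:
        return call("splice_site")
    return call("noncoding")


def worst_effect(calls: Sequence[ConsequenceCall]) -> ConsequenceCall:
    """Most severe call; ties broken by lowest transcript id."""
    if not calls:
        raise ValueError("worst_effect requires at least one call")
    return min(calls, key=lambda c: (c.severity_rank, c.transcript_id))


def annotate_variants(
    variants: Sequence[GenomicVariant],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    splice_window: int = 2,
) -> dict[tuple[str, int, str, str], ConsequenceCall]:
    """Worst-effect call per variant across all overlapping transcripts.

    A variant overlapping no transcript (nor any splice window) gets a
    ``noncoding`` call with an empty transcript id.
    """
    cds_cache = {m.transcript_id: build_cds(m, genome) for m in models}
    spans = []
    for m in models:
        s, e = m.span
        spans.append((m, s - splice_window, e + splice_window))
    out: dict[tuple[str, int, str, str], ConsequenceCall] = {}
    for v in variants:
        vs, ve = v.span0
        calls = [
            classify(v, m, genome, splice_window, cds=cds_cache[m.transcript_id])
            for m, s, e in spans
            if m.chrom == v.chrom and vs < e and s - 1 < ve
        ]
        if calls:
            out[v.key] = worst_effect(calls)
        else:
            out[v.key] = ConsequenceCall(
                variant_key=v.key, transcript_id="", effect="noncoding"
            )
    return out
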