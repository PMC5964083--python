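"""Standard-format I/O and the normalized variant data model.

Variant records enter as VCF 4.x, gene models as GFF3, repeat masks as BED,
reference sequence as FASTA.  Everything downstream of this module works on
a small set of validated containers:

* :class:`GenomicVariant` -- one biallelic, left-trimmed variant with
  per-sample genotypes.  This is the unit that flows through every filter.
* :class:`GeneModel` -- a transcript's exon/CDS structure with strand and
  frame, the substrate for consequence calling.
* :class:`RepeatMask` -- merged per-chromosome repeat intervals.
* :class:`CohortDesign` -- case / sequenced-control / population-panel
  sample assignments.

Coordinate conventions: every public coordinate (VCF ``pos``, GFF
intervals) is 1-based; all internal interval arithmetic is 0-based
half-open.  Helpers on the containers do the conversion so callers never
mix the two.
"""

from __future__ import annotations

import logging
import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

Allele = int | None
Genotype = tuple[Allele, ...]

_ACGT = re.compile(r"^[ACGT]+$")


class VcfParseError(ValueError):
    """A VCF body record could not be parsed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicVariant:
    """A normalized biallelic variant with per-sample genotypes.

    ``pos`` is the 1-based position of the first reference base.  Genotype
    allele indices are restricted to ``{0, 1, None}``; ``None`` encodes a
    missing allele and is never imputed.  ``recoded_other_alt`` lists
    samples whose genotype referenced a different alternate allele of the
    original multiallelic record (recoded to 0 during decomposition).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype]
    source_id: str | None = None
    recoded_other_alt: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele_str in (self.ref, self.alt):
            if not _ACGT.match(allele_str):
                raise ValueError(
                    f"allele {allele_str!r} at {self.chrom}:{self.pos} is not over ACGT"
                )
        for sample, gt in self.genotypes.items():
            for a in gt:
                if a not in (0, 1, None):
                    raise ValueError(
                        f"allele index {a!r} for sample {sample} at "
                        f"{self.chrom}:{self.pos}; expected 0, 1 or missing"
                    )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def genotype(self, sample: str) -> Genotype | None:
        return self.genotypes.get(sample)

    def carries_alt(self, sample: str) -> bool:
        """True if the sample's genotype contains the alternate allele."""
        gt = self.genotypes.get(sample)
        return gt is not None and 1 in gt

    def zygosity(self, sample: str) -> str:
        gt = self.genotypes.get(sample)
        if gt is None or all(a is None for a in gt):
            return "missing"
        alts = sum(1 for a in gt if a == 1)
        if alts == 0:
            return "hom_ref"
        if alts == len([a for a in gt if a is not None]) and None not in gt:
            return "hom_alt"
        return "het"


@dataclass(frozen=True)
class VcfRecord:
    """A raw (possibly multiallelic) VCF body record.

    Genotype allele indices refer to the original allele list: 0 is the
    reference, ``k`` the k-th alternate.  :func:`decompose_multiallelic`
    turns one of these into biallelic :class:`GenomicVariant` records.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: Mapping[str, Genotype]
    source_id: str | None = None

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass(frozen=True)
class GeneModel:
    """A transcript's exon/CDS intervals (1-based closed, ascending).

    ``cds`` items are ``(start, end, phase)``; the phase is the GFF3 frame
    phase of the interval in transcription order.  The total CDS length
    must be divisible by three and every CDS interval must lie inside an
    exon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        _check_sorted_disjoint(self.exons, f"exons of {self.transcript_id}")
        _check_sorted_disjoint(
            [(s, e) for s, e, _ in self.cds], f"CDS of {self.transcript_id}"
        )
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id} ({self.cds_length}) "
                "is not divisible by 3"
            )
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"CDS interval {s}-{e} of {self.transcript_id} "
                    "is not contained in any exon"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        """1-based closed genomic span of the transcript."""
        return (self.exons[0][0], self.exons[-1][1])

    def cds_intervals0(self) -> list[tuple[int, int]]:
        """CDS intervals as 0-based half-open."""
        return [(s - 1, e) for s, e, _ in self.cds]

    def splice_windows(self, window: int = 2) -> list[tuple[int, int]]:
        """Intronic splice-site windows, 1-based closed.

        For every exon that contains CDS, the ``window`` intronic bases
        flanking each intron-facing boundary are returned (donor and
        acceptor sides).  Transcript-terminal boundaries have no intron and
        contribute nothing.
        """
        out: list[tuple[int, int]] = []
        cds_plain = [(s, e) for s, e, _ in self.cds]
        for i, (xs, xe) in enumerate(self.exons):
            if not any(s <= xe and xs <= e for s, e in cds_plain):
                continue
            if i > 0:
                out.append((xs - window, xs - 1))
            if i < len(self.exons) - 1:
                out.append((xe + 1, xe + window))
        return out


def _check_sorted_disjoint(intervals: Sequence[tuple[int, int]], what: str) -> None:
    prev_end = 0
    for s, e in intervals:
        if e < s:
            raise ValueError(f"{what}: interval {s}-{e} has end < start")
        if s <= prev_end:
            raise ValueError(f"{what}: intervals not sorted/non-overlapping at {s}-{e}")
        prev_end = e


@dataclass(frozen=True)
class RepeatMask:
    """Merged per-chromosome repeat intervals, 0-based half-open."""

    intervals: Mapping[str, tuple[tuple[int, int], ...]]

    @classmethod
    def from_intervals(cls, raw: Mapping[str, Iterable[tuple[int, int]]]) -> "RepeatMask":
        merged = {chrom: tuple(merge_intervals(ivs)) for chrom, ivs in raw.items()}
        return cls(intervals=merged)

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None:
            return False
        starts = [s for s, _ in ivs]
        i = bisect_right(starts, end0 - 1)
        return i > 0 and ivs[i - 1][1] > start0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge 0-based half-open intervals (touching intervals merge)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class CohortDesign:
    """Sample-id assignments for the extreme-phenotype study design."""

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    panel_ids: tuple[str, ...] = ()
    cohort_size: int = 0

    def __post_init__(self) -> None:
        if not self.case_ids:
            raise ValueError("case_ids must be non-empty")
        groups = [set(self.case_ids), set(self.control_ids), set(self.panel_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("case/control/panel sample ids must be disjoint")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> Iterator[VcfRecord]:
    """Stream raw VCF records in file order, checking (chrom, pos) sortedness.

    Multiallelic records are passed through untouched; use
    :func:`decompose_multiallelic` (or :func:`read_variants`) to obtain
    biallelic, trimmed :class:`GenomicVariant` records.  Genotype phase is
    ignored.  Requesting a sample absent from the header raises with the
    available sample list.
    """
    vcf = pysam.VariantFile(str(path))
    available = list(vcf.header.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise VcfParseError(
                f"samples {missing} not in {path}; available: {available}"
            )
        vcf.subset_samples(list(samples))
    wanted = list(vcf.header.samples)

    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    it = iter(vcf)
    n = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except Exception as exc:  # pysam parse failure
            raise VcfParseError(
                f"malformed VCF record in {path} at data line {n + 1}: {exc}"
            ) from exc
        n += 1
        if last is not None:
            if rec.chrom == last[0] and rec.pos < last[1]:
                raise VcfParseError(
                    f"{path} not sorted by position at data line {n} "
                    f"({rec.chrom}:{rec.pos} after {last[0]}:{last[1]})"
                )
            if rec.chrom != last[0] and rec.chrom in seen_chroms:
                raise VcfParseError(
                    f"{path}: chromosome {rec.chrom} occurs in non-contiguous blocks"
                )
        seen_chroms.add(rec.chrom)
        last = (rec.chrom, rec.pos)

        gts: dict[str, Genotype] = {}
        for s in wanted:
            gt = rec.samples[s].get("GT")
            gts[s] = (None, None) if gt is None else tuple(gt)
        yield VcfRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=tuple(rec.alts or ()),
            genotypes=gts,
            source_id=rec.id,
        )


def read_variants(
    path: str | Path, samples: Sequence[str] | None = None
) -> list[GenomicVariant]:
    """Read, decompose and left-trim a VCF into biallelic variants."""
    out: list[GenomicVariant] = []
    for rec in read_vcf(path, samples=samples):
        out.extend(decompose_multiallelic(rec))
    return out


_SYMBOLIC = re.compile(r"[<>\[\]*]")


def trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-aligned representation of an allele pair.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``) while both alleles keep at least one base -- the
    standard minimal-representation normalization, so that identical edits
    written differently in different files compare equal by key.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def decompose_multiallelic(record: VcfRecord) -> list[GenomicVariant]:
    """Split a VCF record into one trimmed biallelic variant per alternate.

    For the k-th alternate, genotype indices equal to ``k+1`` become 1;
    indices pointing at *other* alternates become 0 and the sample is
    listed in ``recoded_other_alt``; missing alleles stay missing.
    Symbolic alleles (``<DEL>``, breakends, ``*``) are skipped with a
    warning.
    """
    if not record.alts:
        raise ValueError(f"record {record.chrom}:{record.pos} has no alternate allele")
    out: list[GenomicVariant] = []
    for k, alt in enumerate(record.alts, start=1):
        if _SYMBOLIC.search(alt) or not _ACGT.match(alt):
            log.warning(
                "skipping symbolic/unsupported allele %r at %s:%d",
                alt, record.chrom, record.pos,
            )
            continue
        genotypes: dict[str, Genotype] = {}
        recoded: list[str] = []
        for sample, gt in record.genotypes.items():
            new = []
            touched = False
            for a in gt:
                if a is None:
                    new.append(None)
                elif a == k:
                    new.append(1)
                elif a == 0:
                    new.append(0)
                else:
                    new.append(0)
                    touched = True
            if touched:
                recoded.append(sample)
            genotypes[sample] = tuple(new)
        pos, ref, alt_t = trim_allele_pair(record.pos, record.ref, alt)
        out.append(
            GenomicVariant(
                chrom=record.chrom,
                pos=pos,
                ref=ref,
                alt=alt_t,
                genotypes=genotypes,
                source_id=record.source_id,
                recoded_other_alt=tuple(recoded),
            )
        )
    return out


def write_vcf(
    path: str | Path,
    variants: Iterable[GenomicVariant],
    samples: Sequence[str] | None = None,
) -> None:
    """Write biallelic variants as a minimal sorted VCF 4.2 with GT fields."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    if samples is None:
        seen: dict[str, None] = {}
        for v in variants:
            for s in v.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    chroms: dict[str, None] = {}
    for v in variants:
        chroms.setdefault(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            gts = []
            for s in samples:
                gt = v.genotypes.get(s, (None, None))
                gts.append("/".join("." if a is None else str(a) for a in gt))
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.source_id or '.'}\t{v.ref}\t{v.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED / FASTA
# ---------------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into gene models, resolving gene -> mRNA -> exon/CDS.

    Transcripts whose CDS length is not divisible by three are rejected
    with a warning rather than raising, so one bad annotation does not sink
    a whole file.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for tx in sorted(
        db.features_of_type(("mRNA", "transcript")), key=lambda t: (t.seqid, t.start)
    ):
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds_raw = sorted(
            (f.start, f.end, f.frame) for f in db.children(tx, featuretype="CDS")
        )
        if not exons:
            exons = [(s, e) for s, e, _ in cds_raw]
        cds = _with_phases(cds_raw, tx.strand)
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx.id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=tuple(exons),
                    cds=tuple(cds),
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {tx.id}: {exc}")
    return models


def _with_phases(
    cds_raw: list[tuple[int, int, str]], strand: str
) -> list[tuple[int, int, int]]:
    """Fill CDS phases, recomputing when the file leaves them as '.'."""
    order = cds_raw if strand == "+" else list(reversed(cds_raw))
    phased = []
    cum = 0
    for s, e, frame in order:
        phase = int(frame) if frame not in (".", None, "") else (3 - cum % 3) % 3
        phased.append((s, e, phase))
        cum += e - s + 1
    return sorted(phased)


def read_bed(path: str | Path) -> RepeatMask:
    """Read a BED (0-based half-open) into a merged :class:`RepeatMask`."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: BED interval end ({end}) <= start ({start})"
                )
            raw.setdefault(chrom, []).append((start, end))
    return RepeatMask.from_intervals(raw)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an upper-cased chrom -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff(path: str | Path, models: Iterable[GeneModel]) -> None:
    """Write gene models as GFF3 (gene / mRNA / exon / CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.span[0])):
            s, e = m.span
            fh.write(
                f"{m.chrom}\txps\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\txps\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for xs, xe in m.exons:
                fh.write(
                    f"{m.chrom}\txps\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            for cs, ce, phase in m.cds:
                fh.write(
                    f"{m.chrom}\txps\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t{phase}\t"
                    f"Parent={m.transcript_id}\n"
                )


def write_bed(path: str | Path, mask: RepeatMask) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
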