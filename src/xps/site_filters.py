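"""Site-level quality filters applied before the prioritization cascade.

Three filters run in a fixed order and feed a :class:`FilterTrace` so every
removed variant is attributable to exactly one filter:

1. ``cluster_filter`` -- removes variants sitting in unusually dense
   windows (by default >= 5 distinct variant sites within any 25-bp
   window, counted cohort-wide over the site list).
2. ``repeat_filter`` -- removes variants whose reference span overlaps a
   user-supplied tandem-repeat mask.
3. ``region_filter`` -- retains only variants overlapping coding sequence
   or splice-site windows (default: the 2 canonical intronic donor /
   acceptor bases flanking CDS-containing exons).

Each filter returns ``(retained, removed)`` with input order preserved and
``|retained| + |removed| == |input|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GeneModel, GenomicVariant, RepeatMask

log = logging.getLogger(__name__)

STAGE_CLUSTER = "cluster"
STAGE_REPEAT = "repeat"
STAGE_REGION = "region"

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class ClusterParams:
    """Density-filter parameters: >= ``min_variants`` sites in ``window_bp``."""

    window_bp: int = 25
    min_variants: int = 5

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.min_variants < 2:
            raise ValueError("min_variants must be >= 2")


@dataclass
class FilterTrace:
    """Per-variant audit log of the filter cascade.

    Every input variant appears exactly once; a variant removed by filter k
    is never re-evaluated by later filters, so ``removing_filter`` is the
    unique attribution of its fate.
    """

    removed_by: dict[VariantKey, str] = field(default_factory=dict)
    tags: dict[VariantKey, str] = field(default_factory=dict)
    order: list[VariantKey] = field(default_factory=list)
    final_status: dict[VariantKey, str] = field(default_factory=dict)

    def register(self, variants: Iterable[GenomicVariant]) -> None:
        for v in variants:
            if v.key not in self.removed_by:
                self.order.append(v.key)

    def mark_removed(self, key: VariantKey, stage: str) -> None:
        if key in self.removed_by:
            raise ValueError(f"variant {key} already removed by {self.removed_by[key]}")
        self.removed_by[key] = stage

    def mark_final(self, key: VariantKey, status: str) -> None:
        self.final_status[key] = status

    def tag(self, key: VariantKey, label: str) -> None:
        self.tags[key] = label

    def removing_filter(self, key: VariantKey) -> str | None:
        return self.removed_by.get(key)

    def status(self, key: VariantKey) -> str:
        """Removing stage, or the final candidate status for survivors."""
        return self.removed_by.get(key, self.final_status.get(key, "retained"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c,
                "pos": p,
                "ref": r,
                "alt": a,
                "status": self.status((c, p, r, a)),
                "removing_filter": self.removed_by.get((c, p, r, a), ""),
                "region_tag": self.tags.get((c, p, r, a), ""),
            }
            for (c, p, r, a) in self.order
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "status", "removing_filter", "region_tag"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_sorted(variants: Sequence[GenomicVariant]) -> None:
    seen: set[str] = set()
    last: tuple[str, int] | None = None
    for v in variants:
        if last is not None:
            if v.chrom == last[0] and v.pos < last[1]:
                raise ValueError(
                    f"variants not sorted by (chrom, pos) at {v.chrom}:{v.pos}"
                )
            if v.chrom != last[0] and v.chrom in seen:
                raise ValueError(f"chromosome {v.chrom} occurs in separate blocks")
        seen.add(v.chrom)
        last = (v.chrom, v.pos)


def cluster_filter(
    variants: Sequence[GenomicVariant],
    params: ClusterParams | None = None,
    trace: FilterTrace | None = None,
) -> tuple[list[GenomicVariant], list[GenomicVariant]]:
    """Remove all variants that fall in a dense window.

    A variant is removed iff some ``window_bp``-wide genomic window (any
    interval of consecutive bases, not fixed tiles) contains its position
    together with >= ``min_variants`` distinct variant sites.  All variants
    of such a window are removed, not just the excess.  Input must be
    sorted by (chrom, pos); unsorted input is an error, never silently
    re-sorted.

    Implementation: any qualifying window can be shifted left until its
    leftmost contained site anchors it, so scanning windows anchored at
    each site with a two-pointer sweep over the distinct-site list finds
    exactly the windows the brute-force all-anchors scan finds.
    """
    params = params or ClusterParams()
    _check_sorted(variants)
    if trace is not None:
        trace.register(variants)

    positions: dict[str, list[int]] = {}
    for v in variants:
        lst = positions.setdefault(v.chrom, [])
        if not lst or lst[-1] != v.pos:
            lst.append(v.pos)

    dense: set[tuple[str, int]] = set()
    for chrom, pos_list in positions.items():
        n = len(pos_list)
        j = 0
        for i in range(n):
            hi = pos_list[i] + params.window_bp - 1
            if j < i:
                j = i
            while j + 1 < n and pos_list[j + 1] <= hi:
                j += 1
            if j - i + 1 >= params.min_variants:
                for k in range(i, j + 1):
                    dense.add((chrom, pos_list[k]))

    retained, removed = [], []
    for v in variants:
        if (v.chrom, v.pos) in dense:
            removed.append(v)
            if trace is not None:
                trace.mark_removed(v.key, STAGE_CLUSTER)
        else:
            retained.append(v)
    return retained, removed


def repeat_filter(
    variants: Sequence[GenomicVariant],
    mask: RepeatMask,
    trace: FilterTrace | None = None,
) -> tuple[list[GenomicVariant], list[GenomicVariant]]:
    """Remove variants whose reference span overlaps a masked repeat.

    Any overlap removes (a deletion starting inside and ending outside a
    repeat is removed).  Chromosomes absent from the mask are treated as
    unmasked, logged once per chromosome.
    """
    if trace is not None:
        trace.register(variants)
    warned: set[str] = set()
    retained, removed = [], []
    for v in variants:
        if v.chrom not in mask.intervals and v.chrom not in warned:
            log.info("chromosome %s absent from repeat mask; treating as unmasked", v.chrom)
            warned.add(v.chrom)
        s, e = v.span0
        if mask.overlaps(v.chrom, s, e):
            removed.append(v)
            if trace is not None:
                trace.mark_removed(v.key, STAGE_REPEAT)
        else:
            retained.append(v)
    return retained, removed


def region_filter(
    variants: Sequence[GenomicVariant],
    gene_models: Sequence[GeneModel],
    splice_window: int = 2,
    trace: FilterTrace | None = None,
) -> tuple[list[GenomicVariant], list[GenomicVariant]]:
    """Retain only variants overlapping CDS or splice-site windows.

    The matched region kind ("coding" wins over "splice_site") is recorded
    in the trace when one is supplied.  With an empty gene set everything
    is removed, with a warning.
    """
    if trace is not None:
        trace.register(variants)
    if not gene_models:
        log.warning("region_filter called with no gene models; removing all variants")

    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    splice_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in gene_models:
        cds_by_chrom.setdefault(m.chrom, []).extend(m.cds_intervals0())
        splice_by_chrom.setdefault(m.chrom, []).extend(
            (s - 1, e) for s, e in m.splice_windows(splice_window)
        )

    def _hits(table: dict[str, list[tuple[int, int]]], v: GenomicVariant) -> bool:
        s, e = v.span0
        return any(s < ie and is_ < e for is_, ie in table.get(v.chrom, ()))

    retained, removed = [], []
    for v in variants:
        if _hits(cds_by_chrom, v):
            retained.append(v)
            if trace is not None:
                trace.tag(v.key, "coding")
        elif _hits(splice_by_chrom, v):
            retained.append(v)
            if trace is not None:
                trace.tag(v.key, "splice_site")
        else:
            removed.append(v)
            if trace is not None:
                trace.mark_removed(v.key, STAGE_REGION)
    return retained, removed


def apply_site_filters(
    variants: Sequence[GenomicVariant],
    repeat_mask: RepeatMask,
    gene_models: Sequence[GeneModel],
    cluster_params: ClusterParams | None = None,
    splice_window: int = 2,
    trace: FilterTrace | None = None,
) -> list[GenomicVariant]:
    """Run cluster -> repeat -> region in order and return the survivors."""
    retained, _ = cluster_filter(variants, cluster_params, trace)
    retained, _ = repeat_filter(retained, repeat_mask, trace)
    retained, _ = region_filter(retained, gene_models, splice_window, trace)
    return retained
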