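"""Allele-specific expression testing for nonsense-mediated decay (NMD).

A heterozygous premature-stop allele that triggers NMD leaves a footprint
in RNA-seq: reads over the variant site are depleted for the mutant
allele.  This module tests that allelic imbalance with a two-sided
Fisher's exact test on a 2x2 table of allele counts (RNA observed vs a
null expectation) and converts the observed mutant read fraction into an
NMD efficiency estimate.

NMD model for a heterozygote: the wild-type allele expresses at rate 1,
the mutant allele at ``1 - delta`` (``delta`` = fraction of mutant
transcripts degraded), so the expected mutant read fraction is

    f = (1 - delta) / (2 - delta)

which ranges from 1/2 (no decay) to 0 (complete decay) and inverts to
``delta = (1 - 2 f) / (1 - f)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)

# relative tolerance when comparing hypergeometric probabilities to the
# observed table's probability (two-sided tail definition)
_REL_TOL = 1e-12


@dataclass(frozen=True)
class AseObservation:
    """Per-site, per-tissue allele read counts (reference vs alternate)."""

    variant_key: tuple[str, int, str, str] | str
    tissue: str
    rna_ref_count: int
    rna_alt_count: int
    dna_ref_count: int | None = None
    dna_alt_count: int | None = None

    def __post_init__(self) -> None:
        for name in ("rna_ref_count", "rna_alt_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.dna_ref_count is None) != (self.dna_alt_count is None):
            raise ValueError("DNA ref and alt counts must be given together")
        if self.dna_ref_count is not None and (
            self.dna_ref_count < 0 or self.dna_alt_count < 0
        ):
            raise ValueError("DNA counts must be >= 0")

    @property
    def rna_total(self) -> int:
        return self.rna_ref_count + self.rna_alt_count

    @property
    def has_dna(self) -> bool:
        return self.dna_ref_count is not None


@dataclass(frozen=True)
class NmdResult:
    """Outcome of one allelic-imbalance test."""

    tissue: str
    p_value: float
    mutant_fraction: float
    estimated_delta: float
    nmd_consistent: bool
    no_decay: bool
    table: tuple[tuple[int, int], tuple[int, int]]
    null_spec: str


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities, with margins fixed, of every table
    whose probability is <= the observed table's (relative tolerance 1e-12
    on that comparison).  Log-factorial arithmetic keeps the sum stable
    for totals up to ~1e6.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    k_min = max(0, c1 - (c + d))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    log_pmf = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - ks + 1) - gammaln(n - r1 - (c1 - ks) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = log_pmf[a - k_min]
    p = float(np.exp(log_pmf[log_pmf <= log_obs + math.log1p(_REL_TOL)]).sum())
    return min(p, 1.0)


def estimate_delta(mutant_fraction: float) -> float:
    """Invert the heterozygote NMD model f = (1-d)/(2-d).

    Fractions >= 0.5 are outside the decay regime and clamp to 0 (the
    caller flags this as ``no_decay``); the result always lies in [0, 1].
    """
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must be in [0, 1]")
    if mutant_fraction >= 0.5:
        return 0.0
    return (1.0 - 2.0 * mutant_fraction) / (1.0 - mutant_fraction)


def expected_mutant_fraction(delta: float) -> float:
    """Forward NMD model: expected mutant read fraction at efficiency delta."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    return (1.0 - delta) / (2.0 - delta)


def _null_row(obs: AseObservation, null_spec: str) -> tuple[tuple[int, int], str]:
    if null_spec == "auto":
        null_spec = "dna_counts" if obs.has_dna else "balanced"
    if null_spec == "dna_counts":
        if not obs.has_dna:
            raise ValueError(
                "null_spec='dna_counts' but DNA counts are absent; "
                "use null_spec='balanced'"
            )
        return (obs.dna_ref_count, obs.dna_alt_count), "dna_counts"
    if null_spec == "balanced":
        n = obs.rna_total
        return (n - n // 2, n // 2), "balanced"
    raise ValueError(f"unknown null_spec {null_spec!r}")


def ase_test(
    obs: AseObservation, null_spec: str = "auto", alpha: float = 0.05
) -> NmdResult:
    """Test one site/tissue for NMD-consistent allelic imbalance.

    The 2x2 table rows are the observed RNA counts and the null
    expectation -- the DNA counts when available (default), otherwise a
    balanced 1:1 pseudo-table with the same total as the RNA.  The result
    is flagged ``nmd_consistent`` only when the imbalance is significant
    at ``alpha`` *and* in the deficit direction (mutant fraction < 0.5);
    a significant mutant excess is significant-but-inconsistent.
    """
    if obs.rna_total < 1:
        raise ValueError("at least one RNA read is required")
    (null_ref, null_alt), used = _null_row(obs, null_spec)
    table = ((obs.rna_ref_count, obs.rna_alt_count), (null_ref, null_alt))
    p = fisher_exact_2x2(obs.rna_ref_count, obs.rna_alt_count, null_ref, null_alt)
    f = obs.rna_alt_count / obs.rna_total
    no_decay = f >= 0.5
    delta = estimate_delta(f)
    return NmdResult(
        tissue=obs.tissue,
        p_value=p,
        mutant_fraction=f,
        estimated_delta=delta,
        nmd_consistent=(p < alpha) and not no_decay,
        no_decay=no_decay,
        table=table,
        null_spec=used,
    )


def pool_observations(observations: Sequence[AseObservation]) -> AseObservation:
    """Sum counts across tissues into one pooled observation."""
    if not observations:
        raise ValueError("nothing to pool")
    keys = {o.variant_key for o in observations}
    if len(keys) > 1:
        raise ValueError(f"cannot pool observations of different variants: {keys}")
    has_dna = all(o.has_dna for o in observations)
    return AseObservation(
        variant_key=observations[0].variant_key,
        tissue="pooled",
        rna_ref_count=sum(o.rna_ref_count for o in observations),
        rna_alt_count=sum(o.rna_alt_count for o in observations),
        dna_ref_count=sum(o.dna_ref_count for o in observations) if has_dna else None,
        dna_alt_count=sum(o.dna_alt_count for o in observations) if has_dna else None,
    )


def load_ase_table(path: str | Path) -> list[AseObservation]:
    """Read a TSV of allele counts.

    Required columns: ``variant``, ``tissue``, ``rna_ref``, ``rna_alt``;
    optional ``dna_ref``/``dna_alt``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "tissue", "rna_ref", "rna_alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        dna_ref = getattr(row, "dna_ref", None)
        dna_alt = getattr(row, "dna_alt", None)
        out.append(
            AseObservation(
                variant_key=str(row.variant),
                tissue=str(row.tissue),
                rna_ref_count=int(row.rna_ref),
                rna_alt_count=int(row.rna_alt),
                dna_ref_count=None if pd.isna(dna_ref) else int(dna_ref),
                dna_alt_count=None if pd.isna(dna_alt) else int(dna_alt),
            )
        )
    return out


def write_ase_table(path: str | Path, observations: Sequence[AseObservation]) -> None:
    rows = []
    for o in observations:
        key = o.variant_key
        variant = key if isinstance(key, str) else f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
        rows.append(
            {
                "variant": variant,
                "tissue": o.tissue,
                "rna_ref": o.rna_ref_count,
                "rna_alt": o.rna_alt_count,
                "dna_ref": o.dna_ref_count,
                "dna_alt": o.dna_alt_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
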