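"""Shared fixtures: a handcrafted two-exon gene and seeded synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from xps import SimConfig, simulate_study
from xps.consequence import CODON_TABLE
from xps.io_formats import GeneModel

NON_STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def make_cds_seq(rng: np.random.Generator, n_codons: int,
                 force: dict[int, str] | None = None) -> str:
    """Random open reading frame: ATG start, no internal stop, TAA end.

    ``force`` pins specific codons by 1-based codon number.
    """
    codons = (
        ["ATG"]
        + [NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons - 2)]
        + ["TAA"]
    )
    for num, codon in (force or {}).items():
        codons[num - 1] = codon
    return "".join(codons)


def random_genome(rng: np.random.Generator, length: int) -> list[str]:
    return list("".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]))


@pytest.fixture(scope="session")
def toy_gene():
    """Plus-strand two-exon gene with a UTR, an intron and a 24-codon CDS.

    Exons [101,150] and [201,260]; CDS [121,150] + [201,242] (30 + 42 bp =
    24 codons, split mid-codon at the junction).
    """
    rng = np.random.default_rng(42)
    cds_seq = make_cds_seq(rng, 24, force={5: "CTT"})  # codon 5 = Leu (wobble tests)
    g = random_genome(rng, 400)
    g[120:150] = cds_seq[:30]
    g[200:242] = cds_seq[30:]
    genome = {"chrT": "".join(g)}
    model = GeneModel(
        gene_id="g1",
        transcript_id="g1.t1",
        chrom="chrT",
        strand="+",
        exons=((101, 150), (201, 260)),
        cds=((121, 150, 0), (201, 242, 0)),
    )
    return genome, model


@pytest.fixture(scope="session")
def long_gene():
    """Single-exon 412-codon gene with codon 410 = AAA (Lys)."""
    rng = np.random.default_rng(7)
    cds_seq = make_cds_seq(rng, 412, force={410: "AAA"})
    g = random_genome(rng, 50 + len(cds_seq) + 50)
    g[50 : 50 + len(cds_seq)] = cds_seq
    genome = {"chrL": "".join(g)}
    model = GeneModel(
        gene_id="gL",
        transcript_id="gL.t1",
        chrom="chrL",
        strand="+",
        exons=((51, 50 + len(cds_seq)),),
        cds=((51, 50 + len(cds_seq), 0),),
    )
    return genome, model


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (planted causal variant + decoys)."""
    return simulate_study(SimConfig(seed=11))
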