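"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: equivalence
is decided by editing the whole contig string, premature stops by
re-extracting and re-translating the CDS from the edited contig, and coding
coordinates by an explicit walk over exon bases.
"""

from __future__ import annotations

import random

import pytest
from Bio.Seq import Seq

from varagg.fixtures import FixtureSpec, generate_world
from varagg.genome import CodingPosition, ReferenceGenome, Transcript

# 60 bp repeat-rich contig: (AC)n, homopolymers, (GC)n and (GT)n tracts so
# that shifted indel representations abound
REPEAT60 = (
    "TTAAG" + "AC" * 5 + "GGG" + "T" * 6 + "CG" * 4 + "AATCC" + "A" * 5
    + "GT" * 3 + "CATGCAG" + "ACGTA"
)
assert len(REPEAT60) == 60


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome({"chrT": "AACGT"})


@pytest.fixture(scope="session")
def repeat_genome() -> ReferenceGenome:
    return ReferenceGenome({"chrT": "TACACACAG"})


@pytest.fixture(scope="session")
def repeat60_genome() -> ReferenceGenome:
    return ReferenceGenome({"chrT": REPEAT60})


def contig_edit(seq: str, start: int, ref: str, alt: str) -> str:
    """Whole-contig edit oracle."""
    assert seq[start : start + len(ref)] == ref
    return seq[:start] + alt + seq[start + len(ref) :]


@pytest.fixture(scope="session")
def edit_oracle():
    return contig_edit


# ---------------------------------------------------------------------------
# transcripts

@pytest.fixture(scope="session")
def plus_tx() -> Transcript:
    # single exon [100,130), CDS [103,127) — 24 coding bases
    return Transcript("TXP", "chrT", "+", ((100, 130),), 103, 127)


@pytest.fixture(scope="session")
def minus_tx() -> Transcript:
    return Transcript("TXM", "chrT", "-", ((100, 130),), 103, 127)


@pytest.fixture(scope="session")
def split_tx() -> Transcript:
    # two exons [100,110)+[120,130), CDS [100,128) — 18 coding bases
    return Transcript("TXS", "chrT", "+", ((100, 110), (120, 130)), 100, 128)


def walk_project(tx: Transcript, cpos: CodingPosition) -> int:
    """Exhaustive exon-walk projection oracle."""
    order = [p for s, e in tx.exons for p in range(s, e)]
    if tx.strand == "-":
        order.reverse()
    cds = [p for p in order if tx.cds_start <= p < tx.cds_end]
    utr5 = order[: order.index(cds[0])]
    utr3 = order[order.index(cds[-1]) + 1 :]
    if cpos.region == "cds":
        anchor = cds[cpos.ordinal - 1]
    elif cpos.region == "utr5":
        anchor = utr5[len(utr5) - cpos.ordinal]
    else:
        anchor = utr3[cpos.ordinal - 1]
    step = 1 if tx.strand == "+" else -1
    return anchor + cpos.offset * step


@pytest.fixture(scope="session")
def projection_oracle():
    return walk_project


# ---------------------------------------------------------------------------
# premature-stop oracle: full reconstruction of the edited CDS

def retranslate_premature_stop(
    genome: ReferenceGenome, tx: Transcript, start: int, ref: str, alt: str
) -> bool:
    seq = genome.contigs[tx.contig]
    end = start + len(ref)
    edited = contig_edit(seq, start, ref, alt)
    delta = len(alt) - len(ref)

    def nb(p: int) -> int:  # shift a boundary across the edit, clamping into it
        if p <= start:
            return p
        if p >= end:
            return p + delta
        return start

    segs = []
    for a, b in tx.exons:
        aa = max(nb(a), nb(tx.cds_start))
        bb = min(nb(b), nb(tx.cds_end))
        if aa < bb:
            segs.append((aa, bb))
    cds = "".join(edited[a:b] for a, b in segs)
    if tx.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if cds == tx.cds_sequence(genome):
        return False
    if len(cds) % 3 != 0:
        return True
    prot = str(Seq(cds).translate())
    # truncating iff a stop appears anywhere before the final codon
    return "*" in prot[:-1]


@pytest.fixture(scope="session")
def premature_stop_oracle():
    return retranslate_premature_stop


# ---------------------------------------------------------------------------
# a 60-codon CDS world for translation checks, both strands

@pytest.fixture(scope="session")
def cds60_world() -> tuple[ReferenceGenome, dict[str, Transcript]]:
    rng = random.Random(3)
    nonstop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    cds = "ATG" + "".join(rng.choice(nonstop) for _ in range(58)) + "TAA"
    flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    plus_seq = flank(15) + cds + flank(15)
    minus_seq = flank(15) + str(Seq(cds).reverse_complement()) + flank(15)
    genome = ReferenceGenome({"chrP": plus_seq, "chrM": minus_seq})
    txs = {
        "CDSP": Transcript("CDSP", "chrP", "+", ((5, len(plus_seq) - 5),), 15, 15 + 180),
        "CDSM": Transcript("CDSM", "chrM", "-", ((5, len(minus_seq) - 5),), 15, 15 + 180),
    }
    return genome, txs


# ---------------------------------------------------------------------------
# a small generated world shared by pipeline-level tests

SMALL_WORLD_SPEC = FixtureSpec(
    seed=11, contig_length=12000, n_distinct_variants=60, n_equivalence_aliases=30
)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    out = tmp_path_factory.mktemp("world")
    truth = generate_world(SMALL_WORLD_SPEC, out)
    return out, truth
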