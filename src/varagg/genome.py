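"""Reference genome and transcript models.

All coordinates in this package are 0-based, half-open. The only places
1-based coordinates exist are at the text boundaries: HGVS strings, VCF
records, and the transcript table columns, which are converted on read and
on write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ReferenceGenome",
    "Transcript",
    "CodingPosition",
    "ProjectionError",
    "read_fasta",
    "read_transcript_table",
    "write_transcript_table",
    "fetch_sequence",
    "project_c_to_g",
    "project_g_to_c",
    "reverse_complement",
]

VALID_BASES = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class ProjectionError(ValueError):
    """A coding coordinate cannot be placed on the transcript."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A small in-memory genome: contig name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGTN bases: {sorted(bad)}")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        try:
            return len(self.contigs[contig])
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None


def fetch_sequence(genome: ReferenceGenome, contig: str, start: int, end: int) -> str:
    """Slice [start, end) from a contig. Out-of-bounds is an error, never a clamp."""
    if contig not in genome.contigs:
        raise KeyError(f"unknown contig {contig!r}")
    n = len(genome.contigs[contig])
    if not (0 <= start <= end <= n):
        raise IndexError(f"interval [{start}, {end}) outside contig {contig!r} of length {n}")
    return genome.contigs[contig][start:end]


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> ReferenceGenome:
    """Read a multi-contig FASTA into memory, uppercasing the sequence."""
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig {rec.id!r}")
            contigs[rec.id] = str(rec.seq).upper()
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not contigs:
        raise ValueError("FASTA contains no sequences")
    return ReferenceGenome(contigs)


@dataclass(frozen=True)
class Transcript:
    """A transcript model on one contig.

    exons are 0-based half-open genomic intervals, sorted, non-overlapping.
    cds_start/cds_end bound the coding region genomically; the coding
    sequence is the exonic bases inside those bounds, read in transcript
    orientation (reverse-complemented for minus-strand transcripts).
    """

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if not exons:
            raise ValueError("transcript needs at least one exon")
        if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
            raise ValueError("CDS interval not contained in exon span")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons
        )

    def exonic_positions(self) -> list[int]:
        """All exonic genomic positions in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_segments(self) -> list[tuple[int, int]]:
        """Genomic-order exon∩CDS intervals (may be empty per exon)."""
        segs = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                segs.append((a, b))
        return segs

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        seq = "".join(fetch_sequence(genome, self.contig, s, e) for s, e in self.cds_segments())
        return seq if self.strand == "+" else reverse_complement(seq)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def is_exonic(self, g: int) -> bool:
        return any(s <= g < e for s, e in self.exons)


@dataclass(frozen=True)
class CodingPosition:
    """A c.-scheme position: region anchor, 1-based ordinal, intron offset.

    region 'cds'  -> ordinal n is c.n (n-th coding base, n >= 1)
    region 'utr5' -> ordinal n is c.-n
    region 'utr3' -> ordinal n is c.*n
    offset +k / -k walks k bases into the adjacent intron, in transcript
    orientation (so on minus-strand transcripts +k moves genomically left).
    """

    region: str  # cds | utr5 | utr3
    ordinal: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("cds", "utr5", "utr3"):
            raise ValueError(f"bad region {self.region!r}")
        if self.ordinal < 1:
            raise ValueError("ordinal must be >= 1")

    def __str__(self) -> str:
        core = {"cds": "", "utr5": "-", "utr3": "*"}[self.region] + str(self.ordinal)
        if self.offset > 0:
            core += f"+{self.offset}"
        elif self.offset < 0:
            core += str(self.offset)
        return core


def _anchor_position(tx: Transcript, cpos: CodingPosition) -> int:
    """Genomic position of the exonic base the coding coordinate anchors on."""
    order = tx.exonic_positions()
    in_cds = [tx.cds_start <= p < tx.cds_end for p in order]
    try:
        first_cds = in_cds.index(True)
    except ValueError:  # pragma: no cover - transcript invariant forbids this
        raise ProjectionError(f"{tx.id}: transcript has no coding bases")
    last_cds = len(in_cds) - 1 - in_cds[::-1].index(True)
    if cpos.region == "cds":
        idx = first_cds + cpos.ordinal - 1
        if idx > last_cds:
            raise ProjectionError(f"{tx.id}: c.{cpos.ordinal} beyond CDS of length {tx.cds_length}")
    elif cpos.region == "utr5":
        idx = first_cds - cpos.ordinal
        if idx < 0:
            raise ProjectionError(f"{tx.id}: c.-{cpos.ordinal} beyond transcript 5' end")
    else:
        idx = last_cds + cpos.ordinal
        if idx >= len(order):
            raise ProjectionError(f"{tx.id}: c.*{cpos.ordinal} beyond transcript 3' end")
    return order[idx]


def project_c_to_g(tx: Transcript, cpos: CodingPosition) -> int:
    """Map a coding coordinate (with optional intron offset) to a 0-based genomic position."""
    anchor = _anchor_position(tx, cpos)
    if cpos.offset == 0:
        return anchor
    sign = 1 if tx.strand == "+" else -1
    g = anchor + cpos.offset * sign
    # the anchor must sit on the exon edge facing the offset, and the offset
    # must land strictly inside the adjacent intron
    genomic_step = cpos.offset * sign
    if genomic_step > 0:
        edges = {e - 1: ns for (_, e), (ns, _) in zip(tx.exons, tx.exons[1:])}
        if anchor not in edges:
            raise ProjectionError(f"{tx.id}: intron offset from non-boundary base at g.{anchor}")
        if not (anchor < g < edges[anchor]):
            raise ProjectionError(f"{tx.id}: offset {cpos.offset} leaves the intron")
    else:
        edges = {ns: pe for (_, pe), (ns, _) in zip(tx.exons, tx.exons[1:])}
        if anchor not in edges:
            raise ProjectionError(f"{tx.id}: intron offset from non-boundary base at g.{anchor}")
        if not (edges[anchor] <= g < anchor):
            raise ProjectionError(f"{tx.id}: offset {cpos.offset} leaves the intron")
    return g


def project_g_to_c(tx: Transcript, g: int) -> CodingPosition:
    """Inverse projection: genomic position -> coding coordinate.

    Exonic positions map directly; intronic positions are expressed from the
    nearest exon boundary, ties broken toward the upstream (5') exon as in
    standard coding-coordinate practice.
    """
    if tx.is_exonic(g):
        order = tx.exonic_positions()
        idx = order.index(g)
        in_cds = [tx.cds_start <= p < tx.cds_end for p in order]
        first_cds = in_cds.index(True)
        last_cds = len(in_cds) - 1 - in_cds[::-1].index(True)
        if idx < first_cds:
            return CodingPosition("utr5", first_cds - idx)
        if idx > last_cds:
            return CodingPosition("utr3", idx - last_cds)
        return CodingPosition("cds", idx - first_cds + 1)
    for ps, pe in ((tx.exons[i][1], tx.exons[i + 1][0]) for i in range(len(tx.exons) - 1)):
        if ps <= g < pe:
            d_left = g - (ps - 1)      # distance from last base of upstream-in-genome exon
            d_right = pe - g           # distance from first base of downstream-in-genome exon
            if tx.strand == "+":
                use_left = d_left <= d_right
                anchor, off = (ps - 1, d_left) if use_left else (pe, -d_right)
            else:
                use_right = d_right <= d_left
                anchor, off = (pe, d_right) if use_right else (ps - 1, -d_left)
            base = project_g_to_c(tx, anchor)
            return CodingPosition(base.region, base.ordinal, off)
    raise ProjectionError(f"{tx.id}: g.{g} outside transcript span")


def read_transcript_table(path: Union[str, Path]) -> dict[str, Transcript]:
    """Read transcripts from a tab-delimited table.

    Columns: id, contig, strand, exons (comma-separated start-end pairs,
    0-based half-open), cds_start, cds_end. A header row is required.
    """
    txs: dict[str, Transcript] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "contig", "strand", "exons", "cds_start", "cds_end"]
        if header != expected:
            raise ValueError(f"transcript table header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            tid, contig, strand, exon_str, cs, ce = line.rstrip("\n").split("\t")
            exons = tuple(
                tuple(int(x) for x in pair.split("-")) for pair in exon_str.split(",")
            )
            if tid in txs:
                raise ValueError(f"duplicate transcript id {tid!r}")
            txs[tid] = Transcript(tid, contig, strand, exons, int(cs), int(ce))
    return txs


def write_transcript_table(txs: Iterable[Transcript], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcontig\tstrand\texons\tcds_start\tcds_end\n")
        for tx in txs:
            exon_str = ",".join(f"{s}-{e}" for s, e in tx.exons)
            fh.write(f"{tx.id}\t{tx.contig}\t{tx.strand}\t{exon_str}\t{tx.cds_start}\t{tx.cds_end}\n")
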