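"""A deliberately small HGVS dialect: parse, resolve to genomic, format.

Supported: g. and c. scheme substitutions, deletions, insertions, delins and
duplications — the constructs that carry mergeable genomic coordinates.
Protein (p.) and RNA (r.) descriptions are recognized and rejected; parse
failures are values, never exceptions, because upstream sources routinely
contain malformed strings and the pipeline's job is to log and discard them,
not to crash.

Positions in HGVS text are 1-based per the standard. g.-scheme positions are
converted to 0-based at parse time; c.-scheme positions keep their
structured form (they are not plain integers) and are converted during
resolution against a transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .genome import (
    CodingPosition,
    ProjectionError,
    ReferenceGenome,
    Transcript,
    fetch_sequence,
    project_c_to_g,
    reverse_complement,
)

__all__ = [
    "HgvsDescription",
    "ParseFailure",
    "RawVariant",
    "parse_hgvs",
    "resolve_to_genomic",
    "format_hgvs_g",
    "format_description",
]


@dataclass(frozen=True)
class ParseFailure:
    """A structured parse/resolution failure; reason codes are stable strings."""

    reason: str
    token: str = ""

    def __bool__(self) -> bool:  # failures are falsy so `if parsed:` reads naturally
        return False


@dataclass(frozen=True)
class RawVariant:
    """A genomic variant as claimed by a source, before validation/trimming.

    start is 0-based; ref/alt may share flanking bases (anchored VCF style)
    and ref may disagree with the genome — validation decides that later.
    """

    contig: str
    start: int
    ref: str
    alt: str

    @property
    def end(self) -> int:
        return self.start + len(self.ref)


Position = Union[int, CodingPosition]  # int (0-based) for g., CodingPosition for c.


@dataclass(frozen=True)
class HgvsDescription:
    reference_id: str
    scheme: str  # g | c
    kind: str  # substitution | deletion | insertion | delins | duplication
    start: Position
    end: Position  # inclusive-of-last-base companion position (== start for 1-base spans)
    ref_bases: Optional[str]
    alt_bases: Optional[str]
    raw: str


_BASES = r"[ACGTNacgtn]+"
_GPOS = r"\d+"
_CPOS = r"(?:[-*]?\d+(?:[+-]\d+)?)"


def _parse_cpos(text: str) -> CodingPosition:
    m = re.fullmatch(r"(-|\*)?(\d+)([+-]\d+)?", text)
    assert m, text
    prefix, num, off = m.groups()
    region = {"-": "utr5", "*": "utr3", None: "cds"}[prefix]
    return CodingPosition(region, int(num), int(off) if off else 0)


def parse_hgvs(text: str) -> Union[HgvsDescription, ParseFailure]:
    """Parse one HGVS string; returns a ParseFailure value on any bad input."""
    if not isinstance(text, str) or not text.strip():
        return ParseFailure("missing_variant", repr(text))
    text = text.strip()
    m = re.fullmatch(r"([A-Za-z0-9_.-]+):([a-z])\.(.*)", text)
    if not m:
        return ParseFailure("not_hgvs", text)
    ref_id, scheme, body = m.groups()
    if scheme in ("p", "r", "m", "n"):
        return ParseFailure("unsupported_scheme", f"{scheme}.")
    if scheme not in ("g", "c"):
        return ParseFailure("unsupported_scheme", f"{scheme}.")
    pos_pat = _GPOS if scheme == "g" else _CPOS

    def pos(tok: str) -> Position:
        if scheme == "g":
            return int(tok) - 1  # to 0-based
        return _parse_cpos(tok)

    # substitution: <pos><REF>><ALT>, single bases
    m = re.fullmatch(rf"({pos_pat})([ACGTNacgtn])>([ACGTNacgtn])", body)
    if m:
        p = pos(m.group(1))
        return HgvsDescription(
            ref_id, scheme, "substitution", p, p,
            m.group(2).upper(), m.group(3).upper(), text,
        )
    if ">>" in body or re.search(r">\s*$", body):
        return ParseFailure("malformed_operator", body)

    # range or single position + operation
    m = re.fullmatch(
        rf"({pos_pat})(?:_({pos_pat}))?(del|dup)({_BASES})?", body
    )
    if m:
        p1, p2, op, bases = m.groups()
        start, end = pos(p1), pos(p2) if p2 else pos(p1)
        kind = "deletion" if op == "del" else "duplication"
        return HgvsDescription(
            ref_id, scheme, kind, start, end, bases.upper() if bases else None, None, text
        )
    m = re.fullmatch(rf"({pos_pat})_({pos_pat})ins({_BASES})", body)
    if m:
        return HgvsDescription(
            ref_id, scheme, "insertion", pos(m.group(1)), pos(m.group(2)),
            None, m.group(3).upper(), text,
        )
    m = re.fullmatch(rf"({pos_pat})ins", body) or re.fullmatch(rf"({pos_pat})_({pos_pat})ins", body)
    if m:
        return ParseFailure("empty_insertion", body)
    m = re.fullmatch(
        rf"({pos_pat})(?:_({pos_pat}))?delins({_BASES})", body
    )
    if m:
        p1, p2, bases = m.groups()
        return HgvsDescription(
            ref_id, scheme, "delins", pos(p1), pos(p2) if p2 else pos(p1),
            None, bases.upper(), text,
        )
    return ParseFailure("hgvs_unparseable", body)


def _resolve_positions(
    desc: HgvsDescription,
    genome: ReferenceGenome,
    transcripts: dict[str, Transcript],
) -> Union[tuple[str, int, int, str], ParseFailure]:
    """Return (contig, gstart, gend_exclusive, strand) for the described span."""
    if desc.scheme == "g":
        if desc.reference_id not in genome:
            return ParseFailure("unknown_reference", desc.reference_id)
        s, e = desc.start, desc.end
        if e < s:
            return ParseFailure("bad_range", desc.raw)
        return desc.reference_id, s, e + 1, "+"
    tx = transcripts.get(desc.reference_id)
    if tx is None:
        return ParseFailure("unknown_reference", desc.reference_id)
    try:
        g1 = project_c_to_g(tx, desc.start)
        g2 = project_c_to_g(tx, desc.end)
    except ProjectionError as exc:
        return ParseFailure("projection_error", str(exc))
    lo, hi = min(g1, g2), max(g1, g2)
    if tx.strand == "+" and g2 < g1:
        return ParseFailure("bad_range", desc.raw)
    if tx.strand == "-" and g1 < g2:
        return ParseFailure("bad_range", desc.raw)
    return tx.contig, lo, hi + 1, tx.strand


def resolve_to_genomic(
    desc: HgvsDescription,
    genome: ReferenceGenome,
    transcripts: Optional[dict[str, Transcript]] = None,
) -> Union[RawVariant, ParseFailure]:
    """Turn a parsed description into a raw genomic-plus-strand variant.

    Claimed ref/alt bases from minus-strand c. descriptions are
    reverse-complemented into genomic orientation. Deletions/duplications
    without listed bases take their ref from the genome; listed bases are
    kept verbatim (a wrong listing is caught downstream as ref_mismatch
    rather than silently corrected). A duplication is rewritten as an
    insertion of the duplicated span immediately after it.
    """
    transcripts = transcripts or {}
    loc = _resolve_positions(desc, genome, transcripts)
    if isinstance(loc, ParseFailure):
        return loc
    contig, s, e, strand = loc
    n = genome.length(contig)
    if not (0 <= s <= e <= n):
        return ParseFailure("out_of_bounds", f"{contig}:{s}-{e}")

    def orient(bases: str) -> str:
        return bases if strand == "+" else reverse_complement(bases)

    if desc.kind == "substitution":
        if e - s != 1:
            return ParseFailure("bad_range", desc.raw)
        return RawVariant(contig, s, orient(desc.ref_bases), orient(desc.alt_bases))
    if desc.kind == "deletion":
        ref = orient(desc.ref_bases) if desc.ref_bases else fetch_sequence(genome, contig, s, e)
        return RawVariant(contig, s, ref, "")
    if desc.kind == "insertion":
        if e - s != 2:  # ins positions must flank the insertion point
            return ParseFailure("bad_range", desc.raw)
        return RawVariant(contig, s + 1, "", orient(desc.alt_bases))
    if desc.kind == "delins":
        ref = fetch_sequence(genome, contig, s, e)
        return RawVariant(contig, s, ref, orient(desc.alt_bases))
    if desc.kind == "duplication":
        if desc.ref_bases:
            # keep the claimed span as ref so a wrong listing trips
            # ref_mismatch in validation instead of being silently corrected
            span = orient(desc.ref_bases)
            return RawVariant(contig, s, span, span + span)
        span = fetch_sequence(genome, contig, s, e)
        # dup == insertion of the duplicated span immediately after it
        return RawVariant(contig, e, "", span)
    raise AssertionError(desc.kind)  # pragma: no cover


def format_description(desc: HgvsDescription) -> str:
    """Render a description back to text; parse(format(parse(t))) == parse(t)."""

    def pos(p: Position) -> str:
        return str(p + 1) if desc.scheme == "g" else str(p)

    head = f"{desc.reference_id}:{desc.scheme}."
    span = pos(desc.start) if desc.start == desc.end else f"{pos(desc.start)}_{pos(desc.end)}"
    if desc.kind == "substitution":
        return f"{head}{pos(desc.start)}{desc.ref_bases}>{desc.alt_bases}"
    if desc.kind == "deletion":
        return f"{head}{span}del{desc.ref_bases or ''}"
    if desc.kind == "insertion":
        return f"{head}{pos(desc.start)}_{pos(desc.end)}ins{desc.alt_bases}"
    if desc.kind == "delins":
        return f"{head}{span}delins{desc.alt_bases}"
    if desc.kind == "duplication":
        return f"{head}{span}dup{desc.ref_bases or ''}"
    raise AssertionError(desc.kind)  # pragma: no cover


def format_hgvs_g(variant, genome: ReferenceGenome) -> str:
    """Canonical g.-scheme string for a trimmed variant (inverse of parsing).

    Accepts anything with contig/start/ref/alt attributes in minimal
    (no shared flanks) representation.
    """
    contig, start, ref, alt = variant.contig, variant.start, variant.ref, variant.alt
    if ref and alt and len(ref) == 1 and len(alt) == 1:
        return f"{contig}:g.{start + 1}{ref}>{alt}"
    if ref and not alt:
        if len(ref) == 1:
            return f"{contig}:g.{start + 1}del"
        return f"{contig}:g.{start + 1}_{start + len(ref)}del"
    if alt and not ref:
        # inserted between 1-based positions start and start+1
        return f"{contig}:g.{start}_{start + 1}ins{alt}"
    if len(ref) == 1:
        return f"{contig}:g.{start + 1}delins{alt}"
    return f"{contig}:g.{start + 1}_{start + len(ref)}delins{alt}"
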