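"""Rule-based in-silico flags for merged variants.

These are transparent positional rules — premature-stop by CDS
re-translation, splice proximity by distance to exon/intron junctions,
domain overlap by interval intersection, and a population-frequency
threshold — not calibrated pathogenicity scores. They mark variants for
curator attention; they are not classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio.Seq import Seq

from .genome import ReferenceGenome, Transcript, fetch_sequence, reverse_complement
from .normalize import NormalizedVariant

__all__ = [
    "AnnotationSet",
    "Domain",
    "read_domains_bed",
    "flag_premature_stop",
    "flag_splice_region",
    "flag_frequency",
    "flag_domains",
    "annotate_variant",
]

FREQUENCY_THRESHOLD_DEFAULT = 0.01
NEAR_SPLICE_EXONIC_DEFAULT = 3
NEAR_SPLICE_INTRONIC_DEFAULT = 8


@dataclass(frozen=True)
class Domain:
    contig: str
    start: int
    end: int
    name: str


@dataclass
class AnnotationSet:
    premature_stop: bool = False
    splice_region: str = "none"  # none | canonical_site | near_splice
    domain_hits: list[str] = field(default_factory=list)
    frequency_flag: str = "none"  # none | frequency_incompatible_with_high_risk
    max_af: Optional[float] = None

    def to_json(self) -> dict:
        return {
            "premature_stop": self.premature_stop,
            "splice_region": self.splice_region,
            "domain_hits": list(self.domain_hits),
            "frequency_flag": self.frequency_flag,
            "max_af": self.max_af,
        }


def read_domains_bed(path: Union[str, Path]) -> list[Domain]:
    """BED4: contig, start, end, name (0-based half-open, name required)."""
    domains = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line lacks a name column: {line!r}")
            domains.append(Domain(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return domains


def _effective_span(variant: NormalizedVariant) -> tuple[int, int]:
    """Interval used for intersection tests; insertions count their two flanking bases."""
    if variant.ref:
        return variant.start, variant.end
    return max(variant.start - 1, 0), variant.start + 1


def _first_stop_codon(cds: str) -> Optional[int]:
    """Index (in codons) of the first stop in a CDS string; None if absent."""
    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    i = protein.find("*")
    return i if i >= 0 else None


def flag_premature_stop(
    variant: NormalizedVariant, tx: Transcript, genome: ReferenceGenome
) -> bool:
    """True iff the edit truncates the protein.

    An edit overlapping the coding exonic bases is stop-introducing when it
    shifts the reading frame (net coding length change not a multiple of 3),
    or when re-translating the edited CDS places a stop codon strictly
    before the reference stop. Variants that do not touch coding exonic
    bases are False.
    """
    if variant.contig != tx.contig:
        return False
    segments = tx.cds_segments()
    vs, ve = variant.start, variant.end
    if variant.ref:
        coding_overlap = sum(max(0, min(e, ve) - max(s, vs)) for s, e in segments)
        touches = coding_overlap > 0
    else:
        touches = any(s < vs < e for s, e in segments)
        coding_overlap = 0
    if not touches:
        return False
    # net change in coding length: inserted/retained bases minus deleted coding bases
    if variant.ref:
        inside_one = any(s <= vs and ve <= e for s, e in segments)
        delta = (len(variant.alt) - len(variant.ref)) if inside_one else -coding_overlap
    else:
        delta = len(variant.alt)
    if delta % 3 != 0:
        return True
    # in-frame: rebuild the CDS with the edit applied in genomic orientation
    parts = []
    for s, e in segments:
        seg = fetch_sequence(genome, tx.contig, s, e)
        if s <= vs and ve <= e:
            seg = seg[: vs - s] + variant.alt + seg[ve - s :]
        elif max(s, vs) < min(e, ve):  # partial overlap of an in-frame edit
            left = fetch_sequence(genome, tx.contig, s, max(s, vs))
            right = fetch_sequence(genome, tx.contig, min(e, ve), e)
            mid = variant.alt if s <= vs else ""
            seg = left + mid + right
        parts.append(seg)
    edited = "".join(parts)
    if tx.strand == "-":
        edited = reverse_complement(edited)
    # premature = a stop strictly before the edited CDS's terminal codon;
    # the reference stop codon maps onto that terminal codon for in-frame
    # edits, so this is "stop before the reference stop", robust to the
    # codon renumbering an in-frame indel causes
    new_stop = _first_stop_codon(edited)
    if new_stop is None:
        return False
    return new_stop < len(edited) // 3 - 1


def flag_splice_region(
    variant: NormalizedVariant,
    tx: Transcript,
    exonic_window: int = NEAR_SPLICE_EXONIC_DEFAULT,
    intronic_window: int = NEAR_SPLICE_INTRONIC_DEFAULT,
) -> str:
    """Classify proximity to exon/intron junctions.

    canonical_site: the span touches the first or last two bases of any
    intron (the near-invariant donor/acceptor dinucleotides). near_splice:
    within `exonic_window` exonic or `intronic_window` intronic bases of a
    junction. Else none.
    """
    if variant.contig != tx.contig:
        return "none"
    vs, ve = _effective_span(variant)

    def hits(a: int, b: int) -> bool:
        return max(a, vs) < min(b, ve)

    for istart, iend in tx.introns():
        if hits(istart, min(istart + 2, iend)) or hits(max(iend - 2, istart), iend):
            return "canonical_site"
    for istart, iend in tx.introns():
        if hits(istart - exonic_window, istart + intronic_window):
            return "near_splice"
        if hits(iend - intronic_window, iend + exonic_window):
            return "near_splice"
    return "none"


def flag_frequency(
    af_by_source: dict[str, float], threshold: float = FREQUENCY_THRESHOLD_DEFAULT
) -> tuple[str, Optional[float]]:
    """Population-frequency screen: common variants are incompatible with high risk."""
    if not af_by_source:
        return "none", None
    max_af = max(af_by_source.values())
    if max_af >= threshold:
        return "frequency_incompatible_with_high_risk", max_af
    return "none", max_af


def flag_domains(variant: NormalizedVariant, domains: list[Domain]) -> list[str]:
    """Names of domains whose interval intersects the variant span."""
    if variant.ref:
        vs, ve = variant.start, variant.end
        hit = lambda d: max(d.start, vs) < min(d.end, ve)
    else:
        p = variant.start  # insertion point
        hit = lambda d: d.start < p < d.end
    return sorted({d.name for d in domains if d.contig == variant.contig and hit(d)})


def annotate_variant(
    variant: NormalizedVariant,
    transcripts: dict[str, Transcript],
    genome: ReferenceGenome,
    domains: list[Domain],
    af_by_source: dict[str, float],
    frequency_threshold: float = FREQUENCY_THRESHOLD_DEFAULT,
    exonic_window: int = NEAR_SPLICE_EXONIC_DEFAULT,
    intronic_window: int = NEAR_SPLICE_INTRONIC_DEFAULT,
) -> AnnotationSet:
    """All flags for one variant across all transcripts on its contig."""
    relevant = [t for t in transcripts.values() if t.contig == variant.contig]
    stop = any(flag_premature_stop(variant, t, genome) for t in relevant)
    splice_levels = {flag_splice_region(variant, t, exonic_window, intronic_window) for t in relevant}
    if "canonical_site" in splice_levels:
        splice = "canonical_site"
    elif "near_splice" in splice_levels:
        splice = "near_splice"
    else:
        splice = "none"
    freq_flag, max_af = flag_frequency(af_by_source, frequency_threshold)
    return AnnotationSet(
        premature_stop=stop,
        splice_region=splice,
        domain_hits=flag_domains(variant, domains),
        frequency_flag=freq_flag,
        max_af=max_af,
    )
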