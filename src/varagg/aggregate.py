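"""Group validated records into equivalence classes; build merged variants.

One merged variant per canonical key, with one tile per contributing
source. Tiles preserve each source's submissions verbatim — the aggregation
shows data "as is" and leaves reconciliation to the consensus stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome import ReferenceGenome
from .hgvslite import format_hgvs_g
from .ingest import SourceRecord
from .normalize import NormalizedVariant, canonicalize

__all__ = ["SourceTile", "MergedVariant", "build_equivalence_classes", "assemble_merged"]


@dataclass
class SourceTile:
    source: str
    records: list[SourceRecord]
    classification: Optional[str] = None  # verbatim, from the latest-dated record
    date: Optional[str] = None  # latest date among records
    internal_conflict: bool = False
    fields: dict[str, dict[str, str]] = field(default_factory=dict)  # record_id -> raw cells

    def to_json(self) -> dict:
        return {
            "source": self.source,
            "record_ids": sorted(r.record_id for r in self.records),
            "classification": self.classification,
            "date": self.date,
            "internal_conflict": self.internal_conflict,
            "fields": {k: dict(v) for k, v in sorted(self.fields.items())},
        }


@dataclass
class MergedVariant:
    key: str
    variant: NormalizedVariant
    tiles: list[SourceTile]
    names: list[str]  # sorted union of observed variant_texts + canonical g. HGVS
    hgvs_g: str
    annotations: Optional[dict] = None
    consensus: Optional[dict] = None

    def to_json(self) -> dict:
        return {
            "key": self.key,
            "contig": self.variant.contig,
            "start": self.variant.start,
            "ref": self.variant.ref,
            "alt": self.variant.alt,
            "hgvs_g": self.hgvs_g,
            "names": list(self.names),
            "tiles": {t.source: t.to_json() for t in self.tiles},
            "annotations": self.annotations,
            "consensus": self.consensus,
        }


def build_equivalence_classes(
    records: list[SourceRecord], genome: ReferenceGenome
) -> dict[str, list[SourceRecord]]:
    """Group parsed records by canonical key; each record lands in one class."""
    classes: dict[str, list[SourceRecord]] = {}
    for rec in records:
        if rec.parse_state != "parsed":
            continue
        key = canonicalize(rec.variant, genome).key
        classes.setdefault(key, []).append(rec)
    return classes


def _build_tile(source: str, records: list[SourceRecord]) -> SourceTile:
    by_date = sorted(records, key=lambda r: (r.date or "", r.record_id))
    classifications = {r.classification for r in records if r.classification}
    latest_classified = [r for r in by_date if r.classification]
    tile = SourceTile(
        source=source,
        records=sorted(records, key=lambda r: r.record_id),
        classification=latest_classified[-1].classification if latest_classified else None,
        date=max((r.date for r in records if r.date), default=None),
        internal_conflict=len(classifications) > 1,
        fields={r.record_id: dict(r.raw_fields) for r in records},
    )
    return tile


def assemble_merged(
    classes: dict[str, list[SourceRecord]], genome: ReferenceGenome
) -> list[MergedVariant]:
    """One MergedVariant per class, deterministically ordered.

    Output order is (contig, start, ref, alt); tiles are ordered by source
    name and names are sorted, so the result is independent of input record
    order.
    """
    merged: list[MergedVariant] = []
    for key, records in classes.items():
        variant = canonicalize(records[0].variant, genome)
        by_source: dict[str, list[SourceRecord]] = {}
        for rec in records:
            by_source.setdefault(rec.source, []).append(rec)
        tiles = [_build_tile(src, recs) for src, recs in sorted(by_source.items())]
        hgvs_g = format_hgvs_g(variant, genome)
        names = sorted({r.variant_text for r in records if r.variant_text} | {hgvs_g})
        merged.append(MergedVariant(key, variant, tiles, names, hgvs_g))
    merged.sort(key=lambda m: (m.variant.contig, m.variant.start, m.variant.ref, m.variant.alt))
    return merged
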