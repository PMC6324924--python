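"""Per-source readers: population VCFs and clinical delimited tables.

Every input row becomes a ``SourceRecord`` carrying its original cells
verbatim (``raw_fields``) plus the pipeline's parse state. Source dialects —
which column holds the identifier, the HGVS string, the classification, the
submission date — are declared in a small JSON/YAML config rather than
hard-coded, because real aggregation projects ingest many sources with
incompatible schemas.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam
import yaml

from .genome import ReferenceGenome, Transcript
from .hgvslite import ParseFailure, RawVariant, parse_hgvs, resolve_to_genomic

__all__ = [
    "SourceRecord",
    "TableDialect",
    "read_vcf_source",
    "read_table_source",
    "parse_batch",
    "load_dialects",
]


@dataclass
class SourceRecord:
    source: str
    record_id: str
    raw_fields: dict[str, str]
    variant_text: str = ""
    classification: Optional[str] = None
    date: Optional[str] = None  # ISO yyyy-mm-dd
    allele_frequency: Optional[float] = None
    parse_state: str = "pending"  # pending | parsed | failed
    variant: Optional[RawVariant] = None
    failure: Optional[ParseFailure] = None

    def mark_parsed(self, variant: RawVariant) -> None:
        self.parse_state, self.variant, self.failure = "parsed", variant, None

    def mark_failed(self, failure: ParseFailure) -> None:
        self.parse_state, self.variant, self.failure = "failed", None, failure


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for one delimited source."""

    id_column: str
    hgvs_column: str
    classification_column: Optional[str] = None
    date_column: Optional[str] = None
    delimiter: str = "\t"


def load_dialects(path: Union[str, Path]) -> dict[str, TableDialect]:
    """Read a {source-name: dialect} mapping from JSON or YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {name: TableDialect(**cfg) for name, cfg in doc.items()}


def normalize_date(text: Optional[str]) -> Optional[str]:
    """Normalize to ISO yyyy-mm-dd; month-precision dates get day 01."""
    if text is None or not str(text).strip():
        return None
    text = str(text).strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d", "%d/%m/%Y"):
        try:
            return _dt.datetime.strptime(text, fmt).date().isoformat()
        except ValueError:
            pass
    try:
        return _dt.datetime.strptime(text, "%Y-%m").date().isoformat()
    except ValueError:
        return None


def read_vcf_source(path: Union[str, Path], source_name: str) -> list[SourceRecord]:
    """Read a population-frequency VCF; one record per ALT allele.

    Allele frequency comes from the AF INFO field when present, else AC/AN.
    Multi-allelic sites are decomposed, with per-allele AF/AC values kept
    aligned to their ALT. The VCF anchor base is retained in ref/alt; the
    normalization stage trims it.
    """
    records: list[SourceRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, row in enumerate(vcf):
            alts = row.alts or ()
            af = row.info.get("AF") if "AF" in row.info else None
            ac = row.info.get("AC") if "AC" in row.info else None
            an = row.info.get("AN") if "AN" in row.info else None
            for j, alt in enumerate(alts):
                rid = row.id if row.id and len(alts) == 1 else f"{row.id or f'row{i}'}_{j}"
                raw_fields = {
                    "CHROM": row.chrom,
                    "POS": str(row.pos),
                    "ID": row.id or ".",
                    "REF": row.ref,
                    "ALT": alt,
                }
                rec = SourceRecord(
                    source=source_name,
                    record_id=rid,
                    raw_fields=raw_fields,
                    variant_text=f"{row.chrom}:{row.pos}:{row.ref}>{alt}",
                )
                freq = None
                if af is not None:
                    # htslib stores AF as 32-bit float; round back to the
                    # printed precision
                    freq = round(float(af[j] if isinstance(af, tuple) else af), 6)
                elif ac is not None and an:
                    acj = ac[j] if isinstance(ac, tuple) else ac
                    freq = float(acj) / float(an)
                if freq is not None and not (0.0 <= freq <= 1.0):
                    rec.mark_failed(ParseFailure("bad_allele_frequency", str(freq)))
                else:
                    rec.allele_frequency = freq
                    # VCF is 1-based, anchored
                    rec.variant = RawVariant(row.chrom, row.pos - 1, row.ref.upper(), alt.upper())
                    rec.parse_state = "pending"
                records.append(rec)
    return records


def read_table_source(
    path: Union[str, Path], source_name: str, dialect: TableDialect
) -> list[SourceRecord]:
    """Read a delimited clinical/LSDB-style source with an HGVS column."""
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for col in (dialect.id_column, dialect.hgvs_column):
        if col not in df.columns:
            raise ValueError(f"{source_name}: mandatory column {col!r} missing from {path}")
    records: list[SourceRecord] = []
    for _, row in df.iterrows():
        raw_fields = {c: row[c] for c in df.columns}
        cls = row.get(dialect.classification_column) if dialect.classification_column else None
        date = row.get(dialect.date_column) if dialect.date_column else None
        rec = SourceRecord(
            source=source_name,
            record_id=str(row[dialect.id_column]),
            raw_fields=raw_fields,
            variant_text=str(row[dialect.hgvs_column]),
            classification=cls if cls else None,
            date=normalize_date(date),
        )
        if not rec.variant_text.strip():
            rec.mark_failed(ParseFailure("missing_variant", rec.record_id))
        records.append(rec)
    return records


def dedupe_records(records: list[SourceRecord]) -> tuple[list[SourceRecord], list[SourceRecord]]:
    """Drop true duplicates (same source + record_id), keeping the latest date.

    Returns (kept, superseded); superseded records are marked failed with
    reason ``superseded_duplicate``.
    """
    best: dict[tuple[str, str], SourceRecord] = {}
    superseded: list[SourceRecord] = []
    for rec in records:
        k = (rec.source, rec.record_id)
        prev = best.get(k)
        if prev is None:
            best[k] = rec
        else:
            keep, drop = (rec, prev) if (rec.date or "") >= (prev.date or "") else (prev, rec)
            best[k] = keep
            drop.mark_failed(ParseFailure("superseded_duplicate", drop.record_id))
            superseded.append(drop)
    return list(best.values()), superseded


def parse_batch(
    records: list[SourceRecord],
    genome: ReferenceGenome,
    transcripts: Optional[dict[str, Transcript]] = None,
) -> dict[str, int]:
    """Resolve every pending record to a raw genomic variant, in place.

    VCF-derived records already carry coordinates and just flip to parsed;
    text records go through the HGVS parser and genomic resolution. Returns
    failure counts by reason (empty-string key counts successes).
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.parse_state != "pending":
            if rec.parse_state == "failed" and rec.failure:
                counts[rec.failure.reason] = counts.get(rec.failure.reason, 0) + 1
            continue
        if rec.variant is not None:  # coordinate-born (VCF) record
            rec.mark_parsed(rec.variant)
            counts[""] = counts.get("", 0) + 1
            continue
        desc = parse_hgvs(rec.variant_text)
        if isinstance(desc, ParseFailure):
            rec.mark_failed(desc)
            counts[desc.reason] = counts.get(desc.reason, 0) + 1
            continue
        resolved = resolve_to_genomic(desc, genome, transcripts or {})
        if isinstance(resolved, ParseFailure):
            rec.mark_failed(resolved)
            counts[resolved.reason] = counts.get(resolved.reason, 0) + 1
        else:
            rec.mark_parsed(resolved)
            counts[""] = counts.get("", 0) + 1
    return counts
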