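"""Synthetic world generator: toy genome, transcripts, domains, and
per-source variant files with planted truth.

The generator emits exactly the formats the ingestion stage reads (a VCF
population source plus delimited clinical sources with per-source column
dialects) together with ``truth.json``, which records every planted distinct
variant's canonical key, its alias representations, every planted error with
its reason code, and the consensus each variant should display. Everything
is driven by a single seed and regenerates byte-identically.

Planted structure mirrors what real aggregation has to survive: repeat
tracts so that indels admit shifted-but-equivalent representations, anchored
and delins-padded restatements of the same change, duplication notation for
insertions, classification conflicts between submitters, and records that
are broken in specific, detectable ways.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

from .consensus import DEFAULT_CLASSIFICATION_MAP
from .genome import (
    ReferenceGenome,
    Transcript,
    project_g_to_c,
    reverse_complement,
    write_transcript_table,
)
from .hgvslite import RawVariant
from .normalize import NormalizedVariant, canonicalize, validate_reference

__all__ = ["FixtureSpec", "generate_world", "make_alias", "apply_edit"]

SOURCE_ORDER = ("expertpanel", "clinvar-like", "lsdb-like", "popfreq")
TERMS = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")
CONFLICT_PAIRS = (
    ("Benign", "Pathogenic"),
    ("VUS", "Pathogenic"),
    ("VUS", "Benign"),
    ("Likely benign", "Likely pathogenic"),
)
SUPPORTED_ERROR_REASONS = (
    "ref_mismatch",
    "hgvs_unparseable",
    "unsupported_scheme",
    "malformed_operator",
    "unknown_reference",
    "missing_variant",
)


def _default_errors() -> dict[str, int]:
    return {
        "ref_mismatch": 20,
        "hgvs_unparseable": 10,
        "unsupported_scheme": 5,
        "unknown_reference": 10,
        "missing_variant": 5,
    }


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    contig_length: int = 12000
    n_transcripts: int = 2
    n_distinct_variants: int = 500
    n_equivalence_aliases: int = 200
    n_errors_by_reason: dict[str, int] = field(default_factory=_default_errors)
    n_sources: int = 4
    af_distribution: tuple = ("uniform", 1e-4, 0.05)
    conflict_fraction: float = 0.1
    expert_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_distinct_variants < 0 or self.n_equivalence_aliases < 0:
            raise ValueError("counts must be non-negative")
        if not (2 <= self.n_sources <= len(SOURCE_ORDER)):
            raise ValueError(f"n_sources must be in [2, {len(SOURCE_ORDER)}]")
        for reason, n in self.n_errors_by_reason.items():
            if reason not in SUPPORTED_ERROR_REASONS:
                raise ValueError(f"unsupported planted error reason {reason!r}")
            if n < 0:
                raise ValueError("error counts must be non-negative")

    @property
    def sources(self) -> tuple[str, ...]:
        return SOURCE_ORDER[: self.n_sources]


def apply_edit(seq: str, variant: Union[RawVariant, NormalizedVariant]) -> str:
    """Whole-contig edit oracle: the contig with the variant applied."""
    return seq[: variant.start] + variant.alt + seq[variant.start + len(variant.ref) :]


# ---------------------------------------------------------------------------
# genome / transcript construction

def _build_contig(rng: random.Random, length: int) -> str:
    """Random sequence with (AC)n and homopolymer tracts every ~400 bp."""
    bases = [rng.choice("ACGT") for _ in range(length)]
    pos = 200
    toggle = True
    while pos + 20 < length - 200:
        tract = "AC" * 8 if toggle else rng.choice("AT") * 10
        bases[pos : pos + len(tract)] = list(tract)
        toggle = not toggle
        pos += 400 + rng.randrange(0, 120)
    return "".join(bases)


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _plant_transcripts(
    rng: random.Random, seq: list, contig: str, n: int
) -> dict[str, Transcript]:
    """Carve n three-exon transcripts into the contig, alternating strands.

    Each CDS is written into the exonic bases as ATG + non-stop codons +
    TAA (transcript orientation) so that premature-stop truth is clean.
    """
    length = len(seq)
    txs: dict[str, Transcript] = {}
    region = length // max(n, 1)
    for i in range(n):
        base = i * region + 60
        e1 = (base, base + 90 + 3 * rng.randrange(0, 10))
        gap1 = 60 + rng.randrange(0, 40)
        e2 = (e1[1] + gap1, e1[1] + gap1 + 120 + 3 * rng.randrange(0, 10))
        gap2 = 60 + rng.randrange(0, 40)
        e3 = (e2[1] + gap2, e2[1] + gap2 + 90 + 3 * rng.randrange(0, 10))
        if e3[1] + 60 > (i + 1) * region:
            raise ValueError("contig too short for requested transcripts")
        strand = "+" if i % 2 == 0 else "-"
        cds_start = e1[0] + 30
        cds_end = e3[1] - 30
        exons = (e1, e2, e3)
        cds_len = sum(
            max(0, min(e, cds_end) - max(s, cds_start)) for s, e in exons
        )
        cds_end -= cds_len % 3
        tx = Transcript(f"TX{i + 1}", contig, strand, exons, cds_start, cds_end)
        n_codons = tx.cds_length // 3
        coding = "ATG" + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)) + "TAA"
        genomic = coding if strand == "+" else reverse_complement(coding)
        offset = 0
        for s, e in tx.cds_segments():
            seq[s:e] = list(genomic[offset : offset + (e - s)])
            offset += e - s
        txs[tx.id] = tx
    return txs


def _plant_domains(rng: random.Random, txs: dict[str, Transcript]) -> list[tuple[str, int, int, str]]:
    rows = []
    for i, tx in enumerate(txs.values()):
        segs = tx.cds_segments()
        for j, (s, e) in enumerate(segs[:2]):
            width = max(12, (e - s) // 3)
            start = s + (e - s - width) // 3
            rows.append((tx.contig, start, start + width, f"DOM{i + 1}_{j + 1}"))
    return rows


# ---------------------------------------------------------------------------
# variant and alias construction

def _random_variant(rng: random.Random, contig: str, seq: str) -> RawVariant:
    kind = rng.choices(
        ["snv", "del", "ins", "delins", "dup"], weights=[50, 20, 15, 10, 5]
    )[0]
    pos = rng.randrange(50, len(seq) - 50)
    if kind == "snv":
        ref = seq[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return RawVariant(contig, pos, ref, alt)
    if kind == "del":
        n = rng.randrange(1, 4)
        return RawVariant(contig, pos, seq[pos : pos + n], "")
    if kind == "ins":
        n = rng.randrange(1, 4)
        return RawVariant(contig, pos, "", "".join(rng.choice("ACGT") for _ in range(n)))
    if kind == "dup":
        n = rng.randrange(1, 4)
        span = seq[pos : pos + n]
        return RawVariant(contig, pos, span, span + span)
    n = rng.randrange(2, 4)
    ref = seq[pos : pos + n]
    alt = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
    while alt == ref or (alt and ref and (alt[0] == ref[0] or alt[-1] == ref[-1])):
        alt = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
    return RawVariant(contig, pos, ref, alt)


def make_alias(
    variant: NormalizedVariant,
    genome: ReferenceGenome,
    style: str,
    shift: int = 1,
) -> RawVariant:
    """A textually different representation that edits the contig identically.

    styles: ``anchored`` (prepend the shared preceding base), ``delins``
    (pad one matching base on each side, making a complex-indel
    restatement), ``shifted`` (slide a pure indel rightward through a
    repeat; requires repeat context), ``dup`` (the doubled-span form of an
    insertion that duplicates the preceding bases).
    """
    seq = genome.contigs[variant.contig]
    s, ref, alt = variant.start, variant.ref, variant.alt
    if style == "anchored":
        if s == 0:
            raise ValueError("anchored alias needs a preceding base")
        return RawVariant(variant.contig, s - 1, seq[s - 1] + ref, seq[s - 1] + alt)
    if style == "delins":
        if s == 0 or s + len(ref) >= len(seq):
            raise ValueError("delins alias needs flanking bases")
        left, right = seq[s - 1], seq[s + len(ref)]
        return RawVariant(variant.contig, s - 1, left + ref + right, left + alt + right)
    if style == "shifted":
        if bool(ref) == bool(alt):
            raise ValueError("shifted alias needs a pure indel")
        allele = ref or alt
        start = s
        for _ in range(shift):
            nxt = start + len(allele) if ref else start
            if nxt >= len(seq) or seq[nxt if ref else start] != allele[0]:
                raise ValueError("no repeat context to shift into")
            allele = allele[1:] + allele[0]
            start += 1
            if ref and seq[start : start + len(allele)] != allele:
                raise ValueError("no repeat context to shift into")
        out = (
            RawVariant(variant.contig, start, allele, "")
            if ref
            else RawVariant(variant.contig, start, "", allele)
        )
        if apply_edit(seq, out) != apply_edit(seq, variant):
            raise ValueError("no repeat context to shift into")
        return out
    if style == "dup":
        # a left-aligned insertion whose alt equals the bases right after the
        # insertion point is exactly a duplication of that span
        if ref or not alt:
            raise ValueError("dup alias needs a pure insertion")
        if seq[s : s + len(alt)] != alt:
            raise ValueError("insertion does not duplicate the adjacent span")
        return RawVariant(variant.contig, s, alt, alt + alt)
    raise ValueError(f"unknown alias style {style!r}")


def raw_to_hgvs_g(v: RawVariant, dup_hint: bool = False) -> str:
    """Express a raw (possibly non-canonical) variant in g. notation."""
    s, ref, alt = v.start, v.ref, v.alt
    if dup_hint and ref and alt == ref + ref:
        if len(ref) == 1:
            return f"{v.contig}:g.{s + 1}dup"
        return f"{v.contig}:g.{s + 1}_{s + len(ref)}dup"
    if ref and alt and len(ref) == 1 and len(alt) == 1:
        return f"{v.contig}:g.{s + 1}{ref}>{alt}"
    if ref and not alt:
        if len(ref) == 1:
            return f"{v.contig}:g.{s + 1}del{ref}"
        return f"{v.contig}:g.{s + 1}_{s + len(ref)}del{ref}"
    if alt and not ref:
        return f"{v.contig}:g.{s}_{s + 1}ins{alt}"
    if len(ref) == 1:
        return f"{v.contig}:g.{s + 1}delins{alt}"
    return f"{v.contig}:g.{s + 1}_{s + len(ref)}delins{alt}"


def _c_notation(
    v: NormalizedVariant, txs: dict[str, Transcript]
) -> Optional[str]:
    """c.-scheme text for an exonic SNV fully inside one transcript exon."""
    if not (len(v.ref) == 1 and len(v.alt) == 1):
        return None
    for tx in txs.values():
        if tx.contig == v.contig and tx.is_exonic(v.start):
            cpos = project_g_to_c(tx, v.start)
            ref_t = v.ref if tx.strand == "+" else reverse_complement(v.ref)
            alt_t = v.alt if tx.strand == "+" else reverse_complement(v.alt)
            return f"{tx.id}:c.{cpos}{ref_t}>{alt_t}"
    return None


# ---------------------------------------------------------------------------
# world generation

def _draw_af(rng: random.Random, dist: tuple) -> float:
    if dist[0] == "uniform":
        return round(rng.uniform(dist[1], dist[2]), 6)
    if dist[0] == "point":
        return rng.choice(list(dist[1:]))
    raise ValueError(f"unknown af_distribution {dist!r}")


def _random_date(rng: random.Random, year_lo: int = 2017, year_hi: int = 2018) -> str:
    y = rng.randrange(year_lo, year_hi + 1)
    m = rng.randrange(1, 13)
    d = rng.randrange(1, 29)
    return f"{y:04d}-{m:02d}-{d:02d}"


_VERBATIM: dict[str, list[str]] = {}
for _raw, _term in DEFAULT_CLASSIFICATION_MAP.items():
    _VERBATIM.setdefault(_term, []).append(_raw)


def _verbatim(rng: random.Random, term: str) -> str:
    choice = rng.choice(_VERBATIM[term] + [term])
    return choice.title() if rng.random() < 0.5 else choice


def generate_world(spec: FixtureSpec, out_dir: Union[str, Path]) -> dict:
    """Write the full fixture world under out_dir; return the truth manifest.

    Files: genome.fa, transcripts.tsv, domains.bed, one file per source,
    dialects.json, config.yaml (a ready-to-run pipeline config) and
    truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    contig = "chrT"
    seq_list = list(_build_contig(rng, spec.contig_length))
    txs = _plant_transcripts(rng, seq_list, contig, spec.n_transcripts)
    seq = "".join(seq_list)
    genome = ReferenceGenome({contig: seq})
    domains = _plant_domains(rng, txs)

    # --- distinct variants with unique canonical keys
    variants: list[NormalizedVariant] = []
    seen_keys: set[str] = set()
    guard = 0
    while len(variants) < spec.n_distinct_variants:
        guard += 1
        if guard > 50 * max(spec.n_distinct_variants, 1):
            raise RuntimeError("could not place requested variants; contig too small")
        raw = _random_variant(rng, contig, seq)
        if validate_reference(raw, genome) is not None:
            continue
        canon = canonicalize(raw, genome)
        if canon.key in seen_keys:
            continue
        seen_keys.add(canon.key)
        variants.append(canon)

    sources = spec.sources
    classifying = [s for s in sources if s != "popfreq"]
    non_expert = [s for s in classifying if s != "expertpanel"]
    has_pop = "popfreq" in sources

    # --- per-variant scenario: who reports it and with which words
    table_rows: dict[str, list[dict]] = {s: [] for s in classifying}
    vcf_variants: list[dict] = []  # {variant, af, record_id}
    truth_variants: dict[str, dict] = {}
    rid_counter = {s: 0 for s in sources}

    def next_rid(source: str) -> str:
        rid_counter[source] += 1
        return f"{source[:2].upper()}{rid_counter[source]:06d}"

    def add_table_record(source: str, text: str, term: Optional[str], date: str) -> str:
        rid = next_rid(source)
        table_rows[source].append(
            {
                "id": rid,
                "hgvs": text,
                "classification": _verbatim(rng, term) if term else "",
                "date": date,
            }
        )
        return rid

    for canon in variants:
        scenario = rng.random()
        assigned: dict[str, Optional[str]] = {}
        if "expertpanel" in classifying and scenario < spec.expert_fraction:
            term = rng.choice(TERMS)
            assigned["expertpanel"] = term
            expected = term
            for s in non_expert:
                if rng.random() < 0.5:
                    assigned[s] = rng.choice(TERMS)
        elif len(non_expert) >= 2 and scenario < spec.expert_fraction + spec.conflict_fraction:
            a, b = rng.choice(CONFLICT_PAIRS)
            s1, s2 = rng.sample(non_expert, 2)
            assigned[s1], assigned[s2] = a, b
            expected = "Conflicting"
        else:
            mode = rng.random()
            if mode < 0.15 and has_pop:
                expected = "Not classified"  # population-only sighting
            elif mode < 0.55 or len(non_expert) < 2:
                term = rng.choice(TERMS)
                for s in rng.sample(non_expert, rng.randrange(1, len(non_expert) + 1)):
                    assigned[s] = term
                expected = term
            else:
                fam = rng.choice((("Benign", "Likely benign"), ("Pathogenic", "Likely pathogenic")))
                s1, s2 = rng.sample(non_expert, 2)
                assigned[s1], assigned[s2] = fam
                expected = fam[1]

        in_pop = has_pop and (rng.random() < 0.5 or not assigned)
        af = _draw_af(rng, spec.af_distribution) if in_pop else None
        record_sources = sorted(assigned) + (["popfreq"] if in_pop else [])
        names = []
        for s, term in sorted(assigned.items()):
            text = None
            if rng.random() < 0.3:
                text = _c_notation(canon, txs)
            if text is None:
                text = raw_to_hgvs_g(RawVariant(canon.contig, canon.start, canon.ref, canon.alt))
            add_table_record(s, text, term, _random_date(rng))
            names.append(text)
        if in_pop:
            vcf_variants.append({"variant": canon, "af": af, "record_id": next_rid("popfreq")})
        truth_variants[canon.key] = {
            "expected_consensus": expected,
            "sources": record_sources,
            "n_records": len(record_sources),
            "max_af": af,
            "aliases": [],
        }

    # --- aliases: extra representations of already-planted variants
    styles = ("anchored", "delins", "shifted", "dup")
    alias_count = 0
    attempt = 0
    while alias_count < spec.n_equivalence_aliases:
        attempt += 1
        if attempt > 200 * max(spec.n_equivalence_aliases, 1):
            raise RuntimeError("could not plant requested aliases")
        parent = rng.choice(variants)
        style = rng.choice(styles)
        try:
            alias_raw = make_alias(parent, genome, style)
        except ValueError:
            continue
        assert apply_edit(seq, alias_raw) == apply_edit(seq, parent)
        text = raw_to_hgvs_g(alias_raw, dup_hint=(style == "dup"))
        source = rng.choice(classifying)
        rid = add_table_record(source, text, None, _random_date(rng))
        entry = truth_variants[parent.key]
        entry["aliases"].append({"style": style, "text": text, "source": source, "record_id": rid})
        entry["n_records"] += 1
        if source not in entry["sources"]:
            entry["sources"] = sorted(entry["sources"] + [source])
        alias_count += 1

    # --- planted errors
    errors: list[dict] = []

    def plant_error(reason: str) -> None:
        if reason == "ref_mismatch":
            pos = rng.randrange(50, len(seq) - 50)
            wrong = rng.choice([b for b in "ACGT" if b != seq[pos]])
            alt = rng.choice([b for b in "ACGT" if b != wrong])
            if has_pop and rng.random() < 0.4:
                rid = next_rid("popfreq")
                vcf_variants.append(
                    {
                        "variant": NormalizedVariant(contig, pos, wrong, alt),
                        "af": _draw_af(rng, spec.af_distribution),
                        "record_id": rid,
                        "skip_anchor": True,
                    }
                )
                errors.append({"source": "popfreq", "record_id": rid, "reason": reason})
                return
            text = f"{contig}:g.{pos + 1}{wrong}>{alt}"
            source = rng.choice(classifying)
            rid = add_table_record(source, text, None, _random_date(rng))
            errors.append({"source": source, "record_id": rid, "reason": reason})
            return
        source = rng.choice(classifying)
        if reason == "hgvs_unparseable":
            text = f"{contig}:g.garbled{rng.randrange(1000)}"
        elif reason == "unsupported_scheme":
            text = f"TX1:p.Val{rng.randrange(10, 60)}Glu"
        elif reason == "malformed_operator":
            pos = rng.randrange(50, len(seq) - 50)
            text = f"{contig}:g.{pos + 1}{seq[pos]}>>T"
        elif reason == "unknown_reference":
            text = f"TX_MISSING:c.{rng.randrange(1, 50)}A>G"
        elif reason == "missing_variant":
            text = ""
        else:  # pragma: no cover - guarded by FixtureSpec
            raise AssertionError(reason)
        rid = add_table_record(source, text, None, _random_date(rng))
        errors.append({"source": source, "record_id": rid, "reason": reason})

    for reason in sorted(spec.n_errors_by_reason):
        for _ in range(spec.n_errors_by_reason[reason]):
            plant_error(reason)

    # shuffle row order within each table so output determinism is exercised
    for rows in table_rows.values():
        rng.shuffle(rows)

    # --- write files
    paths = _write_files(out, genome, txs, domains, table_rows, vcf_variants, sources)

    n_wellformed = sum(v["n_records"] for v in truth_variants.values())
    truth = {
        "seed": spec.seed,
        "spec": {**asdict(spec), "af_distribution": list(spec.af_distribution)},
        "counts": {
            "distinct": len(truth_variants),
            "aliases": alias_count,
            "records_wellformed": n_wellformed,
            "errors_by_reason": {
                r: n for r, n in sorted(spec.n_errors_by_reason.items()) if n
            },
        },
        "variants": dict(sorted(truth_variants.items())),
        "errors": sorted(errors, key=lambda e: (e["source"], e["record_id"])),
        "files": {k: v.name for k, v in paths.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


_DIALECTS = {
    "expertpanel": {
        "id_column": "assertion_id",
        "hgvs_column": "hgvs",
        "classification_column": "clinical_significance",
        "date_column": "date_reviewed",
        "delimiter": "\t",
    },
    "clinvar-like": {
        "id_column": "accession",
        "hgvs_column": "hgvs_text",
        "classification_column": "classification",
        "date_column": "last_evaluated",
        "delimiter": "\t",
    },
    "lsdb-like": {
        "id_column": "record",
        "hgvs_column": "dna_change",
        "classification_column": "class",
        "date_column": "submitted",
        "delimiter": ",",
    },
}


def _write_files(out, genome, txs, domains, table_rows, vcf_variants, sources):
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = fasta

    tx_path = out / "transcripts.tsv"
    write_transcript_table(txs.values(), tx_path)
    paths["transcripts"] = tx_path

    bed = out / "domains.bed"
    with open(bed, "w") as fh:
        for c, s, e, name in domains:
            fh.write(f"{c}\t{s}\t{e}\t{name}\n")
    paths["domains"] = bed

    dialects = {s: _DIALECTS[s] for s in sources if s != "popfreq"}
    (out / "dialects.json").write_text(json.dumps(dialects, indent=1, sort_keys=True))
    paths["dialects"] = out / "dialects.json"

    for source, cfg in dialects.items():
        ext = "csv" if cfg["delimiter"] == "," else "tsv"
        path = out / f"{source}.{ext}"
        cols = [cfg["id_column"], cfg["hgvs_column"], cfg["classification_column"], cfg["date_column"]]
        with open(path, "w") as fh:
            fh.write(cfg["delimiter"].join(cols) + "\n")
            for row in table_rows[source]:
                fh.write(
                    cfg["delimiter"].join(
                        [row["id"], row["hgvs"], row["classification"], row["date"]]
                    )
                    + "\n"
                )
        paths[source] = path

    if "popfreq" in sources:
        paths["popfreq"] = _write_vcf(out / "popfreq.vcf", contig, seq, vcf_variants)

    _write_config(out, sources, paths)
    paths["config"] = out / "config.yaml"
    return paths


def _write_vcf(path: Path, contig: str, seq: str, vcf_variants: list[dict]) -> Path:
    """Anchored VCF rows; SNVs sharing (pos, ref) are emitted multi-allelic."""
    rows: dict[tuple[int, str], list[dict]] = {}
    for item in vcf_variants:
        v = item["variant"]
        if v.ref and v.alt and not item.get("skip_anchor") is True and len(v.ref) == len(v.alt) == 1:
            pos, ref, alt = v.start + 1, v.ref, v.alt
        elif item.get("skip_anchor"):
            pos, ref, alt = v.start + 1, v.ref, v.alt
        else:
            anchor = seq[v.start - 1]
            pos, ref, alt = v.start, anchor + v.ref, anchor + v.alt
        rows.setdefault((pos, ref), []).append({**item, "alt": alt})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (pos, ref), items in sorted(rows.items()):
            alts = ",".join(it["alt"] for it in items)
            afs = ",".join(f"{it['af']:.6f}" for it in items)
            rid = items[0]["record_id"] if len(items) == 1 else ";".join(it["record_id"] for it in items)
            fh.write(f"{contig}\t{pos}\t{rid}\t{ref}\t{alts}\t.\t.\tAF={afs}\n")
    return path


def _write_config(out: Path, sources, paths) -> None:
    lines = [
        f"genome: {paths['genome'].name}",
        f"transcripts: {paths['transcripts'].name}",
        f"domains: {paths['domains'].name}",
        f"dialects: {paths['dialects'].name}",
        "expert_order: [expertpanel]",
        "frequency_threshold: 0.01",
        "sources:",
    ]
    for s in sources:
        kind = "vcf" if s == "popfreq" else "table"
        lines.append(f"  - name: {s}")
        lines.append(f"    kind: {kind}")
        lines.append(f"    path: {paths[s].name}")
    (out / "config.yaml").write_text("\n".join(lines) + "\n")
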