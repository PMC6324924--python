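# Methods

## Problem setting

Clinical variant repositories disagree not only about interpretation but
about identity: the same physical sequence change is reported as an HGVS
string against a transcript by one submitter, as an anchored VCF allele by
a population survey, and as a shifted or restated indel by a third party.
Before any cross-source comparison is meaningful, records must be validated
against one reference sequence and reduced to a common identity. This
package implements that aggregation cycle as a deterministic, auditable
pipeline: ingest → parse → validate → canonicalize → merge → annotate →
consensus → release.

## Variant identity

**Definition.** Two validated variants on the same contig are equivalent
iff applying each edit to the entire contig yields the same string. The
equivalent windowed formulation — equality of alternative allele strings
(reference window with the edit applied) over any common window containing
both spans — is implemented as `allele_string` and used as the test oracle.

**Realization.** Equivalence is decided by canonical-key equality:
suffix-then-prefix trimming to the minimal (ref, alt) pair, followed by
left-alignment of pure indels (shift left while the preceding genome base
equals the last base of the moving allele). Left over right alignment is
the VCF convention; either direction yields a consistent identity, and the
choice is invisible to equivalence. Trimming to empty-ref/empty-alt
minimal form (no anchor base) is the internal representation; anchor bases
are re-added only when writing VCF (with right-padding at contig start).
The equivalence of the canonical-key and allele-string formulations is not
assumed: the suite enumerates every 1–3 bp deletion, duplication, delins
and (AC-alphabet) insertion at every position of a 60 bp repeat-rich
contig (~2,000 variants, >100,000 implied pairs) and checks that the two
partitions coincide exactly.

Degenerate inputs: a record whose ref equals its alt is discarded as
`null_variant`; ref spans containing N are discarded (`ref_contains_n`)
because equivalence over unresolved bases is undefined; validation
precedes canonicalization, so claimed reference bases are never silently
corrected.

## Coordinate conventions

All internal coordinates are 0-based half-open. 1-based conversions happen
only in readers and writers (HGVS text, VCF, transcript table
documentation aside — the transcript table itself is 0-based half-open).
Coding (c.) coordinates are structured values (region ∈ {CDS, 5′UTR,
3′UTR}, ordinal, intron offset); projection to genomic coordinates indexes
the transcript's exonic bases in transcript orientation, and intron
offsets move in the strand-appropriate genomic direction. Offsets are
valid only from the exon base adjacent to the intron and must stay
strictly inside that intron; anything else is a projection error. The
projector is checked against an exhaustive linear walk over all exon bases
on plus- and minus-strand transcripts, and `project_g_to_c` inverts it for
every exonic base (intronic positions are expressed from the nearest
boundary, ties toward the upstream exon).

## HGVS subset

Supported: `g.` and `c.` substitution, del (with or without listed bases),
ins, delins, dup. Protein and RNA schemes are recognized and rejected
(`unsupported_scheme`) — they carry no mergeable genomic coordinates. All
parse and resolution failures are values with stable reason codes, never
exceptions, because malformed strings are an expected input class whose
counts are part of the pipeline's output. A duplication without listed
bases resolves to an insertion of the duplicated span immediately after
it; with listed bases it resolves to the doubled-span form so that a wrong
listing flows to validation and is discarded as `ref_mismatch` rather than
silently fixed. Insertions format as `g.{p}_{p+1}ins` where p is the
1-based base before the insertion point; `format_hgvs_g ∘ parse ∘ resolve
∘ canonicalize` is the identity on canonical variants (property-tested).

## Merging and tiles

Records grouped by canonical key become one merged variant each, with one
tile per contributing source. Tiles keep all source cells verbatim; when
two records of one source disagree on classification the tile carries
`internal_conflict` and shows the latest-dated assertion as its face
value, leaving reconciliation to the consensus stage. Output ordering is
(contig, start, ref, alt) with lexicographic tie-breaks, making releases
independent of input record order (tested by permuting input files). True
duplicate rows (same source and record id) keep the latest-dated record;
the loser is logged `superseded_duplicate`.

## Annotation rules

These are transparent positional rules for curator triage, not calibrated
predictors; score calibration is explicitly out of scope.

- **Premature stop.** A variant touching coding exonic bases is flagged
  when it shifts the reading frame (net coding-length change not a
  multiple of 3 — frameshifts are treated as truncating), or when
  re-translating the edited CDS places a stop codon strictly before the
  edited CDS's terminal codon. Anchoring on the terminal codon rather than
  a fixed codon index makes the rule robust to the renumbering an in-frame
  deletion causes: removing a whole codon is not a premature stop, while a
  nonsense substitution is. Insertions count as coding only strictly
  inside a coding segment. Minus-strand logic operates on the reverse
  complement. The flag is checked against an independent
  oracle — full-contig edit, boundary-adjusted CDS re-extraction,
  re-translation — for every single-base substitution and deletion over a
  60-codon CDS on both strands.
- **Splice region.** `canonical_site` if the span touches the first or
  last two intronic bases of any intron; `near_splice` within 3 exonic / 8
  intronic bases of a junction (both windows configurable — the defaults
  are this package's choice of a conventional screening window, not a
  calibrated value); insertions count their two flanking bases.
- **Domains.** Interval intersection against a BED4 catalog; insertions
  use the insertion point.
- **Frequency.** Flagged `frequency_incompatible_with_high_risk` when the
  maximum allele frequency over population sources reaches the threshold
  (default 0.01, configurable): common variants are inconsistent with a
  high-penetrance risk allele.

## Consensus

Source terms are mapped case-insensitively onto {Pathogenic, Likely
pathogenic, VUS, Likely benign, Benign} via a configurable table; unmapped
terms become `other` and do not vote. The first source in the configured
expert order with a mappable classification determines the display
(basis `expert`). Otherwise, non-expert terms decide: all equal →
`unanimous`; disagreement confined to {Benign, Likely benign} or
{Pathogenic, Likely pathogenic} → the less confident term (`majority`);
any other disagreement → `Conflicting`; no votes → `Not classified`. The
rule is order-invariant except through the expert order, and adding
non-expert tiles can never override an expert display (property-tested).
An `--expert-only` output filter mirrors the distinction between a
default expert-curated view and the full database.

## Releases and diffs

A release is an immutable directory: canonical sorted-keys JSON
(`variants.json`, the store diffs operate on), human-readable TSV, VCF
with anchors restored, the discard log, and a manifest with SHA-256
digests of inputs and outputs. Field-level diffs descend into JSON
objects; each change entry carries its path, old and new values, and an
op (`set`/`del`) so a deleted key is distinguishable from a null value —
this makes every diff replayable, and `apply_diff(old, diff(old, new))`
reconstructs `new` exactly. Floating-point values are compared as their
canonical JSON serialization, so diffs are bit-stable. Histories list the
release of first appearance and every release whose serialization changed.

## Synthetic world generator

The generator emulates one aggregation cycle's inputs: a ~12 kb contig
seeded with (AC)n and homopolymer tracts (so shifted indel aliases exist),
two three-exon transcripts on opposite strands whose CDS is written as
ATG + non-stop codons + TAA (so premature-stop truth is clean), a BED
domain catalog, three clinical tables with distinct column dialects
(expert panel, submitter archive, locus-specific database) and one
population VCF with per-allele frequencies, including a multi-allelic
site. Default conditions: 500 distinct variants, 200 equivalence aliases
(anchored / delins-padded / repeat-shifted / duplication-notation, each
verified against the whole-contig edit oracle at generation time), and 50
planted errors across five reason codes (20 ref_mismatch, 10
hgvs_unparseable, 10 unknown_reference, 5 unsupported_scheme, 5
missing_variant) over 4 sources. Consensus truth is derived from the
planted scenario (expert-classified ~30%, cross-family conflicts 10%,
remainder unanimous/within-family/population-only), not by running the
consensus code. Everything is driven by one seed and regenerates
byte-identically.

What the generator does **not** emulate: realistic gene sequence content,
submitter phenotype noise, transcript version churn, withdrawn records, or
assembly differences. Passing the planted-truth tests therefore shows that
the mechanics (parsing, validation, equivalence, provenance, consensus
algebra, versioning) are exact on well-specified input, not that the
annotation rules are clinically calibrated.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to make the checks
exhaustive rather than sampled: a 60 bp contig for the full equivalence
enumeration, a 60-codon CDS for the translation oracle, 1,000 generated
descriptions for the grammar round trip, and the 500/200/50 fixture world
for end-to-end exactness — all complete in seconds. Allele frequencies are
rounded to six decimals on VCF read (htslib stores AF as 32-bit floats);
dates with month precision normalize to the first of the month so that
versioning has a total order. There are no other tolerances: every
comparison in the pipeline is exact.

## Known limitations

- The HGVS subset excludes inversions, repeats, uncertain positions and
  allele phasing; such records are discarded with a reason, not parsed
  approximately.
- Transcript ids are unversioned; sources disagreeing only in accession
  version would be treated as unknown references.
- Equivalence is within-contig; cross-assembly liftover is out of scope.
- Records that disappear from a source are simply reported in the diff as
  removed/changed; there is no withdrawn-record special case.
- A variant spanning an exon/intron boundary with an in-frame net change
  is annotated via clamped segment reconstruction, which is conservative
  for edits that rearrange splice boundaries themselves.
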