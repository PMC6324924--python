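# varagg

Aggregation of clinical variant data from heterogeneous sources into a
single set of distinct, annotated, versioned variants.

Public variant knowledge is scattered: expert panels, submitter archives and
locus-specific databases describe variants as HGVS strings against
transcripts, population surveys ship VCFs against the genome, and the same
physical change routinely appears under several incompatible
representations — shifted indels in repeat tracts, anchored VCF alleles,
complex delins restatements, duplication notation. `varagg` is a library and
CLI for curators and pipeline engineers who need to merge such sources
defensibly: every record is checked against the reference genome, reduced to
a canonical representation, grouped with its equivalents, annotated with
transparent rule-based flags, summarized into a consensus classification
with expert precedence, and tracked across immutable, diffable releases.

## The core algorithm

Two variant records describe the same change iff applying each edit to the
full reference contig yields the same string — equivalently, iff their
*alternative allele strings* (the edited sequence over any common window
containing both spans) agree. `varagg` realizes this equivalence by
canonicalization: for a raw variant (contig, start, ref, alt),

1. trim the shared suffix, then the shared prefix, of ref and alt;
2. if the result is a pure insertion or deletion, shift it left one base at
   a time while the genome base preceding it equals the last base of the
   moving allele (left-alignment, VCF convention);
3. the resulting `contig:start:ref>alt` string is the variant's identity
   key.

Canonical-key equality provably coincides with allele-string equality (the
test suite checks this exhaustively over every 1–3 bp deletion, insertion,
duplication and delins on a repeat-rich contig), and turns merging into an
O(n) hash grouping instead of a pairwise string comparison.

Around that core sit:

- a parser/formatter for a defined HGVS subset (g. and c. substitutions,
  del, ins, delins, dup), with structured failure values for everything
  else — malformed strings are discarded with a reason code, never guessed;
- coding→genomic projection for transcript (c.) coordinates, including
  5′/3′ UTR addressing and intronic `+k`/`−k` offsets, strand-aware;
- validation against the reference: records whose claimed reference bases
  disagree with the genome are discarded (`ref_mismatch`), as are spans
  containing N, out-of-bounds coordinates and unknown reference ids;
- per-source provenance *tiles* on each merged variant, preserving every
  source's cells verbatim;
- rule-based annotation: premature-stop/frameshift detection by CDS
  re-translation, splice-region proximity windows, protein-domain overlap
  (BED), and a population-frequency screen (default threshold 0.01);
- consensus classification: expert-panel sources win outright; otherwise
  non-expert terms are combined (unanimous / within-family majority /
  conflicting / not classified);
- versioned releases: immutable directories with digests, field-level
  replayable diffs, and per-variant history.

## Worked example

Generate a small synthetic world (toy genome, two transcripts, four
sources, 50 planted distinct variants, 20 extra equivalent representations,
50 planted errors) and run one aggregation cycle:

```
$ varagg fixtures generate -o world --seed 1 --distinct 50 --aliases 20
{
 "aliases": 20,
 "distinct": 50,
 "errors_by_reason": {
  "hgvs_unparseable": 10, "missing_variant": 5, "ref_mismatch": 20,
  "unknown_reference": 10, "unsupported_scheme": 5
 },
 "records_wellformed": 142
}

$ varagg run -c world/config.yaml -o releases --date 2018-07-01
{
 "consensus_breakdown": {
  "Benign": 4, "Conflicting": 6, "Likely benign": 9,
  "Likely pathogenic": 14, "Not classified": 3, "Pathogenic": 7, "VUS": 7
 },
 "discards_by_reason": {
  "hgvs_unparseable": 10, "missing_variant": 5, "ref_mismatch": 20,
  "unknown_reference": 10, "unsupported_scheme": 5
 },
 "distinct_variants": 50,
 "equivalent_records_merged": 92,
 "records_discarded": 50,
 "records_parsed": 142,
 "records_read": {
  "clinvar-like": 65, "expertpanel": 34, "lsdb-like": 54, "popfreq": 39
 }
}
```

Reading the summary: 192 input rows were read across the four sources; the
50 planted errors were discarded with exactly their planted reason codes;
the 142 well-formed records collapsed onto 50 distinct variants (92 records
were merged into pre-existing equivalence classes — aliases plus repeat
sightings of the same variant from different sources); each distinct
variant got a consensus classification, with expert-panel assertions taking
precedence. The release directory `releases/001/` contains `merged.tsv`,
`merged.vcf` (anchor bases restored), `variants.json` (the canonical
serialization diffs operate on), `discards.tsv` and a digest manifest.

Follow-up cycles are compared with `varagg diff releases/001 releases/002`,
and a variant's trajectory is queried by canonical key or any HGVS alias:

```
$ varagg history releases "chrT:10096:C>G"
v1	2018-07-01	first appearance
```

## Input formats

- reference genome: FASTA (multi-contig, wrapped lines);
- transcripts: tab-delimited table with header
  `id  contig  strand  exons  cds_start  cds_end`, exons as comma-separated
  `start-end` pairs, all coordinates 0-based half-open;
- domains: BED4 (name column required);
- population sources: VCF 4.2 with `AF` or `AC`/`AN` INFO fields
  (multi-allelic sites are decomposed);
- clinical sources: tab- or comma-delimited tables with a header row; the
  column mapping per source (id / HGVS / classification / date) is declared
  in a JSON or YAML dialect file, not hard-coded.

Discard reason codes written to `discards.tsv`: `ref_mismatch`,
`out_of_bounds`, `ref_contains_n`, `null_variant`, `unknown_reference`,
`hgvs_unparseable`, `unsupported_scheme`, `malformed_operator`,
`missing_variant`, `projection_error`, `bad_range`, `empty_insertion`,
`bad_allele_frequency`, `superseded_duplicate`.

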