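"""Validation, canonicalization, and the allele-string equivalence oracle."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from varagg.hgvslite import RawVariant
from varagg.normalize import allele_string, canonicalize, validate_reference

from conftest import REPEAT60, contig_edit


class TestValidateReference:
    def test_matching_slice_is_ok(self, toy_genome):
        assert validate_reference(RawVariant("chrT", 1, "A", "G"), toy_genome) is None

    def test_mismatch(self, toy_genome):
        failure = validate_reference(RawVariant("chrT", 1, "C", "G"), toy_genome)
        assert failure.reason == "ref_mismatch"

    def test_span_beyond_contig(self, toy_genome):
        failure = validate_reference(RawVariant("chrT", 4, "TC", "A"), toy_genome)
        assert failure.reason == "out_of_bounds"

    def test_n_in_ref_span_rejected(self):
        from varagg.genome import ReferenceGenome

        genome = ReferenceGenome({"chrT": "AANGT"})
        failure = validate_reference(RawVariant("chrT", 1, "AN", ""), genome)
        assert failure.reason == "ref_contains_n"

    def test_unknown_contig(self, toy_genome):
        failure = validate_reference(RawVariant("chrX", 0, "A", "T"), toy_genome)
        assert failure.reason == "unknown_reference"

    def test_noop_variant_rejected(self, toy_genome):
        failure = validate_reference(RawVariant("chrT", 1, "A", "A"), toy_genome)
        assert failure.reason == "null_variant"


class TestCanonicalize:
    def test_deletion_left_aligns_through_repeat(self, repeat_genome):
        # deleting AC at offset 5 of TACACACAG slides to the tract start
        canon = canonicalize(RawVariant("chrT", 5, "AC", ""), repeat_genome)
        assert (canon.start, canon.ref, canon.alt) == (1, "AC", "")
        assert canon.key == "chrT:1:AC>"

    def test_left_alignment_preserves_the_edit(self, repeat_genome):
        seq = repeat_genome.contigs["chrT"]
        raw = RawVariant("chrT", 5, "AC", "")
        canon = canonicalize(raw, repeat_genome)
        assert contig_edit(seq, canon.start, canon.ref, canon.alt) == contig_edit(
            seq, raw.start, raw.ref, raw.alt
        )

    def test_trims_shared_prefix_and_suffix(self):
        from varagg.genome import ReferenceGenome

        genome = ReferenceGenome({"chrT": "AACGTC"})
        canon = canonicalize(RawVariant("chrT", 2, "CGT", "CAT"), genome)
        assert (canon.start, canon.ref, canon.alt) == (3, "G", "A")

    def test_leftmost_among_all_equivalents(self, repeat_genome):
        """Brute force: of all representations yielding TACACAG, canonical is leftmost."""
        seq = repeat_genome.contigs["chrT"]
        target = "TACACAG"
        equivalents = [
            RawVariant("chrT", s, seq[s : s + 2], "")
            for s in range(len(seq) - 1)
            if contig_edit(seq, s, seq[s : s + 2], "") == target
        ]
        assert len(equivalents) >= 3
        canons = {canonicalize(v, repeat_genome) for v in equivalents}
        assert len(canons) == 1
        assert canons.pop().start == min(v.start for v in equivalents)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 58), st.integers(1, 3), st.text("AC", min_size=0, max_size=3))
    def test_idempotent_and_edit_preserving(self, repeat60_genome, start, reflen, alt):
        seq = repeat60_genome.contigs["chrT"]
        ref = seq[start : start + reflen]
        raw = RawVariant("chrT", start, ref, alt)
        if validate_reference(raw, repeat60_genome) is not None:
            return
        c1 = canonicalize(raw, repeat60_genome)
        c2 = canonicalize(RawVariant(c1.contig, c1.start, c1.ref, c1.alt), repeat60_genome)
        assert c1 == c2
        assert contig_edit(seq, c1.start, c1.ref, c1.alt) == contig_edit(seq, start, ref, alt)


class TestAlleleString:
    def test_deletion_over_full_window(self, repeat_genome):
        from varagg.normalize import NormalizedVariant

        v = NormalizedVariant("chrT", 1, "AC", "")
        assert allele_string(v, repeat_genome, (0, 9)) == "TACACAG"

    def test_snv_edit_inside_window(self, repeat_genome):
        from varagg.normalize import NormalizedVariant

        v = NormalizedVariant("chrT", 4, "C", "G")
        assert allele_string(v, repeat_genome, (3, 6)) == "AGA"

    def test_window_equal_to_deleted_span_is_empty(self, repeat_genome):
        from varagg.normalize import NormalizedVariant

        v = NormalizedVariant("chrT", 1, "AC", "")
        assert allele_string(v, repeat_genome, (1, 3)) == ""

    def test_window_must_contain_span(self, repeat_genome):
        from varagg.normalize import NormalizedVariant

        with pytest.raises(ValueError):
            allele_string(NormalizedVariant("chrT", 1, "AC", ""), repeat_genome, (2, 5))

    def test_common_window_agreement_matches_key_equality(self, repeat60_genome):
        """The flanking-allele-string and canonical-key formulations coincide."""
        seq = repeat60_genome.contigs["chrT"]
        rng = random.Random(5)
        variants = []
        for _ in range(150):
            s = rng.randrange(10, 50)
            n = rng.randrange(1, 3)
            variants.append(RawVariant("chrT", s, seq[s : s + n], ""))
            variants.append(RawVariant("chrT", s, "", rng.choice(["A", "C", "AC"])))
        window = (0, len(seq))
        for v1, v2 in itertools.combinations(variants, 2):
            k1 = canonicalize(v1, repeat60_genome).key
            k2 = canonicalize(v2, repeat60_genome).key
            same_string = allele_string(v1, repeat60_genome, window) == allele_string(
                v2, repeat60_genome, window
            )
            assert (k1 == k2) == same_string, (v1, v2)


def enumerate_all_indels(seq: str, contig: str = "chrT"):
    """Every 1–3 bp deletion, duplication, insertion (over the AC alphabet)
    and delins at every position of the contig."""
    variants = []
    for n in (1, 2, 3):
        for s in range(len(seq) - n + 1):
            span = seq[s : s + n]
            variants.append(RawVariant(contig, s, span, ""))  # deletion
            variants.append(RawVariant(contig, s, span, span + span))  # duplication
            for alt in ("A", "C", "AC", "CA", "ACA"):  # delins
                if alt != span:
                    variants.append(RawVariant(contig, s, span, alt))
        for s in range(len(seq) + 1):
            for ins in map("".join, itertools.product("AC", repeat=n)):
                variants.append(RawVariant(contig, s, "", ins))
    return variants


def test_equivalence_oracle_exhaustive_on_repeat_contig(repeat60_genome):
    """Canonical-key equality ⇔ whole-contig edit equality, for every 1–3 bp
    deletion/insertion/duplication/delins at every position of a 60 bp
    repeat-rich contig."""
    seq = repeat60_genome.contigs["chrT"]
    by_edit: dict[str, set[str]] = {}
    by_key: dict[str, set[str]] = {}
    n_variants = 0
    for raw in enumerate_all_indels(seq):
        if validate_reference(raw, repeat60_genome) is not None:
            continue
        n_variants += 1
        edited = contig_edit(seq, raw.start, raw.ref, raw.alt)
        key = canonicalize(raw, repeat60_genome).key
        by_edit.setdefault(edited, set()).add(key)
        by_key.setdefault(key, set()).add(edited)
    assert n_variants > 2000
    # same edited contig ⇒ same canonical key
    assert all(len(keys) == 1 for keys in by_edit.values())
    # same canonical key ⇒ same edited contig
    assert all(len(edits) == 1 for edits in by_key.values())
    # there genuinely are thousands of equivalent pairs in this enumeration
    sizes: dict[str, int] = {}
    for edits in by_key:
        sizes[edits] = 0
    for raw in enumerate_all_indels(seq):
        if validate_reference(raw, repeat60_genome) is None:
            sizes[canonicalize(raw, repeat60_genome).key] += 1
    n_pairs = sum(n * (n - 1) // 2 for n in sizes.values())
    assert n_pairs > 1000
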