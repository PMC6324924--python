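"""HGVS subset: parsing, resolution to genomic variants, formatting."""

import dataclasses
import random

import pytest

from varagg.genome import CodingPosition, ReferenceGenome
from varagg.hgvslite import (
    ParseFailure,
    RawVariant,
    format_description,
    format_hgvs_g,
    parse_hgvs,
    resolve_to_genomic,
)
from varagg.normalize import canonicalize

from conftest import contig_edit


class TestParse:
    def test_genomic_substitution_stored_zero_based(self):
        d = parse_hgvs("chrT:g.5A>T")
        assert (d.kind, d.start, d.ref_bases, d.alt_bases) == ("substitution", 4, "A", "T")

    def test_coding_with_intron_offset(self):
        d = parse_hgvs("TX1:c.10+2T>C")
        assert d.scheme == "c"
        assert d.start == CodingPosition("cds", 10, 2)

    def test_utr_positions(self):
        assert parse_hgvs("TX1:c.-12A>G").start == CodingPosition("utr5", 12)
        assert parse_hgvs("TX1:c.*6del").start == CodingPosition("utr3", 6)

    @pytest.mark.parametrize(
        "text,kind",
        [
            ("chrT:g.3_4del", "deletion"),
            ("chrT:g.3_4delCG", "deletion"),
            ("chrT:g.3_4insAC", "insertion"),
            ("chrT:g.3_5delinsTT", "delins"),
            ("chrT:g.2_3dup", "duplication"),
            ("TX1:c.10_12del", "deletion"),
        ],
    )
    def test_supported_kinds(self, text, kind):
        assert parse_hgvs(text).kind == kind

    @pytest.mark.parametrize(
        "text,reason",
        [
            ("chrT:g.5A>>T", "malformed_operator"),
            ("P1:p.Val600Glu", "unsupported_scheme"),
            ("TX1:r.35a>u", "unsupported_scheme"),
            ("chrT:g.garbage", "hgvs_unparseable"),
            ("not an hgvs at all", "not_hgvs"),
            ("", "missing_variant"),
        ],
    )
    def test_failures_are_values_never_exceptions(self, text, reason):
        failure = parse_hgvs(text)
        assert isinstance(failure, ParseFailure)
        assert failure.reason == reason

    def test_reparse_of_formatted_description_is_equal(self):
        for text in ("chrT:g.5A>T", "TX1:c.10+2T>C", "TX1:c.-3_-1del", "chrT:g.7_8insGT"):
            d1 = parse_hgvs(text)
            d2 = parse_hgvs(format_description(d1))
            assert dataclasses.replace(d1, raw="") == dataclasses.replace(d2, raw="")


def _random_description(rng: random.Random) -> str:
    scheme = rng.choice("gc")
    ref_id = rng.choice(["chrT", "TX1", "NM_0001.2"])
    if scheme == "g":
        p1 = rng.randrange(1, 500)
        pos1 = str(p1)
        pos2 = str(p1 + rng.randrange(1, 4))
        adj = str(p1 + 1)
    else:
        region = rng.choice(["", "", "-", "*"])
        n = rng.randrange(1, 200)
        off = rng.choice([0, 0, 0, rng.randrange(1, 9), -rng.randrange(1, 9)])
        suffix = f"+{off}" if off > 0 else (str(off) if off else "")
        pos1 = f"{region}{n}{suffix}"
        pos2 = f"{region}{n + rng.randrange(1, 4)}"
        adj = f"{region}{n + 1}"
    bases = lambda k: "".join(rng.choice("ACGT") for _ in range(k))
    kind = rng.randrange(5)
    if kind == 0:
        return f"{ref_id}:{scheme}.{pos1}{bases(1)}>{bases(1)}"
    if kind == 1:
        listed = bases(2) if rng.random() < 0.3 else ""
        return f"{ref_id}:{scheme}.{pos1}_{pos2}del{listed}"
    if kind == 2:
        return f"{ref_id}:{scheme}.{pos1}_{adj}ins{bases(rng.randrange(1, 4))}"
    if kind == 3:
        return f"{ref_id}:{scheme}.{pos1}_{pos2}delins{bases(rng.randrange(1, 4))}"
    return f"{ref_id}:{scheme}.{pos1}_{pos2}dup"


def test_parse_format_parse_fixpoint_on_generated_grammar():
    rng = random.Random(42)
    for _ in range(1000):
        text = _random_description(rng)
        d1 = parse_hgvs(text)
        assert not isinstance(d1, ParseFailure), text
        d2 = parse_hgvs(format_description(d1))
        assert dataclasses.replace(d1, raw="") == dataclasses.replace(d2, raw=""), text


class TestResolve:
    def test_plain_deletion_takes_ref_from_genome(self, toy_genome):
        raw = resolve_to_genomic(parse_hgvs("chrT:g.3_4del"), toy_genome)
        assert raw == RawVariant("chrT", 2, "CG", "")

    def test_minus_strand_alleles_reverse_complemented(self, minus_tx):
        # genomic base 126 is T, so transcript c.1 reads A
        genome = ReferenceGenome({"chrT": "A" * 126 + "T" + "A" * 73})
        raw = resolve_to_genomic(
            parse_hgvs("TXM:c.1A>G"), genome, {"TXM": minus_tx}
        )
        assert raw == RawVariant("chrT", 126, "T", "C")

    def test_dup_becomes_insertion_after_span(self, toy_genome):
        raw = resolve_to_genomic(parse_hgvs("chrT:g.2_3dup"), toy_genome)
        assert raw == RawVariant("chrT", 3, "", "AC")

    def test_dup_equals_literal_duplication_by_contig_edit(self, toy_genome):
        seq = toy_genome.contigs["chrT"]
        raw = resolve_to_genomic(parse_hgvs("chrT:g.2_3dup"), toy_genome)
        as_insertion = contig_edit(seq, raw.start, raw.ref, raw.alt)
        literally = seq[:1] + "AC" + "AC" + seq[3:]
        assert as_insertion == literally

    def test_dup_with_wrong_listed_bases_flows_to_ref_mismatch(self, toy_genome):
        from varagg.normalize import validate_reference

        raw = resolve_to_genomic(parse_hgvs("chrT:g.2_3dupGG"), toy_genome)
        failure = validate_reference(raw, toy_genome)
        assert failure is not None and failure.reason == "ref_mismatch"

    def test_unknown_reference(self, toy_genome):
        failure = resolve_to_genomic(parse_hgvs("nope:g.1A>T"), toy_genome)
        assert failure.reason == "unknown_reference"
        failure = resolve_to_genomic(parse_hgvs("TXQ:c.1A>T"), toy_genome, {})
        assert failure.reason == "unknown_reference"

    def test_out_of_bounds(self, toy_genome):
        failure = resolve_to_genomic(parse_hgvs("chrT:g.9A>T"), toy_genome)
        assert failure.reason == "out_of_bounds"

    def test_coding_equals_hand_computed_genomic(self, plus_tx, minus_tx):
        """Every c. description resolves identically to its g. equivalent."""
        genome = ReferenceGenome({"chrT": ("ACGT" * 50)[:200]})
        txs = {"TXP": plus_tx, "TXM": minus_tx}
        seq = genome.contigs["chrT"]
        # plus strand: c.5 -> g.108 (1-based); minus: c.5 -> g.123 (1-based)
        cases = [
            (f"TXP:c.5{seq[107]}>A", f"chrT:g.108{seq[107]}>A"),
            ("TXP:c.2_4del", "chrT:g.105_107del"),
            # minus strand: c.1 is g.127 (1-based), so c.2_4 spans g.124_126
            ("TXM:c.2_4del", "chrT:g.124_126del"),
        ]
        for c_text, g_text in cases:
            via_c = resolve_to_genomic(parse_hgvs(c_text), genome, txs)
            via_g = resolve_to_genomic(parse_hgvs(g_text), genome, txs)
            assert not isinstance(via_c, ParseFailure), c_text
            assert canonicalize(via_c, genome) == canonicalize(via_g, genome), c_text


class TestFormat:
    @pytest.mark.parametrize(
        "variant,text",
        [
            (RawVariant("chrT", 4, "A", "T"), "chrT:g.5A>T"),
            (RawVariant("chrT", 2, "CG", ""), "chrT:g.3_4del"),
            (RawVariant("chrT", 3, "", "AC"), "chrT:g.3_4insAC"),
            (RawVariant("chrT", 1, "A", ""), "chrT:g.2del"),
        ],
    )
    def test_examples(self, toy_genome, variant, text):
        assert format_hgvs_g(variant, toy_genome) == text

    def test_formatted_string_resolves_back_to_same_canonical(self, repeat60_genome):
        """format -> parse -> resolve -> canonicalize is the identity on canonicals."""
        seq = repeat60_genome.contigs["chrT"]
        rng = random.Random(9)
        for _ in range(300):
            s = rng.randrange(1, 55)
            kind = rng.randrange(4)
            if kind == 0:
                raw = RawVariant("chrT", s, seq[s], rng.choice([b for b in "ACGT" if b != seq[s]]))
            elif kind == 1:
                raw = RawVariant("chrT", s, seq[s : s + rng.randrange(1, 4)], "")
            elif kind == 2:
                raw = RawVariant("chrT", s, "", "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 3))))
            else:
                ref = seq[s : s + 2]
                alt = rng.choice([x for x in ("TT", "GA", "A", "CCC") if x != ref and x[0] != ref[0] and x[-1] != ref[-1]])
                raw = RawVariant("chrT", s, ref, alt)
            canon = canonicalize(raw, repeat60_genome)
            text = format_hgvs_g(canon, repeat60_genome)
            back = resolve_to_genomic(parse_hgvs(text), repeat60_genome)
            assert canonicalize(back, repeat60_genome) == canon, text
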