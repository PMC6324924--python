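"""Release persistence, diffing, replay, and history."""

import json
import random

import pytest

from varagg.genome import ReferenceGenome
from varagg.release import (
    Release,
    apply_diff,
    canonical_json,
    diff_releases,
    read_release,
    swap_symmetry_check,
    variant_history,
    write_release,
)


def make_variant(key, contig="chrT", start=1, ref="A", alt="G", consensus="VUS", cls=None):
    return {
        "key": key,
        "contig": contig,
        "start": start,
        "ref": ref,
        "alt": alt,
        "hgvs_g": f"{contig}:g.{start + 1}{ref}>{alt}",
        "names": [f"{contig}:g.{start + 1}{ref}>{alt}"],
        "tiles": {
            "src1": {
                "source": "src1",
                "record_ids": [f"r-{key}"],
                "classification": cls,
                "date": "2018-01-01",
                "internal_conflict": False,
                "fields": {},
            }
        },
        "annotations": {"premature_stop": False, "max_af": None},
        "consensus": {"display": consensus, "basis": "unanimous"},
    }


def make_release(version, keys, date="2018-07-01", **overrides):
    variants = {}
    for k in keys:
        # key-derived position so the same key is identical across releases
        start = 1 + sum(map(ord, k)) % 40
        v = make_variant(k, start=start, ref="A", alt="G")
        v.update(overrides.get(k, {}))
        variants[k] = v
    return Release(version=version, date=date, variants=variants, discard_log=[], provenance={})


@pytest.fixture()
def genome():
    return ReferenceGenome({"chrT": "TACACACAGTTTAAACCGG"})


class TestRoundTrip:
    def test_write_then_read_is_digest_stable(self, tmp_path, genome):
        rel = make_release(1, ["k1", "k2", "k3"])
        out = write_release(rel, tmp_path, genome)
        back = read_release(out)
        assert back.digest == rel.digest
        assert back.variants == rel.variants

    def test_releases_are_immutable_on_disk(self, tmp_path, genome):
        rel = make_release(1, ["k1"])
        write_release(rel, tmp_path, genome)
        with pytest.raises(FileExistsError):
            write_release(rel, tmp_path, genome)

    def test_tampering_detected_by_digest(self, tmp_path, genome):
        out = write_release(make_release(1, ["k1"]), tmp_path, genome)
        text = (out / "variants.json").read_text()
        (out / "variants.json").write_text(text.replace("VUS", "Benign"))
        with pytest.raises(ValueError, match="digest"):
            read_release(out)

    def test_written_vcf_parses_with_htslib(self, tmp_path, genome):
        import pysam

        rel = Release(
            1, "2018-07-01",
            {
                "chrT:1:AC>": {**make_variant("chrT:1:AC>"), "start": 1, "ref": "AC", "alt": ""},
                "chrT:3:A>G": {**make_variant("chrT:3:A>G"), "start": 3, "ref": "A", "alt": "G"},
            },
            [], {},
        )
        out = write_release(rel, tmp_path, genome)
        rows = list(pysam.VariantFile(str(out / "merged.vcf")))
        assert len(rows) == 2
        # anchored indel: 1-based POS 1, REF "TAC" -> ALT "T"
        assert (rows[0].pos, rows[0].ref, rows[0].alts) == (1, "TAC", ("T",))


class TestDiff:
    def test_added_and_removed(self):
        old = make_release(1, ["k1"])
        new = make_release(2, ["k1", "k2"])
        report = diff_releases(old, new)
        assert sorted(report.added) == ["k2"]
        assert report.removed == [] and report.changed == {}

    def test_self_diff_is_empty(self):
        a = make_release(1, ["k1", "k2"])
        b = make_release(2, ["k1", "k2"])
        assert diff_releases(a, b).is_empty()

    def test_tile_classification_change_reported_field_level(self):
        old = make_release(1, ["k1"])
        new = make_release(2, ["k1"])
        new.variants["k1"]["tiles"]["src1"]["classification"] = "Benign"
        report = diff_releases(old, new)
        (change,) = report.changed["k1"]
        assert change["path"] == ["tiles", "src1", "classification"]
        assert (change["old"], change["new"]) == (None, "Benign")
        assert report.source_changes["k1"]["src1"]["new"] == "Benign"

    def test_added_removed_changed_disjoint(self):
        old = make_release(1, ["k1", "k2", "k3"])
        new = make_release(2, ["k2", "k3", "k4"])
        new.variants["k3"]["consensus"]["display"] = "Benign"
        report = diff_releases(old, new)
        groups = [set(report.added), set(report.removed), set(report.changed)]
        assert groups == [{"k4"}, {"k1"}, {"k3"}]

    def test_version_order_enforced(self):
        with pytest.raises(ValueError):
            diff_releases(make_release(2, []), make_release(1, []))


class TestReplayAndSymmetry:
    def _random_release_pair(self, rng):
        keys = [f"k{i}" for i in range(rng.randrange(2, 10))]
        old = make_release(1, keys)
        new_keys = [k for k in keys if rng.random() > 0.3] + [
            f"n{i}" for i in range(rng.randrange(0, 3))
        ]
        new = make_release(2, new_keys)
        for k in new_keys:
            if k in old.variants and rng.random() < 0.5:
                new.variants[k]["consensus"]["display"] = rng.choice(["Benign", "VUS", "Pathogenic"])
            if k in old.variants and rng.random() < 0.2:
                new.variants[k]["tiles"]["src2"] = {
                    "source": "src2", "record_ids": ["x"], "classification": "VUS",
                    "date": None, "internal_conflict": False, "fields": {},
                }
        return old, new

    def test_replaying_a_diff_reconstructs_new_exactly(self):
        rng = random.Random(13)
        for _ in range(50):
            old, new = self._random_release_pair(rng)
            report = diff_releases(old, new)
            assert canonical_json(apply_diff(old, report)) == canonical_json(new.variants)

    def test_swap_symmetry_on_randomized_pairs(self):
        rng = random.Random(14)
        for _ in range(50):
            old, new = self._random_release_pair(rng)
            assert swap_symmetry_check(old, new)

    def test_swap_symmetry_on_identical_releases(self):
        assert swap_symmetry_check(make_release(1, ["k1"]), make_release(2, ["k1"]))


class TestHistory:
    def test_unchanged_variant_has_single_first_seen_entry(self):
        rels = [make_release(v, ["k1"]) for v in (1, 2, 3)]
        entries = variant_history(rels, "k1")
        assert len(entries) == 1 and entries[0]["summary"] == "first appearance"

    def test_change_recorded_at_its_release(self):
        rels = [make_release(v, ["k1"]) for v in (1, 2, 3)]
        rels[1].variants["k1"]["consensus"]["display"] = "Benign"
        rels[2].variants["k1"]["consensus"]["display"] = "Benign"
        entries = variant_history(rels, "k1")
        # first seen at v1, changed at v2, unchanged at v3 -> no v3 entry
        assert [e["version"] for e in entries] == [1, 2]
        assert "consensus.display" in entries[1]["summary"]

    def test_unknown_key_gives_empty_history(self):
        assert variant_history([make_release(1, ["k1"])], "nope") == []
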