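"""Versioned releases: persistence, diffing, and per-variant history.

A release is an immutable dated snapshot written as a directory:

    releases/NNN/
      variants.json   canonical serialization (sorted keys) — the store that
                      round-trips bit-exactly and that diffs operate on
      merged.tsv      one row per merged variant, tiles/annotations as JSON cells
      merged.vcf      canonical variants with anchor bases restored
      discards.tsv    record_id, source, reason
      manifest.json   version, date, input digests, output digests

Diffs are computed on the canonical JSON serialization, so a diff report is
replayable: applying it to the old release reconstructs the new one exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .genome import ReferenceGenome

__all__ = [
    "Release",
    "DiffReport",
    "canonical_json",
    "write_release",
    "read_release",
    "diff_releases",
    "apply_diff",
    "variant_history",
    "swap_symmetry_check",
]


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=True)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class Release:
    version: int
    date: str
    variants: dict[str, dict]  # key -> serialized MergedVariant
    discard_log: list[dict] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)  # input name -> sha256

    @property
    def digest(self) -> str:
        return _sha256(
            canonical_json(
                {
                    "version": self.version,
                    "date": self.date,
                    "variants": self.variants,
                    "discard_log": self.discard_log,
                    "provenance": self.provenance,
                }
            )
        )


@dataclass
class DiffReport:
    old_version: int
    new_version: int
    added: dict[str, dict]  # key -> full new payload (makes the diff replayable)
    removed: list[str]
    changed: dict[str, list[dict]]  # key -> [{path: [..], old, new}]
    source_changes: dict[str, dict[str, dict]]  # key -> source -> {old, new, old_date, new_date}

    def is_empty(self) -> bool:
        return not (self.added or self.removed or self.changed)

    def to_json(self) -> dict:
        return {
            "old_version": self.old_version,
            "new_version": self.new_version,
            "added": self.added,
            "removed": sorted(self.removed),
            "changed": self.changed,
            "source_changes": self.source_changes,
        }

    def to_text(self) -> str:
        lines = [f"release {self.old_version} -> {self.new_version}"]
        lines.append(f"added: {len(self.added)}  removed: {len(self.removed)}  changed: {len(self.changed)}")
        for key in sorted(self.added):
            lines.append(f"+ {key}")
        for key in sorted(self.removed):
            lines.append(f"- {key}")
        for key in sorted(self.changed):
            for ch in self.changed[key]:
                path = ".".join(str(p) for p in ch["path"])
                lines.append(f"~ {key} {path}: {ch['old']!r} -> {ch['new']!r}")
        return "\n".join(lines) + "\n"


def _dict_diff(old, new, path: tuple = ()) -> list[dict]:
    """Recursive field-level diff; descends into dicts, leaves are compared whole.

    Entries carry op "set" or "del" so a deleted key is distinguishable from
    a value set to null, making the diff replayable.
    """
    changes: list[dict] = []
    if isinstance(old, dict) and isinstance(new, dict):
        for k in sorted(set(old) | set(new)):
            if k not in new:
                changes.append({"path": list(path) + [k], "old": old[k], "new": None, "op": "del"})
            elif k not in old:
                changes.append({"path": list(path) + [k], "old": None, "new": new[k], "op": "set"})
            else:
                changes.extend(_dict_diff(old[k], new[k], path + (k,)))
    elif old != new:
        changes.append({"path": list(path), "old": old, "new": new, "op": "set"})
    return changes


def diff_releases(old: Release, new: Release) -> DiffReport:
    """added / removed / field-level changed between two releases."""
    if old.version >= new.version:
        raise ValueError(f"old.version {old.version} must be < new.version {new.version}")
    old_keys, new_keys = set(old.variants), set(new.variants)
    added = {k: new.variants[k] for k in sorted(new_keys - old_keys)}
    removed = sorted(old_keys - new_keys)
    changed: dict[str, list[dict]] = {}
    source_changes: dict[str, dict[str, dict]] = {}
    for k in sorted(old_keys & new_keys):
        delta = _dict_diff(old.variants[k], new.variants[k])
        if delta:
            changed[k] = delta
        ot, nt = old.variants[k].get("tiles", {}), new.variants[k].get("tiles", {})
        per_source = {}
        for src in sorted(set(ot) | set(nt)):
            oc = ot.get(src, {}).get("classification")
            nc = nt.get(src, {}).get("classification")
            if oc != nc:
                per_source[src] = {
                    "old": oc,
                    "new": nc,
                    "old_date": ot.get(src, {}).get("date"),
                    "new_date": nt.get(src, {}).get("date"),
                }
        if per_source:
            source_changes[k] = per_source
    return DiffReport(old.version, new.version, added, removed, changed, source_changes)


def _apply_changes(doc, changes: list[dict]):
    for ch in changes:
        node = doc
        *parents, leaf = ch["path"]
        for p in parents:
            node = node.setdefault(p, {})
        if ch["op"] == "del":
            node.pop(leaf, None)
        else:
            node[leaf] = ch["new"]
    return doc


def apply_diff(old: Release, report: DiffReport) -> dict[str, dict]:
    """Replay a diff on the old release's variants; returns the new variant map."""
    variants = json.loads(canonical_json(old.variants))  # deep copy
    for k in report.removed:
        variants.pop(k, None)
    for k, payload in report.added.items():
        variants[k] = json.loads(canonical_json(payload))
    for k, changes in report.changed.items():
        _apply_changes(variants[k], changes)
    return variants


def variant_history(releases: list[Release], key: str) -> list[dict]:
    """(version, date, summary) for each release where the variant appeared or changed."""
    history: list[dict] = []
    prev: Optional[dict] = None
    for rel in sorted(releases, key=lambda r: r.version):
        cur = rel.variants.get(key)
        if cur is None:
            prev = None
            continue
        if prev is None:
            history.append({"version": rel.version, "date": rel.date, "summary": "first appearance"})
        else:
            delta = _dict_diff(prev, cur)
            if delta:
                paths = ", ".join(".".join(map(str, ch["path"])) for ch in delta)
                history.append({"version": rel.version, "date": rel.date, "summary": f"changed: {paths}"})
        prev = cur
    return history


def swap_symmetry_check(old: Release, new: Release) -> bool:
    """diff(new, old) mirrors diff(old, new): added and removed swap."""
    fwd = diff_releases(old, new)
    rev = diff_releases(
        Release(0, new.date, new.variants, new.discard_log, new.provenance),
        Release(1, old.date, old.variants, old.discard_log, old.provenance),
    )
    return sorted(fwd.added) == sorted(rev.removed) and sorted(fwd.removed) == sorted(rev.added)


# ---------------------------------------------------------------------------
# on-disk layout

def _merged_tsv(variants: dict[str, dict]) -> str:
    cols = ["key", "contig", "start", "ref", "alt", "hgvs_g", "consensus_display",
            "consensus_basis", "names", "tiles", "annotations"]
    lines = ["\t".join(cols)]
    for key in sorted(variants, key=lambda k: _sort_key(variants[k])):
        v = variants[key]
        cons = v.get("consensus") or {}
        lines.append("\t".join([
            v["key"], v["contig"], str(v["start"]), v["ref"], v["alt"], v["hgvs_g"],
            cons.get("display", ""), cons.get("basis", ""),
            "|".join(v["names"]),
            canonical_json(v["tiles"]),
            canonical_json(v.get("annotations")),
        ]))
    return "\n".join(lines) + "\n"


def _sort_key(v: dict):
    return (v["contig"], v["start"], v["ref"], v["alt"])


def _merged_vcf(variants: dict[str, dict], genome: ReferenceGenome, date: str) -> str:
    """Write canonical variants as VCF 4.2 text, restoring anchor bases for indels."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##fileDate={date.replace('-', '')}",
        '##INFO=<ID=SOURCES,Number=.,Type=String,Description="Contributing sources">',
        '##INFO=<ID=CONSENSUS,Number=1,Type=String,Description="Consensus classification">',
    ]
    lines += [f"##contig=<ID={c},length={len(s)}>" for c, s in sorted(genome.contigs.items())]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for key in sorted(variants, key=lambda k: _sort_key(variants[k])):
        v = variants[key]
        contig, start, ref, alt = v["contig"], v["start"], v["ref"], v["alt"]
        if not ref or not alt:  # re-anchor indels on the preceding base
            if start == 0:
                anchor = genome.contigs[contig][len(ref)] if ref else genome.contigs[contig][0]
                pos, vref, valt = 1, ref + anchor, alt + anchor
            else:
                anchor = genome.contigs[contig][start - 1]
                pos, vref, valt = start, anchor + ref, anchor + alt
        else:
            pos, vref, valt = start + 1, ref, alt
        cons = (v.get("consensus") or {}).get("display", ".") or "."
        sources = ",".join(sorted(v["tiles"])) or "."
        info = f"SOURCES={sources};CONSENSUS={cons.replace(' ', '_')}"
        lines.append(f"{contig}\t{pos}\t{key}\t{vref}\t{valt}\t.\t.\t{info}")
    return "\n".join(lines) + "\n"


def _discards_tsv(discard_log: list[dict]) -> str:
    lines = ["record_id\tsource\treason"]
    for entry in sorted(discard_log, key=lambda e: (e["source"], e["record_id"])):
        lines.append(f"{entry['record_id']}\t{entry['source']}\t{entry['reason']}")
    return "\n".join(lines) + "\n"


def release_dir(root: Union[str, Path], version: int) -> Path:
    return Path(root) / f"{version:03d}"


def write_release(release: Release, root: Union[str, Path], genome: ReferenceGenome) -> Path:
    """Persist a release directory; refuses to overwrite (releases are immutable)."""
    out = release_dir(root, release.version)
    if out.exists():
        raise FileExistsError(f"release {release.version} already written at {out}")
    out.mkdir(parents=True)
    variants_json = canonical_json(release.variants)
    tsv = _merged_tsv(release.variants)
    vcf = _merged_vcf(release.variants, genome, release.date)
    discards = _discards_tsv(release.discard_log)
    (out / "variants.json").write_text(variants_json)
    (out / "merged.tsv").write_text(tsv)
    (out / "merged.vcf").write_text(vcf)
    (out / "discards.tsv").write_text(discards)
    manifest = {
        "version": release.version,
        "date": release.date,
        "inputs": release.provenance,
        "discard_log": release.discard_log,
        "outputs": {
            "variants.json": _sha256(variants_json),
            "merged.tsv": _sha256(tsv),
            "merged.vcf": _sha256(vcf),
            "discards.tsv": _sha256(discards),
        },
        "counts": {"variants": len(release.variants), "discards": len(release.discard_log)},
    }
    (out / "manifest.json").write_text(canonical_json(manifest))
    return out


def read_release(path: Union[str, Path]) -> Release:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    variants_text = (path / "variants.json").read_text()
    if _sha256(variants_text) != manifest["outputs"]["variants.json"]:
        raise ValueError(f"digest mismatch for {path / 'variants.json'}")
    return Release(
        version=manifest["version"],
        date=manifest["date"],
        variants=json.loads(variants_text),
        discard_log=manifest["discard_log"],
        provenance=manifest["inputs"],
    )


def read_all_releases(root: Union[str, Path]) -> list[Release]:
    root = Path(root)
    rels = [read_release(p) for p in sorted(root.iterdir()) if (p / "manifest.json").exists()]
    return sorted(rels, key=lambda r: r.version)
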