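"""Classification mapping and consensus derivation.

Each source reports clinical significance in its own words; a configurable
case-insensitive table maps verbatim terms onto the controlled five-term
vocabulary. The displayed consensus gives precedence to expert-panel
sources; absent an expert assertion, non-expert submissions agree
(unanimous), agree up to confidence within one direction
(Benign/Likely benign or Pathogenic/Likely pathogenic → the less confident
term), or conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ConsensusResult",
    "DEFAULT_CLASSIFICATION_MAP",
    "map_classification",
    "derive_consensus",
]

TERMS = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")

DEFAULT_CLASSIFICATION_MAP: dict[str, str] = {
    "pathogenic": "Pathogenic",
    "likely pathogenic": "Likely pathogenic",
    "likely_pathogenic": "Likely pathogenic",
    "probably pathogenic": "Likely pathogenic",
    "vus": "VUS",
    "uncertain significance": "VUS",
    "uncertain_significance": "VUS",
    "variant of uncertain significance": "VUS",
    "unclassified": "VUS",
    "likely benign": "Likely benign",
    "likely_benign": "Likely benign",
    "probably not pathogenic": "Likely benign",
    "benign": "Benign",
    "not pathogenic": "Benign",
}


@dataclass
class ConsensusResult:
    display: str  # five terms | Conflicting | Not classified
    basis: str  # expert | unanimous | majority | conflict | none
    expert_source: Optional[str] = None
    contributing: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "display": self.display,
            "basis": self.basis,
            "expert_source": self.expert_source,
            "contributing": dict(sorted(self.contributing.items())),
        }


def map_classification(
    raw: Optional[str], table: Optional[dict[str, str]] = None
) -> str:
    """Map a verbatim source term to the controlled vocabulary; unmapped -> 'other'."""
    if raw is None or not raw.strip():
        return "other"
    table = table if table is not None else DEFAULT_CLASSIFICATION_MAP
    return table.get(raw.strip().lower(), "other")


def derive_consensus(
    tiles,
    expert_sources: list[str],
    table: Optional[dict[str, str]] = None,
) -> ConsensusResult:
    """One displayed classification per merged variant.

    `tiles` is any iterable with .source and .classification. Precedence:
    the first source in `expert_sources` carrying a mappable classification
    wins outright. Otherwise non-expert mapped terms (ignoring 'other' and
    absent) decide: all equal → unanimous; within {Benign, Likely benign}
    or {Pathogenic, Likely pathogenic} → the less confident term, basis
    majority; anything else → Conflicting; none at all → Not classified.
    """
    by_source = {t.source: map_classification(t.classification, table) for t in tiles}
    contributing = {s: c for s, c in by_source.items() if c != "other"}
    for expert in expert_sources:
        if contributing.get(expert):
            return ConsensusResult(
                display=contributing[expert],
                basis="expert",
                expert_source=expert,
                contributing=contributing,
            )
    terms = sorted(
        {c for s, c in contributing.items() if s not in expert_sources}
    )
    if not terms:
        return ConsensusResult("Not classified", "none", contributing=contributing)
    if len(terms) == 1:
        return ConsensusResult(terms[0], "unanimous", contributing=contributing)
    if set(terms) <= {"Benign", "Likely benign"}:
        return ConsensusResult("Likely benign", "majority", contributing=contributing)
    if set(terms) <= {"Pathogenic", "Likely pathogenic"}:
        return ConsensusResult("Likely pathogenic", "majority", contributing=contributing)
    return ConsensusResult("Conflicting", "conflict", contributing=contributing)
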