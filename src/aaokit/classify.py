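"""Kingdom-specific active-site typing of AAO candidates.

Each kingdom's rules read the residues at two anchored active-site positions:
position *a* (the PeAAO Y92-equivalent, primary classifier) and position *b*
(the PeAAO F501-equivalent, recorded as a consistency check only — the
per-type distributions reported at *b* describe tendencies, not a second
independent rule).

Fungal (PeAAO 92/501): type I keeps an aromatic residue at *a* (all
characterised Basidiomycota AAOs), type II shows aliphatic/uncharged-polar
residues, type III (Ascomycota, MtAAO) a conserved glycine.  Types I and II
expect an aromatic at *b*; type III has lost aromaticity there.

Bacterial (ShAAO 92/455): type I has Ala/Gly at *a* with Tyr at *b*; type II
Phe at *a* (Tyr admitted for the Geminicoccaceae exception) with Phe at *b*;
type III an aliphatic at *a* with Tyr or Phe at *b*.  ShAAO itself is type
II, SdAAO type III.

Arthropod (CpAAO 128/535): a single type with an aromatic at *a* and
predominantly Tyr (occasionally a positively charged residue) at *b*.
"""

from __future__ import annotations

from dataclasses import dataclass

from aaokit.alignment import PositionMap
from aaokit.records import ProteinRecord
from aaokit.references import (
    ALA_GLY,
    ALIPHATIC,
    AROMATIC,
    KINGDOM_ANCHORS,
    POSITIVE,
    UNCHARGED_POLAR,
)

LABELS = ("I", "II", "III", "arthropod", "ambiguous", "unclassified")


@dataclass(frozen=True)
class TypeCall:
    seq_id: str
    kingdom: str
    label: str
    residue_a: str | None
    residue_b: str | None
    rule_id: str
    consistency_flag: bool | None


def _unmapped(residue: str | None) -> bool:
    return residue is None or residue == "UNMAPPED"


def classify_fungal(residue_a: str | None, residue_b: str | None):
    """PeAAO-anchored rules; returns (label, consistency, rule_id)."""
    if _unmapped(residue_a) or _unmapped(residue_b):
        return "unclassified", None, "fungal_unmapped"
    if residue_a in AROMATIC:
        return "I", residue_b in AROMATIC, "fungal_I_aromatic_a"
    if residue_a == "G":
        return "III", residue_b not in AROMATIC, "fungal_III_glycine_a"
    if residue_a in (ALIPHATIC | UNCHARGED_POLAR):
        return "II", residue_b in AROMATIC, "fungal_II_aliphatic_polar_a"
    return "ambiguous", None, "fungal_fallback"


def classify_bacterial(residue_a: str | None, residue_b: str | None):
    """ShAAO-anchored rules; ordered so Ala/Gly claim type I before the
    aliphatic class is tested."""
    if _unmapped(residue_a) or _unmapped(residue_b):
        return "unclassified", None, "bacterial_unmapped"
    if residue_a in ALA_GLY:
        return "I", residue_b == "Y", "bacterial_I_ala_gly_a"
    if residue_a in ("F", "Y"):  # Y admits the Geminicoccaceae exception
        return "II", residue_b == "F", "bacterial_II_phe_a"
    if residue_a in ("V", "L", "I", "M"):
        return "III", residue_b in ("Y", "F"), "bacterial_III_aliphatic_a"
    return "ambiguous", None, "bacterial_fallback"


def classify_arthropod(residue_a: str | None, residue_b: str | None):
    """CpAAO-anchored rule: one structural type, aromatic at *a* required."""
    if _unmapped(residue_a) or _unmapped(residue_b):
        return "unclassified", None, "arthropod_unmapped"
    if residue_a in AROMATIC:
        consistent = residue_b == "Y" or residue_b in POSITIVE
        return "arthropod", consistent, "arthropod_aromatic_a"
    return "ambiguous", None, "arthropod_fallback"


_DISPATCH = {
    "fungi": classify_fungal,
    "bacteria": classify_bacterial,
    "arthropod": classify_arthropod,
}


def classify(
    record: ProteinRecord,
    kingdom: str,
    position_map: PositionMap,
    anchor=None,
) -> TypeCall:
    """Dispatch to the kingdom rule using anchored typing-position residues.

    *anchor* defaults to the published kingdom anchor; pass the anchor the
    position map was built against when using other references.
    """
    if kingdom not in _DISPATCH:
        raise ValueError(f"unknown kingdom {kingdom!r}")
    if anchor is None:
        anchor = KINGDOM_ANCHORS[kingdom]
    pos_a, pos_b = anchor.typing_positions
    res_a = position_map.residue(pos_a)
    res_b = position_map.residue(pos_b)
    label, consistency, rule_id = _DISPATCH[kingdom](res_a, res_b)
    return TypeCall(record.id, kingdom, label, res_a, res_b, rule_id, consistency)


def write_type_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tkingdom\tlabel\tresidue_a\tresidue_b\trule_id\tconsistency_flag\n")
        for c in calls:
            fh.write(
                f"{c.seq_id}\t{c.kingdom}\t{c.label}\t{c.residue_a or 'UNMAPPED'}\t"
                f"{c.residue_b or 'UNMAPPED'}\t{c.rule_id}\t{c.consistency_flag}\n"
            )


def type_counts(calls) -> dict[str, dict[str, int]]:
    """Per-kingdom counts of each type label."""
    out: dict[str, dict[str, int]] = {}
    for c in calls:
        out.setdefault(c.kingdom, {}).setdefault(c.label, 0)
        out[c.kingdom][c.label] += 1
    return out
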