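"""Reference anchors, residue classes and the conserved GMC-family signatures.

Active-site typing is *reference anchored*: a query residue is classified by
locating the query position equivalent (via global alignment) to a numbered
residue in a well-characterised reference enzyme — PeAAO (Pleurotus eryngii)
for fungi, ShAAO (bacterial) for bacteria, CpAAO (Chrysomela populi) for
arthropods.  All residue numbers are 1-based on the reference sequence as
supplied; no signal-peptide arithmetic is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

# PROSITE-style signatures shared by GMC oxidoreductases.
# ADP_MOTIF is the Rossmann beta-alpha-beta fingerprint cradling the FAD's
# ADP moiety; PS00623 sits in the N-terminal region, PS00624 in the central
# portion of the enzyme.
ADP_MOTIF = "G-x-G-x(2)-G-x(18)-E"
PS00623 = (
    "[GA]-[RKNC]-x-[LIVW]-G(2)-[GST](2)-x-[LIVM]-[NH]-x(3)-[FYWA]-x(2)-"
    "[PAG]-x(5)-[DNESHQA]"
)
PS00624 = "[GS]-[PSTA]-x(2)-[ST]-[PS]-x-[LIVM](2)-x(2)-S-G-[LIVM]-G"

#: pattern-id -> signature text, in screening order
SIGNATURES = {"adp": ADP_MOTIF, "ps00623": PS00623, "ps00624": PS00624}

# Residue classes used by the typing rules.  "Aliphatic" excludes glycine,
# which anchors fungal type III on its own; "uncharged polar" excludes
# glycine and aromatics.
AROMATIC = frozenset("FWY")
GLY = frozenset("G")
ALA_GLY = frozenset("AG")
ALIPHATIC = frozenset("AVLIM")
UNCHARGED_POLAR = frozenset("STNQC")
POSITIVE = frozenset("KRH")


@dataclass(frozen=True)
class ReferenceAnchor:
    """Numbered active-site positions on a reference enzyme.

    ``typing_positions`` are the two substrate-stacking positions that define
    the kingdom types (e.g. PeAAO Y92/F501); ``catalytic_positions`` are the
    two conserved catalytic histidines (e.g. PeAAO H502/H546).  1-based.
    """

    reference_id: str
    typing_positions: tuple[int, int]
    catalytic_positions: tuple[int, int]

    def __post_init__(self) -> None:
        positions = (*self.typing_positions, *self.catalytic_positions)
        if len(set(positions)) != 4:
            raise ValueError("anchor positions must be distinct")
        if any(p < 1 for p in positions):
            raise ValueError("anchor positions are 1-based and must be >= 1")

    @property
    def all_positions(self) -> tuple[int, int, int, int]:
        return (*self.typing_positions, *self.catalytic_positions)


# Published anchor numbering.  The CpAAO catalytic histidines are not
# individually numbered in the arthropod literature used here; positions
# adjacent to the second typing position (b+1) and 45 residues downstream
# (b+45) are adopted by analogy with PeAAO (501 -> 502/546) and ShAAO
# (455 -> 456/500).
PEAAO_ANCHOR = ReferenceAnchor("PeAAO", typing_positions=(92, 501), catalytic_positions=(502, 546))
SHAAO_ANCHOR = ReferenceAnchor("ShAAO", typing_positions=(92, 455), catalytic_positions=(456, 500))
CPAAO_ANCHOR = ReferenceAnchor("CpAAO", typing_positions=(128, 535), catalytic_positions=(536, 580))

#: kingdom -> anchor routing
KINGDOM_ANCHORS = {
    "fungi": PEAAO_ANCHOR,
    "bacteria": SHAAO_ANCHOR,
    "arthropod": CPAAO_ANCHOR,
}

KINGDOMS = tuple(KINGDOM_ANCHORS)
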