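"""Synthetic GMC-like protein families with known ground truth.

The generator emulates the sequence population the screening pipeline is
designed for: families of ~450–650-residue GMC-superfamily proteins carrying
(i) the ADP-binding motif near the N-terminus, (ii) a PS00623 instance in the
N-terminal region, (iii) a PS00624 instance in the central portion, (iv) two
catalytic histidines at reference-equivalent positions and (v) type-defining
residues at the two typing positions — plus decoys ablating exactly one of
those features.

Sequences are generated hierarchically: a kingdom ancestor (which doubles as
the kingdom's reference/anchor sequence), per-type ancestors diverged from it
at ``type_divergence``, and family members diverged from their type ancestor
at ``mutation_rate``.  All planted features, typing positions and catalytic
positions are protected from mutation so ground-truth labels survive any
mutation rate.  At the default sequence lengths the anchor positions coincide
with the published reference numbering (PeAAO 92/501/502/546, ShAAO
92/455/456/500, CpAAO 128/535); at other lengths they are scaled
proportionally.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from aaokit import motifs
from aaokit.phylo import DistanceMatrix
from aaokit.records import AMINO_ACIDS, ProteinRecord
from aaokit.references import (
    ALIPHATIC,
    AROMATIC,
    KINGDOMS,
    POSITIVE,
    SIGNATURES,
    UNCHARGED_POLAR,
    ReferenceAnchor,
)

FEATURES = ("adp", "ps00623", "ps00624", "catalytic_his")

#: parsed signature patterns, keyed as in SIGNATURES
PATTERNS = {pid: motifs.parse_prosite(text, pid) for pid, text in SIGNATURES.items()}

# Per-type allowed residues at the two typing positions (position a is the
# Y92-equivalent primary classifier, position b the F501-equivalent).
TYPE_RESIDUES: dict[str, dict[str, tuple[str, str]]] = {
    "fungi": {
        "I": ("".join(sorted(AROMATIC)), "".join(sorted(AROMATIC))),
        "II": (
            "".join(sorted(ALIPHATIC | UNCHARGED_POLAR)),
            "".join(sorted(AROMATIC)),
        ),
        "III": ("G", "".join(sorted(ALIPHATIC | UNCHARGED_POLAR))),
    },
    "bacteria": {
        "I": ("AG", "Y"),
        "II": ("FY", "F"),
        "III": ("VLIM", "YF"),
    },
    "arthropod": {
        "arthropod": ("".join(sorted(AROMATIC)), "Y" + "".join(sorted(POSITIVE))),
    },
}

#: residues planted at the typing positions of each kingdom ancestor
_REF_TYPING = {"fungi": ("Y", "F"), "bacteria": ("F", "F"), "arthropod": ("Y", "Y")}

# Anchor/feature geometry at the base lengths (fungi & bacteria 560,
# arthropod 600); scaled proportionally for other lengths.
_BASE = {
    "fungi": dict(length=560, a=92, b=501, c2=546, ps623=100, ps624=300),
    "bacteria": dict(length=560, a=92, b=455, c2=500, ps623=100, ps624=300),
    "arthropod": dict(length=600, a=128, b=535, c2=580, ps623=160, ps624=300),
}
_ADP_START = 5  # 0-based; well inside the first 60 residues


def _constrained_offsets(pattern: motifs.PrositePattern) -> list[int]:
    """Offsets within a planted instance whose residues are constrained by
    the signature (non-wildcard elements); assumes a fixed-span pattern."""
    if pattern.min_span != pattern.max_span:
        raise ValueError("planted patterns must have a fixed span")
    offsets = []
    pos = 0
    for e in pattern.elements:
        for _ in range(e.min_repeat):
            if e.allowed is not motifs.ANY:
                offsets.append(pos)
            pos += 1
    return offsets


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the study conditions every stage is
    tested under."""

    n_per_type: int = 45
    seq_length: int = 560
    mutation_rate: float = 0.05
    type_divergence: float = 0.25
    seed: int = 0
    kingdoms: tuple[str, ...] = KINGDOMS
    background_freqs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_per_type < 0:
            raise ValueError("n_per_type must be >= 0")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 <= self.type_divergence < 1:
            raise ValueError("type_divergence must be in [0, 1)")
        if self.seq_length < 200:
            raise ValueError("seq_length must be >= 200 to fit all planted features")
        unknown = set(self.kingdoms) - set(KINGDOMS)
        if unknown:
            raise ValueError(f"unknown kingdoms: {sorted(unknown)}")
        if self.background_freqs is not None:
            if set(self.background_freqs) - set(AMINO_ACIDS):
                raise ValueError("background_freqs keys must be canonical residues")
            total = sum(self.background_freqs.values())
            if total <= 0:
                raise ValueError("background_freqs must sum to a positive value")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated sequence."""

    seq_id: str
    kingdom: str
    true_type: str
    planted_positions: dict[str, tuple[int, int]]  # 0-based half-open
    is_decoy: bool = False
    ablated_feature: str | None = None

    def __post_init__(self) -> None:
        intervals = sorted(self.planted_positions.values())
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError("planted feature intervals must be pairwise disjoint")
        if self.is_decoy and self.ablated_feature not in FEATURES:
            raise ValueError("decoys must name exactly one ablated feature")
        if not self.is_decoy and self.ablated_feature is not None:
            raise ValueError("non-decoys must not name an ablated feature")


@dataclass(frozen=True)
class KingdomLayout:
    """Resolved geometry of one kingdom's synthetic sequences (0-based starts,
    1-based anchor positions)."""

    kingdom: str
    ref_id: str
    length: int
    typing_positions: tuple[int, int]
    catalytic_positions: tuple[int, int]
    feature_intervals: dict[str, tuple[int, int]]

    @property
    def anchor(self) -> ReferenceAnchor:
        return ReferenceAnchor(self.ref_id, self.typing_positions, self.catalytic_positions)

    def protected_mask(self) -> np.ndarray:
        """Positions exempt from background mutation: the *constrained*
        positions of each planted motif (wildcard positions may mutate freely
        — any residue still matches), plus typing and catalytic positions."""
        mask = np.zeros(self.length, dtype=bool)
        for pid, (s, _) in self.feature_intervals.items():
            for off in _constrained_offsets(PATTERNS[pid]):
                mask[s + off] = True
        for p in (*self.typing_positions, *self.catalytic_positions):
            mask[p - 1] = True
        return mask

    def truth_positions(self) -> dict[str, tuple[int, int]]:
        a, b = self.typing_positions
        c1, c2 = self.catalytic_positions
        out = dict(self.feature_intervals)
        out.update(
            typing_a=(a - 1, a),
            typing_b=(b - 1, b),
            catalytic_his_1=(c1 - 1, c1),
            catalytic_his_2=(c2 - 1, c2),
        )
        return out


def kingdom_layout(kingdom: str, seq_length: int) -> KingdomLayout:
    base = _BASE[kingdom]
    length = seq_length + 40 if kingdom == "arthropod" else seq_length
    scale = length / base["length"]

    def pos(p: int) -> int:
        return max(1, round(p * scale))

    a = pos(base["a"])
    b = pos(base["b"])
    c1 = b + 1
    c2 = max(pos(base["c2"]), c1 + 2)
    spans = {pid: PATTERNS[pid].min_span for pid in ("adp", "ps00623", "ps00624")}
    intervals = {
        "adp": (_ADP_START, _ADP_START + spans["adp"]),
        "ps00623": (pos(base["ps623"]) - 1, pos(base["ps623"]) - 1 + spans["ps00623"]),
        "ps00624": (pos(base["ps624"]) - 1, pos(base["ps624"]) - 1 + spans["ps00624"]),
    }
    layout = KingdomLayout(
        kingdom, f"{kingdom}_ref", length, (a, b), (c1, c2), intervals
    )
    # geometry sanity: anchors inside the sequence and outside planted motifs
    occupied: set[int] = set()
    for s, e in intervals.values():
        if not (0 <= s < e <= length):
            raise ValueError("planted interval outside sequence")
        if occupied & set(range(s, e)):
            raise ValueError("planted intervals overlap")
        occupied.update(range(s, e))
    for p in (a, b, c1, c2):
        if not 1 <= p <= length:
            raise ValueError("anchor position outside sequence")
        if (p - 1) in occupied:
            raise ValueError("anchor position collides with a planted motif")
    if len({a, b, c1, c2}) != 4:
        raise ValueError("anchor positions must be distinct")
    return layout


def _freq_arrays(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    if config.background_freqs is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([config.background_freqs.get(a, 0.0) for a in AMINO_ACIDS])
        probs = probs / probs.sum()
    return letters, probs


def _sample_background(n: int, rng, letters, probs) -> np.ndarray:
    return rng.choice(letters, size=n, p=probs)


def _sample_instance(pattern: motifs.PrositePattern, rng) -> str:
    """Draw one concrete match of a signature: uniform residue per element,
    uniform width for range repeats."""
    out = []
    for e in pattern.elements:
        width = int(rng.integers(e.min_repeat, e.max_repeat + 1))
        choices = sorted(set(e.allowed) & set(AMINO_ACIDS))
        out.extend(rng.choice(choices) for _ in range(width))
    return "".join(out)


def _scrub_pattern(
    seq: np.ndarray,
    pattern: motifs.PrositePattern,
    keep_start: int | None,
    protected: np.ndarray,
    rng,
    letters,
    probs,
    max_rounds: int = 100,
) -> None:
    """Resample background residues until *pattern* matches only at
    *keep_start* (nowhere, if None).  Mutates *seq* in place."""
    for _ in range(max_rounds):
        rec = ProteinRecord("tmp", seq.tobytes().decode())
        hits = [h for h in motifs.scan(pattern, rec) if h.start != keep_start]
        if not hits:
            return
        for h in hits:
            idx = [i for i in range(h.start, h.end) if not protected[i]]
            if not idx:
                raise RuntimeError(
                    f"cannot scrub spurious {pattern.pattern_id} hit at {h.start}: "
                    "all positions protected"
                )
            seq[idx] = _sample_background(len(idx), rng, letters, probs)
    raise RuntimeError(f"failed to scrub spurious {pattern.pattern_id} hits")


def _build_ancestor(layout: KingdomLayout, config: SynthConfig, rng) -> np.ndarray:
    letters, probs = _freq_arrays(config)
    seq = _sample_background(layout.length, rng, letters, probs)
    for pid, (s, e) in layout.feature_intervals.items():
        inst = _sample_instance(PATTERNS[pid], rng)
        seq[s : s + len(inst)] = np.frombuffer(inst.encode(), dtype="S1")
    for p in layout.catalytic_positions:
        seq[p - 1] = b"H"
    a, b = layout.typing_positions
    ra, rb = _REF_TYPING[layout.kingdom]
    seq[a - 1] = ra.encode()
    seq[b - 1] = rb.encode()
    protected = layout.protected_mask()
    for pid, (s, _) in layout.feature_intervals.items():
        _scrub_pattern(seq, PATTERNS[pid], s, protected, rng, letters, probs)
    return seq


def _mutate(seq: np.ndarray, rate: float, protected: np.ndarray, rng, letters, probs):
    """Per-site substitution at *rate* outside protected positions; a drawn
    residue may equal the original (effective rate 19/20 of nominal under the
    uniform background)."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = (rng.random(len(seq)) < rate) & ~protected
    n = int(hit.sum())
    if n:
        out[hit] = _sample_background(n, rng, letters, probs)
    return out


def _kingdom_rng(config: SynthConfig, kingdom: str, stream: int, extra: int = 0):
    return np.random.default_rng(
        [config.seed % (2**31), KINGDOMS.index(kingdom), stream, extra]
    )


def reference_records(config: SynthConfig) -> dict[str, ProteinRecord]:
    """The kingdom ancestors, used as reference/anchor sequences."""
    refs = {}
    for kingdom in config.kingdoms:
        layout = kingdom_layout(kingdom, config.seq_length)
        rng = _kingdom_rng(config, kingdom, 0)
        seq = _build_ancestor(layout, config, rng)
        refs[kingdom] = ProteinRecord(layout.ref_id, seq.tobytes().decode(), kingdom=kingdom)
    return refs


def reference_anchors(config: SynthConfig) -> dict[str, ReferenceAnchor]:
    return {
        kingdom: kingdom_layout(kingdom, config.seq_length).anchor
        for kingdom in config.kingdoms
    }


def _family_members(
    config: SynthConfig, kingdom: str
) -> tuple[KingdomLayout, list[ProteinRecord], list[TruthRecord]]:
    layout = kingdom_layout(kingdom, config.seq_length)
    letters, probs = _freq_arrays(config)
    ancestor = _build_ancestor(layout, config, _kingdom_rng(config, kingdom, 0))
    protected = layout.protected_mask()
    rng = _kingdom_rng(config, kingdom, 1)
    a, b = layout.typing_positions
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for type_name, (allowed_a, allowed_b) in TYPE_RESIDUES[kingdom].items():
        type_ancestor = _mutate(ancestor, config.type_divergence, protected, rng, letters, probs)
        for i in range(config.n_per_type):
            seq = _mutate(type_ancestor, config.mutation_rate, protected, rng, letters, probs)
            seq[a - 1] = rng.choice(sorted(allowed_a)).encode()
            seq[b - 1] = rng.choice(sorted(allowed_b)).encode()
            seq_id = f"{kingdom}_{type_name}_{i:03d}"
            records.append(
                ProteinRecord(seq_id, seq.tobytes().decode(), kingdom=kingdom)
            )
            truths.append(
                TruthRecord(seq_id, kingdom, type_name, layout.truth_positions())
            )
    return layout, records, truths


def generate_family(config: SynthConfig) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Generate all (kingdom, type) cells of non-decoy AAO-like sequences."""
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for kingdom in config.kingdoms:
        _, recs, trus = _family_members(config, kingdom)
        records.extend(recs)
        truths.extend(trus)
    return records, truths


def generate_decoys(
    config: SynthConfig, ablate: str
) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Decoys failing exactly one feature check.

    Each decoy is a paired non-decoy with the named feature ablated:
    ``catalytic_his`` substitutes both anchored histidines with alanine;
    motif ablations replace the planted instance with background residues
    rescanned to contain no match anywhere in the sequence.
    """
    if ablate not in FEATURES:
        raise ValueError(f"unknown feature {ablate!r}; expected one of {FEATURES}")
    letters, probs = _freq_arrays(config)
    ablate_idx = FEATURES.index(ablate)
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for kingdom in config.kingdoms:
        layout, base_records, base_truths = _family_members(config, kingdom)
        if not base_records:
            continue
        rng = _kingdom_rng(config, kingdom, 2, ablate_idx)
        n_types = len(TYPE_RESIDUES[kingdom])
        for i in range(config.n_per_type):
            base = base_records[(i % n_types) * config.n_per_type + i]
            truth = base_truths[(i % n_types) * config.n_per_type + i]
            seq = np.frombuffer(base.sequence.encode(), dtype="S1").copy()
            if ablate == "catalytic_his":
                for p in layout.catalytic_positions:
                    seq[p - 1] = b"A"
            else:
                s, e = layout.feature_intervals[ablate]
                seq[s:e] = _sample_background(e - s, rng, letters, probs)
                protected = layout.protected_mask()
                protected[s:e] = False
                _scrub_pattern(seq, PATTERNS[ablate], None, protected, rng, letters, probs)
            seq_id = f"{kingdom}_decoy_{ablate}_{i:03d}"
            records.append(ProteinRecord(seq_id, seq.tobytes().decode(), kingdom=kingdom))
            truths.append(
                TruthRecord(
                    seq_id,
                    kingdom,
                    truth.true_type,
                    layout.truth_positions(),
                    is_decoy=True,
                    ablated_feature=ablate,
                )
            )
    return records, truths


def generate_outgroup(config: SynthConfig, n: int = 2) -> list[ProteinRecord]:
    """Distantly related GMC-like sequences (cholesterol-oxidase stand-ins)
    for outgroup rooting: independent backgrounds with the shared GMC
    features planted."""
    layout = kingdom_layout("bacteria", config.seq_length)
    rng = np.random.default_rng([config.seed % (2**31), 99])
    letters, probs = _freq_arrays(config)
    ancestor = _build_ancestor(layout, config, rng)
    protected = layout.protected_mask()
    out = []
    for i in range(n):
        seq = _mutate(ancestor, 0.05, protected, rng, letters, probs)
        out.append(ProteinRecord(f"outgroup_{i+1}", seq.tobytes().decode()))
    return out


HIT_TABLE_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


def generate_hit_table(
    ids: list[str],
    identity_values: list[float],
    evalues: list[float],
    seed: int = 0,
    query_id: str = "reference_query",
) -> pd.DataFrame:
    """A 12-column homology hit table (tabular outfmt-6 dialect) with the
    given per-subject identities and e-values; remaining columns are filled
    with plausible values."""
    if not (len(ids) == len(identity_values) == len(evalues)):
        raise ValueError("ids, identity_values and evalues must have equal length")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, pid, ev in zip(ids, identity_values, evalues):
        length = int(rng.integers(300, 600))
        mismatches = int(round(length * (1 - pid / 100.0)))
        rows.append(
            (query_id, sid, float(pid), length, mismatches, int(rng.integers(0, 5)),
             1, length, 1, length, float(ev), float(rng.uniform(50, 900)))
        )
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def write_hit_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False)


def generate_additive_matrix(newick: str) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a Newick tree (test oracle for
    neighbor joining)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < 0:
            raise ValueError("tree must have non-negative branch lengths")
    labels = [leaf.taxon.label for leaf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    return DistanceMatrix(labels, D)


def write_truth_tsv(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# planted intervals are 0-based half-open\n")
        fh.write("seq_id\tkingdom\ttrue_type\tis_decoy\tablated_feature\tplanted\n")
        for t in truths:
            planted = ";".join(
                f"{k}:{s}-{e}" for k, (s, e) in sorted(t.planted_positions.items())
            )
            fh.write(
                f"{t.seq_id}\t{t.kingdom}\t{t.true_type}\t{int(t.is_decoy)}\t"
                f"{t.ablated_feature or '-'}\t{planted}\n"
            )
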