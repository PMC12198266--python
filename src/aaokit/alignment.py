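"""Global pairwise alignment, reference-position anchoring, progressive MSA.

Pairwise alignment is Needleman–Wunsch with affine gaps (Gotoh) under a
substitution matrix, delegated to :class:`Bio.Align.PairwiseAligner`.
Anchoring maps numbered reference residues (e.g. PeAAO 92/501/502/546) to
their aligned query positions.  The progressive multiple aligner builds a
neighbor-joining guide tree from k-mer distances and merges profiles with an
affine-gap profile–profile dynamic programme; it exists so logo and
phylogeny stages run without an external alignment tool, and an externally
computed aligned FASTA can always be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from aaokit.records import AMINO_ACIDS, ProteinRecord
from aaokit.references import ReferenceAnchor

#: sentinel for a reference position with no aligned query residue
UNMAPPED = None

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap alignment parameters.

    A gap of length k costs ``gap_open + (k-1) * gap_extend`` (substitution
    matrix units); defaults are the common BLOSUM62 / 10 / 0.5 choice.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class Alignment:
    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned rows must have equal length")


@dataclass(frozen=True)
class PositionMap:
    """Reference 1-based position -> (query 1-based position, query residue).

    Unmapped positions (query gap at the reference column) carry
    ``(None, None)``.
    """

    ref_id: str
    query_id: str
    entries: dict[int, tuple[int | None, str | None]]

    def query_position(self, ref_pos: int) -> int | None:
        return self.entries[ref_pos][0]

    def residue(self, ref_pos: int) -> str | None:
        return self.entries[ref_pos][1]


@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    return aligner


def global_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignParams = DEFAULT_PARAMS
) -> Alignment:
    """Optimal global alignment of *a* (reference row) against *b* (query row)."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    aln = aligner.align(a.sequence, b.sequence)[0]
    return Alignment(a.id, b.id, str(aln[0]), str(aln[1]), float(aln.score))


def alignment_score(
    a: ProteinRecord, b: ProteinRecord, params: AlignParams = DEFAULT_PARAMS
) -> float:
    """Optimal global alignment score only (no traceback)."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    return float(_make_aligner(params).score(a.sequence, b.sequence))


def map_positions(aln: Alignment, anchor: ReferenceAnchor) -> PositionMap:
    """Locate the query positions equivalent to the anchor's reference positions."""
    if aln.ref_id != anchor.reference_id:
        raise ValueError(
            f"alignment reference {aln.ref_id!r} does not match anchor "
            f"{anchor.reference_id!r}"
        )
    ref_len = sum(1 for c in aln.aligned_ref if c != "-")
    wanted = sorted(set(anchor.all_positions))
    if wanted[-1] > ref_len:
        raise ValueError(f"anchor position {wanted[-1]} beyond reference length {ref_len}")
    entries: dict[int, tuple[int | None, str | None]] = {}
    ref_pos = 0
    query_pos = 0
    targets = set(wanted)
    for rc, qc in zip(aln.aligned_ref, aln.aligned_query):
        if qc != "-":
            query_pos += 1
        if rc != "-":
            ref_pos += 1
            if ref_pos in targets:
                if qc == "-":
                    entries[ref_pos] = (UNMAPPED, UNMAPPED)
                else:
                    entries[ref_pos] = (query_pos, qc)
    return PositionMap(aln.ref_id, aln.query_id, entries)


def write_position_map(pmap: PositionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# reference and query positions are 1-based\n")
        fh.write("ref_pos\tquery_pos\tquery_residue\n")
        for ref_pos in sorted(pmap.entries):
            qp, res = pmap.entries[ref_pos]
            fh.write(f"{ref_pos}\t{qp if qp is not None else 'UNMAPPED'}\t{res or '-'}\n")


# --- progressive multiple alignment -------------------------------------------------


def _gotoh_profile_kernel(S, gap_open, gap_extend):
    """Three-state affine DP over a precomputed column-score matrix.

    Returns the three score layers and per-layer backpointers; tie-breaks
    prefer diagonal, then up (gap in second profile), then left.
    """
    n1, n2 = S.shape
    NEG = -1e30
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)
    Y = np.full((n1 + 1, n2 + 1), NEG)
    pM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, n2 + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            # match layer
            bm, bp = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > bm:
                bm, bp = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > bm:
                bm, bp = Y[i - 1, j - 1], 2
            M[i, j] = bm + S[i - 1, j - 1]
            pM[i, j] = bp
            # gap in second profile (consume a column of the first)
            bm, bp = M[i - 1, j] - gap_open, 0
            if X[i - 1, j] - gap_extend > bm:
                bm, bp = X[i - 1, j] - gap_extend, 1
            if Y[i - 1, j] - gap_open > bm:
                bm, bp = Y[i - 1, j] - gap_open, 2
            X[i, j] = bm
            pX[i, j] = bp
            # gap in first profile
            bm, bp = M[i, j - 1] - gap_open, 0
            if X[i, j - 1] - gap_open > bm:
                bm, bp = X[i, j - 1] - gap_open, 1
            if Y[i, j - 1] - gap_extend > bm:
                bm, bp = Y[i, j - 1] - gap_extend, 2
            Y[i, j] = bm
            pY[i, j] = bp
    return M, X, Y, pM, pX, pY


try:  # optional acceleration; the pure-Python kernel is the reference
    from numba import njit as _njit

    _gotoh_profile_kernel = _njit(cache=False)(_gotoh_profile_kernel)
except Exception:  # pragma: no cover
    pass


_CODE_LUT = np.full(256, 20, dtype=np.int64)  # 20 = gap/unknown bucket
for _a, _i in _AA_INDEX.items():
    _CODE_LUT[ord(_a)] = _i


def _profile_freqs(rows: list[str]) -> np.ndarray:
    codes = _CODE_LUT[
        np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    ]
    L = codes.shape[1]
    flat = (codes + 21 * np.arange(L)[None, :]).ravel()
    counts = np.bincount(flat, minlength=21 * L).reshape(L, 21)[:, :20]
    return counts.astype(float) / len(rows)


_B62 = None


def _blosum_array(matrix_name: str) -> np.ndarray:
    global _B62
    if _B62 is None or matrix_name != "BLOSUM62":
        mat = substitution_matrices.load(matrix_name)
        arr = np.zeros((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                arr[i, j] = mat[a, b]
        if matrix_name == "BLOSUM62":
            _B62 = arr
        return arr
    return _B62


def _align_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignParams
) -> tuple[list[str], list[str]]:
    B = _blosum_array(params.matrix)
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    S = fa @ B @ fb.T
    M, X, Y, pM, pX, pY = _gotoh_profile_kernel(S, params.gap_open, params.gap_extend)
    i, j = S.shape
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[int] = []  # 0=both, 1=consume A, 2=consume B
    while i > 0 or j > 0:
        if state == 0:
            ops.append(0)
            state = int(pM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            state = int(pX[i, j])
            i -= 1
        else:
            ops.append(2)
            state = int(pY[i, j])
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    buf_a: list[list[str]] = [[] for _ in rows_a]
    buf_b: list[list[str]] = [[] for _ in rows_b]
    for op in ops:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                buf_a[r].append(row[ia])
            ia += 1
        else:
            for r in range(len(rows_a)):
                buf_a[r].append("-")
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                buf_b[r].append(row[ib])
            ib += 1
        else:
            for r in range(len(rows_b)):
                buf_b[r].append("-")
    out_a = ["".join(b) for b in buf_a]
    out_b = ["".join(b) for b in buf_b]
    return out_a, out_b


def _kmer_distance_matrix(records: list[ProteinRecord], k: int = 3) -> np.ndarray:
    sets = []
    for r in records:
        s = r.sequence
        sets.append({s[i : i + k] for i in range(max(len(s) - k + 1, 0))} or {s})
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            D[i, j] = D[j, i] = 1.0 - shared / denom
    return D


def progressive_msa(
    records: list[ProteinRecord], params: AlignParams = DEFAULT_PARAMS
) -> Msa:
    """Progressive multiple alignment over an NJ guide tree (k-mer distances)."""
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(records) == 2:
        aln = global_align(records[0], records[1], params)
        return Msa(ids, [aln.aligned_ref, aln.aligned_query])

    from aaokit.phylo import DistanceMatrix, neighbor_joining

    D = _kmer_distance_matrix(records)
    tree = neighbor_joining(DistanceMatrix(ids, D))
    by_id = {r.id: r for r in records}

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            rec = by_id[node.taxon.label]
            return [rec.id], [rec.sequence]
        child_profiles = [merge(c) for c in node.child_nodes()]
        ids_acc, rows_acc = child_profiles[0]
        for cid, crows in child_profiles[1:]:
            rows_acc, crows = _align_profiles(rows_acc, crows, params)
            ids_acc = ids_acc + cid
            rows_acc = rows_acc + crows
        return ids_acc, rows_acc

    merged_ids, merged_rows = merge(tree.seed_node)
    order = {sid: i for i, sid in enumerate(merged_ids)}
    rows = [merged_rows[order[sid]] for sid in ids]
    return Msa(ids, rows)


def degap(row: str) -> str:
    return row.replace("-", "")
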