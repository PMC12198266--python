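"""Pairwise alignment scoring, anchor mapping, progressive MSA round trips."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from aaokit import synthetic
from aaokit.alignment import (
    AlignParams,
    Msa,
    degap,
    global_align,
    map_positions,
    progressive_msa,
)
from aaokit.records import AMINO_ACIDS, ProteinRecord
from aaokit.references import ReferenceAnchor

PARAMS = AlignParams()
B62 = substitution_matrices.load("BLOSUM62")


def gotoh_score_oracle(a: str, b: str, params: AlignParams) -> float:
    """Independent three-state affine-gap DP (scores only); a gap of length k
    costs open + (k-1) * extend, end gaps included."""
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = B62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def test_self_alignment_identity():
    rec = ProteinRecord("a", "HEAGAWGHEE")
    aln = global_align(rec, ProteinRecord("b", rec.sequence))
    assert aln.aligned_ref == aln.aligned_query == rec.sequence
    assert aln.score == pytest.approx(sum(B62[c, c] for c in rec.sequence))


def test_score_matches_dp_oracle():
    pairs = [
        ("HEAGAWGHEE", "PAWHEAE"),
        ("MKVLA", "MKLA"),
        ("WWWW", "AW"),
        ("ACDEFGHIK", "ACDFGIK"),
    ]
    rng = np.random.default_rng(11)
    for _ in range(6):
        n, m = rng.integers(3, 15, size=2)
        pairs.append((
            "".join(rng.choice(list(AMINO_ACIDS), size=n)),
            "".join(rng.choice(list(AMINO_ACIDS), size=m)),
        ))
    for a, b in pairs:
        aln = global_align(ProteinRecord("a", a), ProteinRecord("b", b), PARAMS)
        assert aln.score == pytest.approx(gotoh_score_oracle(a, b, PARAMS))
        # score symmetry under the symmetric matrix
        rev = global_align(ProteinRecord("b", b), ProteinRecord("a", a), PARAMS)
        assert rev.score == pytest.approx(aln.score)
        # round trip
        assert degap(aln.aligned_ref) == a and degap(aln.aligned_query) == b
        assert not any(
            r == q == "-" for r, q in zip(aln.aligned_ref, aln.aligned_query)
        )


def test_single_deletion_yields_one_gap_column():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    query = seq[:30] + seq[31:]
    aln = global_align(ProteinRecord("r", seq), ProteinRecord("q", query))
    assert aln.aligned_query.count("-") == 1 and aln.aligned_ref.count("-") == 0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align(ProteinRecord("a", "AA"), ProteinRecord("b", ""))


class TestMapPositions:
    anchor = ReferenceAnchor("ref", (92, 120), (121, 140))

    def _record(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return ProteinRecord("ref", "".join(rng.choice(list(AMINO_ACIDS), size=n)))

    def test_identity_map(self):
        ref = self._record()
        aln = global_align(ref, ProteinRecord("q", ref.sequence))
        pmap = map_positions(aln, self.anchor)
        assert pmap.query_position(92) == 92
        assert pmap.residue(92) == ref.sequence[91]

    def test_leading_deletion_offsets_map(self):
        ref = self._record()
        aln = global_align(ref, ProteinRecord("q", ref.sequence[10:]))
        pmap = map_positions(aln, self.anchor)
        assert pmap.query_position(92) == 82

    def test_gap_at_anchor_is_unmapped(self):
        ref = self._record()
        query = ref.sequence[:115] + ref.sequence[125:]  # removes ref 116-125
        aln = global_align(ref, ProteinRecord("q", query))
        pmap = map_positions(aln, self.anchor)
        assert pmap.query_position(120) is None and pmap.residue(120) is None
        assert pmap.query_position(92) == 92

    def test_monotonicity(self):
        ref = self._record(seed=5)
        rng = np.random.default_rng(6)
        keep = sorted(rng.choice(200, size=170, replace=False))
        query = "".join(ref.sequence[i] for i in keep)
        aln = global_align(ref, ProteinRecord("q", query))
        pmap = map_positions(aln, self.anchor)
        mapped = [pmap.query_position(p) for p in sorted(pmap.entries)]
        mapped = [m for m in mapped if m is not None]
        assert mapped == sorted(mapped)
        assert all(m1 < m2 for m1, m2 in zip(mapped, mapped[1:]))

    def test_anchor_beyond_reference_rejected(self):
        ref = ProteinRecord("ref", "ACDEF")
        aln = global_align(ref, ProteinRecord("q", "ACDEF"))
        with pytest.raises(ValueError):
            map_positions(aln, self.anchor)

    def test_reference_id_mismatch_rejected(self):
        other = ProteinRecord("other", "ACDEFGH" * 30)
        aln = global_align(other, ProteinRecord("q", other.sequence))
        with pytest.raises(ValueError):
            map_positions(aln, self.anchor)


class TestProgressiveMsa:
    def test_two_sequences_equal_pairwise(self):
        a, b = ProteinRecord("a", "HEAGAWGHEE"), ProteinRecord("b", "PAWHEAE")
        msa = progressive_msa([a, b])
        aln = global_align(a, b)
        assert msa.rows == [aln.aligned_ref, aln.aligned_query]

    def test_identical_sequences_align_without_gaps(self):
        recs = [ProteinRecord(f"s{i}", "MKVLAWHEAGAWGHEE") for i in range(3)]
        msa = progressive_msa(recs)
        assert all("-" not in row for row in msa.rows)

    def test_round_trip_recovers_inputs(self):
        config = synthetic.SynthConfig(n_per_type=3, mutation_rate=0.1, seed=21,
                                       kingdoms=("bacteria",))
        records, _ = synthetic.generate_family(config)
        msa = progressive_msa(records)
        for rec, row in zip(records, msa.rows):
            assert degap(row) == rec.sequence

    def test_planted_motifs_share_columns(self):
        """All PS00623 instances of a mutated family start in one MSA column."""
        config = synthetic.SynthConfig(n_per_type=5, mutation_rate=0.1, seed=21,
                                       kingdoms=("fungi",))
        records, truths = synthetic.generate_family(config)
        msa = progressive_msa(records[:10])
        start_columns = set()
        for rec, truth, row in zip(records, truths, msa.rows):
            start, _ = truth.planted_positions["ps00623"]
            residue_index = -1
            for col, char in enumerate(row):
                if char != "-":
                    residue_index += 1
                    if residue_index == start:
                        start_columns.add(col)
                        break
        assert len(start_columns) == 1

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([ProteinRecord("a", "ACD")])


def test_msa_container_validation():
    with pytest.raises(ValueError):
        Msa(["a"], ["AC", "AC"])
    with pytest.raises(ValueError):
        Msa(["a", "b"], ["AC-", "AC"])
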