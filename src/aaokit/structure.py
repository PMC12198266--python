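"""Sequence-aligned C-alpha superposition and RMSD between structure pairs.

Chains are read with gemmi (PDB or mmCIF); C-alpha atoms are paired through a
global sequence alignment of the two chains' one-letter sequences, then
superposed with the Kabsch algorithm (SVD least-squares rigid fit with
reflection correction) and iteratively refined by discarding pairs whose
post-fit distance exceeds ``reject_multiplier`` times the current RMSD —
mirroring common align-and-refine superposition protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from aaokit.alignment import AlignParams, DEFAULT_PARAMS, global_align
from aaokit.records import AA_SET, ProteinRecord


@dataclass(frozen=True)
class ChainCoords:
    """Ordered C-alpha trace of one protein chain."""

    structure_id: str
    residue_numbers: tuple[int, ...]
    one_letter_sequence: str
    calpha_xyz: np.ndarray  # (n, 3), Angstrom

    def __post_init__(self) -> None:
        n = len(self.residue_numbers)
        if len(self.one_letter_sequence) != n or self.calpha_xyz.shape != (n, 3):
            raise ValueError("residue numbers, sequence and coordinates must correspond")
        if not np.all(np.isfinite(self.calpha_xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_pairs: int
    iterations: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det +1)")
        if np.max(np.abs(self.rotation @ self.rotation.T - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthonormal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def read_calpha(path: str | Path, chain: str | None = None) -> ChainCoords:
    """Extract the C-alpha trace of the longest (or named) protein chain.

    First model, first alternate location; residues lacking a C-alpha are
    skipped.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable structure file {path}: {exc}") from exc
    if not len(structure):
        raise ValueError(f"no models in {path}")
    structure.setup_entities()
    model = structure[0]
    candidates = []
    for ch in model:
        numbers, letters, coords = [], [], []
        for res in ch:
            # first CA in file order = first alternate location
            ca = next((atom for atom in res if atom.name == "CA"), None)
            if ca is None:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            letters.append(one if one in AA_SET else "X")
            numbers.append(res.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if numbers:
            candidates.append(
                ChainCoords(
                    f"{structure.name or Path(path).stem}:{ch.name}",
                    tuple(numbers),
                    "".join(letters),
                    np.asarray(coords, dtype=float),
                )
            )
            if chain is not None and ch.name == chain:
                return candidates[-1]
    if chain is not None:
        raise ValueError(f"chain {chain!r} not found in {path}")
    if not candidates:
        raise ValueError(f"no protein chain with C-alpha atoms in {path}")
    return max(candidates, key=len)


def kabsch(pairs_a: np.ndarray, pairs_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *pairs_a* onto *pairs_b*.

    Returns the proper rotation R and translation t minimising
    ||(R a + t) - b||; rmsd is over the fitted pairs.
    """
    A = np.asarray(pairs_a, dtype=float)
    B = np.asarray(pairs_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate lists must be matching (n, 3) arrays")
    if len(A) < 3:
        raise ValueError("at least 3 coordinate pairs required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    fitted = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - B) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, len(A), 0)


def _paired_indices(
    a: ChainCoords, b: ChainCoords, params: AlignParams
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of C-alpha pairs from a global alignment of the two chain
    sequences; columns with gaps or non-standard residues are excluded."""
    ra = ProteinRecord(a.structure_id, a.one_letter_sequence.replace("X", "A"))
    rb = ProteinRecord(b.structure_id, b.one_letter_sequence.replace("X", "A"))
    aln = global_align(ra, rb, params)
    ia = ib = 0
    keep_a, keep_b = [], []
    for ca_, cb_ in zip(aln.aligned_ref, aln.aligned_query):
        if ca_ != "-" and cb_ != "-":
            if a.one_letter_sequence[ia] != "X" and b.one_letter_sequence[ib] != "X":
                keep_a.append(ia)
                keep_b.append(ib)
        if ca_ != "-":
            ia += 1
        if cb_ != "-":
            ib += 1
    return np.array(keep_a, dtype=int), np.array(keep_b, dtype=int)


def superpose_structures(
    a: ChainCoords,
    b: ChainCoords,
    reject_multiplier: float = 2.0,
    max_iterations: int = 5,
    align_params: AlignParams = DEFAULT_PARAMS,
) -> SuperpositionResult:
    """Align-and-refine C-alpha superposition of two chains.

    Pairs are discarded when their post-fit distance exceeds
    ``reject_multiplier`` x current RMSD; refitting stops when no pair is
    discarded or after ``max_iterations`` rounds.
    """
    if len(a) < 50 or len(b) < 50:
        raise ValueError("both chains must have at least 50 residues")
    ia, ib = _paired_indices(a, b, align_params)
    if len(ia) < 3:
        raise ValueError("fewer than 3 alignable C-alpha pairs")
    A = a.calpha_xyz[ia]
    B = b.calpha_xyz[ib]
    result = kabsch(A, B)
    iterations = 0
    for _ in range(max_iterations):
        fitted = A @ result.rotation.T + result.translation
        dist = np.sqrt(np.sum((fitted - B) ** 2, axis=1))
        cutoff = reject_multiplier * result.rmsd
        keep = dist <= cutoff
        if keep.all() or result.rmsd == 0.0:
            break
        if keep.sum() < 3:
            raise ValueError("fewer than 3 surviving pairs after outlier rejection")
        A, B = A[keep], B[keep]
        iterations += 1
        result = kabsch(A, B)
    return SuperpositionResult(
        result.rotation, result.translation, result.rmsd, len(A), iterations
    )


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation
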