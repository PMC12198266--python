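"""Sequence-logo information content (Schneider–Stephens, as WebLogo computes it).

Per-column conservation is R = log2(20) - (H_obs + e(n)) bits, where H_obs is
the Shannon entropy of the observed residue frequencies and
e(n) = (s - 1) / (2 ln 2 n) with s = 20 is the small-sample correction.
Letter heights are residue frequencies scaled by R.  Gaps are excluded from
the counts (WebLogo default) rather than treated as a 21st symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from aaokit.alignment import Msa
from aaokit.records import AMINO_ACIDS

MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class LogoColumn:
    column_index: int  # reference residue numbering (1-based)
    counts: dict[str, int]
    n_effective: int
    information_bits: float
    letter_heights: dict[str, float]


def column_information(
    counts: Mapping[str, int], apply_small_sample_correction: bool = False
) -> float:
    """Information content in bits of one alignment column.

    Clamped at 0 from below; the correction e(n) = 19/(2 ln2 n) is applied
    only when requested.
    """
    n = sum(counts.values())
    if n < 1:
        raise ValueError("column has no observations")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    h = 0.0
    for v in counts.values():
        if v > 0:
            f = v / n
            h -= f * math.log2(f)
    penalty = h
    if apply_small_sample_correction:
        penalty += 19.0 / (2.0 * math.log(2.0) * n)
    return max(0.0, MAX_BITS - penalty)


def _reference_column_map(ref_row: str) -> dict[int, int]:
    """reference residue number (1-based) -> MSA column index (0-based)."""
    mapping = {}
    pos = 0
    for col, c in enumerate(ref_row):
        if c != "-":
            pos += 1
            mapping[pos] = col
    return mapping


def build_logo(
    msa: Msa,
    reference_id: str,
    positions: Sequence[int],
    correction: str = "auto",
    small_sample_threshold: int = 50,
) -> tuple[list[LogoColumn], list[str]]:
    """One LogoColumn per requested reference-numbered position.

    ``correction``: 'auto' (on when n_effective < small_sample_threshold),
    'on', or 'off'.  Returns (columns, warnings); an all-gap column is
    emitted with n_effective 0 and a warning.
    """
    if correction not in ("auto", "on", "off"):
        raise ValueError(f"unknown correction mode {correction!r}")
    ref_row = msa.row(reference_id)
    colmap = _reference_column_map(ref_row)
    ref_len = max(colmap) if colmap else 0
    columns = []
    warnings = []
    for pos in positions:
        if pos < 1 or pos > ref_len:
            raise ValueError(f"reference position {pos} outside reference length {ref_len}")
        col = colmap[pos]
        counts = {}
        for row in msa.rows:
            c = row[col]
            if c in AMINO_ACIDS:
                counts[c] = counts.get(c, 0) + 1
        n_eff = sum(counts.values())
        if n_eff == 0:
            warnings.append(f"reference position {pos}: all-gap column")
            columns.append(LogoColumn(pos, {}, 0, 0.0, {}))
            continue
        use_corr = correction == "on" or (
            correction == "auto" and n_eff < small_sample_threshold
        )
        bits = column_information(counts, use_corr)
        heights = {a: (counts[a] / n_eff) * bits for a in counts}
        columns.append(LogoColumn(pos, counts, n_eff, bits, heights))
    return columns, warnings


def write_logo_tsv(columns: Sequence[LogoColumn], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "column_index\tn_effective\tinformation_bits\t"
            + "\t".join(AMINO_ACIDS)
            + "\n"
        )
        for col in columns:
            heights = "\t".join(f"{col.letter_heights.get(a, 0.0):.6f}" for a in AMINO_ACIDS)
            fh.write(f"{col.column_index}\t{col.n_effective}\t{col.information_bits:.6f}\t{heights}\n")


def plot_logo(columns: Sequence[LogoColumn], path) -> None:
    """Cosmetic stacked-bar rendering of the logo columns (the TSV is the
    authoritative numeric output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(columns) * 0.4), 3))
    for x, col in enumerate(columns):
        bottom = 0.0
        for letter, h in sorted(col.letter_heights.items(), key=lambda kv: kv[1]):
            ax.bar(x, h, bottom=bottom, width=0.8)
            if h > 0.15:
                ax.text(x, bottom + h / 2, letter, ha="center", va="center", fontsize=7)
            bottom += h
    ax.set_xticks(range(len(columns)))
    ax.set_xticklabels([str(c.column_index) for c in columns], rotation=90, fontsize=6)
    ax.set_ylabel("bits")
    ax.set_ylim(0, MAX_BITS)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
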