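"""Candidate selection: homology-hit filtering plus conserved-feature checks.

A sequence is retained as a putative AAO candidate only when (a) it has a
homology hit with identity strictly above 35% and e-value strictly below
1e-10 (when hit evidence exists), and (b) it displays *all* of: the
ADP-binding motif and a PS00623 instance in the N-terminal region, a PS00624
instance in the central portion, and histidine at both reference-anchored
catalytic positions.  Sequences without any hit evidence are screened on
features alone and flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from aaokit import motifs
from aaokit.alignment import AlignParams, DEFAULT_PARAMS, alignment_score, global_align, map_positions
from aaokit.records import ProteinRecord, write_fasta
from aaokit.references import ReferenceAnchor
from aaokit.synthetic import PATTERNS


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if min(self.q_start, self.q_end, self.s_start, self.s_end) < 1:
            raise ValueError("coordinate fields must be positive")


def parse_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a header-less tab-separated hit table; '#' comment lines are
    ignored; a bad row raises with its line number."""
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(f"row {lineno}: expected 12 columns, got {len(fields)}")
        try:
            hits.append(
                HitRecord(
                    fields[0], fields[1], float(fields[2]), int(fields[3]),
                    int(fields[4]), int(fields[5]), int(fields[6]), int(fields[7]),
                    int(fields[8]), int(fields[9]), float(fields[10]), float(fields[11]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {lineno}: {exc}") from exc
    return hits


def hits_from_dataframe(table) -> list[HitRecord]:
    """Convert a 12-column DataFrame (synthetic_data layout) to HitRecords."""
    return [HitRecord(*row) for row in table.itertuples(index=False, name=None)]


def filter_hits(
    table: list[HitRecord], min_identity: float = 35.0, max_evalue: float = 1e-10
) -> set[str]:
    """Subjects with any hit passing identity > min_identity AND
    evalue < max_evalue (both strict, read literally from the thresholds)."""
    if min_identity < 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    return {
        h.subject_id
        for h in table
        if h.percent_identity > min_identity and h.evalue < max_evalue
    }


@dataclass(frozen=True)
class ScreenParams:
    """Region windows (fractions of query length) and length floor.

    The N-terminal window spans the first 40% of the sequence and the
    central window [30%, 75%) — deliberately permissive readings of
    "N-terminal region" and "central portion".
    """

    nterm_fraction: float = 0.40
    central_start_fraction: float = 0.30
    central_end_fraction: float = 0.75
    min_length: int = 100
    min_identity: float = 35.0
    max_evalue: float = 1e-10
    align_params: AlignParams = field(default_factory=AlignParams)


DEFAULT_SCREEN = ScreenParams()


@dataclass
class FeatureReport:
    seq_id: str
    has_adp: bool
    has_ps00623: bool
    has_ps00624: bool
    has_catalytic_his: bool
    evidence: dict
    retained: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = (
            self.has_adp and self.has_ps00623 and self.has_ps00624
            and self.has_catalytic_his and "too_short" not in self.flags
        )
        if self.retained != expected:
            raise ValueError("retained must equal the conjunction of the feature checks")


def check_features(
    record: ProteinRecord,
    reference: ProteinRecord,
    anchor: ReferenceAnchor,
    patterns: dict[str, motifs.PrositePattern] | None = None,
    params: ScreenParams = DEFAULT_SCREEN,
) -> FeatureReport:
    """Check the four conserved AAO features on one sequence.

    Motif positions are judged by hit *start* inside the region window;
    catalytic histidines by alignment to the anchored reference positions.
    """
    patterns = patterns or PATTERNS
    n = len(record)
    if n < params.min_length:
        return FeatureReport(
            record.id, False, False, False, False,
            {"reason": "too_short", "length": n}, False, ("too_short",),
        )
    nterm = (0, int(n * params.nterm_fraction))
    central = (int(n * params.central_start_fraction), int(n * params.central_end_fraction))
    evidence: dict = {}

    def first_hit(pid, window):
        hits = motifs.scan(patterns[pid], record, window)
        if hits:
            evidence[pid] = (hits[0].start, hits[0].end)
        return bool(hits)

    has_adp = first_hit("adp", nterm)
    has_623 = first_hit("ps00623", nterm)
    has_624 = first_hit("ps00624", central)

    aln = global_align(reference, record, params.align_params)
    pmap = map_positions(aln, anchor)
    cat = []
    for p in anchor.catalytic_positions:
        qp, res = pmap.entries[p]
        cat.append(res == "H")
        evidence[f"catalytic_{p}"] = (qp, res)
    has_his = all(cat)
    retained = has_adp and has_623 and has_624 and has_his
    return FeatureReport(record.id, has_adp, has_623, has_624, has_his, evidence, retained)


def infer_kingdom(
    record: ProteinRecord,
    references: dict[str, ProteinRecord],
    params: AlignParams = DEFAULT_PARAMS,
) -> str:
    """Kingdom hint if present, else the best-scoring reference anchor."""
    if record.kingdom is not None:
        if record.kingdom not in references:
            raise ValueError(f"no reference for kingdom {record.kingdom!r}")
        return record.kingdom
    scores = {
        kd: alignment_score(ref, record, params) for kd, ref in sorted(references.items())
    }
    return max(scores, key=lambda kd: scores[kd])


def select_candidates(
    records: list[ProteinRecord],
    hit_table: list[HitRecord] | None,
    references: dict[str, ProteinRecord],
    anchors: dict[str, ReferenceAnchor],
    patterns: dict[str, motifs.PrositePattern] | None = None,
    params: ScreenParams = DEFAULT_SCREEN,
) -> tuple[list[ProteinRecord], dict[str, FeatureReport], dict[str, str]]:
    """Compose the hit filter with the feature checks over a batch.

    Returns (retained records, per-sequence FeatureReports, per-sequence
    kingdom routing).  Every input sequence gets a report; rejections carry
    at least one failed criterion.
    """
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence ids: {dupes}")
    passing_subjects = filter_hits(hit_table, params.min_identity, params.max_evalue) if hit_table else None
    subjects_with_hits = {h.subject_id for h in hit_table} if hit_table else set()
    retained: list[ProteinRecord] = []
    reports: dict[str, FeatureReport] = {}
    kingdoms: dict[str, str] = {}
    for rec in records:
        kd = infer_kingdom(rec, references, params.align_params)
        kingdoms[rec.id] = kd
        report = check_features(rec, references[kd], anchors[kd], patterns, params)
        flags = list(report.flags)
        keep = report.retained
        if hit_table is not None and rec.id in subjects_with_hits:
            if rec.id not in passing_subjects:
                keep = False
                flags.append("hit_thresholds_failed")
        elif hit_table is not None:
            flags.append("no_hit_evidence")
        report.flags = tuple(flags)  # report.retained stays feature-level
        reports[rec.id] = report
        if keep:
            retained.append(rec)
    return retained, reports, kingdoms


def write_feature_reports(reports: dict[str, FeatureReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\thas_adp\thas_ps00623\thas_ps00624\thas_catalytic_his\t"
            "retained\tflags\n"
        )
        for sid in sorted(reports):
            r = reports[sid]
            fh.write(
                f"{sid}\t{int(r.has_adp)}\t{int(r.has_ps00623)}\t{int(r.has_ps00624)}\t"
                f"{int(r.has_catalytic_his)}\t{int(r.retained)}\t"
                f"{';'.join(r.flags) or '-'}\n"
            )
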