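"""Pipeline orchestration: screen -> type -> logo -> phylogeny, with reports.

``run_pipeline`` consumes a validated :class:`PipelineConfig` and writes the
retained-candidates FASTA, per-sequence feature reports, type calls and
per-kingdom type counts, conserved-motif logo tables, a distance matrix,
a Newick tree and a monophyly report, plus a run manifest and a summary.
Coordinates follow one convention throughout: 0-based half-open in hit/motif
tables, 1-based residue numbers in anchor/type evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from aaokit import __version__, classify as classify_mod, logos, motifs, phylo, screen
from aaokit.alignment import Msa, global_align, map_positions, progressive_msa
from aaokit.records import ProteinRecord, read_fasta, write_fasta
from aaokit.references import KINGDOM_ANCHORS, ReferenceAnchor, SIGNATURES

log = logging.getLogger("aaokit")

_KNOWN_KEYS = {
    "sequences", "hit_table", "msa", "references", "anchors", "signatures",
    "outgroup", "min_identity", "max_evalue", "nterm_fraction",
    "central_start_fraction", "central_end_fraction", "phylo_correction",
    "output_dir", "seed", "log_level",
}


@dataclass
class PipelineConfig:
    sequences: str
    references: str
    anchors: str | None = None
    hit_table: str | None = None
    msa: str | None = None
    signatures: str | None = None
    outgroup: str | None = None
    min_identity: float = 35.0
    max_evalue: float = 1e-10
    nterm_fraction: float = 0.40
    central_start_fraction: float = 0.30
    central_end_fraction: float = 0.75
    phylo_correction: str = "none"
    output_dir: str = "aaokit_out"
    seed: int = 0
    log_level: str = "INFO"

    def screen_params(self) -> screen.ScreenParams:
        return screen.ScreenParams(
            nterm_fraction=self.nterm_fraction,
            central_start_fraction=self.central_start_fraction,
            central_end_fraction=self.central_end_fraction,
            min_identity=self.min_identity,
            max_evalue=self.max_evalue,
        )


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; errors are aggregated."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = []
    unknown = set(raw) - _KNOWN_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown key {key!r}")
    raw = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    for req in ("sequences", "references"):
        if req not in raw:
            errors.append(f"missing required key {req!r}")
    cfg = None
    if not errors:
        cfg = PipelineConfig(**raw)
        for attr in ("sequences", "references", "anchors", "hit_table", "msa",
                     "signatures", "outgroup"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).exists():
                errors.append(f"{attr}: file not found: {value}")
        if cfg.min_identity < 0 or cfg.min_identity > 100:
            errors.append("min_identity must be in [0, 100]")
        if cfg.max_evalue <= 0:
            errors.append("max_evalue must be positive")
        if not 0 < cfg.nterm_fraction <= 1:
            errors.append("nterm_fraction must be in (0, 1]")
        if cfg.phylo_correction not in ("none", "poisson"):
            errors.append("phylo_correction must be 'none' or 'poisson'")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    log.info("effective config: %s", asdict(cfg))
    return cfg


def load_anchors(path: str | Path) -> dict[str, ReferenceAnchor]:
    raw = yaml.safe_load(Path(path).read_text())
    anchors = {}
    for kingdom, spec in raw.items():
        anchors[kingdom] = ReferenceAnchor(
            spec["reference_id"],
            tuple(spec["typing_positions"]),
            tuple(spec["catalytic_positions"]),
        )
    return anchors


def write_anchors(anchors: dict[str, ReferenceAnchor], path: str | Path) -> None:
    out = {
        kd: {
            "reference_id": a.reference_id,
            "typing_positions": list(a.typing_positions),
            "catalytic_positions": list(a.catalytic_positions),
        }
        for kd, a in anchors.items()
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def _reference_signature_positions(
    reference: ProteinRecord, patterns, params: screen.ScreenParams
) -> dict[str, list[int]]:
    """Reference residue numbers (1-based) spanned by the reference's own
    PS00623/PS00624 instances; these number the logo columns."""
    n = len(reference)
    windows = {
        "ps00623": (0, int(n * params.nterm_fraction)),
        "ps00624": (int(n * params.central_start_fraction), int(n * params.central_end_fraction)),
    }
    out = {}
    for pid, window in windows.items():
        hits = motifs.scan(patterns[pid], reference, window)
        if hits:
            out[pid] = list(range(hits[0].start + 1, hits[0].end + 1))
    return out


@dataclass
class PipelineReport:
    summary: dict
    outputs: dict[str, str]


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs[name] = str(path)
        return path

    # --- inputs ---------------------------------------------------------
    try:
        records = read_fasta(config.sequences)
        refs_list = read_fasta(config.references)
        references = {r.kingdom: r for r in refs_list if r.kingdom}
        if not references:
            raise ValueError("reference FASTA carries no kingdom= annotations")
        if config.anchors:
            anchors = load_anchors(config.anchors)
        else:
            anchors = {kd: KINGDOM_ANCHORS[kd] for kd in references}
        patterns = (
            motifs.load_signatures(config.signatures)
            if config.signatures
            else {pid: motifs.parse_prosite(text, pid) for pid, text in SIGNATURES.items()}
        )
        hits = screen.parse_hit_table(config.hit_table) if config.hit_table else None
        outgroup = read_fasta(config.outgroup) if config.outgroup else []
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load_inputs", exc) from exc
    log.info("loaded %d sequences, %d references", len(records), len(references))

    params = config.screen_params()
    summary: dict = {
        "n_input": len(records),
        "n_retained": 0,
        "n_rejected": 0,
        "type_counts": {},
        "monophyly": {},
    }
    manifest = {
        "aaokit_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_input_sequences": len(records),
    }
    emit("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True)))
    if not records:
        emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)))
        return PipelineReport(summary, outputs)

    # --- screen ---------------------------------------------------------
    try:
        retained, reports, kingdoms = screen.select_candidates(
            records, hits, references, anchors, patterns, params
        )
    except Exception as exc:
        raise StageError("screen", exc) from exc
    summary["n_retained"] = len(retained)
    summary["n_rejected"] = len(records) - len(retained)
    emit("feature_reports.tsv", lambda p: screen.write_feature_reports(reports, p))
    emit("retained.fasta", lambda p: write_fasta(retained, p))
    log.info("screen: retained %d / %d", len(retained), len(records))

    # --- type -----------------------------------------------------------
    try:
        calls = []
        for rec in retained:
            kd = kingdoms[rec.id]
            aln = global_align(references[kd], rec, params.align_params)
            pmap = map_positions(aln, anchors[kd])
            calls.append(classify_mod.classify(rec, kd, pmap, anchors[kd]))
    except Exception as exc:
        raise StageError("type", exc) from exc
    summary["type_counts"] = classify_mod.type_counts(calls)
    emit("type_calls.tsv", lambda p: classify_mod.write_type_calls(calls, p))
    emit(
        "type_counts.json",
        lambda p: p.write_text(json.dumps(summary["type_counts"], indent=2, sort_keys=True)),
    )
    labels = {c.seq_id: f"{c.kingdom}:{c.label}" for c in calls}

    # --- logos ----------------------------------------------------------
    try:
        supplied_msa = None
        if config.msa:
            rows = read_fasta(config.msa)
            supplied_msa = Msa([r.id for r in rows], [r.sequence for r in rows])
        kingdom_msas: dict[str, Msa] = {}
        for kd, ref in sorted(references.items()):
            members = [r for r in retained if kingdoms[r.id] == kd]
            if not members:
                continue
            if supplied_msa is not None and ref.id in supplied_msa.ids:
                wanted = {ref.id} | {m.id for m in members}
                rows = [r for i, r in zip(supplied_msa.ids, supplied_msa.rows) if i in wanted]
                ids = [i for i in supplied_msa.ids if i in wanted]
                kingdom_msas[kd] = Msa(ids, rows)
            else:
                kingdom_msas[kd] = progressive_msa([ref] + members)
            positions = _reference_signature_positions(ref, patterns, params)
            for pid, cols in positions.items():
                logo_cols, warns = logos.build_logo(kingdom_msas[kd], ref.id, cols)
                for w in warns:
                    log.warning("logo %s/%s: %s", kd, pid, w)
                emit(f"logo_{kd}_{pid}.tsv", lambda p, lc=logo_cols: logos.write_logo_tsv(lc, p))
    except Exception as exc:
        raise StageError("logo", exc) from exc

    # --- phylogeny ------------------------------------------------------
    tree_taxa = retained + outgroup
    if len(tree_taxa) >= 3:
        try:
            if supplied_msa is not None and all(
                r.id in supplied_msa.ids for r in tree_taxa
            ):
                wanted = {r.id for r in tree_taxa}
                msa = Msa(
                    [i for i in supplied_msa.ids if i in wanted],
                    [r for i, r in zip(supplied_msa.ids, supplied_msa.rows) if i in wanted],
                )
            else:
                msa = progressive_msa(tree_taxa)
            dm = phylo.p_distance_matrix(msa, config.phylo_correction)
            emit("distance_matrix.tsv", lambda p: dm.write_tsv(p))
            tree = phylo.neighbor_joining(dm)
            if outgroup:
                tree = phylo.root_with_outgroup(tree, [r.id for r in outgroup])
                tree_labels = dict(labels)
                for r in outgroup:
                    tree_labels[r.id] = "outgroup"
                mono = phylo.monophyly_report(tree, tree_labels)
                summary["monophyly"] = {
                    lab: {
                        "is_monophyletic": m.is_monophyletic,
                        "clade_purity": m.clade_purity,
                        "clade_size": m.clade_size,
                    }
                    for lab, m in mono.items()
                }
                emit(
                    "monophyly.json",
                    lambda p: p.write_text(
                        json.dumps(summary["monophyly"], indent=2, sort_keys=True)
                    ),
                )
            emit("tree.nwk", lambda p: p.write_text(phylo.to_newick(tree) + "\n"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("phylo", exc) from exc

    emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)))
    log.info("pipeline complete: %s", summary)
    return PipelineReport(summary, outputs)
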