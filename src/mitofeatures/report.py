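"""Full-pipeline orchestration and the consolidated JSON report.

Runs annotation arithmetic, composition, codon usage, tRNA folding and
control-region scans over one genome + feature table, degrading gracefully
when inputs for a stage are missing (stage marked ``skipped``) or a stage
fails (marked ``failed`` with its diagnostic, never an unhandled raise).
The report serializes to JSON and back without loss; all thresholds are
carried in a validated :class:`PipelineConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Any

from pydantic import BaseModel, Field

from . import __version__
from .annotation import (
    FeatureTable,
    check_bicistron_motif,
    genome_length,
    junction_ledger,
    summarize_junctions,
)
from .codon_usage import count_codons, start_stop_report
from .composition import composition_table
from .control_region import (
    detect_flanking_motifs,
    find_poly_runs,
    find_stem_loops,
    find_tandem_repeats,
    segment_control_region,
)
from .genes import N
from .trna import FoldFailure, fold_cloverleaf, pair_census


class PipelineConfig(BaseModel):
    """All tunable thresholds, with published-analysis defaults."""

    poly_min_len: int = Field(default=7, ge=2)
    repeat_min_period: int = Field(default=2, ge=2)
    repeat_max_period: int = Field(default=200, ge=2)
    repeat_min_copies: float = Field(default=2.0, ge=2.0)
    repeat_min_identity: float = Field(default=0.8, gt=0, le=1)
    hairpin_min_stem: int = Field(default=10, ge=4)
    hairpin_loop_min: int = Field(default=3, ge=3)
    hairpin_loop_max: int = Field(default=20, ge=3)
    hairpin_max_mismatch: int = Field(default=2, ge=0)
    motif_window: int = Field(default=20, ge=4)
    csb_min_len: int = Field(default=15, ge=2)
    csb_min_identity_class: int = Field(default=50)
    split_serine: bool = False
    bicistron_pairs: tuple[tuple[str, str], ...] = (
        ("ATP8", "ATP6"),
        ("ND4L", "ND4"),
    )


@dataclass
class StageResult:
    status: str  # ok | skipped | failed
    payload: Any = None
    error: str | None = None


@dataclass
class AnalysisReport:
    """Consolidated per-stage results plus provenance."""

    stages: dict[str, StageResult]
    provenance: dict[str, Any]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        raw = json.loads(text)
        return cls(
            stages={k: StageResult(**v) for k, v in raw["stages"].items()},
            provenance=raw["provenance"],
        )


def _run_stage(stages: dict, name: str, fn) -> None:
    try:
        # normalize to JSON-native types so serialize/deserialize is lossless
        payload = json.loads(json.dumps(fn(), default=str))
        stages[name] = StageResult(status="ok", payload=payload)
    except Exception as exc:  # recorded, not raised: partial inputs degrade
        stages[name] = StageResult(status="failed", error=f"{type(exc).__name__}: {exc}")


def run_full_pipeline(
    genome: str | None,
    table: FeatureTable | None,
    config: PipelineConfig | dict | None = None,
) -> AnalysisReport:
    """Execute every stage the inputs allow; see module docstring."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    stages: dict[str, StageResult] = {}

    if table is not None:
        def annotation_stage():
            ledger = junction_ledger(table)
            summary = summarize_junctions(ledger)
            return {
                "genome_length": genome_length(table),
                "n_features": len(table),
                "junctions": [asdict(r) for r in ledger],
                "summary": asdict(summary),
            }

        _run_stage(stages, "annotation", annotation_stage)
    else:
        stages["annotation"] = StageResult(status="skipped")

    if genome is not None and table is not None:
        def composition_stage():
            return composition_table(genome, table).to_dict(orient="records")

        def codon_stage():
            usage = count_codons(genome, table, split_serine=config.split_serine)
            return {
                "usage": usage.to_dataframe().to_dict(orient="records"),
                "skipped_ambiguous": usage.skipped_ambiguous,
                "start_stop": [asdict(r) for r in start_stop_report(genome, table)],
                "bicistrons": [
                    asdict(check_bicistron_motif(genome, table, pair))
                    for pair in config.bicistron_pairs
                    if all(_has(table, g) for g in pair)
                ],
            }

        def trna_stage():
            out = []
            for f in table.trnas:
                if f.anticodon_start is None:
                    continue
                if f.direction == N:
                    offset = f.end - (f.anticodon_end or f.anticodon_start) + 1
                else:
                    offset = f.anticodon_start - f.start + 1
                seq = f.sequence(genome)
                folded = fold_cloverleaf(seq, offset)
                if isinstance(folded, FoldFailure):
                    out.append({"gene": f.name, "fold": "failed", "reason": folded.reason})
                    continue
                census = pair_census(folded, seq)
                out.append(
                    {
                        "gene": f.name,
                        "dhu_present": folded.dhu_present,
                        "dot_bracket": folded.dot_bracket(),
                        "wc": census.total_wc,
                        "gu": census.total_gu,
                        "mismatch": census.total_mismatch,
                    }
                )
            return out

        def cr_stage():
            cr_feats = [f for f in table.features if f.gene_class == "CR"]
            if not cr_feats:
                raise ValueError("no control region annotated")
            cr = cr_feats[0]
            seq = genome[cr.slice]
            seg = segment_control_region(
                seq,
                min_period=config.repeat_min_period,
                max_period=config.repeat_max_period,
                min_copies=config.repeat_min_copies,
                min_identity=config.repeat_min_identity,
            )
            hairpins = find_stem_loops(
                seq,
                min_stem=config.hairpin_min_stem,
                loop_range=(config.hairpin_loop_min, config.hairpin_loop_max),
                max_mismatch=config.hairpin_max_mismatch,
            )
            hairpins = [detect_flanking_motifs(seq, sl, config.motif_window) for sl in hairpins]
            return {
                "cr_span": (cr.start, cr.end),
                "segmentation": asdict(seg),
                "poly_runs": [asdict(r) for r in find_poly_runs(seq, config.poly_min_len)],
                "repeats": [
                    asdict(r) for r in find_tandem_repeats(
                        seq,
                        min_period=config.repeat_min_period,
                        max_period=config.repeat_max_period,
                        min_copies=config.repeat_min_copies,
                        min_identity=config.repeat_min_identity,
                    )
                ],
                "stem_loops": [asdict(sl) for sl in hairpins],
            }

        _run_stage(stages, "composition", composition_stage)
        _run_stage(stages, "codon_usage", codon_stage)
        _run_stage(stages, "trna", trna_stage)
        _run_stage(stages, "control_region", cr_stage)
    else:
        for name in ("composition", "codon_usage", "trna", "control_region"):
            stages[name] = StageResult(status="skipped")

    provenance = {
        "version": __version__,
        "config": config.model_dump(),
        "genome_sha1": (
            hashlib.sha1(str(genome).encode()).hexdigest() if genome else None
        ),
        "n_features": len(table) if table is not None else None,
    }
    provenance = json.loads(json.dumps(provenance, default=str))
    return AnalysisReport(stages=stages, provenance=provenance)


def _has(table: FeatureTable, gene: str) -> bool:
    try:
        table[gene]
        return True
    except KeyError:
        return False
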