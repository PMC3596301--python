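"""End-to-end drivers tying scan -> annotate -> compare together, for both
simulated and on-disk inputs."""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy

from . import io as sio
from .annotate import AnnotateParams, GenomeAnnotation, annotate_genome
from .compare import (
    CompareParams,
    PresenceAbsenceMatrix,
    build_matrix,
    event_recovery,
    place_events,
)
from .records import EvolutionEvent, GenomeRecord
from .scan import ScanParams, scan_genome
from .simulate import SimulationResult


@dataclass
class PipelineResult:
    annotations: dict[str, GenomeAnnotation]
    matrix: PresenceAbsenceMatrix
    events: list[EvolutionEvent]


def analyze_genomes(
    genomes: dict[str, GenomeRecord],
    references: dict[str, str],
    rrna: str,
    scan_params: ScanParams | None = None,
    annotate_params: AnnotateParams | None = None,
) -> dict[str, GenomeAnnotation]:
    out: dict[str, GenomeAnnotation] = {}
    for label, genome in sorted(genomes.items()):
        snos = scan_genome(genome, references, rrna, scan_params)
        out[label] = annotate_genome(genome, snos, annotate_params)
    return out


def run_pipeline(
    genomes: dict[str, GenomeRecord],
    references: dict[str, str],
    rrna: str,
    tree: dendropy.Tree,
    scan_params: ScanParams | None = None,
    annotate_params: AnnotateParams | None = None,
    compare_params: CompareParams | None = None,
) -> PipelineResult:
    annotations = analyze_genomes(genomes, references, rrna, scan_params,
                                  annotate_params)
    families = list(references)
    matrix = build_matrix(annotations, families=families, params=compare_params)
    events = place_events(matrix, tree, annotations, family_order=families,
                          params=compare_params)
    return PipelineResult(annotations=annotations, matrix=matrix, events=events)


def run_pipeline_on_simulation(
    result: SimulationResult,
    scan_params: ScanParams | None = None,
    annotate_params: AnnotateParams | None = None,
    compare_params: CompareParams | None = None,
) -> PipelineResult:
    genomes = {label: leaf.record for label, leaf in result.leaves.items()}
    return run_pipeline(
        genomes, result.references, result.rrna, result.tree,
        scan_params, annotate_params, compare_params,
    )


def benchmark_recovery(result: SimulationResult,
                       pipeline: PipelineResult) -> dict[str, float]:
    return event_recovery(result.events, pipeline.events)


def write_detected_gff3(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Detected snoRNAs + introns in the same canonical GFF3 layout used for
    simulator truth output."""
    sio.write_gff3(
        list(ann.snornas) + list(ann.introns),
        path,
        record_lengths={ann.genome.record_id: ann.genome.length},
    )


def events_table(events: list[EvolutionEvent]):
    import pandas as pd

    rows = []
    for ev in events:
        etype = ev.evidence[0].kind if ev.evidence else "."
        detail = ev.evidence[0].detail if ev.evidence else {}
        rows.append(
            {
                "kind": ev.kind,
                "branch": ev.branch,
                "subject": ev.subject,
                "evidence_type": etype,
                "evidence_detail": ";".join(f"{k}={v}" for k, v in sorted(detail.items())),
                "confidence": ev.confidence,
            }
        )
    return pd.DataFrame(
        rows, columns=["kind", "branch", "subject", "evidence_type",
                       "evidence_detail", "confidence"],
    ).sort_values(["branch", "kind", "subject"]).reset_index(drop=True)
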