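"""End-to-end orchestration: reads -> clusters -> fractions -> enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .cluster import ClusterParams, ClusterTable, cluster, dereplicate
from .design import LibraryDesign, SampleSheet
from .quantify import (
    EnrichmentTable,
    PoolFractionTable,
    enrichment_from_clusters,
)
from .readprep import DemuxReport, FilterReport, ReadPair, iter_read_pairs, process_run


@dataclass
class PipelineResult:
    cluster_table: ClusterTable
    fractions: PoolFractionTable
    enrichment: EnrichmentTable
    demux_report: DemuxReport
    filter_report: FilterReport


def analyze_pairs(
    pairs: Iterable[ReadPair],
    design: LibraryDesign,
    sheet: SampleSheet,
    cluster_params: ClusterParams = ClusterParams(),
    barcode_mismatch: int = 0,
    constant_mismatch: int = 0,
    min_overlap: int = 10,
    input_sample: str | None = None,
) -> PipelineResult:
    """Run the full analysis on one lane of barcoded read pairs."""
    records, demux_report, filter_report = process_run(
        pairs, design, sheet, barcode_mismatch, constant_mismatch, min_overlap
    )
    table = cluster(dereplicate(records), cluster_params, sample_order=sheet.sample_ids)
    fractions, enrichment = enrichment_from_clusters(
        table,
        input_sample or sheet.input_sample(),
        sheet.wt_samples(),
        sheet.branches(),
    )
    return PipelineResult(table, fractions, enrichment, demux_report, filter_report)


def analyze_fastq(
    r1_path,
    r2_path,
    design: LibraryDesign,
    sheet: SampleSheet,
    **kwargs,
) -> PipelineResult:
    return analyze_pairs(iter_read_pairs(r1_path, r2_path), design, sheet, **kwargs)
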