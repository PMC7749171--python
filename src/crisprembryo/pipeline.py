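"""End-to-end orchestration: pooled reads -> per-embryo classifications.

Chains the stage modules in run order (CCS quality filter, barcode
demultiplexing, per-embryo allele calling, mosaicism classification,
group summaries) with the study's default thresholds: minimum 3 passes,
99% predicted accuracy, 700 bp maximum length; allele noise floor of
2 reads and 1% of reads; embryo QC minimum of 20 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alleles import AlleleTable, call_alleles
from .mosaic import (
    AUTOSOMAL,
    X_LINKED_MALE,
    EmbryoClassification,
    GroupSummary,
    classify_embryo,
    summarize_group,
)
from .reads import BarcodeSheet, CcsRead, demultiplex, filter_ccs
from .synthetic import AmpliconTarget


@dataclass
class PipelineResult:
    tables: dict[str, AlleleTable]
    classifications: list[EmbryoClassification]
    summaries: list[GroupSummary] = field(default_factory=list)
    n_input_reads: int = 0
    n_filtered_reads: int = 0
    n_unassigned: int = 0


def run_study_pipeline(
    reads: Sequence[CcsRead],
    sheet: BarcodeSheet,
    amplicons: dict[str, AmpliconTarget],
    min_passes: int = 3,
    min_accuracy: float = 0.99,
    max_length: int = 700,
    max_barcode_mismatch: int = 1,
    window: int = 10,
    min_reads_per_allele: int = 2,
    min_fraction_per_allele: float = 0.01,
    min_total_reads: int = 20,
    het_tolerance: float = 0.15,
) -> PipelineResult:
    """Run filter -> demux -> allele calling -> classification and
    summarize per (locus, cas9_form) group. X-linked loci in male
    embryos (per the sample sheet's sex column, locus "ZFX") are
    classified hemizygously."""
    kept, _rej = filter_ccs(reads, min_passes, min_accuracy, max_length)
    assigned, unassigned = demultiplex(kept, sheet, max_barcode_mismatch)
    tables: dict[str, AlleleTable] = {}
    classifications: list[EmbryoClassification] = []
    for sample in sheet:
        amp = amplicons[sample.locus]
        sample_reads = assigned[sample.sample_id]
        if sample_reads:
            table = call_alleles(
                sample_reads,
                amp.sequence,
                amp.cut_site,
                window=window,
                min_reads_per_allele=min_reads_per_allele,
                min_fraction_per_allele=min_fraction_per_allele,
                embryo_id=sample.sample_id,
                locus=sample.locus,
            )
        else:
            table = AlleleTable(
                embryo_id=sample.sample_id, locus=sample.locus,
                total_reads=0, rows=[], qc_pass=False,
            )
        tables[sample.sample_id] = table
        ploidy = (
            X_LINKED_MALE
            if sample.locus == "ZFX" and sample.sex == "male"
            else AUTOSOMAL
        )
        cls = classify_embryo(
            table, ploidy_mode=ploidy, het_tolerance=het_tolerance,
            min_total_reads=min_total_reads,
        )
        cls.cas9_form = sample.cas9_form
        classifications.append(cls)
    groups = sorted(
        {(s.locus, s.cas9_form) for s in sheet}
    )
    summaries = []
    by_sample = {c.embryo_id: c for c in classifications}
    for locus, form in groups:
        members = [
            by_sample[s.sample_id]
            for s in sheet
            if s.locus == locus and s.cas9_form == form
        ]
        summary = summarize_group(members, group=(locus, form))
        if summary is not None:
            summaries.append(summary)
    return PipelineResult(
        tables=tables,
        classifications=classifications,
        summaries=summaries,
        n_input_reads=len(reads),
        n_filtered_reads=len(kept),
        n_unassigned=len(unassigned),
    )
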