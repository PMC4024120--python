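"""End-to-end orchestration: prefilter -> cascade -> concordance -> CNV -> triage.

The pipeline mirrors the reporting surfaces of a diagnostic panel run:
per-caller cascade flow counts, the dual-caller concordance table, CNV
calls and coverage QC from the depth tracks, and the per-sample
diagnosis summary (two mutations in one gene / one mutation / none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cnv import (
    CnvCall,
    CnvConfig,
    CoverageQcReport,
    DosageTable,
    ExonCoverageProfile,
    area_matrix,
    call_gross_indels,
    calls_to_frame,
    coverage_qc,
    floor_areas,
    normalize_and_ratio,
)
from .concordance import (
    ConcordanceRecord,
    TruthSet,
    annotate_truth,
    caller_specific_false_positives,
    merge_callsets,
    miss_rate,
    records_to_frame,
)
from .filters import CascadeReport, FilterConfig, run_cascade
from .panel import PanelDesign
from .triage import (
    DiagnosisRecord,
    FamilyGenotypes,
    assess_pathogenicity,
    classify_zygosity,
    diagnose_sample,
    diagnoses_to_frame,
)
from .variants import AnnotatedVariant, CohortCallTable, prefilter_callset


@dataclass
class PipelineResult:
    cascade_reports: dict[str, CascadeReport]
    decision_frames: dict[str, pd.DataFrame]
    survivors: dict[str, CohortCallTable]
    merged_records: dict[tuple, ConcordanceRecord]
    merged_survivor_table: CohortCallTable
    diagnoses: list[DiagnosisRecord]
    cnv_calls: list[CnvCall]
    dosage: DosageTable | None
    qc: CoverageQcReport | None
    miss_rates: dict[str, float] = field(default_factory=dict)
    fp_partition: tuple[set, set, set] | None = None

    def diagnosis_counts(self) -> dict[str, int]:
        counts = {"diagnosed": 0, "carrier": 0, "undiagnosed": 0}
        for d in self.diagnoses:
            counts[d.status] += 1
        return counts


def _merge_survivors(
    tables: dict[str, CohortCallTable]
) -> tuple[CohortCallTable, dict[tuple, ConcordanceRecord]]:
    """Union the per-caller survivor sets, keeping one record per
    (sample, site) — the call with the deepest quality wins."""
    callers = list(tables)
    records = merge_callsets(
        tables[callers[0]].variants,
        tables[callers[1]].variants if len(callers) > 1 else [],
        caller_a=callers[0],
        caller_b=callers[1] if len(callers) > 1 else "none",
    )
    best: dict[tuple, AnnotatedVariant] = {}
    for table in tables.values():
        for v in table.variants:
            cur = best.get(v.sample_key)
            if cur is None or (v.quality.depth or 0) > (cur.quality.depth or 0):
                best[v.sample_key] = v
    any_table = next(iter(tables.values()))
    merged = CohortCallTable(
        variants=list(best.values()),
        samples=any_table.samples,
        batch_id=any_table.batch_id,
    )
    return merged, records


def run_pipeline(
    panel: PanelDesign,
    callsets: dict[str, CohortCallTable],
    profiles: list[ExonCoverageProfile] | None = None,
    filter_config: FilterConfig | None = None,
    cnv_config: CnvConfig | None = None,
    truth: TruthSet | None = None,
    predictions: dict[tuple, list[str]] | None = None,
    family: FamilyGenotypes | None = None,
    inheritance: dict[str, str] | None = None,
    mappability_mask: list[tuple[str, int, int]] | None = None,
    sample_sex: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full prioritization pipeline over per-caller call tables."""
    filter_config = filter_config or FilterConfig()
    cnv_config = cnv_config or CnvConfig()
    x_genes = {g for g, m in (inheritance or {}).items() if m == "XL"}

    # stage 1+2: prefilter and cascade, per caller
    reports: dict[str, CascadeReport] = {}
    frames: dict[str, pd.DataFrame] = {}
    survivors: dict[str, CohortCallTable] = {}
    for caller, table in callsets.items():
        pre = prefilter_callset(table, mappability_mask)
        surv, report, frame = run_cascade(pre, filter_config)
        reports[caller] = report
        frames[caller] = frame
        survivors[caller] = surv

    # stage 3: concordance over surviving calls
    merged_table, records = _merge_survivors(survivors)
    miss_rates: dict[str, float] = {}
    fp_partition = None
    if truth is not None:
        annotate_truth(records, truth)
        callers = list(callsets)
        for caller, table in callsets.items():
            miss_rates[caller] = miss_rate(truth, table.variants)
        if len(callers) >= 2:
            raw_records = merge_callsets(
                callsets[callers[0]].variants,
                callsets[callers[1]].variants,
                caller_a=callers[0],
                caller_b=callers[1],
            )
            annotate_truth(raw_records, truth)
            fp_partition = caller_specific_false_positives(
                raw_records, callers[0], callers[1]
            )

    # stage 4: CNV + coverage QC from depth profiles
    dosage = None
    cnv_calls: list[CnvCall] = []
    qc = None
    if profiles:
        qc = coverage_qc(profiles, depth_threshold=int(cnv_config.floor_mean_depth))
        areas = area_matrix(profiles)
        floors = floor_areas(panel, cnv_config.floor_mean_depth).reindex(areas.columns)
        dosage = normalize_and_ratio(areas, floors)
        cnv_calls = call_gross_indels(dosage, cnv_config)

    # stage 5: triage on the merged surviving calls
    by_sample: dict[str, list[AnnotatedVariant]] = {
        s: [] for s in merged_table.samples
    }
    for v in merged_table.variants:
        by_sample[v.sample_id].append(v)
    diagnoses: list[DiagnosisRecord] = []
    for sample, variants in by_sample.items():
        assessed = []
        for v in variants:
            zyg = classify_zygosity(
                v.quality,
                target_is_x=v.gene in x_genes,
                sample_sex=(sample_sex or {}).get(sample, "unknown"),
                key=v.sample_key,
            )
            same_gene = [o for o in variants if o.gene == v.gene]
            a = assess_pathogenicity(
                v,
                same_gene_variants=same_gene,
                cohort=merged_table,
                family=family,
                predictions=predictions,
                zygosity=zyg,
            )
            assessed.append((v, a, zyg))
        diagnoses.append(
            diagnose_sample(sample, assessed, inheritance=inheritance, family=family)
        )

    return PipelineResult(
        cascade_reports=reports,
        decision_frames=frames,
        survivors=survivors,
        merged_records=records,
        merged_survivor_table=merged_table,
        diagnoses=diagnoses,
        cnv_calls=cnv_calls,
        dosage=dosage,
        qc=qc,
        miss_rates=miss_rates,
        fp_partition=fp_partition,
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write every reporting surface as TSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    flow_rows = []
    for caller, report in result.cascade_reports.items():
        for stage, count in zip(
            ("input", "after_filter1", "after_filter2"),
            (report.n_input, report.n_after_filter1, report.n_after_filter2),
        ):
            flow_rows.append({"caller": caller, "stage": stage, "count": count})
    p = outdir / "cascade_flow.tsv"
    pd.DataFrame(flow_rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    for caller, frame in result.decision_frames.items():
        p = outdir / f"filter_decisions_{caller}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = outdir / "concordance.tsv"
    records_to_frame(result.merged_records).to_csv(p, sep="\t", index=False)
    written.append(p)

    p = outdir / "cnv_calls.tsv"
    calls_to_frame(result.cnv_calls).to_csv(p, sep="\t", index=False)
    written.append(p)

    if result.qc is not None:
        p = outdir / "coverage_qc.tsv"
        result.qc.per_exon.to_csv(p, sep="\t", index=False, float_format="%.2f")
        written.append(p)
        p = outdir / "coverage_qc_genes.tsv"
        result.qc.per_gene.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = outdir / "diagnosis_summary.tsv"
    diagnoses_to_frame(result.diagnoses).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written
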