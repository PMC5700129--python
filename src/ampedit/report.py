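"""Per-sample summaries, headline statistics, and pipeline orchestration.

The headline numbers are the HDR and NHEJ percentages of classified target
reads, their HDR:indel ratio (the precise-to-imprecise editing statistic),
and the fold enrichment of that ratio between two conditions.  Percentages
use target reads as the denominator (raw-read denominators are reported
alongside); a sample without NHEJ reads has an undefined ratio rather than
an infinite one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .classify import AlleleCall, ClassParams, classify_sample
from .locus_model import DonorSpec, LocusSpec
from .pairwise_align import ScoringScheme, events_to_cigar
from .preprocess import StageCounts, parse_fastq, preprocess_sample

__all__ = [
    "SampleSummary",
    "ComparisonResult",
    "summarize_sample",
    "summarize_clones",
    "compare_conditions",
    "run_pipeline",
    "allele_table",
    "write_sample_outputs",
]


@dataclass
class SampleSummary:
    sample_id: str
    n_raw: int = 0
    n_quality_pass: int = 0
    n_unique: int = 0
    n_freq_pass: int = 0
    n_target: int = 0
    reads_wt: int = 0
    reads_hdr: int = 0
    reads_nhej: int = 0
    reads_ambiguous: int = 0
    pct_hdr: Optional[float] = None
    pct_nhej: Optional[float] = None
    pct_hdr_of_raw: Optional[float] = None
    pct_nhej_of_raw: Optional[float] = None
    hdr_indel_ratio: Optional[float] = None
    ratio_defined: bool = False
    stage_counts: dict = field(default_factory=dict)

    @property
    def total_target_reads(self) -> int:
        return self.reads_wt + self.reads_hdr + self.reads_nhej + self.reads_ambiguous

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["total_target_reads"] = self.total_target_reads
        return d


@dataclass
class ComparisonResult:
    sample_id: str
    control_id: str
    fold_enrichment: Optional[float]
    defined: bool


def summarize_sample(
    calls: Sequence[AlleleCall],
    stage_counts: Optional[StageCounts] = None,
    sample_id: str = "sample",
    pseudocount: bool = False,
) -> SampleSummary:
    """Aggregate allele calls into the per-sample headline statistics.

    Percentages are computed over all classified target reads (ambiguous
    reads stay in the denominator but in neither numerator).  With
    ``pseudocount`` a +0.5 is added to both ratio counts, giving a finite
    ratio for zero-NHEJ samples; off by default.
    """
    summary = SampleSummary(sample_id=sample_id)
    for call in calls:
        if call.label == "WT":
            summary.reads_wt += call.count
        elif call.label == "HDR":
            summary.reads_hdr += call.count
        elif call.label == "NHEJ":
            summary.reads_nhej += call.count
        else:
            summary.reads_ambiguous += call.count
    total = summary.total_target_reads
    if stage_counts is not None:
        summary.n_raw = stage_counts.n_raw
        summary.n_quality_pass = stage_counts.n_quality_pass
        summary.n_unique = stage_counts.n_unique
        summary.n_freq_pass = stage_counts.n_freq_pass
        summary.n_target = stage_counts.n_target
        summary.stage_counts = stage_counts.as_dict()
    if total > 0:
        summary.pct_hdr = 100.0 * summary.reads_hdr / total
        summary.pct_nhej = 100.0 * summary.reads_nhej / total
        if summary.n_raw > 0:
            summary.pct_hdr_of_raw = 100.0 * summary.reads_hdr / summary.n_raw
            summary.pct_nhej_of_raw = 100.0 * summary.reads_nhej / summary.n_raw
    if pseudocount:
        summary.hdr_indel_ratio = (summary.reads_hdr + 0.5) / (summary.reads_nhej + 0.5)
        summary.ratio_defined = True
    elif summary.reads_nhej > 0:
        summary.hdr_indel_ratio = summary.reads_hdr / summary.reads_nhej
        summary.ratio_defined = True
    return summary


def summarize_clones(labels: Iterable[str], sample_id: str = "clones") -> SampleSummary:
    """Clone-mode input: one genotype label per isolated clone (count 1 each).

    Lets clonal Sanger genotyping runs (WT/HDR/NHEJ per clone) flow through
    the same ratio statistic as deep-sequencing reads.
    """
    calls = [AlleleCall(sequence="", count=1, label=label) for label in labels]
    return summarize_sample(calls, sample_id=sample_id)


def compare_conditions(sample: SampleSummary, control: SampleSummary) -> ComparisonResult:
    """Fold enrichment of the sample's HDR:indel ratio over the control's."""
    defined = (
        sample.ratio_defined
        and control.ratio_defined
        and control.hdr_indel_ratio is not None
        and control.hdr_indel_ratio > 0
    )
    fold = None
    if defined:
        fold = sample.hdr_indel_ratio / control.hdr_indel_ratio  # type: ignore[operator]
    return ComparisonResult(sample.sample_id, control.sample_id, fold, defined)


def allele_table(calls: Sequence[AlleleCall]) -> pd.DataFrame:
    """Per-allele report: sequence, count, label, event CIGAR, audit flags."""
    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in calls],
            "count": [c.count for c in calls],
            "label": [c.label for c in calls],
            "cigar": [events_to_cigar(c.events) for c in calls],
            "hdr_marker_present": [c.hdr_marker_present for c in calls],
            "indel_in_window": [c.indel_in_window for c in calls],
        }
    )


@dataclass
class PipelineResult:
    sample_id: str
    calls: List[AlleleCall]
    summary: SampleSummary
    stage_counts: StageCounts


def run_sample(
    fastq_path,
    locus: LocusSpec,
    donor: Optional[DonorSpec],
    sample_id: Optional[str] = None,
    min_mean_q: float = 20.0,
    min_count: int = 10,
    max_primer_mismatch: int = 0,
    params: Optional[ClassParams] = None,
    scoring: Optional[ScoringScheme] = None,
) -> PipelineResult:
    """Preprocess, align, classify, and summarize one FASTQ sample."""
    sample_id = sample_id or Path(str(fastq_path)).stem
    reads = parse_fastq(fastq_path)
    targets, stage_counts = preprocess_sample(
        reads, locus, min_mean_q=min_mean_q, min_count=min_count,
        max_primer_mismatch=max_primer_mismatch,
    )
    calls = classify_sample(targets, locus, donor, params, scoring)
    summary = summarize_sample(calls, stage_counts, sample_id=sample_id)
    return PipelineResult(sample_id, calls, summary, stage_counts)


def write_sample_outputs(result: PipelineResult, out_dir) -> dict:
    """Write the per-allele TSV and per-sample JSON summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alleles_path = out_dir / f"{result.sample_id}.alleles.tsv"
    summary_path = out_dir / f"{result.sample_id}.summary.json"
    allele_table(result.calls).to_csv(alleles_path, sep="\t", index=False)
    with open(summary_path, "w") as fh:
        json.dump(result.summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"alleles": str(alleles_path), "summary": str(summary_path)}


def run_pipeline(
    fastq_paths: Sequence,
    locus: LocusSpec,
    donor: Optional[DonorSpec],
    out_dir=None,
    control_index: Optional[int] = None,
    **kwargs,
) -> tuple[List[PipelineResult], List[ComparisonResult]]:
    """Run the full pipeline over one or more samples.

    When ``control_index`` is given, every other sample is compared against
    that control and a comparison TSV is written alongside the per-sample
    outputs.  The pipeline is deterministic: identical inputs produce
    byte-identical reports.
    """
    results = [
        run_sample(path, locus, donor, **kwargs) for path in fastq_paths
    ]
    comparisons: List[ComparisonResult] = []
    if control_index is not None:
        control = results[control_index].summary
        for i, res in enumerate(results):
            if i != control_index:
                comparisons.append(compare_conditions(res.summary, control))
    if out_dir is not None:
        for res in results:
            write_sample_outputs(res, out_dir)
        if comparisons:
            pd.DataFrame(
                {
                    "sample_id": [c.sample_id for c in comparisons],
                    "control_id": [c.control_id for c in comparisons],
                    "fold_enrichment": [c.fold_enrichment for c in comparisons],
                    "defined": [c.defined for c in comparisons],
                }
            ).to_csv(Path(out_dir) / "comparisons.tsv", sep="\t", index=False)
    return results, comparisons
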